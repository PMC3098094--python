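"""Iterative classification-EM clustering of sequences.

Each cluster is modeled by an interpolated context model (or, in "oracle"
mode, an exact maximum-likelihood fixed-order chain).  The loop alternates
(1) retraining models on the current members and (2) reassigning every
sequence to the cluster maximizing ``log p_k + log P(s | model_k)``, and
halts when fewer than a configured fraction of sequences change clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import imm
from .chains import FixedOrderChain
from .imm import IcmConfig, IcmModel
from .io_core import Assignment, SequenceSet

__all__ = [
    "ClusterState",
    "ClassificationTable",
    "IterationLog",
    "cml_criterion",
    "assign_step",
    "retrain_step",
    "run_scimm",
    "one_iteration",
    "physcimm_seed",
    "compact_assignment",
]

logger = logging.getLogger(__name__)

#: rows of (sequence id, taxon label); sequences absent are "unclassified"
ClassificationTable = Dict[str, str]


@dataclass
class IterationLog:
    iteration: int
    n_changed: int
    frac_changed: float
    cml: float


@dataclass
class ClusterState:
    assignment: Assignment
    models: List[object]
    priors: np.ndarray
    cml: float
    iteration: int
    converged: bool = False
    history: List[IterationLog] = field(default_factory=list)


def compact_assignment(assignment: Assignment) -> Assignment:
    """Relabel clusters to a contiguous 0..K-1 range (order of first use
    by ascending original label)."""
    labels = sorted(set(assignment.values()))
    remap = {lab: i for i, lab in enumerate(labels)}
    return {sid: remap[lab] for sid, lab in assignment.items()}


# ---------------------------------------------------------------------------
# model backends


class IcmBackend:
    """Shared window corpus for training and scoring ICMs over one set."""

    def __init__(self, sset: SequenceSet, cfg: IcmConfig):
        self.sset = sset
        self.cfg = cfg
        w = cfg.w
        too_short = [rec.id for rec in sset if len(rec) <= w]
        if too_short:
            raise ValueError(
                f"sequences not longer than w={w} cannot be scored: {too_short[:10]}"
            )
        ctx_parts, out_parts, valid_parts, counts = [], [], [], []
        for rec in sset:
            contexts, outcomes, valid = imm._windows_of_codes(rec.codes, w)
            ctx_parts.append(contexts)
            out_parts.append(outcomes)
            valid_parts.append(valid)
            counts.append(len(outcomes))
        self.contexts = np.ascontiguousarray(np.concatenate(ctx_parts))
        self.outcomes = np.concatenate(out_parts)
        self.valid = np.concatenate(valid_parts)
        self.offsets = np.concatenate([[0], np.cumsum(counts)])

    def _window_rows(self, member_idx: np.ndarray) -> np.ndarray:
        rows = np.concatenate(
            [np.arange(self.offsets[i], self.offsets[i + 1]) for i in member_idx]
        )
        return rows[self.valid[rows]]

    def train(self, member_idx: np.ndarray) -> IcmModel:
        rows = self._window_rows(member_idx)
        corpus = imm.ContextCorpus(
            w=self.cfg.w, contexts=self.contexts[rows], outcomes=self.outcomes[rows]
        )
        bp = int(self.sset.lengths[member_idx].sum())
        return imm.train_icm_from_corpus(corpus, self.cfg, trained_bp=bp)

    def score_all(self, model: IcmModel) -> np.ndarray:
        logp = imm.position_log_probs(model, self.contexts, self.outcomes, self.valid)
        sums = np.add.reduceat(logp, self.offsets[:-1])
        sums[self.offsets[:-1] == self.offsets[1:]] = 0.0  # no scoreable positions
        return sums


class FixedBackend:
    """Fixed-order chain models; exact ML when ``pseudocount`` is 0."""

    def __init__(self, sset: SequenceSet, order: int, pseudocount: float = 0.0):
        self.sset = sset
        self.order = order
        self.pseudocount = pseudocount
        too_short = [rec.id for rec in sset if len(rec) <= order]
        if too_short:
            raise ValueError(
                f"sequences not longer than order={order} cannot be scored: {too_short[:10]}"
            )

    def train(self, member_idx: np.ndarray) -> FixedOrderChain:
        return FixedOrderChain.fit(
            [self.sset[int(i)] for i in member_idx], self.order, self.pseudocount
        )

    def score_all(self, model: FixedOrderChain) -> np.ndarray:
        return model.score_set(self.sset)


def make_backend(
    sset: SequenceSet,
    model: str = "icm",
    icm_config: Optional[IcmConfig] = None,
    w: int = 8,
    order: int = 3,
    pseudocount: float = 0.0,
):
    if model == "icm":
        return IcmBackend(sset, icm_config or IcmConfig(w=w))
    if model == "fixed":
        return FixedBackend(sset, order=order, pseudocount=pseudocount)
    raise ValueError(f"unknown model backend {model!r}")


# ---------------------------------------------------------------------------
# CEM steps


def _labels_for(sset: SequenceSet, assignment: Assignment) -> Tuple[np.ndarray, np.ndarray]:
    """(indices of covered sequences, their labels) for ``assignment``."""
    idx, labels = [], []
    for i, rec in enumerate(sset):
        if rec.id in assignment:
            idx.append(i)
            labels.append(assignment[rec.id])
    return np.array(idx, dtype=np.intp), np.array(labels, dtype=np.intp)


def retrain_step(
    sset: SequenceSet,
    assignment: Assignment,
    backend,
    prior_mode: str = "bp",
) -> Tuple[List[object], np.ndarray]:
    """Train one model per cluster; priors are bp (or count) shares of the
    training members."""
    idx, labels = _labels_for(sset, assignment)
    if len(idx) == 0:
        raise ValueError("assignment covers no sequence in the set")
    k = int(labels.max()) + 1
    lengths = sset.lengths
    models: List[object] = []
    weights = np.zeros(k)
    for c in range(k):
        members = idx[labels == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty; compact the assignment first")
        models.append(backend.train(members))
        weights[c] = lengths[members].sum() if prior_mode == "bp" else len(members)
    priors = weights / weights.sum()
    return models, priors


def score_matrix(backend, models: Sequence[object]) -> np.ndarray:
    """(K, n) matrix of per-sequence log-likelihoods."""
    return np.vstack([backend.score_all(m) for m in models])


def assign_step(scores: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Per-sequence argmax of ``log p_k + loglik``; ties to the lowest k."""
    with np.errstate(divide="ignore"):
        post = scores + np.log(priors)[:, None]
    return np.argmax(post, axis=0)


def cml_criterion(scores: np.ndarray, priors: np.ndarray, labels: np.ndarray) -> float:
    """Classification log-likelihood of a hard assignment."""
    with np.errstate(divide="ignore"):
        logp = np.log(priors)
    n = scores.shape[1]
    return float(scores[labels, np.arange(n)].sum() + logp[labels].sum())


def _reseed_empty(labels: np.ndarray, k: int, scores: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Move the worst max-posterior sequences into any emptied clusters."""
    labels = labels.copy()
    with np.errstate(divide="ignore"):
        post = scores + np.log(priors)[:, None]
    best = post.max(axis=0)
    order = np.argsort(best, kind="stable")
    used = set()
    for c in range(k):
        if (labels == c).any():
            continue
        for i in order:
            i = int(i)
            if i in used:
                continue
            # never strip a cluster down to zero by reseeding
            if (labels == labels[i]).sum() > 1:
                labels[i] = c
                used.add(i)
                break
    return labels


def run_scimm(
    sset: SequenceSet,
    k: int,
    init: Assignment,
    w: int = 8,
    max_iters: int = 100,
    converge_frac: float = 0.001,
    seed: int = 0,
    model: str = "icm",
    icm_config: Optional[IcmConfig] = None,
    order: int = 3,
    pseudocount: float = 0.0,
    prior_mode: str = "bp",
    reseed_empty: bool = True,
    backend=None,
) -> ClusterState:
    """Alternate model retraining and maximum-posterior reassignment.

    ``init`` may cover only a subsample of ``sset``; from the first
    iteration on, every sequence is scored and assigned.  The loop stops
    when the fraction of sequences changing clusters drops below
    ``converge_frac`` or after ``max_iters`` iterations (logged, not fatal).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    init = compact_assignment(init)
    n_init_clusters = len(set(init.values()))
    if n_init_clusters > k:
        raise ValueError(f"initialization has {n_init_clusters} clusters, more than k={k}")
    if backend is None:
        backend = make_backend(
            sset, model=model, icm_config=icm_config, w=w, order=order, pseudocount=pseudocount
        )
    n = len(sset)
    ids = sset.ids
    assignment = dict(init)
    k_run = n_init_clusters
    prev_labels: Optional[np.ndarray] = None  # full-coverage labels, current space
    state: Optional[ClusterState] = None
    history: List[IterationLog] = []
    converged = False
    for it in range(1, max_iters + 1):
        models, priors = retrain_step(sset, assignment, backend, prior_mode=prior_mode)
        scores = score_matrix(backend, models)
        labels = assign_step(scores, priors)
        if reseed_empty:
            labels = _reseed_empty(labels, k_run, scores, priors)
        cml = cml_criterion(scores, priors, labels)
        # model indices correspond 1:1 to the previous iteration's cluster
        # labels, so change counting compares like with like
        if prev_labels is None:
            idx, init_labels = _labels_for(sset, assignment)
            n_changed = int((labels[idx] != init_labels).sum()) + (n - len(idx))
        else:
            n_changed = int((labels != prev_labels).sum())
        frac = n_changed / n
        history.append(IterationLog(it, n_changed, frac, cml))
        logger.info("iteration %d: %d/%d changed (%.4f), CML=%.3f", it, n_changed, n, frac, cml)
        # clusters may die when reseeding is off; compact the label space so
        # the next retrain sees contiguous cluster ids
        present = np.unique(labels)
        if len(present) < k_run:
            remap = np.full(k_run, -1, dtype=np.intp)
            remap[present] = np.arange(len(present))
            labels = remap[labels]
            k_run = len(present)
        assignment = {ids[i]: int(labels[i]) for i in range(n)}
        prev_labels = labels
        state = ClusterState(
            assignment=assignment,
            models=models,
            priors=priors,
            cml=cml,
            iteration=it,
            history=history,
        )
        if frac < converge_frac:
            converged = True
            break
    if not converged:
        logger.warning("did not converge within %d iterations", max_iters)
    state.converged = converged
    return state


def one_iteration(
    sset: SequenceSet,
    init: Assignment,
    w: int = 8,
    **kwargs,
) -> Tuple[Assignment, float]:
    """One retrain+assign pass from ``init``; returns (assignment, CML)."""
    state = run_scimm(sset, k=len(set(init.values())), init=init, w=w, max_iters=1,
                      converge_frac=2.0, **kwargs)
    return state.assignment, state.cml


# ---------------------------------------------------------------------------
# supervised seeding


def physcimm_seed(
    sset: SequenceSet,
    table: ClassificationTable,
    k_expected: int,
) -> Assignment:
    """Seed clusters from a taxonomic classification table.

    Sequences are grouped by taxon label; groups holding more than
    ``20 / k_expected`` percent of the classified bp are kept as clusters
    (ordered by decreasing bp), and everything else -- filtered groups and
    unclassified sequences -- forms one additional catch-all cluster.  With
    an empty table all sequences land in a single cluster.
    """
    if k_expected < 1:
        raise ValueError("k_expected must be >= 1")
    groups: Dict[str, List[str]] = {}
    group_bp: Dict[str, int] = {}
    by_id = sset.by_id()
    classified_bp = 0
    for sid, label in table.items():
        if sid not in by_id:
            continue
        bp = len(by_id[sid])
        groups.setdefault(label, []).append(sid)
        group_bp[label] = group_bp.get(label, 0) + bp
        classified_bp += bp
    threshold = (20.0 / k_expected) / 100.0 * classified_bp
    kept = [lab for lab in groups if group_bp[lab] > threshold]
    kept.sort(key=lambda lab: (-group_bp[lab], lab))
    assignment: Assignment = {}
    for cid, lab in enumerate(kept):
        for sid in groups[lab]:
            assignment[sid] = cid
    extra = len(kept)
    for rec in sset:
        if rec.id not in assignment:
            assignment[rec.id] = extra
    return assignment
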
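"""Interpolated context models (ICMs) over fixed-width context windows.

An ICM is a probabilistic decision tree over the ``w`` positions preceding a
base.  Training greedily splits on the context position with the highest
(conditional) mutual information with the outcome base, and each node's
distribution is interpolated with its parent's using a chi-square-derived
weight, so the effective model order adapts to the available data.

Window indexing convention: a window covers positions ``i-w .. i`` of a
sequence; context position ``j`` (1-based, ``1..w``) is the base ``w-j+1``
steps before the outcome, i.e. position ``w`` is the base immediately
preceding the outcome.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import chi2

from .io_core import N_CODE, SequenceRecord, SequenceSet, encode, reverse_complement

__all__ = [
    "IcmConfig",
    "ContextCorpus",
    "IcmNode",
    "IcmModel",
    "build_corpus",
    "mutual_information",
    "interpolate",
    "train_icm",
    "score_sequence",
    "save_model",
    "load_model",
]

_LOG_QUARTER = math.log(0.25)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class IcmConfig:
    """Training hyper-parameters for :func:`train_icm`.

    ``stop_alpha=None`` disables the similarity stopping rule (used together
    with ``interpolation=False`` and ``min_split_windows=1`` to force a
    full-depth tree equivalent to a fixed order-``w`` chain).
    """

    w: int = 8
    min_split_windows: int = 200
    pseudocount: float = 0.5
    n0: float = 400.0
    stop_alpha: Optional[float] = 0.05
    interpolation: bool = True

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("w must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class ContextCorpus:
    """Training windows: context matrix (n, w) and outcome vector (n,).

    Only N-free windows are retained; entries are codes 0..3.
    """

    w: int
    contexts: np.ndarray
    outcomes: np.ndarray

    def __len__(self) -> int:
        return len(self.outcomes)


def _windows_of_codes(codes: np.ndarray, w: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (contexts, outcomes, valid) for every window of one sequence.

    ``valid`` marks windows free of N; invalid windows are still returned so
    scoring can charge them log(1/4) per outcome position.
    """
    n_pos = len(codes) - w
    if n_pos <= 0:
        empty = np.empty((0, w), dtype=np.uint8)
        return empty, np.empty(0, dtype=np.uint8), np.empty(0, dtype=bool)
    win = sliding_window_view(codes, w + 1)
    contexts = win[:, :w]
    outcomes = win[:, w]
    valid = (win != N_CODE).all(axis=1)
    return contexts, outcomes, valid


def build_corpus(sset: SequenceSet, w: int) -> ContextCorpus:
    """Collect every N-free (context, outcome) window of width ``w``+1."""
    if w < 0:
        raise ValueError("w must be >= 0")
    ctx_parts, out_parts = [], []
    for rec in sset:
        contexts, outcomes, valid = _windows_of_codes(rec.codes, w)
        ctx_parts.append(contexts[valid])
        out_parts.append(outcomes[valid])
    if ctx_parts:
        contexts = np.concatenate(ctx_parts)
        outcomes = np.concatenate(out_parts)
    else:
        contexts = np.empty((0, w), dtype=np.uint8)
        outcomes = np.empty(0, dtype=np.uint8)
    return ContextCorpus(w=w, contexts=np.ascontiguousarray(contexts), outcomes=outcomes)


def _mi_bits(joint: np.ndarray) -> float:
    """Plug-in mutual information (bits) from a 4x4 joint count table."""
    n = joint.sum()
    if n == 0:
        return 0.0
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float((p[mask] * np.log2(p[mask] / (px @ py)[mask])).sum())


def mutual_information(corpus: ContextCorpus, position: int) -> float:
    """MI in bits between the base at ``position`` (1..w) and the outcome."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    if not 1 <= position <= corpus.w:
        raise ValueError(f"position must be in 1..{corpus.w}")
    joint = np.bincount(
        corpus.contexts[:, position - 1].astype(np.intp) * 4 + corpus.outcomes,
        minlength=16,
    ).reshape(4, 4)
    return _mi_bits(joint)


def interpolate(
    child_counts: np.ndarray,
    parent_dist: np.ndarray,
    pseudocount: float,
    n0: float = 400.0,
) -> Tuple[float, np.ndarray]:
    """Blend a node's empirical distribution with its parent's.

    A chi-square goodness-of-fit test compares the child counts against
    ``n * parent_dist``; with ``q = 1 - pvalue`` the weight is
    ``lambda = q * n / (n + n0)`` and the result is
    ``lambda * child + (1 - lambda) * parent`` where the child distribution
    carries ``pseudocount`` per outcome.
    """
    counts = np.asarray(child_counts, dtype=float)
    parent = np.asarray(parent_dist, dtype=float)
    n = counts.sum()
    child_emp = (counts + pseudocount) / (n + 4.0 * pseudocount)
    lam, _ = _chi2_weight(counts, parent, n0)
    dist = lam * child_emp + (1.0 - lam) * parent
    return lam, dist / dist.sum()


def _chi2_weight(counts: np.ndarray, parent: np.ndarray, n0: float) -> Tuple[float, float]:
    """Return (lambda, pvalue) of the chi-square comparison to the parent."""
    n = counts.sum()
    if n == 0:
        return 0.0, 1.0
    expected = n * parent
    stat = float(((counts - expected) ** 2 / expected).sum())
    pvalue = float(chi2.sf(stat, df=3))
    lam = (1.0 - pvalue) * n / (n + n0)
    return lam, pvalue


@dataclass
class IcmNode:
    """One decision-tree node; ``split_position`` is None at leaves."""

    n_windows: int
    raw_dist: np.ndarray
    interp_dist: np.ndarray
    lam: float
    split_position: Optional[int] = None
    children: Optional[List["IcmNode"]] = None  # indexed by base code 0..3

    @property
    def is_leaf(self) -> bool:
        return self.split_position is None


@dataclass
class IcmModel:
    w: int
    root: IcmNode
    config: IcmConfig
    trained_bp: int = 0

    def score(self, record: SequenceRecord, strand_mode: str = "forward") -> float:
        return score_sequence(self, record, strand_mode)


def _build_node(
    ctx: np.ndarray,
    out: np.ndarray,
    idx: np.ndarray,
    parent_dist: Optional[np.ndarray],
    used: List[int],
    depth: int,
    cfg: IcmConfig,
) -> IcmNode:
    counts = np.bincount(out[idx], minlength=4).astype(float)
    n = int(counts.sum())
    raw = counts / n if n else np.full(4, 0.25)
    child_emp = (counts + cfg.pseudocount) / (n + 4.0 * cfg.pseudocount)

    if parent_dist is None:
        # Root: interpolate against the uniform prior.  The similarity stop
        # never applies here -- a uniform outcome marginal can still hide
        # highly informative context positions.
        ref = np.full(4, 0.25)
        pvalue = 0.0
    else:
        ref = parent_dist
        _, pvalue = _chi2_weight(counts, ref, cfg.n0)

    if cfg.interpolation:
        lam, _ = _chi2_weight(counts, ref, cfg.n0)
        interp = lam * child_emp + (1.0 - lam) * ref
        interp = interp / interp.sum()
    else:
        lam, interp = 1.0, child_emp

    node = IcmNode(n_windows=n, raw_dist=raw, interp_dist=interp, lam=lam)

    stop_similar = (
        parent_dist is not None
        and cfg.stop_alpha is not None
        and pvalue >= cfg.stop_alpha
    )
    if (
        depth >= cfg.w
        or len(used) >= cfg.w
        or n < cfg.min_split_windows
        or stop_similar
    ):
        return node

    # Choose the most informative unused position; ties go to the position
    # closest to the predicted base (largest index).
    best_pos, best_mi = -1, -1.0
    sub_out = out[idx]
    for pos in range(1, cfg.w + 1):
        if pos in used:
            continue
        joint = np.bincount(
            ctx[idx, pos - 1].astype(np.intp) * 4 + sub_out, minlength=16
        ).reshape(4, 4)
        mi = _mi_bits(joint)
        if mi >= best_mi:
            best_mi, best_pos = mi, pos

    bases = ctx[idx, best_pos - 1]
    child_idx = [idx[bases == b] for b in range(4)]
    if cfg.stop_alpha is not None:
        # the split is worthless if every prospective child looks like this
        # node; in that case stop branching here
        child_pvals = [
            _chi2_weight(np.bincount(out[ci], minlength=4).astype(float), node.interp_dist, cfg.n0)[1]
            for ci in child_idx
        ]
        if all(p >= cfg.stop_alpha for p in child_pvals):
            return node

    node.split_position = best_pos
    node.children = [
        _build_node(
            ctx,
            out,
            child_idx[b],
            node.interp_dist,
            used + [best_pos],
            depth + 1,
            cfg,
        )
        for b in range(4)
    ]
    return node


def train_icm(
    sset: SequenceSet,
    w: int = 8,
    min_split_windows: int = 200,
    pseudocount: float = 0.5,
    config: Optional[IcmConfig] = None,
) -> IcmModel:
    """Train an ICM on all N-free windows of ``sset``.

    Raises ``ValueError`` when the set yields no training window at width
    ``w`` (use a smaller ``w``).
    """
    cfg = config or IcmConfig(w=w, min_split_windows=min_split_windows, pseudocount=pseudocount)
    corpus = build_corpus(sset, cfg.w)
    return train_icm_from_corpus(corpus, cfg, trained_bp=sset.total_bp)


def train_icm_from_corpus(
    corpus: ContextCorpus, cfg: IcmConfig, trained_bp: int = 0
) -> IcmModel:
    if len(corpus) == 0:
        raise ValueError(
            f"no training windows at w={cfg.w}; sequences are too short -- use a smaller w"
        )
    idx = np.arange(len(corpus), dtype=np.intp)
    root = _build_node(corpus.contexts, corpus.outcomes, idx, None, [], 0, cfg)
    return IcmModel(w=cfg.w, root=root, config=cfg, trained_bp=trained_bp)


def position_log_probs(
    model: IcmModel, contexts: np.ndarray, outcomes: np.ndarray, valid: np.ndarray
) -> np.ndarray:
    """Per-window log-probabilities; windows containing N get log(1/4).

    Descends the decision tree with index partitioning, so cost is linear in
    the number of windows times the tree depth.
    """
    n = len(outcomes)
    logp = np.full(n, _LOG_QUARTER)
    if n == 0:
        return logp
    stack = [(model.root, np.flatnonzero(valid))]
    while stack:
        node, idx = stack.pop()
        if len(idx) == 0:
            continue
        if node.is_leaf:
            logp[idx] = np.log(node.interp_dist)[outcomes[idx]]
            continue
        bases = contexts[idx, node.split_position - 1]
        for b in range(4):
            stack.append((node.children[b], idx[bases == b]))
    return logp


def score_sequence(
    model: IcmModel, record: SequenceRecord, strand_mode: str = "forward"
) -> float:
    """Log-probability of ``record`` under ``model`` (sum over windows).

    ``strand_mode='both-max'`` also scores the reverse complement and keeps
    the larger value.
    """
    if strand_mode not in ("forward", "both-max"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if len(record) <= model.w:
        raise ValueError(
            f"sequence {record.id!r} (length {len(record)}) is not longer than w={model.w}"
        )
    fwd = _score_codes(model, record.codes)
    if strand_mode == "forward":
        return fwd
    rc = encode(reverse_complement(record.seq))
    return max(fwd, _score_codes(model, rc))


def _score_codes(model: IcmModel, codes: np.ndarray) -> float:
    contexts, outcomes, valid = _windows_of_codes(codes, model.w)
    return float(position_log_probs(model, contexts, outcomes, valid).sum())


# ---------------------------------------------------------------------------
# serialization


def _node_to_dict(node: IcmNode) -> dict:
    d = {
        "n_windows": node.n_windows,
        "raw_dist": [float(x) for x in node.raw_dist],
        "interp_dist": [float(x) for x in node.interp_dist],
        "lambda": node.lam,
        "split_position": node.split_position,
    }
    if node.children is not None:
        d["children"] = [_node_to_dict(c) for c in node.children]
    return d


def _node_from_dict(d: dict) -> IcmNode:
    node = IcmNode(
        n_windows=d["n_windows"],
        raw_dist=np.array(d["raw_dist"]),
        interp_dist=np.array(d["interp_dist"]),
        lam=d["lambda"],
        split_position=d["split_position"],
    )
    if "children" in d:
        node.children = [_node_from_dict(c) for c in d["children"]]
    return node


def save_model(model: IcmModel, path: Union[str, Path]) -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "w": model.w,
        "trained_bp": model.trained_bp,
        "config": {
            "w": model.config.w,
            "min_split_windows": model.config.min_split_windows,
            "pseudocount": model.config.pseudocount,
            "n0": model.config.n0,
            "stop_alpha": model.config.stop_alpha,
            "interpolation": model.config.interpolation,
        },
        "root": _node_to_dict(model.root),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: Union[str, Path]) -> IcmModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version in {path}")
    cfg = IcmConfig(**doc["config"])
    return IcmModel(
        w=doc["w"], root=_node_from_dict(doc["root"]), config=cfg, trained_bp=doc["trained_bp"]
    )
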
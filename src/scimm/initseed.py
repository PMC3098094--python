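"""Initial partitioning strategies for the clustering loop.

Two unsupervised initializers are provided: a composition-based recursive
spectral bisection (k-mer profiles -> PCA -> nearest-neighbor graph ->
normalized cut) and a stochastic-search initializer that reassigns
sequences between fixed-order Markov chain clusters under a Metropolis
rule.  ``select_initialization`` arbitrates between candidate partitions by
running one clustering iteration on each and keeping the one with the
higher classification log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .chains import context_codes
from .io_core import Assignment, SequenceRecord, SequenceSet, encode, reverse_complement

__all__ = [
    "KmerProfile",
    "NeighborGraph",
    "kmer_profile",
    "profile_matrix",
    "pca_project",
    "num_neighbors",
    "knn_graph",
    "normalized_cut",
    "compostbin_partition",
    "likelybin_partition",
    "random_partition",
    "select_initialization",
]


@dataclass
class KmerProfile:
    m: int
    freq: np.ndarray  # length 4^m, sums to 1


@dataclass
class NeighborGraph:
    """Symmetric weighted graph as a CSR adjacency matrix (no self-loops)."""

    weights: sp.csr_matrix

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()


def _kmer_counts(codes: np.ndarray, m: int) -> np.ndarray:
    ctx, out, valid = context_codes(codes, m - 1)
    flat = ctx[valid] * 4 + out[valid]
    return np.bincount(flat, minlength=4 ** m)


def kmer_profile(record: SequenceRecord, m: int) -> KmerProfile:
    """Strand-symmetric m-mer frequency vector (forward + reverse complement).

    Sequences shorter than ``m`` (or with no N-free m-mer) get the uniform
    profile.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    counts = _kmer_counts(record.codes, m)
    counts = counts + _kmer_counts(encode(reverse_complement(record.seq)), m)
    total = counts.sum()
    if total == 0:
        return KmerProfile(m=m, freq=np.full(4 ** m, 1.0 / 4 ** m))
    return KmerProfile(m=m, freq=counts / total)


def profile_matrix(sset: SequenceSet, m: int) -> np.ndarray:
    return np.vstack([kmer_profile(rec, m).freq for rec in sset])


def pca_project(profiles: np.ndarray, dims: int = 3) -> np.ndarray:
    """Project rows onto the top principal axes (deterministic signs).

    Signs are fixed by making the largest-magnitude loading of each
    component positive.
    """
    X = np.asarray(profiles, dtype=float)
    n = X.shape[0]
    if n < dims:
        raise ValueError(f"need at least {dims} rows for a {dims}-D projection, got {n}")
    Xc = X - X.mean(axis=0)
    # SVD of the centered matrix: rows of Vt are the principal axes ordered
    # by decreasing singular value (= decreasing explained variance).
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    comps = vt[:dims]
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return Xc @ comps.T


def num_neighbors(n: int) -> int:
    """Neighborhood size for the sequence graph: 2 + floor(floor(ln n)/2).

    Capped at ``n - 1`` so the graph stays simple.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    return min(2 + math.floor(math.floor(math.log(n)) / 2), n - 1)


def knn_graph(points: np.ndarray, k_nn: int) -> NeighborGraph:
    """Union-symmetrized k-nearest-neighbor graph with Gaussian weights.

    Edge weight is ``exp(-d^2 / sigma^2)`` with ``sigma`` the median of the
    directed neighbor distances; if that median is 0 (duplicate-heavy data)
    all edges get weight 1.  Distance ties are broken by input order.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if not 1 <= k_nn < n:
        raise ValueError(f"k_nn must be in [1, n-1], got {k_nn} for n={n}")
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    # stable argsort => ties resolved toward lower input index
    nbr = np.argsort(d2, axis=1, kind="stable")[:, :k_nn]
    rows = np.repeat(np.arange(n), k_nn)
    cols = nbr.ravel()
    dist2 = d2[rows, cols]
    sigma = math.sqrt(float(np.median(dist2)))
    if sigma > 0:
        w = np.exp(-dist2 / sigma ** 2)
    else:
        w = np.ones_like(dist2)
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)  # union of directed edges; weights depend only on d
    return NeighborGraph(weights=W)


def _sweep_cut(W: sp.csr_matrix, order: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Best prefix split of ``order`` by normalized-cut value."""
    n = W.shape[0]
    deg = np.asarray(W.sum(axis=1)).ravel()
    total_assoc = deg.sum()
    in_a = np.zeros(n, dtype=bool)
    cut = 0.0
    assoc_a = 0.0
    best = (math.inf, -1)
    for i in range(n - 1):
        v = order[i]
        row = W.getrow(v)
        links_a = float(row[:, np.flatnonzero(in_a)].sum()) if in_a.any() else 0.0
        cut += deg[v] - 2.0 * links_a
        assoc_a += deg[v]
        in_a[v] = True
        assoc_b = total_assoc - assoc_a
        if assoc_a <= 0 or assoc_b <= 0:
            continue
        ncut = cut / assoc_a + cut / assoc_b
        if ncut < best[0]:
            best = (ncut, i)
    if best[1] < 0:
        # degenerate weights; fall back to a half split
        best = (math.inf, n // 2 - 1)
    i = best[1]
    return order[: i + 1].copy(), order[i + 1 :].copy(), best[0]


def ncut_value(W: sp.csr_matrix, side_a: Sequence[int]) -> float:
    """Normalized-cut objective of a bipartition (inf if one side is empty)."""
    n = W.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[list(side_a)] = True
    if not mask.any() or mask.all():
        return math.inf
    deg = np.asarray(W.sum(axis=1)).ravel()
    Wd = W.toarray()
    cut = float(Wd[np.ix_(mask, ~mask)].sum())
    assoc_a = float(deg[mask].sum())
    assoc_b = float(deg[~mask].sum())
    if assoc_a == 0 or assoc_b == 0:
        return math.inf
    return cut / assoc_a + cut / assoc_b


def normalized_cut(graph: NeighborGraph) -> Tuple[np.ndarray, np.ndarray]:
    """Bipartition approximately minimizing the normalized cut.

    Uses the eigenvector of the second-smallest eigenvalue of the normalized
    Laplacian, thresholded by sweeping the sorted entries and keeping the
    minimum-Ncut prefix split.  A disconnected graph is split along its
    components (largest component vs. the rest) without any eigensolve.
    """
    W = graph.weights
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 vertices to bipartition")
    n_comp, labels = connected_components(W, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        big = int(np.argmax(sizes))
        a = np.flatnonzero(labels == big)
        b = np.flatnonzero(labels != big)
        return a, b
    deg = np.asarray(W.sum(axis=1)).ravel()
    d_isqrt = 1.0 / np.sqrt(deg)
    Wd = W.toarray()
    L = np.eye(n) - (d_isqrt[:, None] * Wd) * d_isqrt[None, :]
    L = (L + L.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(L)
    fiedler = eigvecs[:, 1] * d_isqrt
    order = np.argsort(fiedler, kind="stable")
    a, b, _ = _sweep_cut(W, order)
    return a, b


def _bp_of(sset: SequenceSet, indices: np.ndarray) -> int:
    lengths = sset.lengths
    return int(lengths[indices].sum())


def compostbin_partition(
    sset: SequenceSet, k: int, m: int = 5, seed: int = 0, dims: int = 3
) -> Assignment:
    """Recursive spectral bisection into ``k`` clusters.

    At each step the part holding the most sequenced bp (with at least two
    sequences) is bisected: 5-mer profiles -> PCA to 3-D -> kNN graph with
    ``num_neighbors(n)`` neighbors -> normalized cut.  Deterministic; the
    ``seed`` parameter is accepted for interface symmetry only.
    """
    n = len(sset)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, n], got k={k} for n={n}")
    profiles = profile_matrix(sset, m)
    parts: List[np.ndarray] = [np.arange(n, dtype=np.intp)]
    while len(parts) < k:
        splittable = [i for i, p in enumerate(parts) if len(p) >= 2]
        # k <= n guarantees a splittable part exists
        target = max(splittable, key=lambda i: _bp_of(sset, parts[i]))
        part = parts.pop(target)
        if len(part) == 2:
            a, b = part[:1], part[1:]
        else:
            sub = profiles[part]
            d = min(dims, len(part) - 1, sub.shape[1])
            coords = pca_project(sub, dims=max(1, d))
            k_nn = num_neighbors(len(part))
            graph = knn_graph(coords, k_nn)
            ia, ib = normalized_cut(graph)
            a, b = part[ia], part[ib]
        parts.append(a)
        parts.append(b)
    assignment: Assignment = {}
    for cid, part in enumerate(parts):
        for i in part:
            assignment[sset[int(i)].id] = cid
    return assignment


def random_partition(sset: SequenceSet, k: int, seed: int) -> Assignment:
    """Uniform random assignment with every cluster seeded at least once."""
    n = len(sset)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, n], got k={k} for n={n}")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, k, size=n)
    labels[rng.permutation(n)[:k]] = np.arange(k)
    return {rec.id: int(labels[i]) for i, rec in enumerate(sset)}


class _ChainObjective:
    """Incremental smoothed classification log-likelihood for the MCMC search.

    Each cluster is scored by its own pseudocounted fixed-order chain plus a
    bp-share prior term.  Moving one sequence touches only the transition
    counts it contributes, so the likelihood delta is computed from those
    entries alone.
    """

    def __init__(self, sset: SequenceSet, k: int, order: int, pseudocount: float):
        self.k = k
        self.order = order
        self.ps = pseudocount
        self.n_ctx = 4 ** order
        self.seq_ctx: List[np.ndarray] = []  # unique context codes per sequence
        self.seq_rows: List[np.ndarray] = []  # (n_ctx_i, 4) transition counts
        self.seq_bp = sset.lengths.astype(float)
        for rec in sset:
            # strand-symmetric counts: shotgun reads are unoriented, and a
            # directional chain would otherwise split clusters by strand
            parts = []
            for codes in (rec.codes, encode(reverse_complement(rec.seq))):
                ctx, out, valid = context_codes(codes, order)
                parts.append(ctx[valid] * 4 + out[valid])
            flat = np.concatenate(parts)
            dense = np.bincount(flat, minlength=self.n_ctx * 4).reshape(self.n_ctx, 4) / 2.0
            ctx_ids = np.flatnonzero(dense.any(axis=1))
            self.seq_ctx.append(ctx_ids)
            self.seq_rows.append(dense[ctx_ids])
        self.counts = np.zeros((k, self.n_ctx, 4))
        self.labels = np.full(len(sset), -1, dtype=np.intp)
        self.cluster_bp = np.zeros(k)
        self.cluster_n = np.zeros(k)
        self.total_bp = float(self.seq_bp.sum())

    def set_labels(self, labels: np.ndarray) -> None:
        self.counts[:] = 0.0
        self.cluster_bp[:] = 0.0
        self.cluster_n[:] = 0.0
        self.labels = labels.astype(np.intp).copy()
        for i, lab in enumerate(self.labels):
            self.counts[lab, self.seq_ctx[i]] += self.seq_rows[i]
            self.cluster_bp[lab] += self.seq_bp[i]
            self.cluster_n[lab] += 1

    def _term(self, rows: np.ndarray) -> np.ndarray:
        """Smoothed log-likelihood of count rows under their own estimate."""
        totals = rows.sum(axis=-1, keepdims=True)
        return (rows * np.log((rows + self.ps) / (totals + 4 * self.ps))).sum(axis=(-2, -1))

    def _prior_term(self) -> float:
        shares = self.cluster_bp / self.total_bp
        mask = self.cluster_n > 0
        return float((self.cluster_n[mask] * np.log(shares[mask])).sum())

    def total(self) -> float:
        return float(self._term(self.counts).sum()) + self._prior_term()

    def move_delta(self, i: int, dst: int) -> float:
        src = int(self.labels[i])
        if dst == src:
            return 0.0
        ctx_ids = self.seq_ctx[i]
        R = self.seq_rows[i]
        S = self.counts[src, ctx_ids]
        D = self.counts[dst, ctx_ids]
        stacked = np.stack([S, D, S - R, D + R])
        terms = self._term(stacked)
        delta_ll = float(terms[2] + terms[3] - terms[0] - terms[1])
        # prior: only the src/dst shares and occupancies change
        bp = self.seq_bp[i]
        old = self._pair_prior(self.cluster_n[src], self.cluster_bp[src],
                               self.cluster_n[dst], self.cluster_bp[dst])
        new = self._pair_prior(self.cluster_n[src] - 1, self.cluster_bp[src] - bp,
                               self.cluster_n[dst] + 1, self.cluster_bp[dst] + bp)
        return delta_ll + new - old

    def _pair_prior(self, n_a: float, bp_a: float, n_b: float, bp_b: float) -> float:
        out = 0.0
        if n_a > 0:
            out += n_a * math.log(bp_a / self.total_bp)
        if n_b > 0:
            out += n_b * math.log(bp_b / self.total_bp)
        return out

    def apply_move(self, i: int, dst: int) -> None:
        src = int(self.labels[i])
        self.counts[src, self.seq_ctx[i]] -= self.seq_rows[i]
        self.counts[dst, self.seq_ctx[i]] += self.seq_rows[i]
        self.cluster_bp[src] -= self.seq_bp[i]
        self.cluster_bp[dst] += self.seq_bp[i]
        self.cluster_n[src] -= 1
        self.cluster_n[dst] += 1
        self.labels[i] = dst


def likelybin_partition(
    sset: SequenceSet,
    k: int,
    order: int = 3,
    n_starts: int = 2,
    steps: Optional[int] = None,
    seed: int = 0,
    pseudocount: float = 0.5,
) -> Assignment:
    """Stochastic-search initializer over hard assignments.

    From each random start, single-sequence reassignments are proposed and
    accepted by the Metropolis rule on the smoothed classification
    log-likelihood under per-cluster fixed-order chains (priors = cluster bp
    share).  The best of ``n_starts`` final states (by likelihood) wins.
    """
    if order not in (2, 3, 4):
        raise ValueError("order must be 2, 3, or 4")
    n = len(sset)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, n], got k={k} for n={n}")
    if steps is None:
        steps = 30 * n
    rng = np.random.default_rng(seed)
    obj = _ChainObjective(sset, k, order, pseudocount)
    best_labels, best_ll = None, -math.inf
    for _ in range(max(1, n_starts)):
        labels = rng.integers(0, k, size=n)
        labels[rng.permutation(n)[:k]] = np.arange(k)
        obj.set_labels(labels)
        if k > 1:
            picks = rng.integers(0, n, size=steps)
            dests = rng.integers(0, k - 1, size=steps)
            us = rng.random(size=steps)
            for t in range(steps):
                i = int(picks[t])
                dst = int(dests[t])
                if dst >= obj.labels[i]:
                    dst += 1  # propose a cluster different from the current one
                delta = obj.move_delta(i, dst)
                if delta >= 0 or us[t] < math.exp(delta):
                    obj.apply_move(i, dst)
        ll = obj.total()
        if ll > best_ll:
            best_ll, best_labels = ll, obj.labels.copy()
    return {rec.id: int(best_labels[i]) for i, rec in enumerate(sset)}


def select_initialization(
    candidates: Sequence[Assignment],
    sset: SequenceSet,
    w: int = 8,
    **cluster_kwargs,
) -> Assignment:
    """Run one clustering iteration per candidate and keep the best by CML.

    Ties (including duplicate candidates) resolve to the earliest candidate.
    Returns the post-iteration assignment, which covers every sequence in
    ``sset`` even when a candidate covered only a subsample.
    """
    from .cluster import one_iteration  # deferred: avoid circular import

    if not candidates:
        raise ValueError("need at least one candidate assignment")
    best_assign, best_cml = None, -math.inf
    for cand in candidates:
        assignment, cml = one_iteration(sset, cand, w=w, **cluster_kwargs)
        if cml > best_cml:
            best_cml, best_assign = cml, assignment
    return best_assign
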
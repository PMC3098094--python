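"""Fixed-order Markov chain models over DNA.

These serve two roles: the per-cluster models of the MCMC initializer, and
an exact maximum-likelihood model family for the clustering loop's "oracle"
mode, where the classification-likelihood objective is guaranteed to be
non-decreasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_core import N_CODE, SequenceRecord, SequenceSet

__all__ = ["FixedOrderChain", "context_codes", "transition_counts"]

_LOG_QUARTER = math.log(0.25)


def context_codes(codes: np.ndarray, order: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rolling (context code, outcome, valid) triples for one sequence.

    Context codes are lexicographic base-4 integers over the ``order``
    preceding bases.  Windows touching an N are flagged invalid.
    """
    n_pos = len(codes) - order
    if n_pos <= 0:
        return (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.uint8),
            np.empty(0, dtype=bool),
        )
    win = sliding_window_view(codes, order + 1)
    valid = (win != N_CODE).all(axis=1)
    powers = 4 ** np.arange(order - 1, -1, -1, dtype=np.int64) if order else np.empty(0, np.int64)
    safe = np.where(win[:, :order] == N_CODE, 0, win[:, :order]).astype(np.int64)
    ctx = safe @ powers if order else np.zeros(n_pos, dtype=np.int64)
    return ctx, win[:, order], valid


def transition_counts(records: Iterable[SequenceRecord], order: int) -> np.ndarray:
    """(4^order, 4) matrix of N-free transition counts."""
    counts = np.zeros(4 ** order * 4, dtype=np.int64)
    for rec in records:
        ctx, out, valid = context_codes(rec.codes, order)
        flat = ctx[valid] * 4 + out[valid]
        counts += np.bincount(flat, minlength=len(counts))
    return counts.reshape(4 ** order, 4)


@dataclass
class FixedOrderChain:
    """Order-``order`` Markov chain with optional pseudocounts.

    ``pseudocount=0`` gives the exact maximum-likelihood estimate (zeros
    allowed, scored as -inf); positive pseudocounts smooth every
    conditional distribution.
    """

    order: int
    log_probs: np.ndarray  # (4^order, 4)
    pseudocount: float = 0.0

    @classmethod
    def fit(
        cls,
        records: Iterable[SequenceRecord],
        order: int,
        pseudocount: float = 0.0,
    ) -> "FixedOrderChain":
        counts = transition_counts(records, order).astype(float) + pseudocount
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            probs = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), 0.25)
            logp = np.log(probs)
        return cls(order=order, log_probs=logp, pseudocount=pseudocount)

    def score_codes(self, codes: np.ndarray) -> float:
        """Log-probability of one encoded sequence (N windows give log 1/4)."""
        if len(codes) <= self.order:
            raise ValueError(f"sequence of length {len(codes)} not longer than order {self.order}")
        ctx, out, valid = context_codes(codes, self.order)
        n_invalid = int((~valid).sum())
        lp = self.log_probs[ctx[valid], out[valid]].sum()
        return float(lp + n_invalid * _LOG_QUARTER)

    def score(self, record: SequenceRecord) -> float:
        return self.score_codes(record.codes)

    def score_set(self, sset: SequenceSet) -> np.ndarray:
        return np.array([self.score(rec) for rec in sset])
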
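"""Clustering evaluation against a known sequence-to-genome truth.

Recall and precision are weighted by sequenced nucleotides: recall asks how
well each genome's bases stay together, precision asks how pure each
cluster's bases are.  The adjusted Rand index treats each sequence as one
item (unweighted), the standard Hubert-Arabie definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy.special import comb

from .io_core import Assignment, SequenceSet

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "recall",
    "precision",
    "adjusted_rand",
    "apply_taxmap",
    "read_truth",
    "evaluate",
]


@dataclass
class ConfusionMatrix:
    """bp counts ``c[i, j]`` = nucleotides from genome ``j`` in cluster ``i``."""

    c: np.ndarray
    cluster_ids: List[int]
    genome_ids: List[str]

    @property
    def total_bp(self) -> int:
        return int(self.c.sum())


def confusion_matrix(
    assignment: Assignment, truth: Mapping[str, str], sset: SequenceSet
) -> ConfusionMatrix:
    """Tally per-(cluster, genome) nucleotide counts over ``sset``.

    ``assignment`` and ``truth`` must cover exactly the ids in ``sset``.
    """
    ids = set(sset.ids)
    missing_a = sorted(ids - set(assignment))
    missing_t = sorted(ids - set(truth))
    if missing_a or missing_t:
        raise ValueError(
            f"ids missing from assignment: {missing_a[:5]}; from truth: {missing_t[:5]}"
        )
    cluster_ids = sorted({assignment[i] for i in ids})
    genome_ids = sorted({truth[i] for i in ids})
    ci = {c: i for i, c in enumerate(cluster_ids)}
    gi = {g: j for j, g in enumerate(genome_ids)}
    c = np.zeros((len(cluster_ids), len(genome_ids)), dtype=np.int64)
    for rec in sset:
        c[ci[assignment[rec.id]], gi[truth[rec.id]]] += len(rec)
    return ConfusionMatrix(c=c, cluster_ids=cluster_ids, genome_ids=genome_ids)


def recall(cm: ConfusionMatrix) -> Tuple[np.ndarray, float]:
    """Per-genome max_i c_ij / sum_i c_ij, and its bp-weighted global mean."""
    c = cm.c
    col_sums = c.sum(axis=0)
    if (col_sums == 0).any():
        bad = [cm.genome_ids[j] for j in np.flatnonzero(col_sums == 0)]
        raise ValueError(f"genomes with zero evaluated bp: {bad}")
    per_genome = c.max(axis=0) / col_sums
    global_recall = float((col_sums * per_genome).sum() / col_sums.sum())
    return per_genome, global_recall


def precision(cm: ConfusionMatrix) -> Tuple[np.ndarray, float]:
    """Per-cluster max_j c_ij / sum_j c_ij, and its bp-weighted global mean."""
    c = cm.c
    row_sums = c.sum(axis=1)
    if (row_sums == 0).any():
        bad = [cm.cluster_ids[i] for i in np.flatnonzero(row_sums == 0)]
        raise ValueError(f"clusters with zero evaluated bp: {bad}")
    per_cluster = c.max(axis=1) / row_sums
    global_precision = float((row_sums * per_cluster).sum() / row_sums.sum())
    return per_cluster, global_precision


def adjusted_rand(assignment: Assignment, truth: Mapping[str, str]) -> float:
    """Hubert-Arabie adjusted Rand index over sequence pairs (per item)."""
    ids = sorted(assignment)
    if set(ids) != set(truth):
        raise ValueError("assignment and truth must cover the same ids")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 items for the adjusted Rand index")
    a_labels = {c: i for i, c in enumerate(sorted({assignment[i] for i in ids}))}
    t_labels = {g: j for j, g in enumerate(sorted({truth[i] for i in ids}))}
    cont = np.zeros((len(a_labels), len(t_labels)), dtype=np.int64)
    for i in ids:
        cont[a_labels[assignment[i]], t_labels[truth[i]]] += 1
    sum_comb = comb(cont, 2).sum()
    sum_a = comb(cont.sum(axis=1), 2).sum()
    sum_b = comb(cont.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0  # both partitions degenerate (all-together or all-apart)
    return float((sum_comb - expected) / (max_index - expected))


def apply_taxmap(truth: Mapping[str, str], taxmap: Mapping[str, str]) -> Dict[str, str]:
    """Map truth labels (e.g. strain) to a higher taxonomic level.

    Labels absent from ``taxmap`` pass through unchanged, so partial maps
    are usable.
    """
    return {sid: taxmap.get(label, label) for sid, label in truth.items()}


def read_truth(path) -> Dict[str, str]:
    """Two-column TSV: sequence_id TAB label."""
    truth: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            truth[parts[0]] = parts[1]
    return truth


def evaluate(
    assignment: Assignment,
    truth: Mapping[str, str],
    sset: SequenceSet,
    taxmap: Optional[Mapping[str, str]] = None,
) -> Dict[str, object]:
    """Convenience bundle of confusion matrix, recall, precision, and ARI."""
    if taxmap is not None:
        truth = apply_taxmap(truth, taxmap)
    cm = confusion_matrix(assignment, truth, sset)
    per_genome, global_recall = recall(cm)
    per_cluster, global_precision = precision(cm)
    sub = {i: assignment[i] for i in sset.ids}
    tsub = {i: truth[i] for i in sset.ids}
    ari = adjusted_rand(sub, tsub)
    return {
        "confusion": cm,
        "recall_per_genome": per_genome,
        "recall": global_recall,
        "precision_per_cluster": per_cluster,
        "precision": global_precision,
        "ari": ari,
    }
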
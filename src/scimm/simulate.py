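"""Synthetic test-data generation: Markov-chain genomes, mixture read
sampling with random abundances, and substitution-error injection.

Everything here is a pure function of its inputs and a seed, so the full
clustering pipeline can be exercised without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np

from .io_core import (
    Assignment,
    SequenceRecord,
    SequenceSet,
    decode,
    encode,
    reverse_complement,
    write_fasta,
)

__all__ = [
    "ReadSimConfig",
    "LabeledRead",
    "generate_markov_genome",
    "random_divergent_params",
    "chain_js_divergence",
    "sample_abundances",
    "simulate_reads",
    "inject_errors",
    "reads_for_total_bp",
    "write_simulation",
]


@dataclass(frozen=True)
class ReadSimConfig:
    """Parameters of one read-sampling experiment."""

    n_reads: int
    read_len: int
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class LabeledRead:
    """A read together with its ground-truth provenance."""

    record: SequenceRecord
    source_genome: str
    source_pos: int  # 0-based start on the forward strand
    strand: str  # '+' or '-'


def _check_stochastic(params: np.ndarray, order: int) -> np.ndarray:
    params = np.asarray(params, dtype=float)
    expected_shape = (4 ** order, 4)
    if params.shape != expected_shape:
        raise ValueError(f"transition_params must have shape {expected_shape}, got {params.shape}")
    if (params < 0).any() or not np.allclose(params.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("rows of transition_params must be non-negative and sum to 1")
    return params


def generate_markov_genome(
    order: int,
    transition_params: np.ndarray,
    length: int,
    seed: int,
    genome_id: str = "genome",
) -> SequenceRecord:
    """Sample one sequence from a fixed-order Markov chain.

    The first ``order`` bases are drawn uniformly; afterwards each base is
    drawn from the row of ``transition_params`` indexed by the preceding
    ``order`` bases (lexicographic base-4 code).
    """
    params = _check_stochastic(transition_params, order)
    if length <= order:
        raise ValueError("length must exceed the chain order")
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(params, axis=1)
    cdf[:, -1] = 1.0
    out = np.empty(length, dtype=np.uint8)
    out[:order] = rng.integers(0, 4, size=order)
    ctx = 0
    for j in range(order):
        ctx = ctx * 4 + int(out[j])
    mask = 4 ** order
    u = rng.random(length - order)
    for i in range(order, length):
        b = int(np.searchsorted(cdf[ctx], u[i - order], side="right"))
        b = min(b, 3)
        out[i] = b
        ctx = (ctx * 4 + b) % mask if order else 0
    return SequenceRecord(genome_id, decode(out))


def _js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (bits) between two distributions."""
    m = 0.5 * (p + q)

    def _kl(a, b):
        mask = a > 0
        return float((a[mask] * np.log2(a[mask] / b[mask])).sum())

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def chain_js_divergence(params_a: np.ndarray, params_b: np.ndarray) -> float:
    """Mean per-context Jensen-Shannon divergence between two chains, bits."""
    a = np.asarray(params_a, dtype=float)
    b = np.asarray(params_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parameter tensors must have the same shape")
    return float(np.mean([_js_divergence(a[i], b[i]) for i in range(a.shape[0])]))


def random_divergent_params(
    k: int,
    order: int,
    seed: int,
    min_js: float = 0.05,
    concentration: float = 1.0,
    max_tries: int = 1000,
) -> List[np.ndarray]:
    """Draw ``k`` chain parameter sets with pairwise divergence >= ``min_js``.

    Rows are Dirichlet(``concentration``) draws; candidates too close to an
    already-accepted set are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    chains: List[np.ndarray] = []
    tries = 0
    while len(chains) < k:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not draw {k} chains with pairwise JS >= {min_js} in {max_tries} tries"
            )
        cand = rng.dirichlet(np.full(4, concentration), size=4 ** order)
        if all(chain_js_divergence(cand, c) >= min_js for c in chains):
            chains.append(cand)
    return chains


def sample_abundances(k: int, seed: int) -> np.ndarray:
    """k uniform(0,1) draws normalized to sum 1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(0.0, 1.0, size=k)
    return draws / draws.sum()


def simulate_reads(
    genomes: SequenceSet,
    abundances: Sequence[float],
    cfg: ReadSimConfig,
) -> List[LabeledRead]:
    """Sample labeled reads from a genome mixture.

    Per read: source genome drawn by abundance, start uniform over valid
    positions, strand uniform; substitution errors applied at
    ``cfg.error_rate``.
    """
    ab = np.asarray(abundances, dtype=float)
    if len(ab) != len(genomes):
        raise ValueError("need one abundance per genome")
    if not math.isclose(float(ab.sum()), 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError("abundances must sum to 1")
    short = [rec.id for rec in genomes if len(rec) < cfg.read_len]
    if short:
        raise ValueError(f"genomes shorter than read_len={cfg.read_len}: {short}")
    rng = np.random.default_rng(cfg.seed)
    sources = rng.choice(len(genomes), size=cfg.n_reads, p=ab)
    strands = rng.integers(0, 2, size=cfg.n_reads)
    starts = np.empty(cfg.n_reads, dtype=np.int64)
    for g in range(len(genomes)):
        mask = sources == g
        hi = len(genomes[g]) - cfg.read_len + 1
        starts[mask] = rng.integers(0, hi, size=int(mask.sum()))
    reads: List[LabeledRead] = []
    digits = len(str(cfg.n_reads))
    for r in range(cfg.n_reads):
        g = int(sources[r])
        pos = int(starts[r])
        frag = genomes[g].seq[pos : pos + cfg.read_len]
        strand = "+" if strands[r] == 0 else "-"
        if strand == "-":
            frag = reverse_complement(frag)
        rid = f"read_{r:0{digits}d}"
        reads.append(
            LabeledRead(
                record=SequenceRecord(rid, frag),
                source_genome=genomes[g].id,
                source_pos=pos,
                strand=strand,
            )
        )
    if cfg.error_rate > 0:
        reads = inject_errors(reads, cfg.error_rate, seed=int(rng.integers(2 ** 31)))
    return reads


def inject_errors(reads: List[LabeledRead], rate: float, seed: int) -> List[LabeledRead]:
    """Substitute each base independently with probability ``rate``.

    A substituted base becomes one of the three other nucleotides, chosen
    uniformly.  N positions are left untouched; provenance labels are
    unchanged.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return list(reads)
    rng = np.random.default_rng(seed)
    mutated: List[LabeledRead] = []
    for read in reads:
        codes = read.record.codes.copy()
        hit = (rng.random(len(codes)) < rate) & (codes != 4)
        n_hit = int(hit.sum())
        if n_hit:
            shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
            codes[hit] = (codes[hit] + shift) % 4
        mutated.append(
            LabeledRead(
                record=SequenceRecord(read.record.id, decode(codes)),
                source_genome=read.source_genome,
                source_pos=read.source_pos,
                strand=read.strand,
            )
        )
    return mutated


def reads_for_total_bp(total_bp: int, read_len: int) -> int:
    """Read count holding total sequenced bp constant (floor division)."""
    n = total_bp // read_len
    if n < 1:
        raise ValueError("total_bp must be at least read_len")
    return n


def reads_to_set(reads: Sequence[LabeledRead]) -> SequenceSet:
    return SequenceSet([r.record for r in reads])


def truth_table(reads: Sequence[LabeledRead]) -> dict:
    return {r.record.id: r.source_genome for r in reads}


def write_simulation(
    out_dir,
    genomes: SequenceSet,
    abundances: Sequence[float],
    reads: Sequence[LabeledRead],
) -> None:
    """Write reads.fa, truth.tsv, genomes.fa, and abundances.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta([r.record for r in reads], out_dir / "reads.fa")
    write_fasta(genomes, out_dir / "genomes.fa")
    with open(out_dir / "truth.tsv", "w", newline="\n") as fh:
        for r in reads:
            fh.write(f"{r.record.id}\t{r.source_genome}\n")
    with open(out_dir / "abundances.tsv", "w", newline="\n") as fh:
        for rec, a in zip(genomes, abundances):
            fh.write(f"{rec.id}\t{a:.8f}\n")
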
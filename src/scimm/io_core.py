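"""FASTA input/output, cluster-assignment tables, and deterministic subsampling.

Sequences are plain A/C/G/T/N strings.  Any character outside {A,C,G,T}
(IUPAC ambiguity codes, gaps, lowercase soft-masking) is collapsed to ``N``
on ingest so that downstream models see a four-letter alphabet plus one
"unknown" symbol.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Sequence, Union

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SequenceRecord",
    "SequenceSet",
    "Assignment",
    "read_fasta",
    "write_fasta",
    "write_assignments",
    "read_assignments",
    "subsample_bp",
    "encode",
    "decode",
    "reverse_complement",
]

PathLike = Union[str, Path]

#: mapping from sequence id to integer cluster id
Assignment = Dict[str, int]

# Translation table: uppercase, then anything outside ACGT becomes N.
_CLEAN = {}
for _c in range(256):
    _ch = chr(_c).upper()
    _CLEAN[_c] = _ch if _ch in "ACGT" else "N"
_CLEAN_TABLE = str.maketrans(_CLEAN)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> code lookup used by encode(); A=0 C=1 G=2 T=3, everything else 4
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

N_CODE = 4


def clean_sequence(raw: str) -> str:
    """Uppercase ``raw`` and collapse non-ACGT characters to N."""
    return raw.translate(_CLEAN_TABLE)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as a uint8 array (A=0, C=1, G=2, T=3, N=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DEC[codes].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence with a unique identifier."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if len(self.seq) == 0:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.seq)


@dataclass
class SequenceSet:
    """Ordered collection of records with unique ids."""

    records: List[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen, dups = set(), []
            for i in ids:
                if i in seen:
                    dups.append(i)
                seen.add(i)
            raise ValueError(f"duplicate sequence ids: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> List[str]:
        return [r.id for r in self.records]

    @property
    def total_bp(self) -> int:
        return sum(len(r) for r in self.records)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(r) for r in self.records], dtype=np.int64)

    def subset(self, indices: Sequence[int]) -> "SequenceSet":
        return SequenceSet([self.records[i] for i in indices])

    def by_id(self) -> Dict[str, SequenceRecord]:
        return {r.id: r for r in self.records}


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: PathLike) -> SequenceSet:
    """Parse a (possibly gzipped) FASTA file into a :class:`SequenceSet`.

    The record id is the first whitespace-delimited token of the header.
    Sequences are uppercased and non-ACGT characters become N.  Empty
    sequences and duplicate ids raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[SequenceRecord] = []
    seen = set()
    with _open_text(path) as fh:
        for header, raw in SimpleFastaParser(fh):
            seq = clean_sequence(raw.replace(" ", "").replace("\t", ""))
            if not seq:
                raise ValueError(f"empty sequence for FASTA entry {header!r}")
            rid = header.split()[0]
            if rid in seen:
                raise ValueError(f"duplicate sequence id {rid!r} in {path}")
            seen.add(rid)
            records.append(SequenceRecord(rid, seq))
    return SequenceSet(records)


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_assignments(assignment: Assignment, sset: SequenceSet, out_dir: PathLike) -> List[Path]:
    """Write ``clusters.tsv`` plus one FASTA per non-empty cluster.

    Every sequence id in ``sset`` must be present in ``assignment``.
    Returns the list of written file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = [r.id for r in sset if r.id not in assignment]
    if missing:
        raise ValueError(f"sequences missing from assignment: {missing[:10]}")
    written: List[Path] = []
    tsv = out_dir / "clusters.tsv"
    with open(tsv, "w", newline="\n") as fh:
        for rec in sset:
            fh.write(f"{rec.id}\t{assignment[rec.id]}\n")
    written.append(tsv)
    clusters: Dict[int, List[SequenceRecord]] = {}
    for rec in sset:
        clusters.setdefault(assignment[rec.id], []).append(rec)
    for cid in sorted(clusters):
        fa = out_dir / f"cluster-{cid}.fa"
        write_fasta(clusters[cid], fa)
        written.append(fa)
    return written


def read_assignments(path: PathLike) -> Assignment:
    """Read a two-column ``clusters.tsv`` (sequence_id TAB cluster_id)."""
    assignment: Assignment = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, cid = parts
            if sid in assignment:
                raise ValueError(f"{path}:{lineno}: duplicate sequence id {sid!r}")
            assignment[sid] = int(cid)
    return assignment


def subsample_bp(sset: SequenceSet, target_bp: int, seed: int) -> SequenceSet:
    """Pick whole sequences uniformly at random until ``target_bp`` is covered.

    Sequences are drawn without replacement; sampling stops as soon as the
    cumulative length reaches ``target_bp`` (or the set is exhausted).  The
    result preserves the input ordering of the selected records and is
    deterministic for a fixed seed.
    """
    if target_bp < 1:
        raise ValueError("target_bp must be >= 1")
    if sset.total_bp <= target_bp:
        return SequenceSet(list(sset.records))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sset))
    cum = np.cumsum(sset.lengths[order])
    n_take = int(np.searchsorted(cum, target_bp)) + 1
    chosen = np.sort(order[:n_take])
    return sset.subset(chosen.tolist())
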
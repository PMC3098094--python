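"""End-to-end orchestration and the ``scimm`` command-line interface.

Subcommands: ``simulate`` (synthetic mixtures), ``cluster`` (unsupervised
clustering), ``physcimm`` (clustering seeded from a classification table),
and ``eval`` (accuracy against a truth table).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional

import click
import numpy as np

from . import __version__
from .cluster import ClusterState, physcimm_seed, run_scimm
from .imm import IcmConfig
from .initseed import (
    compostbin_partition,
    likelybin_partition,
    random_partition,
    select_initialization,
)
from .io_core import (
    Assignment,
    SequenceSet,
    read_assignments,
    read_fasta,
    subsample_bp,
    write_assignments,
)
from .metrics import evaluate, read_truth
from .simulate import (
    ReadSimConfig,
    generate_markov_genome,
    random_divergent_params,
    reads_to_set,
    sample_abundances,
    simulate_reads,
    write_simulation,
)
logger = logging.getLogger("scimm")

INIT_MODES = ("both", "compostbin", "likelybin", "random", "file")


@dataclass
class RunConfig:
    """Validated configuration of one clustering run."""

    input: Path
    out_dir: Path
    k: int = 2
    init: str = "both"
    init_file: Optional[Path] = None
    w: int = 8
    seed: int = 1
    subsample_bp: int = 3_000_000
    converge_frac: float = 0.001
    max_iters: int = 100
    min_split_windows: int = 200
    classifications: Optional[Path] = None
    k_expected: Optional[int] = None
    truth: Optional[Path] = None
    taxmap: Optional[Path] = None

    def validate(self) -> None:
        problems: List[str] = []
        if not Path(self.input).exists():
            problems.append(f"input file not found: {self.input}")
        if self.k < 1:
            problems.append(f"k must be >= 1, got {self.k}")
        if not 0.0 < self.converge_frac < 1.0:
            problems.append(f"converge_frac must be in (0,1), got {self.converge_frac}")
        if self.init not in INIT_MODES:
            problems.append(f"init must be one of {INIT_MODES}, got {self.init!r}")
        if self.init == "file" and (self.init_file is None or not Path(self.init_file).exists()):
            problems.append("init mode 'file' requires an existing --init-file")
        for name in ("classifications", "truth", "taxmap"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                problems.append(f"{name} file not found: {p}")
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))


def read_config_file(path) -> Dict[str, str]:
    """Parse a simple ``key = value`` config file (# comments allowed)."""
    options: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            options[key.strip().replace("-", "_")] = value.strip()
    return options


def _initial_candidates(cfg: RunConfig, sset: SequenceSet) -> List[Assignment]:
    sub = subsample_bp(sset, cfg.subsample_bp, seed=cfg.seed)
    k = min(cfg.k, len(sub))
    if cfg.init == "compostbin":
        return [compostbin_partition(sub, k, seed=cfg.seed)]
    if cfg.init == "likelybin":
        return [likelybin_partition(sub, k, seed=cfg.seed)]
    if cfg.init == "random":
        return [random_partition(sub, k, seed=cfg.seed)]
    if cfg.init == "file":
        assignment = read_assignments(cfg.init_file)
        known = set(sset.ids)
        return [{sid: cid for sid, cid in assignment.items() if sid in known}]
    # "both": dual initialization, arbitrated by CML
    return [
        compostbin_partition(sub, k, seed=cfg.seed),
        likelybin_partition(sub, k, seed=cfg.seed),
    ]


def run_pipeline(cfg: RunConfig) -> ClusterState:
    """Initialize, cluster, and write all run outputs.

    In ``physcimm`` mode (``cfg.classifications`` set) the initial partition
    comes from the classification table; otherwise from the configured
    unsupervised initializer(s) on a subsample.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(out_dir)
    sset = read_fasta(cfg.input)
    icm_cfg = IcmConfig(w=cfg.w, min_split_windows=cfg.min_split_windows)
    from .cluster import make_backend

    backend = make_backend(sset, model="icm", icm_config=icm_cfg)
    if cfg.classifications is not None:
        table = read_truth(cfg.classifications)
        k_expected = cfg.k_expected or cfg.k
        init = physcimm_seed(sset, table, k_expected)
        k = len(set(init.values()))
        logger.info("classification seeding produced %d clusters", k)
    else:
        candidates = _initial_candidates(cfg, sset)
        init = select_initialization(candidates, sset, w=cfg.w, backend=backend)
        k = min(cfg.k, len(set(init.values())))
    state = run_scimm(
        sset,
        k=max(k, len(set(init.values()))),
        init=init,
        w=cfg.w,
        max_iters=cfg.max_iters,
        converge_frac=cfg.converge_frac,
        seed=cfg.seed,
        backend=backend,
    )
    write_assignments(state.assignment, sset, out_dir)
    _write_run_metadata(cfg, state, out_dir)
    if cfg.truth is not None:
        report = _metrics_report(state.assignment, cfg, sset)
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info(
            "recall=%.4f precision=%.4f ari=%.4f",
            report["recall"], report["precision"], report["ari"],
        )
    return state


def _metrics_report(assignment: Assignment, cfg: RunConfig, sset: SequenceSet) -> Dict:
    truth = read_truth(cfg.truth)
    taxmap = read_truth(cfg.taxmap) if cfg.taxmap else None
    result = evaluate(assignment, truth, sset, taxmap=taxmap)
    return {
        "recall": result["recall"],
        "precision": result["precision"],
        "ari": result["ari"],
        "recall_per_genome": {
            g: float(v)
            for g, v in zip(result["confusion"].genome_ids, result["recall_per_genome"])
        },
        "precision_per_cluster": {
            str(c): float(v)
            for c, v in zip(result["confusion"].cluster_ids, result["precision_per_cluster"])
        },
    }


def _write_run_metadata(cfg: RunConfig, state: ClusterState, out_dir: Path) -> None:
    meta = {
        "version": __version__,
        "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(cfg).items()},
        "iterations": state.iteration,
        "converged": state.converged,
        "cml": state.cml,
        "n_clusters": len(set(state.assignment.values())),
        "history": [
            {"iteration": h.iteration, "n_changed": h.n_changed, "cml": h.cml}
            for h in state.history
        ],
    }
    with open(out_dir / "run.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def _setup_run_logging(out_dir: Path) -> None:
    root = logging.getLogger("scimm")
    root.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        root.addHandler(handler)
    logging.getLogger("scimm.cluster").setLevel(logging.INFO)


# ---------------------------------------------------------------------------
# CLI


def _apply_config_file(ctx, param, value):
    if value is None:
        return None
    options = read_config_file(value)
    ctx.default_map = dict(options, **(ctx.default_map or {}))
    return value


@click.group()
@click.version_option(version=__version__)
def cli() -> None:
    """Cluster metagenomic sequences with interpolated context models."""


_config_option = click.option(
    "--config", type=click.Path(exists=True), callback=_apply_config_file,
    is_eager=True, expose_value=False,
    help="key=value config file; command-line flags take precedence.",
)


@cli.command("cluster")
@click.argument("input_fasta", type=click.Path(exists=True))
@click.option("-k", "k", type=int, default=2, show_default=True, help="Number of clusters.")
@click.option("--init", type=click.Choice(INIT_MODES), default="both", show_default=True)
@click.option("--init-file", type=click.Path(), default=None,
              help="clusters.tsv used when --init file.")
@click.option("--width", "w", type=int, default=8, show_default=True,
              help="Context window width of the cluster models.")
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--max-iters", type=int, default=100, show_default=True)
@click.option("--converge", "converge_frac", type=float, default=0.001, show_default=True,
              help="Halt when fewer than this fraction of sequences move.")
@click.option("--subsample-bp", type=int, default=3_000_000, show_default=True,
              help="bp of sequence used for initialization.")
@click.option("--truth", type=click.Path(exists=True), default=None,
              help="Optional truth TSV; writes metrics.json.")
@click.option("--taxmap", type=click.Path(exists=True), default=None)
@click.option("-o", "--out-dir", type=click.Path(), required=True)
@_config_option
def cluster_cmd(input_fasta, k, init, init_file, w, seed, max_iters, converge_frac,
                subsample_bp, truth, taxmap, out_dir):
    """Unsupervised clustering of a FASTA file."""
    cfg = RunConfig(
        input=Path(input_fasta), out_dir=Path(out_dir), k=k, init=init,
        init_file=Path(init_file) if init_file else None, w=w, seed=seed,
        subsample_bp=subsample_bp, converge_frac=converge_frac, max_iters=max_iters,
        truth=Path(truth) if truth else None, taxmap=Path(taxmap) if taxmap else None,
    )
    state = run_pipeline(cfg)
    click.echo(
        f"{len(set(state.assignment.values()))} clusters after {state.iteration} iterations "
        f"(converged={state.converged}); outputs in {out_dir}"
    )


@cli.command("physcimm")
@click.argument("input_fasta", type=click.Path(exists=True))
@click.option("--classifications", type=click.Path(exists=True), required=True,
              help="TSV of sequence_id TAB taxon_label seeding the clusters.")
@click.option("--k-expected", type=int, required=True,
              help="Expected genome count; sets the 20/k%% bp filter.")
@click.option("--width", "w", type=int, default=8, show_default=True)
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--max-iters", type=int, default=100, show_default=True)
@click.option("--converge", "converge_frac", type=float, default=0.001, show_default=True)
@click.option("--truth", type=click.Path(exists=True), default=None)
@click.option("--taxmap", type=click.Path(exists=True), default=None)
@click.option("-o", "--out-dir", type=click.Path(), required=True)
@_config_option
def physcimm_cmd(input_fasta, classifications, k_expected, w, seed, max_iters,
                 converge_frac, truth, taxmap, out_dir):
    """Clustering seeded from a supervised classification table."""
    cfg = RunConfig(
        input=Path(input_fasta), out_dir=Path(out_dir), k=k_expected,
        classifications=Path(classifications), k_expected=k_expected, w=w, seed=seed,
        converge_frac=converge_frac, max_iters=max_iters,
        truth=Path(truth) if truth else None, taxmap=Path(taxmap) if taxmap else None,
    )
    state = run_pipeline(cfg)
    click.echo(
        f"{len(set(state.assignment.values()))} clusters after {state.iteration} iterations "
        f"(converged={state.converged}); outputs in {out_dir}"
    )


@cli.command("simulate")
@click.option("-k", "k", type=int, default=2, show_default=True, help="Number of genomes.")
@click.option("--n-reads", type=int, default=2000, show_default=True)
@click.option("--read-len", type=int, default=800, show_default=True)
@click.option("--error-rate", type=float, default=0.0, show_default=True)
@click.option("--genome-len", type=int, default=200_000, show_default=True)
@click.option("--order", type=int, default=3, show_default=True,
              help="Order of the genome-generating Markov chains.")
@click.option("--min-js", type=float, default=0.05, show_default=True,
              help="Minimum pairwise Jensen-Shannon divergence between genomes (bits).")
@click.option("--genomes", "genome_fasta", type=click.Path(exists=True), default=None,
              help="Sample from these genomes instead of synthesizing them.")
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("-o", "--out-dir", type=click.Path(), required=True)
@_config_option
def simulate_cmd(k, n_reads, read_len, error_rate, genome_len, order, min_js,
                 genome_fasta, seed, out_dir):
    """Generate a synthetic read mixture with ground truth."""
    if genome_fasta is not None:
        genomes = read_fasta(genome_fasta)
        k = len(genomes)
    else:
        params = random_divergent_params(k, order, seed=seed, min_js=min_js)
        genomes = SequenceSet(
            [
                generate_markov_genome(order, params[g], genome_len, seed=seed + g,
                                       genome_id=f"genome_{g}")
                for g in range(k)
            ]
        )
    abundances = sample_abundances(k, seed=seed)
    cfg = ReadSimConfig(n_reads=n_reads, read_len=read_len, error_rate=error_rate, seed=seed)
    reads = simulate_reads(genomes, abundances, cfg)
    write_simulation(out_dir, genomes, abundances, reads)
    click.echo(f"wrote {len(reads)} reads from {k} genomes to {out_dir}")


@cli.command("eval")
@click.argument("clusters_tsv", type=click.Path(exists=True))
@click.argument("input_fasta", type=click.Path(exists=True))
@click.option("--truth", type=click.Path(exists=True), required=True)
@click.option("--taxmap", type=click.Path(exists=True), default=None)
@_config_option
def eval_cmd(clusters_tsv, input_fasta, truth, taxmap):
    """Score a clustering against a truth table."""
    sset = read_fasta(input_fasta)
    assignment = read_assignments(clusters_tsv)
    truth_map = read_truth(truth)
    taxmap_map = read_truth(taxmap) if taxmap else None
    result = evaluate(assignment, truth_map, sset, taxmap=taxmap_map)
    cm = result["confusion"]
    click.echo("per-genome recall:")
    for g, v in zip(cm.genome_ids, result["recall_per_genome"]):
        click.echo(f"  {g}\t{v:.4f}")
    click.echo("per-cluster precision:")
    for c, v in zip(cm.cluster_ids, result["precision_per_cluster"]):
        click.echo(f"  {c}\t{v:.4f}")
    click.echo(f"recall\t{result['recall']:.4f}")
    click.echo(f"precision\t{result['precision']:.4f}")
    click.echo(f"ari\t{result['ari']:.4f}")


def main() -> None:  # pragma: no cover
    cli()
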
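# scimm

Unsupervised clustering ("binning") of metagenomic DNA sequences with
interpolated context models (ICMs).

Each cluster is modeled by an ICM — a probabilistic decision tree over a
fixed-width context window that splits on the most informative positions
(by mutual information) and blends each node's distribution with its
parent's using a chi-square-derived weight, so the effective model order
adapts to the amount of training data. Clustering alternates model
retraining with maximum-posterior reassignment (hard-assignment
classification EM) and halts when fewer than 0.1% of sequences change
clusters.

The package also provides:

- **Initializers**: composition-based recursive spectral bisection
  (k-mer profiles → PCA → kNN graph → normalized cut) and a
  Metropolis-search initializer over fixed-order Markov chain clusters,
  with CML-based arbitration between candidate initializations.
- **Supervised seeding**: start from a taxonomic classification table,
  keeping only taxa holding > 20/k % of classified bases and sending
  everything else to a catch-all cluster.
- **Evaluation**: bp-weighted recall and precision, adjusted Rand index,
  with optional truth-label remapping to a higher taxonomic level.
- **Simulation**: synthetic Markov-chain genomes, mixture read sampling
  with random abundances, and substitution-error injection, so the whole
  pipeline is testable without any external data.

## Command line

```sh
# generate a synthetic 2-genome mixture with ground truth
scimm simulate -k 2 --n-reads 2000 --read-len 800 --seed 1 -o sim/

# cluster it (dual initialization; -k clusters)
scimm cluster sim/reads.fa -k 2 --init both --width 8 --seed 1 -o run/

# clustering seeded from a classification table (taxon per sequence)
scimm physcimm sim/reads.fa --classifications cls.tsv --k-expected 10 -o run2/

# score a clustering against truth
scimm eval run/clusters.tsv sim/reads.fa --truth sim/truth.tsv
```

A run directory contains `clusters.tsv` (sequence_id TAB cluster_id), one
FASTA per cluster, `run.json` (config echo, per-iteration log, CML), and
`metrics.json` when `--truth` is given. All commands accept `--config
FILE` with `key = value` lines; explicit flags win. Runs are fully
deterministic given inputs and `--seed`.

## Python API

```python
from scimm import read_fasta, run_scimm, IcmConfig
from scimm.initseed import compostbin_partition

sset = read_fasta("reads.fa")
init = compostbin_partition(sset, k=2)
state = run_scimm(sset, k=2, init=init, icm_config=IcmConfig(w=8))
state.assignment   # {sequence_id: cluster_id}
```

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance suite (oracle equivalence
of ICM scoring against an independent fixed-order chain, normalized-cut
optimality against exhaustive search, CML monotonicity in oracle mode,
two-genome recovery, read-length and error-rate robustness trends, metric
reference values, and the supervised seeding filter). The full suite takes
several minutes because the clustering criteria run simulated experiments
over many seeds.

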
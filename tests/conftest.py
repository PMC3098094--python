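import pytest

from scimm import simulate as sim
from scimm.io_core import SequenceSet, write_fasta


def make_mixture(
    k=2,
    n_reads=1000,
    read_len=800,
    genome_len=150_000,
    order=3,
    min_js=0.08,
    error_rate=0.0,
    seed=7,
):
    """Synthetic mixture of k divergent Markov-chain genomes.

    Returns (reads SequenceSet, truth dict, genomes SequenceSet, abundances).
    """
    params = sim.random_divergent_params(k, order, seed=seed, min_js=min_js)
    genomes = SequenceSet(
        [
            sim.generate_markov_genome(order, params[g], genome_len, seed=seed * 1000 + g,
                                       genome_id=f"genome_{g}")
            for g in range(k)
        ]
    )
    abundances = sim.sample_abundances(k, seed=seed + 1)
    cfg = sim.ReadSimConfig(n_reads=n_reads, read_len=read_len,
                            error_rate=error_rate, seed=seed + 2)
    reads = sim.simulate_reads(genomes, abundances, cfg)
    return sim.reads_to_set(reads), sim.truth_table(reads), genomes, abundances


@pytest.fixture(scope="session")
def two_genome_mixture():
    sset, truth, genomes, ab = make_mixture(k=2, n_reads=1000)
    return sset, truth


@pytest.fixture
def fasta_file(tmp_path):
    def _write(records, name="seqs.fa"):
        path = tmp_path / name
        write_fasta(records, path)
        return path

    return _write


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
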
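import math

import numpy as np
import pytest
from scipy.stats import chi2

from scimm.imm import (
    ContextCorpus,
    IcmConfig,
    IcmModel,
    IcmNode,
    build_corpus,
    interpolate,
    load_model,
    mutual_information,
    save_model,
    score_sequence,
    train_icm,
)
from scimm.io_core import SequenceRecord, SequenceSet

from conftest import random_dna


# ---------------------------------------------------------------------------
# independent oracle: a plain dict-based fixed-order chain


class DictChainOracle:
    """Order-w Markov chain with per-context pseudocounts, no numpy."""

    def __init__(self, training: list, w: int, pseudocount: float):
        self.w = w
        self.ps = pseudocount
        self.counts = {}
        for seq in training:
            for i in range(w, len(seq)):
                window = seq[i - w : i + 1]
                if "N" in window:
                    continue
                ctx = window[:w]
                self.counts.setdefault(ctx, {b: 0 for b in "ACGT"})
                self.counts[ctx][seq[i]] += 1

    def log_prob(self, ctx: str, base: str) -> float:
        by_base = self.counts.get(ctx, {b: 0 for b in "ACGT"})
        total = sum(by_base.values())
        return math.log((by_base[base] + self.ps) / (total + 4 * self.ps))

    def score(self, seq: str) -> float:
        total = 0.0
        for i in range(self.w, len(seq)):
            window = seq[i - self.w : i + 1]
            if "N" in window:
                total += math.log(0.25)
            else:
                total += self.log_prob(window[: self.w], seq[i])
        return total


def corpus_from_pairs(pairs, w=1):
    """Build a ContextCorpus from (context string, outcome char) pairs."""
    code = {c: i for i, c in enumerate("ACGT")}
    contexts = np.array([[code[c] for c in ctx] for ctx, _ in pairs], dtype=np.uint8)
    outcomes = np.array([code[o] for _, o in pairs], dtype=np.uint8)
    return ContextCorpus(w=w, contexts=contexts.reshape(len(pairs), w), outcomes=outcomes)


class TestBuildCorpus:
    def test_enumeration(self):
        corpus = build_corpus(SequenceSet([SequenceRecord("a", "ACGTA")]), w=2)
        windows = {
            ("".join("ACGT"[b] for b in ctx), "ACGT"[out])
            for ctx, out in zip(corpus.contexts, corpus.outcomes)
        }
        assert windows == {("AC", "G"), ("CG", "T"), ("GT", "A")}
        assert len(corpus) == 3

    def test_short_sequence_boundary(self):
        corpus = build_corpus(SequenceSet([SequenceRecord("a", "AC")]), w=2)
        assert len(corpus) == 0

    def test_n_exclusion(self):
        corpus = build_corpus(SequenceSet([SequenceRecord("a", "ACNGT")]), w=1)
        windows = {
            ("ACGT"[ctx[0]], "ACGT"[out])
            for ctx, out in zip(corpus.contexts, corpus.outcomes)
        }
        assert windows == {("A", "C"), ("G", "T")}

    def test_window_count_formula(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 300)
        for w in (0, 1, 3):
            corpus = build_corpus(SequenceSet([SequenceRecord("a", seq)]), w=w)
            assert len(corpus) == max(0, len(seq) - w)


class TestMutualInformation:
    def test_independence_is_zero(self):
        pairs = [(c, o) for c in "ACGT" for o in "ACGT"]
        corpus = corpus_from_pairs(pairs)
        assert mutual_information(corpus, 1) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_copy_is_two_bits(self):
        pairs = [(c, c) for c in "ACGT"]
        corpus = corpus_from_pairs(pairs)
        assert mutual_information(corpus, 1) == pytest.approx(2.0, abs=1e-12)

    def test_plug_in_formula(self):
        # joint counts {(A,A):8,(A,C):2,(C,A):2,(C,C):8}; oracle is the
        # direct entropy computation H(X) + H(Y) - H(X,Y)
        pairs = [("A", "A")] * 8 + [("A", "C")] * 2 + [("C", "A")] * 2 + [("C", "C")] * 8
        corpus = corpus_from_pairs(pairs)

        def h(ps):
            return -sum(p * math.log2(p) for p in ps if p > 0)

        expected = h([0.5, 0.5]) + h([0.5, 0.5]) - h([0.4, 0.1, 0.1, 0.4])
        assert mutual_information(corpus, 1) == pytest.approx(expected, abs=1e-12)

    def test_empty_corpus_errors(self):
        corpus = ContextCorpus(
            w=1, contexts=np.empty((0, 1), dtype=np.uint8), outcomes=np.empty(0, dtype=np.uint8)
        )
        with pytest.raises(ValueError):
            mutual_information(corpus, 1)


class TestInterpolate:
    def test_proportional_counts_keep_parent(self):
        parent = np.array([0.25, 0.25, 0.25, 0.25])
        lam, dist = interpolate(np.array([10, 10, 10, 10]), parent, pseudocount=0.5)
        assert lam == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(dist, parent, atol=1e-9)

    def test_large_divergent_counts_dominate(self):
        parent = np.array([0.25, 0.25, 0.25, 0.25])
        counts = np.array([100_000, 0, 0, 0])
        lam, dist = interpolate(counts, parent, pseudocount=0.5)
        assert lam > 0.99
        assert dist[0] > 0.99

    def test_chi_square_oracle(self):
        # counts (40,0,0,0) against a uniform parent, N0 = 400
        counts = np.array([40.0, 0, 0, 0])
        parent = np.full(4, 0.25)
        lam, dist = interpolate(counts, parent, pseudocount=0.5, n0=400.0)
        stat = sum((c - 10.0) ** 2 / 10.0 for c in counts)
        expected_lam = (1.0 - chi2.sf(stat, df=3)) * 40.0 / (40.0 + 400.0)
        assert lam == pytest.approx(expected_lam, abs=1e-12)
        child_emp = (counts + 0.5) / (40.0 + 2.0)
        np.testing.assert_allclose(
            dist, expected_lam * child_emp + (1 - expected_lam) * parent, atol=1e-12
        )

    def test_distribution_sums_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 50, size=4).astype(float)
            parent = rng.dirichlet(np.ones(4))
            _, dist = interpolate(counts, parent, pseudocount=0.5)
            assert dist.sum() == pytest.approx(1.0, abs=1e-9)
            assert (dist > 0).all()


def _tree_nodes(node, depth=0, path=()):
    yield node, depth, path
    if node.children:
        for child in node.children:
            yield from _tree_nodes(child, depth + 1, path + (node.split_position,))


class TestTrainIcm:
    def test_independent_outcome_gives_root_leaf(self):
        # corpus where the outcome is exactly independent of both context
        # positions (every context sees outcome counts 4:3:2:1)
        from scimm.imm import train_icm_from_corpus

        pairs = []
        for c1 in "ACGT":
            for c2 in "ACGT":
                for out, reps in zip("ACGT", (4, 3, 2, 1)):
                    pairs.extend([(c1 + c2, out)] * reps)
        corpus = corpus_from_pairs(pairs, w=2)
        model = train_icm_from_corpus(corpus, IcmConfig(w=2, min_split_windows=1))
        assert model.root.is_leaf
        np.testing.assert_allclose(model.root.raw_dist, [0.4, 0.3, 0.2, 0.1], atol=1e-12)

    def test_root_splits_on_determining_position(self):
        # outcome copies the immediately preceding base (position w); MI
        # oracle ranks position w strictly highest
        rng = np.random.default_rng(6)
        chunks = []
        for _ in range(3000):
            b = "ACGT"[rng.integers(4)]
            chunks.append(random_dna(rng, 2) + b + b)
        seq = "".join(chunks)
        corpus = build_corpus(SequenceSet([SequenceRecord("a", seq)]), w=3)
        mis = [mutual_information(corpus, p) for p in (1, 2, 3)]
        assert np.argmax(mis) == 2  # position 3 == w
        model = train_icm(SequenceSet([SequenceRecord("a", seq)]), w=3,
                          min_split_windows=50)
        assert model.root.split_position == 3

    def test_homopolymer_monotonicity(self):
        model = train_icm(SequenceSet([SequenceRecord("a", "A" * 1000)]), w=3)
        assert score_sequence(model, SequenceRecord("x", "AAAA")) > score_sequence(
            model, SequenceRecord("y", "ACGT")
        )

    def test_no_windows_errors(self):
        with pytest.raises(ValueError, match="smaller w"):
            train_icm(SequenceSet([SequenceRecord("a", "ACG")]), w=5)

    def test_tree_invariants(self):
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 20_000)
        model = train_icm(SequenceSet([SequenceRecord("a", seq)]), w=5,
                          min_split_windows=50)
        for node, depth, path in _tree_nodes(model.root):
            assert depth <= 5
            assert node.interp_dist.sum() == pytest.approx(1.0, abs=1e-9)
            assert (node.interp_dist > 0).all()
            assert node.raw_dist.sum() == pytest.approx(1.0, abs=1e-9)
            if node.split_position is not None:
                assert node.split_position not in path  # no reuse along a path
                assert node.n_windows == sum(c.n_windows for c in node.children)

    def test_training_deterministic(self, tmp_path):
        rng = np.random.default_rng(8)
        sset = SequenceSet([SequenceRecord("a", random_dna(rng, 5000))])
        m1 = train_icm(sset, w=4, min_split_windows=50)
        m2 = train_icm(sset, w=4, min_split_windows=50)
        probe = SequenceRecord("p", random_dna(rng, 500))
        assert score_sequence(m1, probe) == score_sequence(m2, probe)


def uniform_leaf_model(w):
    node = IcmNode(n_windows=0, raw_dist=np.full(4, 0.25),
                   interp_dist=np.full(4, 0.25), lam=0.0)
    return IcmModel(w=w, root=node, config=IcmConfig(w=w))


class TestScoreSequence:
    def test_uniform_leaf_constant_terms(self):
        model = uniform_leaf_model(5)
        s = SequenceRecord("s", "ACGTACGTAC")  # |s| = 10, w = 5 -> 5 windows
        assert score_sequence(model, s) == pytest.approx(5 * math.log(0.25), abs=1e-12)

    def test_too_short_errors(self):
        model = uniform_leaf_model(5)
        with pytest.raises(ValueError):
            score_sequence(model, SequenceRecord("s", "ACGTA"))

    def test_n_positions_score_log_quarter(self):
        model = uniform_leaf_model(2)
        a = score_sequence(model, SequenceRecord("s", "ACGNNTACG"))
        assert a == pytest.approx(7 * math.log(0.25), abs=1e-12)

    @pytest.mark.parametrize("w", [2, 4])
    def test_fixed_order_oracle_equivalence(self, w):
        # interpolation off + full depth == brute-force order-w chain
        rng = np.random.default_rng(9)
        train_seq = random_dna(rng, 30_000)
        cfg = IcmConfig(w=w, min_split_windows=1, pseudocount=0.5,
                        stop_alpha=None, interpolation=False)
        sset = SequenceSet([SequenceRecord("t", train_seq)])
        model = train_icm(sset, config=cfg)
        oracle = DictChainOracle([train_seq], w=w, pseudocount=0.5)
        for _ in range(5):
            probe = random_dna(rng, 300)
            assert score_sequence(model, SequenceRecord("p", probe)) == pytest.approx(
                oracle.score(probe), abs=1e-9
            )

    def test_concatenation_additivity(self):
        # windows of s are exactly windows of s[:j] plus windows of s[j-w:]
        rng = np.random.default_rng(10)
        w = 4
        sset = SequenceSet([SequenceRecord("t", random_dna(rng, 10_000))])
        model = train_icm(sset, w=w, min_split_windows=50)
        s = random_dna(rng, 200)
        j = 77
        total = score_sequence(model, SequenceRecord("s", s))
        left = score_sequence(model, SequenceRecord("l", s[:j]))
        right = score_sequence(model, SequenceRecord("r", s[j - w :]))
        assert total == pytest.approx(left + right, abs=1e-9)

    def test_source_model_scores_higher(self):
        # 1 kbp probes score higher under a model trained on their own
        # source than under a compositionally divergent source's model
        from scimm import simulate as sim

        wins = 0
        for seed in range(20):
            params = sim.random_divergent_params(2, 2, seed=100 + seed, min_js=0.1)
            g0 = sim.generate_markov_genome(2, params[0], 30_000, seed=seed)
            g1 = sim.generate_markov_genome(2, params[1], 30_000, seed=seed + 500)
            m0 = train_icm(SequenceSet([g0]), w=4, min_split_windows=100)
            m1 = train_icm(SequenceSet([g1]), w=4, min_split_windows=100)
            probe = SequenceRecord("p", sim.generate_markov_genome(
                2, params[0], 1000, seed=seed + 900).seq)
            if score_sequence(m0, probe) >= score_sequence(m1, probe):
                wins += 1
        assert wins >= 19

    def test_both_max_strand_mode(self):
        rng = np.random.default_rng(11)
        sset = SequenceSet([SequenceRecord("t", random_dna(rng, 5000))])
        model = train_icm(sset, w=3, min_split_windows=50)
        from scimm.io_core import reverse_complement

        s = random_dna(rng, 200)
        fwd = score_sequence(model, SequenceRecord("s", s))
        rc = score_sequence(model, SequenceRecord("s", reverse_complement(s)))
        both = score_sequence(model, SequenceRecord("s", s), strand_mode="both-max")
        assert both == pytest.approx(max(fwd, rc), abs=1e-12)

    def test_unknown_strand_mode(self):
        model = uniform_leaf_model(2)
        with pytest.raises(ValueError):
            score_sequence(model, SequenceRecord("s", "ACGTACGT"), strand_mode="sideways")


def test_model_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(12)
    sset = SequenceSet([SequenceRecord("t", random_dna(rng, 8000))])
    model = train_icm(sset, w=4, min_split_windows=100)
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    probe = SequenceRecord("p", random_dna(rng, 400))
    assert score_sequence(back, probe) == pytest.approx(
        score_sequence(model, probe), abs=1e-12
    )
    assert back.w == model.w
    assert back.config == model.config
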
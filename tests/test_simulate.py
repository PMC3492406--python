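import numpy as np
import pytest

from lrmotifs.pwm import PositionWeightMatrix, build_pwm
from lrmotifs.seqcore import DnaSequence
from lrmotifs.simulate import (
    MarkovModel,
    PlantConfig,
    fit_markov,
    generate_null_clusters,
    generate_planted_dataset,
    iid_model,
    random_peaked_pfm,
    sample_iid_background,
    sample_markov,
    sample_pwm_instance,
)


class TestFitMarkov:
    def test_order0_no_pseudocount(self):
        m = fit_markov([DnaSequence("a", "ACGT")], 0, pseudocount=0)
        assert m.conditional_probs[0] == pytest.approx([0.25] * 4)

    def test_order1_hand_tally(self):
        m = fit_markov([DnaSequence("a", "AAAA")], 1, pseudocount=1)
        assert m.conditional_probs[0, 0] == pytest.approx(4 / 7)  # (3+1)/(3+4)

    def test_unseen_context_uniform(self):
        m = fit_markov([DnaSequence("a", "AAAA")], 1, pseudocount=1)
        c_idx = 1  # context "C" never observed
        assert m.conditional_probs[c_idx] == pytest.approx([0.25] * 4)

    def test_input_errors(self):
        with pytest.raises(ValueError):
            fit_markov([], 0)
        with pytest.raises(ValueError):
            fit_markov([DnaSequence("a", "AC")], -1)

    def test_round_trip_recovery(self, rng):
        gen = fit_markov([DnaSequence("t", "ACGTTGCAACGGT" * 40)], 1)
        samp = sample_markov(gen, 100_000, rng)
        samp.id = "x"
        refit = fit_markov([samp], 1, pseudocount=0)
        assert np.abs(refit.conditional_probs - gen.conditional_probs).max() < 0.02


class TestSampling:
    def test_degenerate_chain(self, rng):
        m = MarkovModel(0, np.array([[1e9, 0, 0, 0]]), np.ones(1), pseudocount=0)
        assert sample_markov(m, 12, rng).residues == "A" * 12

    def test_gc_concentration(self):
        rng = np.random.default_rng(8)
        s = sample_iid_background(0.4, 100_000, rng)
        gc = (s.residues.count("C") + s.residues.count("G")) / len(s)
        a = s.residues.count("A") / len(s)
        assert gc == pytest.approx(0.4, abs=0.01)
        assert a == pytest.approx(0.3, abs=0.01)

    def test_gc_extremes(self, rng):
        assert set(sample_iid_background(0.0, 100, rng).residues) <= {"A", "T"}
        assert set(sample_iid_background(1.0, 100, rng).residues) <= {"C", "G"}

    def test_seed_determinism(self):
        m = iid_model(0.4)
        a = sample_markov(m, 500, np.random.default_rng(5)).residues
        b = sample_markov(m, 500, np.random.default_rng(5)).residues
        assert a == b

    def test_markov_order2_reproducible_and_sized(self, rng):
        m = fit_markov([DnaSequence("a", "ACGTACGGTTACG" * 30)], 2)
        s = sample_markov(m, 777, rng)
        assert len(s) == 777


class TestPwmInstance:
    def test_deterministic_consensus(self, rng):
        m = build_pwm(["ACGT"] * 5, pseudocount=0)
        assert sample_pwm_instance(m, rng) == "ACGT"

    def test_uniform_base_frequencies(self):
        rng = np.random.default_rng(9)
        m = PositionWeightMatrix(np.ones((4, 1)), pseudocount=0)
        draws = [sample_pwm_instance(m, rng) for _ in range(10_000)]
        for b in "ACGT":
            assert draws.count(b) / 1e4 == pytest.approx(0.25, abs=0.02)

    def test_seed_determinism(self):
        m = random_peaked_pfm(8, np.random.default_rng(0))
        a = sample_pwm_instance(m, np.random.default_rng(3))
        b = sample_pwm_instance(m, np.random.default_rng(3))
        assert a == b


class TestPlantedDataset:
    def _deterministic_pfm(self, width=6):
        counts = np.zeros((4, width))
        counts[0] = 1e9  # poly-A consensus with probability ~1
        return PositionWeightMatrix(counts, pseudocount=0, name="polyA")

    def test_consensus_at_recorded_offsets(self):
        cfg = PlantConfig(
            pfms=[self._deterministic_pfm()], cluster_sizes=[5],
            sequence_length=50, seed=3,
        )
        coll, records, _ = generate_planted_dataset(cfg)
        seqs = {s.id: s for s in coll.all_sequences()}
        for r in records:
            assert seqs[r.sequence_id].residues[r.offset : r.offset + 6] == "AAAAAA"

    def test_cluster_shapes(self):
        rng = np.random.default_rng(1)
        pfms = [random_peaked_pfm(8, rng, name=f"p{i}") for i in range(2)]
        cfg = PlantConfig(pfms=pfms, cluster_sizes=[10, 20], sequence_length=100, seed=0)
        coll, records, true_pwms = generate_planted_dataset(cfg)
        assert [len(c) for c in coll] == [10, 20]
        assert len(records) == 30
        assert set(true_pwms) == {c.cluster_id for c in coll}

    def test_offsets_within_bounds_and_spread(self):
        rng = np.random.default_rng(2)
        pfm = random_peaked_pfm(8, rng, name="p")
        cfg = PlantConfig(pfms=[pfm], cluster_sizes=[400], sequence_length=40, seed=6)
        _, records, _ = generate_planted_dataset(cfg)
        offs = np.array([r.offset for r in records])
        assert offs.min() >= 0 and offs.max() <= 40 - 8
        # chi-square uniformity over the 33 possible offsets
        from scipy.stats import chisquare

        obs = np.bincount(offs, minlength=33)
        assert chisquare(obs).pvalue > 0.01

    def test_pfm_wider_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            PlantConfig(
                pfms=[self._deterministic_pfm(20)], cluster_sizes=[2],
                sequence_length=10,
            )

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        pfms = [random_peaked_pfm(8, rng, name="p")]
        cfg = PlantConfig(pfms=pfms, cluster_sizes=[3], sequence_length=60, seed=11)
        a, _, _ = generate_planted_dataset(cfg)
        b, _, _ = generate_planted_dataset(cfg)
        assert [s.residues for s in a.all_sequences()] == [
            s.residues for s in b.all_sequences()
        ]

    def test_background_composition_preserved(self):
        rng = np.random.default_rng(5)
        pfm = random_peaked_pfm(10, rng, name="p")
        cfg = PlantConfig(pfms=[pfm], cluster_sizes=[150], sequence_length=800, seed=13)
        coll, records, _ = generate_planted_dataset(cfg)
        recs = {r.sequence_id: r for r in records}
        gc_total, n_total = 0, 0
        for s in coll.all_sequences():
            r = recs[s.id]
            bgres = s.residues[: r.offset] + s.residues[r.offset + 10 :]
            gc_total += bgres.count("C") + bgres.count("G")
            n_total += len(bgres)
        assert gc_total / n_total == pytest.approx(0.4, abs=0.01)


class TestNullClusters:
    def test_partition(self, rng):
        pool = [DnaSequence(f"s{i}", "ACGTACGT") for i in range(10)]
        coll = generate_null_clusters(pool, [5, 5], rng)
        ids = [i for c in coll for i in c.member_ids()]
        assert sorted(ids) == sorted(s.id for s in pool)
        assert coll.disjoint

    def test_pool_exhausted(self, rng):
        pool = [DnaSequence(f"s{i}", "ACGT") for i in range(10)]
        with pytest.raises(ValueError):
            generate_null_clusters(pool, [6, 5], rng)

    def test_different_seeds_differ(self):
        pool = [DnaSequence(f"s{i}", "ACGT") for i in range(30)]
        a = generate_null_clusters(pool, [10], np.random.default_rng(1))
        b = generate_null_clusters(pool, [10], np.random.default_rng(2))
        assert a.clusters[0].member_ids() != b.clusters[0].member_ids()
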
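import numpy as np
import pytest
from scipy.stats import chi2, kstest

from lrmotifs.discovery import (
    DegenerateLabelsError,
    FitFailureError,
    alr_discover,
    alr_select_features,
    bh_fdr,
    build_seed_pwm,
    discover_multi_width,
    enumerate_candidates,
    fit_logistic,
    lr_discover,
    wilks_test,
)
from lrmotifs.mismatch import CoreMotif, core_distance, min_distance_in_sequence
from lrmotifs.seqcore import DnaSequence, SequenceCluster, reverse_complement
from lrmotifs.simulate import sample_iid_background


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        fit = fit_logistic(None, [1, 1, 0, 0])
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.log_likelihood == pytest.approx(4 * np.log(0.5))

    def test_uninformative_feature_zero_slope(self):
        fit = fit_logistic([[0], [0], [2], [2]], [1, 0, 1, 0])
        assert fit.coef[1] == pytest.approx(0.0, abs=1e-8)
        assert fit.log_likelihood == pytest.approx(4 * np.log(0.5))

    def test_perfect_separation_flagged(self):
        fit = fit_logistic([[0], [0], [2], [2]], [1, 1, 0, 0])
        assert fit.separated
        assert fit.log_likelihood == pytest.approx(0.0, abs=1e-3)

    def test_degenerate_labels_error(self):
        with pytest.raises(DegenerateLabelsError):
            fit_logistic([[1], [2], [3]], [1, 1, 1])

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        y = (rng.random(60) < 0.5).astype(int)
        ours = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert ours.log_likelihood == pytest.approx(ref.llf, abs=1e-6)
        assert ours.coef == pytest.approx(ref.params, abs=1e-5)

    def test_nesting_monotonicity(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 2))
        y = (rng.random(40) < 0.4).astype(int)
        full = fit_logistic(X, y)
        sub = fit_logistic(X[:, :1], y)
        none = fit_logistic(None, y)
        assert full.log_likelihood >= sub.log_likelihood - 1e-8
        assert sub.log_likelihood >= none.log_likelihood - 1e-8


class TestWilks:
    def test_equal_likelihoods(self):
        y = [1, 0, 1, 0]
        alt = fit_logistic([[0], [0], [2], [2]], y)
        null = fit_logistic(None, y)
        lam, p = wilks_test(alt, null)
        assert lam == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-3)

    def test_chi2_tail_value(self):
        # Lambda = 3.841 at 1 df sits at the 5% tail
        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)

    def test_fit_failure_detected(self):
        y = [1, 0, 1, 0, 1, 0]
        alt = fit_logistic([[0], [1], [2], [3], [4], [5]], y)
        null = fit_logistic(None, y)
        null.log_likelihood = alt.log_likelihood + 1.0
        null.coef = np.array([])
        null.feature_names = []
        with pytest.raises(FitFailureError):
            wilks_test(alt, null)

    def test_permutation_pvalues_uniform(self):
        """Under label permutation the Wilks p-values are uniform (KS)."""
        rng = np.random.default_rng(77)
        d = rng.integers(0, 6, size=200).astype(float)
        y = np.array([1] * 100 + [0] * 100)
        ps = []
        for _ in range(500):
            yp = rng.permutation(y)
            alt = fit_logistic(d[:, None], yp)
            null = fit_logistic(None, yp)
            ps.append(wilks_test(alt, null)[1])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestBhFdr:
    def test_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestEnumerateCandidates:
    def test_counts_and_stride(self):
        cl = SequenceCluster("c", [DnaSequence("a", "ACGTACGTAC")])
        assert len(enumerate_candidates(cl, 8)) == 3
        assert len(enumerate_candidates(cl, 8, stride=2)) == 2

    def test_n_windows_excluded(self):
        cl = SequenceCluster("c", [DnaSequence("a", "AANACGTA")])
        cores = {c.core for c in enumerate_candidates(cl, 4)}
        assert cores == {"ACGT", "CGTA"}

    def test_source_tagging(self):
        cl = SequenceCluster("c", [DnaSequence("a", "ACGTA"), DnaSequence("b", "GGGGG")])
        cands = enumerate_candidates(cl, 4)
        assert {(c.source_sequence_id, c.source_offset) for c in cands} == {
            ("a", 0), ("a", 1), ("b", 0), ("b", 1),
        }


class TestLrDiscover:
    def test_recovers_strong_planted_motif(self, strong_planted):
        fg, bg, pfm, _ = strong_planted
        res = lr_discover(fg, bg, 10)
        d = min(
            core_distance(res.best.core.core, pfm.consensus),
            core_distance(res.best.core.core, reverse_complement(pfm.consensus)),
        )
        assert d <= 1
        assert res.best.q_value < 0.05
        assert res.best.core.core in {c.core for c in enumerate_candidates(fg, 10)}

    def test_constant_features_give_zero_lambda(self, rng):
        # every member identical -> the mismatch feature carries no label
        # information and Lambda vanishes for every candidate
        residues = sample_iid_background(0.4, 60, rng).residues
        fg = SequenceCluster("fg", [DnaSequence(f"s{i}", residues) for i in range(4)])
        bg = SequenceCluster("bg", [DnaSequence(f"t{i}", residues) for i in range(4)])
        res = lr_discover(fg, bg, 6)
        assert (res.candidates["lambda"] < 1e-6).all()

    def test_identical_cluster_content_not_significant(self, rng):
        members = [sample_iid_background(0.4, 60, rng) for _ in range(6)]
        for i, s in enumerate(members):
            s.id = f"s{i}"
        fg = SequenceCluster("fg", members)
        bg = SequenceCluster(
            "bg", [DnaSequence(f"t{i}", s.residues) for i, s in enumerate(members)]
        )
        res = lr_discover(fg, bg, 6)
        assert res.best.q_value > 0.05

    def test_nesting_invariant(self, strong_planted):
        fg, bg, _, _ = strong_planted
        res = lr_discover(fg, bg, 10, stride=4)
        assert res.alt_fit.log_likelihood >= res.null_fit.log_likelihood - 1e-8

    def test_small_cluster_errors(self):
        a = SequenceCluster("a", [DnaSequence("x", "ACGTACGT")])
        b = SequenceCluster("b", [DnaSequence("y", "ACGTACGT")])
        with pytest.raises(ValueError):
            lr_discover(a, b, 4)


class TestBuildSeedPwm:
    def test_strict_threshold_inclusion(self):
        # background median distance 2; foreground windows at distance 0/1 kept
        core = CoreMotif("ACGTACGT", "f0", 0)
        fg = SequenceCluster(
            "fg",
            [
                DnaSequence("f0", "TTACGTACGTTT"),  # contains core, d=0
                DnaSequence("f1", "TTACGAACGTTT"),  # best window d=1
            ],
        )
        bg = SequenceCluster(
            "bg",
            [DnaSequence(f"b{i}", "TTACGAAGGTTT") for i in range(3)],  # d=2
        )
        assert min_distance_in_sequence(core, bg.members[0]) == 2
        seeds, pwm = build_seed_pwm(core, fg, bg)
        assert "ACGTACGT" in seeds
        assert any(core_distance(core, s) == 1 for s in seeds)
        assert pwm.width == 8

    def test_zero_threshold_fallback(self):
        # core occurs exactly in every background sequence -> t = 0 -> fallback
        core = CoreMotif("ACGTACGT", "f0", 0)
        fg = SequenceCluster("fg", [DnaSequence("f0", "GGACGTACGTGG")])
        bg = SequenceCluster("bg", [DnaSequence(f"b{i}", "TTACGTACGTTT") for i in range(2)])
        seeds, _ = build_seed_pwm(core, fg, bg)
        assert seeds == ["ACGTACGT"]  # one best window per foreground member

    def test_covers_planted_windows(self, strong_planted):
        fg, bg, pfm, records = strong_planted
        res = lr_discover(fg, bg, 10)
        planted = {
            s.residues[r.offset : r.offset + 10]
            for r in records
            for s in fg.members
            if s.id == r.sequence_id
        }
        seedset = set(res.seed_sequences) | {
            reverse_complement(s) for s in res.seed_sequences
        }
        frac = sum(1 for p in planted if p in seedset) / len(planted)
        assert frac >= 0.8


class TestAlr:
    def _gc_shift_pair(self, n=24, length=240, seed=9):
        rng = np.random.default_rng(seed)
        fg, bg = [], []
        for i in range(n):
            s = sample_iid_background(0.6, length, rng)
            s.id = f"f{i}"
            fg.append(s)
            t = sample_iid_background(0.4, length, rng)
            t.id = f"b{i}"
            bg.append(t)
        return SequenceCluster("fg", fg), SequenceCluster("bg", bg)

    def test_select_features_perfect_predictor_first(self):
        fg, bg = self._gc_shift_pair()
        sel = alr_select_features(fg, bg, 3)
        assert sel[0] in ("C/G", "A/T")  # monomer GC split is the strongest signal

    def test_select_features_tie_lexicographic(self):
        fg = SequenceCluster("fg", [DnaSequence(f"f{i}", "ACGT" * 5) for i in range(3)])
        bg = SequenceCluster("bg", [DnaSequence(f"b{i}", "ACGT" * 5) for i in range(3)])
        sel = alr_select_features(fg, bg, 12)
        assert sel == sorted(sel)

    def test_gc_shift_not_significant_but_discriminates(self):
        """Composition differences alone do not yield a significant core,
        yet the combined model still separates the clusters."""
        from lrmotifs.benchmark import auroc

        fg, bg = self._gc_shift_pair()
        res = alr_discover(fg, bg, 8, m=3, stride=3)
        assert res.best.q_value > 0.05
        assert auroc(res.score(fg.members), res.score(bg.members)) > 0.9

    def test_m0_reduces_to_lr(self, strong_planted):
        fg, bg, _, _ = strong_planted
        a = alr_discover(fg, bg, 10, m=0, stride=4)
        b = lr_discover(fg, bg, 10, stride=4)
        assert a.best.core.core == b.best.core.core
        assert a.best.p_value == pytest.approx(b.best.p_value)

    def test_planted_motif_matches_lr_core(self, strong_planted):
        fg, bg, _, _ = strong_planted
        a = alr_discover(fg, bg, 10, m=3, stride=2)
        b = lr_discover(fg, bg, 10, stride=2)
        assert a.best.core.core == b.best.core.core


class TestMultiWidth:
    def test_single_width_identity(self, strong_planted):
        fg, bg, _, _ = strong_planted
        single = lr_discover(fg, bg, 10, stride=4)
        multi = discover_multi_width(fg, bg, [10], stride=4)
        assert multi.best.core.core == single.best.core.core
        assert multi.best.p_value == pytest.approx(single.best.p_value)
        assert multi.best.q_value == pytest.approx(single.best.q_value)

    def test_planted_width_overlap(self, strong_planted):
        fg, bg, pfm, records = strong_planted
        res = discover_multi_width(fg, bg, [8, 10, 12], stride=2)
        # winning core overlaps the planted site of its source sequence
        rec = {r.sequence_id: r for r in records}[res.best.core.source_sequence_id]
        lo, hi = res.best.core.source_offset, res.best.core.source_offset + res.width
        assert lo < rec.offset + 10 and rec.offset < hi

    def test_pooled_q_never_smaller(self, rng):
        members = [sample_iid_background(0.4, 50, rng) for _ in range(5)]
        for i, s in enumerate(members):
            s.id = f"p{i}"
        fg = SequenceCluster("fg", members[:3])
        bg_seqs = [sample_iid_background(0.4, 50, rng) for _ in range(3)]
        for i, s in enumerate(bg_seqs):
            s.id = f"q{i}"
        bg = SequenceCluster("bg", bg_seqs)
        single = lr_discover(fg, bg, 6, stride=2)
        multi = discover_multi_width(fg, bg, [6, 8], stride=2)
        if multi.width == 6 and multi.best.core.core == single.best.core.core:
            assert multi.best.q_value >= single.best.q_value - 1e-12
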
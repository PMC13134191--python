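import numpy as np
import pytest
from scipy import stats as sstats

import chondropipe as cp

from oracles import auc_bruteforce, dice_bruteforce, masd_bruteforce


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((5, 5, 3), bool)
        m[1:3, 1:3, 1] = True
        assert cp.dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5, 3), bool)
        b = np.zeros((5, 5, 3), bool)
        a[0, 0, 0] = True
        b[4, 4, 2] = True
        assert cp.dsc(a, b) == 0.0

    def test_shifted_block_half_overlap(self):
        a = np.zeros((6, 6, 3), bool)
        b = np.zeros((6, 6, 3), bool)
        a[1:3, 1:3, 1] = True
        b[2:4, 1:3, 1] = True  # overlap 2 of 4+4
        assert cp.dsc(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        e = np.zeros((4, 4, 2), bool)
        assert cp.dsc(e, e) == 1.0
        f = e.copy()
        f[0, 0, 0] = True
        assert cp.dsc(e, f) == 0.0

    def test_matches_bruteforce_and_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = rng.random((6, 6, 4)) < 0.3
            b = rng.random((6, 6, 4)) < 0.3
            assert cp.dsc(a, b) == pytest.approx(dice_bruteforce(a, b), abs=1e-12)
            assert cp.dsc(a, b) == cp.dsc(b, a)


class TestMasd:
    def test_identical_masks_zero(self):
        m = np.zeros((6, 6, 4), bool)
        m[2:4, 2:4, 1:3] = True
        assert cp.masd(m, m, (1, 1, 1)) == 0.0

    def test_single_voxels_along_x(self):
        a = np.zeros((8, 4, 4), bool)
        b = np.zeros((8, 4, 4), bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True
        assert cp.masd(a, b, (1, 1, 1)) == pytest.approx(3.0)

    def test_anisotropic_spacing_z_offset(self):
        a = np.zeros((4, 4, 8), bool)
        b = np.zeros((4, 4, 8), bool)
        a[1, 1, 1] = True
        b[1, 1, 4] = True
        assert cp.masd(a, b, (1, 1, 4.5)) == pytest.approx(13.5)

    def test_empty_mask_undefined(self):
        e = np.zeros((4, 4, 4), bool)
        f = e.copy()
        f[1, 1, 1] = True
        assert cp.masd(e, f, (1, 1, 1)) is None
        assert cp.masd(f, e, (1, 1, 1)) is None

    def test_matches_bruteforce_and_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            a = rng.random((5, 5, 4)) < 0.25
            b = rng.random((5, 5, 4)) < 0.25
            got = cp.masd(a, b, (0.6, 0.6, 4.5))
            want = masd_bruteforce(a, b, (0.6, 0.6, 4.5))
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, rel=1e-9)
                assert got == pytest.approx(cp.masd(b, a, (0.6, 0.6, 4.5)), rel=1e-12)


class TestClassificationReport:
    def test_perfect_predictions(self):
        truth = ["NT"] * 3 + ["EC"] * 4 + ["ACT"] * 2
        rep = cp.classification_report(truth, truth)
        for cls in ("NT", "EC", "ACT"):
            for metric, v in rep.per_class[cls].items():
                assert v == 1.0

    def test_hand_confusion_arithmetic(self):
        truth = ["ACT"] * 5 + ["EC"] * 10
        pred = (["ACT"] * 4 + ["EC"]) + (["ACT"] * 2 + ["EC"] * 8)
        rep = cp.classification_report(truth, pred, classes=("EC", "ACT"))
        m = rep.per_class["ACT"]
        assert m["Precision"] == pytest.approx(4 / 6)
        assert m["Sensitivity"] == pytest.approx(4 / 5)
        f1 = 2 * (4 / 6) * (4 / 5) / (4 / 6 + 4 / 5)
        assert m["F1"] == pytest.approx(f1)

    def test_all_one_class_zero_specificity(self):
        truth = ["EC", "ACT", "EC"]
        pred = ["ACT", "ACT", "ACT"]
        rep = cp.classification_report(truth, pred, classes=("EC", "ACT"))
        assert rep.per_class["ACT"]["Specificity"] == 0.0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside the class set"):
            cp.classification_report(["EC"], ["XX"], classes=("EC", "ACT"))

    def test_micro_consistency(self):
        rng = np.random.default_rng(2)
        classes = np.array(["NT", "EC", "ACT"])
        truth = classes[rng.integers(0, 3, 60)]
        pred = classes[rng.integers(0, 3, 60)]
        rep = cp.classification_report(truth, pred)
        assert rep.confusion.trace() == int((truth == pred).sum())
        assert rep.confusion.sum(axis=1).tolist() == [
            rep.n_per_class[c] for c in rep.classes
        ]

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        classes = np.array(["EC", "ACT"])
        truth = classes[rng.integers(0, 2, 40)]
        pred = np.where(rng.random(40) < 0.8, truth, classes[rng.integers(0, 2, 40)])
        rep = cp.classification_report(truth, pred, classes=("EC", "ACT"),
                                       ci=True, n_resamples=300, seed=0)
        for cls in ("EC", "ACT"):
            for metric, (lo, hi) in rep.ci[cls].items():
                point = rep.per_class[cls][metric]
                assert lo - 1e-9 <= point <= hi + 1e-9


class TestAuc:
    def test_perfect_separation(self):
        assert cp.auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert cp.auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_count_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = rng.integers(6, 20)
            scores = rng.integers(0, 6, n).astype(float)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert cp.auc(scores, labels) == pytest.approx(
                auc_bruteforce(scores, labels), abs=1e-12)

    def test_complement_under_no_ties(self):
        rng = np.random.default_rng(5)
        scores = rng.permutation(20).astype(float)
        labels = np.r_[np.ones(8), np.zeros(12)]
        assert cp.auc(scores, labels) + cp.auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cp.auc([1, 2], [1, 1])


class TestBcaCi:
    def test_constant_sample_degenerates_to_point(self):
        lo, hi = cp.bca_ci(np.mean, np.full(10, 3.5), n_resamples=200, seed=0)
        assert (lo, hi) == (3.5, 3.5)

    def test_close_to_percentile_for_symmetric_case(self):
        rng = np.random.default_rng(6)
        sample = rng.normal(0, 1, 80)
        lo, hi = cp.bca_ci(np.mean, sample, n_resamples=4000, seed=1,
                           vectorized=False)
        res = sstats.bootstrap((sample,), np.mean, n_resamples=4000,
                               method="percentile",
                               random_state=np.random.default_rng(1))
        plo, phi = res.confidence_interval
        mc_err = 3 * sample.std() / np.sqrt(len(sample)) / np.sqrt(40)
        assert abs(lo - plo) < mc_err * 4
        assert abs(hi - phi) < mc_err * 4

    def test_brackets_statistic(self):
        rng = np.random.default_rng(7)
        sample = rng.exponential(1.0, 60)
        lo, hi = cp.bca_ci(np.mean, sample, n_resamples=1000, seed=2)
        assert lo < sample.mean() < hi


class TestDelong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        a1, a2, z, p = cp.delong_test(s, s, y)
        assert a1 == a2
        assert p == 1.0

    def test_internal_auc_matches_rank_auc(self):
        rng = np.random.default_rng(9)
        sa = rng.normal(size=50)
        sb = rng.normal(size=50)
        y = np.r_[np.ones(20), np.zeros(30)].astype(int)
        a1, a2, z, p = cp.delong_test(sa, sb, y)
        assert a1 == pytest.approx(cp.auc(sa, y), abs=1e-12)
        assert a2 == pytest.approx(cp.auc(sb, y), abs=1e-12)

    def test_detects_a_real_difference(self):
        rng = np.random.default_rng(10)
        y = np.r_[np.ones(60), np.zeros(60)].astype(int)
        good = y + rng.normal(0, 0.3, 120)
        bad = rng.normal(0, 1, 120)
        _, _, _, p = cp.delong_test(good, bad, y)
        assert p < 0.01


class TestPermutationTest:
    @staticmethod
    def _accuracy(pred, truth):
        return float(np.mean(np.asarray(pred) == np.asarray(truth)))

    def test_identical_predictions_p_one(self):
        truth = np.array(["EC", "ACT"] * 10)
        p = cp.permutation_test(self._accuracy, truth, truth, truth,
                                n_iter=200, seed=0)
        assert p == 1.0

    def test_dominant_model_small_p(self):
        truth = np.array(["EC", "ACT"] * 15)
        a = truth.copy()                      # perfect
        b = np.array(["EC"] * 30)             # misses every ACT
        p = cp.permutation_test(self._accuracy, a, b, truth,
                                n_iter=2000, seed=1)
        assert p <= 0.01


class TestMannWhitneyR:
    def test_complete_separation_exact_u(self):
        x = np.arange(10) + 100.0
        y = np.arange(10).astype(float)
        # U = n1*n2 under complete separation; r = |Z|/sqrt(N)
        n1 = n2 = 10
        n = n1 + n2
        z = (n1 * n2 / 2) / np.sqrt(n1 * n2 * (n + 1) / 12.0)
        assert cp.mann_whitney_r(x, y) == pytest.approx(z / np.sqrt(n), rel=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=9)
            assert 0.0 <= cp.mann_whitney_r(x, y) <= 1.0
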
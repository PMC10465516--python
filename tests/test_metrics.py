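import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fissureintegrity.boundary import FissureKind, encode_ground_truth
from fissureintegrity.metrics import (Category, FissureReport,
                                      UndefinedMetricError, acc_fis,
                                      auc_complete, categorize, fi_percent,
                                      fis_error, reproducibility,
                                      summarize_cohort)
from fissureintegrity.volio import LabelVolume


def counting_fi(mask: np.ndarray) -> float:
    """Independent voxel-counting oracle."""
    n1 = sum(1 for v in mask.ravel() if v == 1)
    n2 = sum(1 for v in mask.ravel() if v == 2)
    return 100.0 * n1 / (n1 + n2)


def pairwise_auc(scores):
    """Exhaustive pair-enumeration oracle (ties count 1/2)."""
    pos = [s for s, c in scores if Category(c) is Category.COMPLETE]
    neg = [s for s, c in scores if Category(c) is not Category.COMPLETE]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestFiPercent:
    def test_examples(self):
        m = np.zeros((10, 10), dtype=int)
        m.ravel()[:100] = 1
        assert fi_percent(m) == 100.0
        m.ravel()[:25] = 2
        assert fi_percent(m) == 75.0

    @settings(max_examples=100, derandomize=True)
    @given(n_intact=st.integers(0, 200), n_incomplete=st.integers(0, 200))
    def test_ratio_for_any_surface_composition(self, n_intact, n_incomplete):
        if n_intact + n_incomplete == 0:
            return
        m = np.concatenate([np.ones(n_intact, dtype=int),
                            np.full(n_incomplete, 2)]).reshape(1, 1, -1)
        fi = fi_percent(m)
        assert fi == pytest.approx(
            100.0 * n_intact / (n_intact + n_incomplete), abs=1e-9)
        assert 0.0 <= fi <= 100.0
        assert categorize(fi) in list(Category)

    def test_empty_surface_raises(self):
        with pytest.raises(UndefinedMetricError):
            fi_percent(np.zeros((4, 4, 4), dtype=int))

    def test_matches_counting_oracle_on_random_masks(self, rng):
        for _ in range(100):
            m = rng.choice([0, 1, 2], size=(6, 6, 6), p=[0.8, 0.1, 0.1])
            if not (m > 0).any():
                m[0, 0, 0] = 1
            assert fi_percent(m) == pytest.approx(counting_fi(m), abs=1e-9)

    def test_consistent_with_ground_truth_encoding(self, rng):
        comp = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        comp[0, 0, 0] = 1
        intact = (comp & (rng.random((8, 8, 8)) < 0.5)).astype(np.uint8)
        gt = encode_ground_truth(LabelVolume(data=comp),
                                 LabelVolume(data=intact))
        assert fi_percent(gt) == pytest.approx(
            100.0 * intact.sum() / comp.sum(), abs=1e-9)


class TestFisError:
    @pytest.mark.parametrize("pred,truth,expected", [
        (90.0, 90.0, 0.0),
        (45.0, 90.0, -0.5),
        (100.0, 80.0, 0.25),
    ])
    def test_examples(self, pred, truth, expected):
        assert fis_error(pred, truth) == pytest.approx(expected, abs=1e-12)

    def test_zero_truth_undefined(self):
        with pytest.raises(UndefinedMetricError):
            fis_error(10.0, 0.0)


class TestAccFis:
    def test_perfect_and_partial(self, rng):
        truth = np.zeros((4, 4, 4), dtype=int)
        truth[0, 0, :4] = [1, 1, 2, 2]
        assert acc_fis(truth, truth) == 100.0
        pred = truth.copy()
        pred[0, 0, 0] = 2
        assert acc_fis(pred, truth) == 75.0

    def test_different_surfaces_rejected(self):
        a = np.zeros((4, 4, 4), dtype=int)
        b = np.zeros((4, 4, 4), dtype=int)
        a[0, 0, 0] = 1
        b[1, 1, 1] = 1
        with pytest.raises(UndefinedMetricError):
            acc_fis(a, b)

    def test_matches_counting_oracle(self, rng):
        for _ in range(100):
            surf = rng.random((6, 6, 6)) < 0.3
            if not surf.any():
                surf[0, 0, 0] = True
            t = np.where(surf, rng.choice([1, 2], size=(6, 6, 6)), 0)
            p = np.where(surf, rng.choice([1, 2], size=(6, 6, 6)), 0)
            expected = 100.0 * sum(
                1 for a, b, s in zip(p.ravel(), t.ravel(), surf.ravel())
                if s and a == b) / surf.sum()
            assert acc_fis(p, t) == pytest.approx(expected, abs=1e-9)

    def test_perfect_accuracy_implies_zero_fis_error(self, rng):
        surf = rng.random((6, 6, 6)) < 0.3
        surf[0, 0, 0] = True
        t = np.where(surf, rng.choice([1, 2], size=(6, 6, 6)), 0)
        assert acc_fis(t, t) == 100.0
        assert fis_error(fi_percent(t), fi_percent(t)) == 0.0


class TestCategorize:
    @pytest.mark.parametrize("fi,expected", [
        (90.0, Category.COMPLETE),
        (100.0, Category.COMPLETE),
        (10.0, Category.PARTIAL),
        (9.99, Category.MISSING),
        (0.0, Category.MISSING),
        (90.0 - 1e-9, Category.PARTIAL),
        (10.0 - 1e-9, Category.MISSING),
    ])
    def test_thresholds(self, fi, expected):
        assert categorize(fi) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize(101.0)


class TestAuc:
    def test_perfect_separation(self):
        scores = [(95.0, "complete"), (96.0, "complete"),
                  (50.0, "partial"), (5.0, "missing")]
        assert auc_complete(scores) == 1.0

    def test_all_ties_half(self):
        scores = [(50.0, "complete"), (50.0, "partial")]
        assert auc_complete(scores) == 0.5

    def test_enumerated_example(self):
        scores = [(95.0, "complete"), (85.0, "complete"),
                  (80.0, "partial"), (88.0, "missing")]
        assert auc_complete(scores) == 0.75   # 3 of 4 pairs concordant

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc_complete([(95.0, "complete"), (92.0, "complete")])

    def test_matches_pair_enumeration_and_mannwhitney(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 20))
            fi = rng.uniform(0, 100, size=n).round(0)
            cats = [categorize(v) for v in rng.uniform(0, 100, size=n)]
            if len({c is Category.COMPLETE for c in cats}) < 2:
                cats[0] = Category.COMPLETE
                cats[1] = Category.PARTIAL
            scores = list(zip(fi, cats))
            expected = pairwise_auc(scores)
            got = auc_complete(scores)
            assert got == pytest.approx(expected, abs=1e-9)
            pos = [s for s, c in scores if c is Category.COMPLETE]
            neg = [s for s, c in scores if c is not Category.COMPLETE]
            u = stats.mannwhitneyu(pos, neg, alternative="two-sided",
                                   method="asymptotic").statistic
            assert got == pytest.approx(u / (len(pos) * len(neg)), abs=1e-9)


class TestReproducibility:
    def test_identical_timepoints_zero(self):
        fi = {"a": {"t0": 80.0, "t1": 80.0}, "b": {"t0": 55.0, "t1": 55.0}}
        out = reproducibility(fi)
        assert out[("t0", "t1")]["mean"] == 0.0
        assert out[("t0", "t1")]["sd"] == 0.0

    def test_mean_of_diffs(self):
        fi = {"a": {"t0": 80.0, "t1": 82.0}, "b": {"t0": 50.0, "t1": 54.0}}
        out = reproducibility(fi, pairs=[("t0", "t1")])
        assert out[("t0", "t1")]["mean"] == pytest.approx(3.0)

    def test_missing_timepoint_excluded_with_warning(self):
        fi = {"a": {"t0": 80.0, "t1": 81.0}, "b": {"t0": 50.0}}
        with pytest.warns(UserWarning, match="missing timepoint"):
            out = reproducibility(fi, pairs=[("t0", "t1")])
        assert out[("t0", "t1")]["n"] == 1


class TestSummarizeCohort:
    def _report(self, kind, fi, acc=None, err=None, true_fi=None):
        return FissureReport(fissure=kind, fi_percent=fi,
                             n_surface_voxels=100, category=categorize(fi),
                             acc_fis=acc, fis_error=err, true_fi=true_fi)

    def test_two_reports_mean_and_sample_sd(self):
        reports = [self._report(FissureKind.LOBL, 90.0),
                   self._report(FissureKind.LOBL, 100.0)]
        out = summarize_cohort(reports)
        s = out["LOBL"]["all"]["fi_percent"]
        assert s["mean"] == pytest.approx(95.0)
        assert s["sd"] == pytest.approx(np.sqrt(50.0), abs=1e-6)

    def test_single_report_sd_zero(self):
        out = summarize_cohort([self._report(FissureKind.RHOR, 70.0)])
        assert out["RHOR"]["all"]["fi_percent"]["sd"] == 0.0

    def test_fis_error_absolute_and_signed(self):
        reports = [self._report(FissureKind.LOBL, 90.0, err=-0.1),
                   self._report(FissureKind.LOBL, 80.0, err=0.1)]
        out = summarize_cohort(reports)
        g = out["LOBL"]["all"]
        assert g["fis_error_abs"]["mean"] == pytest.approx(0.1)
        assert g["fis_error_signed"]["mean"] == pytest.approx(0.0)

    def test_zero_truth_cases_counted_separately(self):
        reports = [self._report(FissureKind.LOBL, 90.0, err=None),
                   self._report(FissureKind.LOBL, 80.0, err=0.2)]
        out = summarize_cohort(reports)
        assert out["LOBL"]["all"]["n_excluded_fis_error"] == 1

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])
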
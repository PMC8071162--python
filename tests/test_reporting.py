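import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepaquant import (
    auroc,
    best_cutoff,
    icc_absolute_agreement,
    reliability_band,
    repeatability_cv,
)
from hepaquant.errors import DegenerateInputError, DomainError, HepaquantError


def auroc_oracle(neg, pos):
    """Brute-force pair counting over all (pos, neg) pairs."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def cutoff_oracle(neg, pos):
    """Exhaustive scan of all midpoint thresholds; returns best Youden metrics."""
    uniq = sorted(set(neg) | set(pos))
    best = None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = (lo + hi) / 2.0
        tp = sum(p >= cut for p in pos)
        fp = sum(n >= cut for n in neg)
        sens = tp / len(pos)
        spec = (len(neg) - fp) / len(neg)
        youden = sens + spec - 1
        if best is None or youden > best[0] + 1e-12:
            best = (youden, cut, sens, spec)
    return best


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3], [4, 5, 6]) == 1.0

    def test_identical_groups_is_half(self):
        assert auroc([1, 2, 3], [1, 2, 3]) == 0.5

    def test_pair_counting_example(self):
        assert auroc([1, 2, 3], [2, 3, 4]) == pytest.approx(7 / 9, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(HepaquantError):
            auroc([], [1.0])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            neg = rng.integers(0, 8, size=rng.integers(2, 20)).astype(float)
            pos = rng.integers(0, 8, size=rng.integers(2, 20)).astype(float)
            assert auroc(neg, pos) == pytest.approx(auroc_oracle(neg, pos), abs=1e-8)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=15),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=15),
    )
    def test_complement_symmetry(self, neg, pos):
        assert auroc(neg, pos) + auroc(pos, neg) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        neg = rng.normal(0, 1, 30)
        pos = rng.normal(1, 1, 25)
        base = auroc(neg, pos)
        for f in (np.exp, np.cbrt, lambda x: 3 * x + 2):
            assert auroc(f(neg), f(pos)) == pytest.approx(base, abs=1e-12)


class TestBestCutoff:
    def test_clean_separation_midpoint(self):
        r = best_cutoff([1, 2], [3, 4])
        assert r.cutoff == pytest.approx(2.5)
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert r.diagnostic_accuracy == 1.0
        assert r.counts == (2, 0, 2, 0)

    def test_interleaved_case_matches_scan(self):
        r = best_cutoff([1, 3], [2, 4])
        youden, cut, sens, spec = cutoff_oracle([1, 3], [2, 4])
        assert r.sensitivity + r.specificity - 1 == pytest.approx(youden)
        assert r.cutoff == pytest.approx(cut)
        assert youden == pytest.approx(0.5)

    def test_all_identical_scores_degenerate(self):
        with pytest.raises(DegenerateInputError):
            best_cutoff([2.0], [2.0])

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            neg = rng.integers(0, 10, size=rng.integers(2, 25)).astype(float)
            pos = rng.integers(0, 10, size=rng.integers(2, 25)).astype(float)
            if len(set(neg) | set(pos)) < 2:
                continue
            r = best_cutoff(neg, pos)
            youden, cut, sens, spec = cutoff_oracle(list(neg), list(pos))
            assert r.cutoff == pytest.approx(cut, abs=1e-8)
            assert r.sensitivity == pytest.approx(sens, abs=1e-8)
            assert r.specificity == pytest.approx(spec, abs=1e-8)

    def test_rates_consistent_with_counts(self):
        rng = np.random.default_rng(13)
        neg = rng.normal(5, 1, 40)
        pos = rng.normal(7, 1.5, 30)
        r = best_cutoff(neg, pos)
        tp, fp, tn, fn = r.counts
        assert r.diagnostic_accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
        assert r.ppv == pytest.approx(tp / (tp + fp))
        assert r.npv == pytest.approx(tn / (tn + fn))
        assert r.auroc_ci[0] <= r.auroc <= r.auroc_ci[1]

    def test_auroc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(14)
        neg = rng.normal(5, 1, 35)
        pos = rng.normal(6, 1, 45)
        labels = np.r_[np.zeros(35), np.ones(45)]
        scores = np.r_[neg, pos]
        assert auroc(neg, pos) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def icc_ms_oracle(x):
    """Second, independently coded mean-squares ICC(2,1) (scalar loops)."""
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_perfect_agreement(self):
        a = np.array([3.0, 5.0, 7.0, 9.0, 11.0, 13.0])
        res = icc_absolute_agreement(np.column_stack([a, a]))
        assert res.icc == pytest.approx(1.0)
        assert res.reliability_band == "excellent"

    def test_constant_offset_penalised_and_matches_oracle(self):
        a = np.array([1.0, 4.0, 7.0, 10.0, 13.0, 16.0])
        tab = np.column_stack([a, a + 10])
        res = icc_absolute_agreement(tab)
        assert res.icc < 1.0
        assert res.icc == pytest.approx(icc_ms_oracle(tab), abs=1e-12)

    def test_band_thresholds(self):
        assert reliability_band(0.718) == "good"
        assert reliability_band(0.39) == "poor"
        assert reliability_band(0.45) == "moderate"
        assert reliability_band(0.85) == "excellent"

    def test_matches_independent_oracle_on_random_tables(self):
        rng = np.random.default_rng(15)
        for _ in range(100):
            n = int(rng.integers(5, 12))
            k = int(rng.integers(2, 5))
            tab = rng.normal(10, 3, size=(n, k)) + rng.normal(0, 2, size=(n, 1))
            res = icc_absolute_agreement(tab)
            assert res.icc == pytest.approx(icc_ms_oracle(tab), abs=1e-9)

    def test_matches_pingouin_icc_and_ci(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(16)
        tab = rng.normal(10, 3, size=(8, 3)) + rng.normal(0, 2, size=(8, 1))
        res = icc_absolute_agreement(tab)
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(8), 3),
                "rater": np.tile(["a", "b", "c"], 8),
                "score": tab.flatten(),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            icc = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="score")
        row = icc[icc["Type"] == "ICC(A,1)"].iloc[0]
        assert res.icc == pytest.approx(float(row["ICC"]), abs=1e-9)
        lo, hi = row["CI95"]
        assert res.icc_ci_low == pytest.approx(lo, abs=0.01)
        assert res.icc_ci_high == pytest.approx(hi, abs=0.01)

    def test_missing_cells_rejected(self):
        tab = np.ones((6, 2))
        tab[2, 1] = np.nan
        with pytest.raises(DomainError, match="missing"):
            icc_absolute_agreement(tab)

    def test_too_small_table_rejected(self):
        with pytest.raises(DomainError):
            icc_absolute_agreement(np.ones((4, 2)))


class TestRepeatabilityCv:
    def test_identical_repeats_zero(self):
        assert repeatability_cv(np.array([[5.0, 5.0], [7.0, 7.0]])) == 0.0

    def test_two_point_closed_form(self):
        # repeats {90, 110}: SD 14.142, mean 100 -> 14.14
        assert repeatability_cv(np.array([[90.0, 110.0]])) == pytest.approx(14.142, abs=0.001)

    def test_mean_over_subjects(self):
        # per-subject CVs averaged: subjects with CV 14.142% and 28.284%
        tab = np.array([[90.0, 110.0], [80.0, 120.0]])
        cv1 = tab[0].std(ddof=1) / tab[0].mean() * 100
        cv2 = tab[1].std(ddof=1) / tab[1].mean() * 100
        assert repeatability_cv(tab) == pytest.approx((cv1 + cv2) / 2, rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(DomainError):
            repeatability_cv(np.array([[1.0, -1.0]]))
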
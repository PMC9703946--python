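"""Scan statistics against closed-form oracles: two-group regression LOD for
the EM scan at informative markers, Kruskal-Wallis for the rank scan, plus
permutation-threshold arithmetic and support-interval geometry."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xcrossqtl import (
    DegeneratePhenotypeError,
    conditional_genotype_probs,
    dagostino_pearson,
    em_scan,
    genotype_class_stats,
    log2_transform,
    np_scan,
    peak_summaries,
    permutation_threshold,
    support_interval,
)
from xcrossqtl.qtl_scan import PermutationResult, ScanResult, _em_lod_profile

from conftest import make_cross


def regression_lod(values_a, values_h):
    """Independent oracle: two-group regression LOD = (n/2) log10(RSS0/RSS1)."""
    y = np.concatenate([values_a, values_h])
    rss0 = ((y - y.mean()) ** 2).sum()
    rss1 = (
        ((np.asarray(values_a) - np.mean(values_a)) ** 2).sum()
        + ((np.asarray(values_h) - np.mean(values_h)) ** 2).sum()
    )
    return len(y) / 2.0 * math.log10(rss0 / rss1)


class TestTraitPreprocessing:
    def test_log2_values(self):
        np.testing.assert_allclose(
            log2_transform([100.0, 200.0]), [6.643856, 7.643856], atol=1e-6
        )
        assert log2_transform([64.0])[0] == 6.0
        assert log2_transform([1.0])[0] == 0.0

    def test_log2_preserves_missing_and_rejects_nonpositive(self):
        s = pd.Series([4.0, np.nan, 8.0], index=["a", "b", "c"])
        out = log2_transform(s)
        assert math.isnan(out["b"]) and out["c"] == 3.0
        with pytest.raises(ValueError, match="c"):
            log2_transform(pd.Series([1.0, -2.0], index=["b", "c"]))

    def test_normality_test_needs_twenty(self):
        with pytest.raises(ValueError):
            dagostino_pearson(np.arange(10.0))

    def test_normality_test_calibration_and_power(self):
        rng = np.random.default_rng(7)
        normal_ok = sum(
            dagostino_pearson(rng.normal(size=500))[1] > 0.05 for _ in range(100)
        )
        expo_reject = sum(
            dagostino_pearson(rng.exponential(size=500))[1] < 0.05
            for _ in range(100)
        )
        assert normal_ok >= 94
        assert expo_reject >= 99


class TestEmScan:
    def test_identical_class_statistics_give_zero(self, informative_marker_cross):
        _, probs = informative_marker_cross([1.0, 2.0], [1.0, 2.0])
        scan = em_scan(probs, [1.0, 2.0, 1.0, 2.0])
        assert scan.lod[0] == pytest.approx(0.0, abs=1e-8)

    def test_separated_groups_match_regression_oracle(self, informative_marker_cross):
        a, h = [10.0, 11.0, 12.0], [14.0, 15.0, 16.0]
        _, probs = informative_marker_cross(a, h)
        scan = em_scan(probs, a + h)
        expected = regression_lod(a, h)  # = 3 log10(28/4) = 2.5353
        assert expected == pytest.approx(2.5353, abs=1e-4)
        assert scan.lod[0] == pytest.approx(expected, abs=1e-6)

    def test_marker_equivalence_random_data(self, informative_marker_cross):
        rng = np.random.default_rng(3)
        a = list(rng.normal(0, 1, 15))
        h = list(rng.normal(0.8, 1, 12))
        _, probs = informative_marker_cross(a, h)
        scan = em_scan(probs, a + h)
        assert scan.lod[0] == pytest.approx(regression_lod(a, h), abs=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        geno = rng.choice(["A", "H"], size=(40, 3))
        cross = make_cross(["".join(g) for g in geno], cm=[0.0, 12.0, 30.0])
        probs = conditional_genotype_probs(cross, step_cm=3.0)
        y = rng.normal(size=40) + 0.8 * (geno[:, 1] == "A")
        lod1 = em_scan(probs, y).lod
        lod2 = em_scan(probs, 3.7 * y - 11.0).lod
        np.testing.assert_allclose(lod1, lod2, atol=1e-5)

    def test_loglik_monotone_across_iterations(self):
        rng = np.random.default_rng(9)
        geno = rng.choice(["A", "H", "-"], size=(50, 4), p=[0.45, 0.45, 0.1])
        cross = make_cross(["".join(g) for g in geno], cm=[0.0, 10.0, 22.0, 37.0])
        probs = conditional_genotype_probs(cross, step_cm=2.0, error_prob=1e-3)
        y = rng.normal(size=(6, 50))
        track = []
        _em_lod_profile(probs.probs.transpose(1, 0, 2), y, track=track)
        assert len(track) >= 2
        for prev, cur in zip(track, track[1:]):
            if prev.shape == cur.shape:  # same chunk
                assert (cur >= prev - 1e-6).all()

    def test_constant_trait_rejected(self, informative_marker_cross):
        _, probs = informative_marker_cross([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(DegeneratePhenotypeError, match="degenerate"):
            em_scan(probs, [1.0, 1.0, 1.0, 1.0])

    def test_missing_trait_values_dropped(self, informative_marker_cross):
        a, h = [10.0, 11.0, 12.0], [14.0, 15.0, 16.0]
        _, probs = informative_marker_cross(a + [99.0], h)
        scan = em_scan(probs, a + [np.nan] + h)
        assert scan.n == 6
        assert scan.lod[0] == pytest.approx(regression_lod(a, h), abs=1e-6)


class TestNpScan:
    def test_equal_rank_sums_give_zero(self, informative_marker_cross):
        _, probs = informative_marker_cross([1.0, 4.0], [2.0, 3.0])
        scan = np_scan(probs, [1.0, 4.0, 2.0, 3.0])
        assert scan.lod[0] == pytest.approx(0.0, abs=1e-12)

    def test_kruskal_wallis_closed_form(self, informative_marker_cross):
        _, probs = informative_marker_cross([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        scan = np_scan(probs, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        h = 12.0 / (6 * 7) * (6**2 / 3 + 15**2 / 3) - 3 * 7
        assert h == pytest.approx(3.857143, abs=1e-6)
        assert scan.lod[0] == pytest.approx(h / (2 * math.log(10)), abs=1e-10)

    def test_matches_scipy_kruskal_with_ties(self, informative_marker_cross):
        rng = np.random.default_rng(13)
        a = list(rng.integers(0, 6, 14).astype(float))
        h = list(rng.integers(2, 8, 11).astype(float))
        _, probs = informative_marker_cross(a, h)
        scan = np_scan(probs, a + h)
        expected = stats.kruskal(a, h).statistic / (2 * math.log(10))
        assert scan.lod[0] == pytest.approx(expected, abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(17)
        geno = rng.choice(["A", "H"], size=(30, 3))
        cross = make_cross(["".join(g) for g in geno], cm=[0.0, 15.0, 33.0])
        probs = conditional_genotype_probs(cross, step_cm=1.0)
        y = rng.normal(size=30)
        np.testing.assert_allclose(
            np_scan(probs, y).lod, np_scan(probs, np.exp(y)).lod, atol=1e-12
        )


class TestPermutations:
    def test_constant_maxima_threshold(self):
        perm = PermutationResult("t", np.full(150, 2.5), seed=0, method="em")
        for alpha in (0.01, 0.05, 0.5):
            assert perm.threshold(alpha) == 2.5

    def test_interpolated_quantile(self):
        maxima = 1.0 + 0.01 * np.arange(200)  # 1.00, 1.01, ..., 2.99
        perm = PermutationResult("t", maxima, seed=0, method="em")
        # h = 0.95 * 199 = 189.05 -> v_189 + 0.05 * 0.01
        assert perm.threshold(0.05) == pytest.approx(2.8905, abs=1e-12)

    def test_thresholds_nondecreasing_as_alpha_shrinks(self):
        rng = np.random.default_rng(0)
        perm = PermutationResult("t", rng.exponential(size=500), 0, "em")
        ts = [perm.threshold(a) for a in (0.5, 0.2, 0.1, 0.05, 0.01)]
        assert all(b >= a for a, b in zip(ts, ts[1:]))

    def test_alpha_and_nperm_validation(self, informative_marker_cross):
        _, probs = informative_marker_cross([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            permutation_threshold(probs, [1.0, 2.0, 3.0, 4.0], n_perm=10)
        perm = PermutationResult("t", np.ones(100), 0, "em")
        with pytest.raises(ValueError):
            perm.threshold(0.0)

    def test_permutation_reproducible(self, planted_cross):
        probs = conditional_genotype_probs(planted_cross, step_cm=0.0)
        y = planted_cross.phenotypes["bw"]
        p1 = permutation_threshold(probs, y, n_perm=100, seed=4, method="np")
        p2 = permutation_threshold(probs, y, n_perm=100, seed=4, method="np")
        np.testing.assert_array_equal(p1.maxima, p2.maxima)


def _scan_from_curve(cm, lod, chrom="1"):
    pos = pd.DataFrame(
        {
            "chrom": chrom,
            "cm": cm,
            "is_marker": True,
            "name": [f"p{i}" for i in range(len(cm))],
            "nearest_marker": [f"p{i}" for i in range(len(cm))],
        }
    )
    return ScanResult("t", "em", pos, np.asarray(lod, dtype=float), n=100)


class TestSupportInterval:
    def test_single_spike(self):
        cm = np.arange(0.0, 41.0, 1.0)
        lod = np.zeros(len(cm))
        lod[20] = 8.0
        scan = _scan_from_curve(cm, lod)
        lo, hi = support_interval(scan, "1", method="bayes")
        assert (lo, hi) == (20.0, 20.0)

    def test_lod_drop_on_triangular_curve(self):
        # peak LOD 3 at 20 cM falling 0.1/cM -> within 1.5 LOD: [5, 35]
        cm = np.arange(0.0, 41.0, 1.0)
        lod = np.maximum(3.0 - 0.1 * np.abs(cm - 20.0), 0.0)
        scan = _scan_from_curve(cm, lod)
        assert support_interval(scan, "1", method="lod_drop") == (5.0, 35.0)

    def test_bayes_interval_contains_mass_and_peak(self):
        rng = np.random.default_rng(2)
        cm = np.arange(0.0, 51.0, 1.0)
        lod = np.maximum(4.0 - 0.15 * np.abs(cm - 25.0) + rng.normal(0, 0.1, len(cm)), 0)
        scan = _scan_from_curve(cm, lod)
        lo, hi = support_interval(scan, "1", method="bayes", coverage=0.95)
        assert lo <= 25.0 <= hi
        inside = (cm >= lo) & (cm <= hi)
        mass = 10.0**lod
        assert mass[inside].sum() / mass.sum() >= 0.94  # trapezoid vs sum slack

    def test_flat_curve_spans_chromosome_with_warning(self):
        cm = np.arange(0.0, 11.0, 1.0)
        scan = _scan_from_curve(cm, np.zeros(len(cm)))
        with pytest.warns(UserWarning, match="flat"):
            assert support_interval(scan, "1") == (0.0, 10.0)


class TestSummaries:
    def test_class_stats_hand_arithmetic(self):
        cross = make_cross(["A", "A", "H", "H"], cm=[0.0],
                           phenotypes={"y": [2.0, 4.0, 1.0, 3.0]})
        out = genotype_class_stats(cross, "m0", "y")
        assert out["A"].mean == 3.0 and out["H"].mean == 2.0
        assert out["A"].sem == pytest.approx(1.0)
        assert out["H"].sem == pytest.approx(1.0)
        assert (out["A"].n, out["H"].n) == (2, 2)

    def test_single_class_population(self):
        cross = make_cross(["A", "A"], cm=[0.0], phenotypes={"y": [1.0, 2.0]})
        out = genotype_class_stats(cross, "m0", "y")
        assert out["A"].n == 2 and out["H"].n == 0
        assert math.isnan(out["H"].mean)

    def test_below_threshold_yields_empty(self, planted_cross):
        probs = conditional_genotype_probs(planted_cross, step_cm=0.0)
        scan = em_scan(probs, planted_cross.phenotypes["bw"])
        assert peak_summaries(scan, threshold=1e6, cross=planted_cross) == []

    def test_planted_qtl_recovered(self, planted_cross):
        probs = conditional_genotype_probs(planted_cross, step_cm=1.0)
        scan = em_scan(probs, planted_cross.phenotypes["bw"], trait="bw")
        summaries = peak_summaries(scan, threshold=3.0, cross=planted_cross)
        assert [s.chromosome for s in summaries] == ["14"]
        s = summaries[0]
        assert s.ci_lo <= s.peak_cm <= s.ci_hi
        assert s.ci_lo <= 30.0 <= s.ci_hi  # planted position inside the CI
        assert s.class_stats["A"].n + s.class_stats["H"].n <= 300
        assert s.class_stats["A"].mean > s.class_stats["H"].mean
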
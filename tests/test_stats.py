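import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pseudotract.recipes import load_recipes
from pseudotract.stats import (
    attempted_count,
    compare_methods,
    confidence_ellipse,
    method_comparison_table,
    metric_vs_ei,
    success_rate,
)

# every printed generated/attempted pair with its published percentage
PRINTED_PAIRS = [
    (647, 672, 96.3),
    (678, 700, 96.9),
    (663, 672, 98.7),
    (692, 700, 98.9),
    (916, 952, 96.2),
    (951, 952, 99.9),
    (669, 672, 99.6),
    (700, 700, 100.0),
]


class TestSuccessRate:
    @pytest.mark.parametrize("generated,attempted,expected", PRINTED_PAIRS)
    def test_published_pairs_reproduced_exactly(self, generated, attempted, expected):
        assert success_rate(generated, attempted) == expected

    def test_full_success_is_100(self):
        assert success_rate(37, 37) == 100.0

    def test_half_up_rounding(self):
        # 0.25% rounds up at one decimal: 199/200 = 99.5 exactly
        assert success_rate(199, 200) == 99.5
        assert success_rate(1, 3) == 33.3

    def test_zero_attempted_is_error(self):
        with pytest.raises(ValueError):
            success_rate(0, 0)

    def test_generated_beyond_attempted_is_error(self):
        with pytest.raises(ValueError):
            success_rate(5, 4)


class TestAttemptedCount:
    def test_cohort_sizes_give_published_totals(self):
        recipes = load_recipes()
        assert attempted_count(recipes, 48) == 672
        assert attempted_count(recipes, 50) == 700
        assert attempted_count(recipes, 68) == 952

    def test_zero_subjects(self):
        assert attempted_count(load_recipes(), 0) == 0


def closed_form_paired_t(a, b):
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), two-sided p."""
    d = np.asarray(a) - np.asarray(b)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return t, p


def closed_form_pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    r = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
        np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
    )
    n = len(a)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return r, p


class TestCompareMethods:
    def test_worked_example(self):
        a = (0.50, 0.60, 0.70)
        b = (0.40, 0.45, 0.65)
        row = compare_methods(a, b)
        assert np.isclose(row.mean_difference, 0.10, atol=1e-12)
        t, p = closed_form_paired_t(a, b)
        assert np.isclose(row.t_p, p, atol=1e-12)
        r, rp = closed_form_pearson(a, b)
        assert np.isclose(row.r, r, atol=1e-12)
        assert np.isclose(row.r_p, rp, atol=1e-12)

    def test_identical_vectors(self):
        row = compare_methods([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert row.mean_difference == 0.0
        assert row.t_p == 1.0  # zero difference everywhere
        assert row.r is not None  # both vary, correlation defined (r = 1)

    def test_constant_vector_gives_missing_correlation(self):
        row = compare_methods([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert row.r is None and row.r_p is None

    def test_matches_closed_forms_on_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            a = rng.normal(size=n)
            b = a + rng.normal(scale=0.5, size=n)
            row = compare_methods(a, b)
            t, p = closed_form_paired_t(a, b)
            r, rp = closed_form_pearson(a, b)
            assert np.isclose(row.mean_difference, (a - b).mean(), atol=1e-10)
            assert np.isclose(row.t_p, p, atol=1e-10)
            assert np.isclose(row.r, r, atol=1e-10)
            assert np.isclose(row.r_p, rp, atol=1e-10)

    def test_pairwise_deletion_and_insufficient_marker(self):
        row = compare_methods([1.0, np.nan, 3.0, 4.0], [1.1, 2.0, np.nan, 4.2])
        assert row.n == 2 and row.insufficient

    def test_dropping_a_pair_keeps_mean_difference_sign(self):
        rng = np.random.default_rng(5)
        a = np.sort(rng.uniform(0.5, 0.9, 8))
        b = a - rng.uniform(0.05, 0.1, 8)  # a always above b
        full = compare_methods(a, b)
        for drop in range(8):
            keep = np.ones(8, bool)
            keep[drop] = False
            part = compare_methods(a[keep], b[keep])
            assert np.sign(part.mean_difference) == np.sign(full.mean_difference)

    def test_null_p_values_uniform(self):
        """Paired t under a true null: p ~ U(0,1) by Kolmogorov-Smirnov."""
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(500):
            a = rng.normal(size=20)
            b = a + rng.normal(size=20)  # same marginal location: true null
            ps.append(compare_methods(a, b).t_p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestComparisonTable:
    def _frames(self):
        rng = np.random.default_rng(3)
        subjects = [f"s{i}" for i in range(10)]
        rows_p, rows_a = [], []
        for s in subjects:
            fa = rng.uniform(0.5, 0.8)
            rows_p.append({"subject": s, "tract": "gCC", "FA": fa, "MD": 0.0007})
            rows_a.append({"subject": s, "tract": "gCC", "FA": fa - 0.1, "MD": 0.0009})
        return pd.DataFrame(rows_p), pd.DataFrame(rows_a)

    def test_sign_convention_negative_when_pseudo_atlas_higher(self):
        pseudo, atlas = self._frames()
        tab = method_comparison_table(pseudo, atlas)
        fa_row = tab[(tab.tract == "gCC") & (tab.metric == "FA")].iloc[0]
        assert fa_row["mean_difference"] < 0  # pseudo-atlas FA is higher
        md_row = tab[(tab.tract == "gCC") & (tab.metric == "MD")].iloc[0]
        assert md_row["mean_difference"] > 0  # pseudo-atlas MD is lower
        assert fa_row["n"] == 10

    def test_rounding_matches_table_precision(self):
        pseudo, atlas = self._frames()
        tab = method_comparison_table(pseudo, atlas)
        fa = tab[(tab.metric == "FA")].iloc[0]["mean_difference"]
        assert fa == round(fa, 4)


class TestConfidenceEllipse:
    def test_identity_covariance_radius_is_chi2_quantile_root(self):
        # data with sample covariance exactly I: +-1 on each axis
        x = np.array([1.0, -1.0, 1.0, -1.0, 0, 0, 0, 0]) * np.sqrt(8 / 7) / 1.0
        y = np.array([0, 0, 0, 0, 1.0, -1.0, 1.0, -1.0]) * np.sqrt(8 / 7) / 1.0
        # rescale so np.cov (ddof=1) is exactly identity
        x *= np.sqrt(1.0 / np.cov(np.vstack([x, y]))[0, 0])
        y *= np.sqrt(1.0 / np.cov(np.vstack([x, y]))[1, 1])
        es = confidence_ellipse(x, y, 0.95)
        expected = np.sqrt(-2.0 * np.log(0.05))  # closed-form chi2(2) quantile
        assert np.allclose(es.semi_axes, expected, atol=1e-9)
        assert np.isclose(expected, 2.4477, atol=1e-4)

    def test_shrinks_to_point_as_level_vanishes(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 50))
        es = confidence_ellipse(x, y, 1e-12)
        assert max(es.semi_axes) <= 1e-4

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(scale=3.0, size=400)
        y = rng.normal(scale=0.5, size=400)
        base = confidence_ellipse(x, y)
        th = np.deg2rad(30)
        xr = x * np.cos(th) - y * np.sin(th)
        yr = x * np.sin(th) + y * np.cos(th)
        rot = confidence_ellipse(xr, yr)
        assert np.isclose((rot.angle_deg - base.angle_deg) % 180, 30.0, atol=1.0)
        assert np.allclose(sorted(rot.semi_axes), sorted(base.semi_axes), rtol=1e-9)

    def test_degenerate_covariance_flagged(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        es = confidence_ellipse(x, 2 * x)
        assert es.degenerate or min(es.semi_axes) <= 1e-12


class TestMetricVsEi:
    def test_exact_linear_relation(self):
        ei = np.array([0.25, 0.30, 0.35, 0.40])
        res = metric_vs_ei(2 * ei + 1, ei)
        assert np.isclose(res["slope"], 2.0, atol=1e-12)
        assert np.isclose(res["r"], 1.0, atol=1e-12)

    def test_constant_ei_flagged_undefined(self):
        res = metric_vs_ei([0.1, 0.2, 0.3], [0.3, 0.3, 0.3])
        assert res["undefined"] and res["slope"] is None

    def test_independent_metric_has_small_correlation(self):
        """Null calibration: p-values uniform over repeated draws."""
        rng = np.random.default_rng(31)
        ps = []
        for _ in range(200):
            ei = rng.uniform(0.25, 0.4, 30)
            metric = rng.normal(0.7, 0.05, 30)  # no coupling
            ps.append(metric_vs_ei(metric, ei)["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01
        assert np.mean(np.abs([metric_vs_ei(rng.normal(size=30), rng.uniform(0.2, 0.4, 30))["r"]
                               for _ in range(50)])) < 0.3
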
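"""Closed-form agreement statistics and the repeated-measures comparison."""

import numpy as np
import pandas as pd
import pytest

from lvquant.phantom import StudySpec, _draw_correlated_spans
from lvquant.stats import (
    bland_altman,
    correlate,
    linear_fit,
    paired_modalities_test,
    rm_anova_f,
)


class TestBlandAltman:
    def test_identical_pairs_have_zero_bias_and_limits(self):
        res = bland_altman([(10.0, 10.0), (20.0, 20.0), (30.0, 30.0)])
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_hand_computed_example(self):
        # d = (-2, 2, -3): bias = -1, sd = sqrt(7), loa = -1 -+ 1.96*sqrt(7)
        res = bland_altman([(10, 12), (20, 18), (30, 33)])
        assert res.bias == pytest.approx(-1.0, abs=1e-12)
        assert res.sd_diff == pytest.approx(np.sqrt(7), abs=1e-12)
        assert res.loa_low == pytest.approx(-6.185672569686598, abs=1e-12)
        assert res.loa_high == pytest.approx(4.185672569686598, abs=1e-12)

    def test_swapping_negates_bias_and_mirrors_limits(self):
        pairs = np.array([(10, 12), (20, 18), (30, 33)], float)
        a = bland_altman(pairs)
        b = bland_altman(pairs[:, ::-1])
        assert b.bias == -a.bias
        assert b.loa_low == pytest.approx(-a.loa_high)
        assert b.loa_high == pytest.approx(-a.loa_low)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="2 pairs"):
            bland_altman([(1.0, 2.0)])


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == 0.0

    def test_pearson_frozen_example_exact(self):
        # x=(1..5), y=(2,1,4,3,5): r = 0.8 exactly (r^2 = 16/25)
        res = correlate([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8, abs=1e-12)
        assert res.p_value == pytest.approx(0.10408803866182778, abs=1e-6)

    def test_spearman_rank_example(self):
        res = correlate([1, 2, 3, 4], [1, 3, 2, 4], method="spearman")
        assert res.r == pytest.approx(0.8, abs=1e-12)

    def test_fisher_ci_brackets_r_and_matches_direction(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        res = correlate(x, y)
        assert res.ci95 is not None
        assert res.ci95[0] < res.r < res.ci95[1]
        assert res.ci95[0] > 0  # clearly positive association

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_recovers_generator_span_correlation(self):
        """Mean estimated r over seeds tracks the sampler's true correlation."""
        target = 0.5
        rs = []
        for seed in range(200):
            spec = StudySpec(n_subjects=14, cross_modality_rho=target, seed=seed)
            spans = _draw_correlated_spans(spec, np.random.default_rng(seed))
            rs.append(correlate(spans[:, 0], spans[:, 1]).r)
        # empirical truth-level correlation of the truncated sampler
        big = _draw_correlated_spans(
            StudySpec(n_subjects=20000, cross_modality_rho=target, seed=0),
            np.random.default_rng(123),
        )
        truth_r = np.corrcoef(big[:, 0], big[:, 1])[0, 1]
        assert np.mean(rs) == pytest.approx(truth_r, abs=0.05)


class TestLinearFit:
    def test_exact_line(self):
        fit = linear_fit([0, 1, 2], [0, 1, 2])
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.residual_sd == 0.0

    def test_frozen_example_exact(self):
        # x=(0,1,2,3), y=(1,3,2,5): slope = intercept = 11/10 exactly
        fit = linear_fit([0, 1, 2, 3], [1, 3, 2, 5])
        assert fit.slope == pytest.approx(1.1, abs=1e-12)
        assert fit.intercept == pytest.approx(1.1, abs=1e-12)

    def test_confidence_band_narrowest_at_mean_and_monotone(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 30)
        y = 2 * x + rng.normal(0, 1, 30)
        fit = linear_fit(x, y)
        grid = np.linspace(-5, 15, 201)
        lo, hi = fit.confidence_band(grid)
        width = hi - lo
        i_min = np.argmin(width)
        assert grid[i_min] == pytest.approx(fit.x_mean, abs=0.1)
        assert np.all(np.diff(width[i_min:]) >= 0)
        assert np.all(np.diff(width[: i_min + 1]) <= 0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([0, 1], [0, 1])


def _long_table(data: np.ndarray, modalities=("A", "B", "C")) -> pd.DataFrame:
    rows = []
    for i in range(data.shape[0]):
        for j, m in enumerate(modalities):
            rows.append((f"s{i:03d}", 0, m, "area", data[i, j]))
    return pd.DataFrame(
        rows, columns=["subject", "slice", "modality", "method", "enhancement_pct"]
    )


class TestPairedModalities:
    def test_identical_columns_give_null_result(self):
        rng = np.random.default_rng(1)
        col = rng.uniform(20, 60, 20)
        data = np.column_stack([col, col, col])
        res = paired_modalities_test(_long_table(data))
        assert res.f_statistic == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0)
        assert all(p == pytest.approx(1.0) for p in res.tukey_p.values())

    def test_closed_form_f_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(3)
        data = rng.normal([40, 45, 55], 8, size=(16, 3))
        f, df1, df2 = rm_anova_f(data)
        long = _long_table(data)
        long["unit"] = long["subject"]
        sm = AnovaRM(long, "enhancement_pct", "unit", within=["modality"]).fit()
        assert f == pytest.approx(sm.anova_table["F Value"].iloc[0], rel=1e-10)
        assert df1 == sm.anova_table["Num DF"].iloc[0]
        assert df2 == sm.anova_table["Den DF"].iloc[0]

    def test_tukey_p_ordering_follows_mean_differences(self):
        rng = np.random.default_rng(4)
        data = rng.normal([40, 44, 53], 6, size=(14, 3))
        res = paired_modalities_test(_long_table(data))
        assert res.p_value < 0.01  # clear effect present
        assert all(0.0 <= p <= 1.0 for p in res.tukey_p.values())
        # larger mean separation -> smaller adjusted p (same error term)
        diffs = {
            pair: abs(res.group_means[pair[0]] - res.group_means[pair[1]])
            for pair in res.tukey_p
        }
        order_by_diff = sorted(diffs, key=diffs.get, reverse=True)
        order_by_p = sorted(res.tukey_p, key=res.tukey_p.get)
        assert order_by_diff == order_by_p
        assert res.tukey_p[("A", "C")] < 0.05

    def test_offset_modality_detected_with_power(self):
        """A +15-point offset on one modality is flagged at p < 0.001 in
        >= 95% of seeded replicates."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            base = rng.uniform(20, 60, 56)
            data = np.column_stack(
                [
                    base + rng.normal(0, 5, 56),
                    base + rng.normal(0, 5, 56),
                    base + 15 + rng.normal(0, 5, 56),
                ]
            )
            res = paired_modalities_test(_long_table(data))
            if (
                res.tukey_p[("A", "C")] < 0.001
                and res.tukey_p[("B", "C")] < 0.001
            ):
                hits += 1
        assert hits >= 95

    def test_incomplete_blocks_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        table = _long_table(rng.uniform(10, 90, (10, 3)))
        table = table.drop(table[(table.subject == "s000") & (table.modality == "B")].index)
        with pytest.warns(UserWarning, match="incomplete"):
            res = paired_modalities_test(table)
        assert res.n_units == 9
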
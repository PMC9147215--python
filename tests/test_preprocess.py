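"""Imputation, winsorization, interpolation, split and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panelcast import (
    PanelSeries,
    SyntheticConfig,
    apply_standardizer,
    correlation_screen,
    destandardize,
    fit_standardizer,
    generate_panel,
    impute_missing,
    interpolate_uniform,
    preprocess_panel,
    sequential_split,
    winsorize,
)

from conftest import make_series


def panel_from_columns(*cols, dates=None):
    values = np.column_stack(cols).astype(float)
    n = values.shape[0]
    if dates is None:
        dates = pd.Timestamp("2020-01-01") + pd.to_timedelta(np.arange(n), unit="D")
    names = tuple(f"I{j}" for j in range(values.shape[1]))
    return PanelSeries(dates=pd.DatetimeIndex(dates), values=values, index_names=names)


class TestImpute:
    def test_interior_missing_takes_neighbor_mean(self):
        p = panel_from_columns([2.0, np.nan, 4.0])
        out = impute_missing(p)
        np.testing.assert_allclose(out.values[:, 0], [2.0, 3.0, 4.0])
        assert not out.missing_mask.any()

    def test_no_missing_is_identity(self):
        p = panel_from_columns([1.0, 2.0, 3.0])
        out = impute_missing(p)
        np.testing.assert_array_equal(out.values, p.values)

    def test_symmetric_case(self):
        p = panel_from_columns([10.0, np.nan, 10.0])
        np.testing.assert_allclose(impute_missing(p).values[:, 0], [10.0, 10.0, 10.0])

    def test_consecutive_interior_missing_rejected_naming_index(self):
        p = panel_from_columns([1.0, np.nan, np.nan, 4.0])
        with pytest.raises(ValueError, match="I0"):
            impute_missing(p)

    def test_boundary_missing_takes_single_neighbor(self, caplog):
        p = panel_from_columns([np.nan, 5.0, 7.0])
        with caplog.at_level("WARNING"):
            out = impute_missing(p)
        assert out.values[0, 0] == 5.0
        assert any("nearest neighbor" in r.message for r in caplog.records)


class TestWinsorize:
    def test_single_extreme_clipped_to_two_sigma_bound(self):
        col = [0.0] * 9 + [100.0]
        p = panel_from_columns(col)
        mu, sd = np.mean(col), np.std(col, ddof=1)
        out = winsorize(p)
        assert out.values[-1, 0] == pytest.approx(mu + 2 * sd)
        np.testing.assert_array_equal(out.values[:-1, 0], 0.0)

    def test_values_within_band_untouched(self):
        p = panel_from_columns([1.0, 2.0, 3.0, 2.0, 1.0])
        np.testing.assert_array_equal(winsorize(p).values, p.values)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=30))
    def test_idempotent_under_fixed_thresholds(self, col):
        # re-applying the clip with the same mu/sigma is exactly the identity;
        # recomputing the moments after clipping would narrow the bounds, so
        # the thresholds are what carries the idempotence
        from panelcast.preprocess import winsor_stats

        p = panel_from_columns(col)
        stats = winsor_stats(p)
        once = winsorize(p, stats=stats)
        twice = winsorize(once, stats=stats)
        np.testing.assert_array_equal(twice.values, once.values)

    def test_recomputed_second_pass_narrows_bounds(self):
        # the documented non-idempotence of moment recomputation: clipping
        # shrinks mu and sigma, so a recomputed pass clips further
        p = panel_from_columns([0.0] * 9 + [100.0])
        once = winsorize(p)
        twice = winsorize(once)
        assert twice.values[-1, 0] < once.values[-1, 0]

    def test_constant_column_is_noop(self, caplog):
        p = panel_from_columns([5.0, 5.0, 5.0, 5.0])
        with caplog.at_level("WARNING"):
            out = winsorize(p)
        np.testing.assert_array_equal(out.values, p.values)

    def test_requires_imputed_series(self):
        p = panel_from_columns([1.0, np.nan, 3.0])
        with pytest.raises(ValueError, match="imputed"):
            winsorize(p)


class TestInterpolate:
    def test_reference_grid_size(self):
        # 42 visits from 2013-05-10 to 2014-05-14 (369-day span) at 0.5-day
        # steps must give 2*369 + 1 = 739 grid rows
        rng = np.random.default_rng(0)
        interior = np.sort(rng.choice(np.arange(1, 369), size=40, replace=False))
        days = np.concatenate(([0], interior, [369]))
        dates = pd.Timestamp("2013-05-10") + pd.to_timedelta(days, unit="D")
        assert dates[-1] == pd.Timestamp("2014-05-14")
        p = panel_from_columns(rng.normal(size=42), dates=dates)
        grid = interpolate_uniform(p, step=0.5)
        assert grid.n == 739

    def test_two_point_linear_case(self):
        p = panel_from_columns(
            [0.0, 1.0], dates=pd.to_datetime(["2020-01-01", "2020-01-02"])
        )
        grid = interpolate_uniform(p, step=0.5)
        np.testing.assert_allclose(grid.values[:, 0], [0.0, 0.5, 1.0])

    def test_visit_values_reproduced_at_knots(self):
        panel = generate_panel(SyntheticConfig(missing_cells=0, outlier_cells=0, seed=8))
        grid = interpolate_uniform(panel, step=0.5)
        knots = (panel.day_offsets / 0.5).astype(int)
        np.testing.assert_allclose(grid.values[knots], panel.values, atol=1e-9)

    def test_single_visit_rejected(self):
        p = panel_from_columns([1.0], dates=pd.to_datetime(["2020-01-01"]))
        with pytest.raises(ValueError):
            interpolate_uniform(p)


class TestSplit:
    def test_reference_split_arithmetic(self):
        s = make_series(np.zeros((739, 2)) + np.arange(739)[:, None])
        split = sequential_split(s, ratio=0.9)
        assert split.train.n == 665
        assert split.test.n == 74

    def test_minimum_size_split(self):
        s = make_series(np.arange(20.0).reshape(10, 2))
        split = sequential_split(s)
        assert (split.train.n, split.test.n) == (9, 1)

    def test_concatenation_reproduces_input(self):
        vals = np.random.default_rng(1).normal(size=(30, 3))
        split = sequential_split(make_series(vals))
        np.testing.assert_array_equal(
            np.vstack([split.train.values, split.test.values]), vals
        )


class TestStandardizer:
    def test_unbiased_formula(self):
        s = make_series(np.array([[1.0], [3.0]]))
        stats = fit_standardizer(s)
        assert stats.mu[0] == pytest.approx(2.0)
        assert stats.sigma[0] == pytest.approx(np.sqrt(2.0))

    def test_train_standardized_to_zero_mean_unit_sd(self):
        vals = np.random.default_rng(2).normal(5, 3, size=(50, 4))
        s = make_series(vals)
        stats = fit_standardizer(s)
        z = apply_standardizer(s, stats)
        np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_stats_never_read_test_rows(self):
        vals = np.random.default_rng(3).normal(size=(30, 2))
        split = sequential_split(make_series(vals))
        stats_before = fit_standardizer(split.train)
        split.test.values[:] = 1e6  # mutate test rows
        stats_after = fit_standardizer(split.train)
        np.testing.assert_array_equal(stats_before.mu, stats_after.mu)
        np.testing.assert_array_equal(stats_before.sigma, stats_after.sigma)

    def test_trivial_points_and_round_trip(self):
        vals = np.random.default_rng(4).normal(size=(20, 3))
        s = make_series(vals)
        stats = fit_standardizer(s)
        z = apply_standardizer(s, stats)
        # x = mu -> 0 and x = mu + sigma -> 1
        np.testing.assert_allclose(
            apply_standardizer(make_series(stats.mu[None, :].repeat(2, 0)), stats).values, 0.0,
            atol=1e-12,
        )
        np.testing.assert_allclose(
            apply_standardizer(
                make_series((stats.mu + stats.sigma)[None, :].repeat(2, 0)), stats
            ).values,
            1.0,
            atol=1e-12,
        )
        np.testing.assert_allclose(destandardize(z.values, stats), vals, atol=1e-10)

    def test_name_mismatch_rejected(self):
        s = make_series(np.random.default_rng(5).normal(size=(10, 2)))
        stats = fit_standardizer(s)
        other = make_series(np.random.default_rng(5).normal(size=(10, 2)))
        other.index_names = ("X", "Y")
        with pytest.raises(ValueError, match="match"):
            apply_standardizer(other, stats)

    def test_constant_index_rejected_by_name(self):
        vals = np.ones((10, 2))
        vals[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="I1"):
            fit_standardizer(make_series(vals))


class TestPipelineOrderAndScreen:
    def test_full_preprocess_on_default_patient(self, default_panel):
        split, stats, grid = preprocess_panel(default_panel)
        assert grid.n == 739
        assert (split.train.n, split.test.n) == (665, 74)
        assert stats.n_fit == 665

    def test_correlation_screen_unflagged_on_default_patient(self, default_panel):
        _, _, grid = preprocess_panel(default_panel)
        screen = correlation_screen(grid)
        assert len(screen) == 36
        assert not screen["flagged"].any()
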
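"""Crown rasterization, subplot cover aggregation and the logistic fit."""

import math

import numpy as np
import pandas as pd
import pytest

from ecotone.core import FormatError, TransectSpec
from ecotone.discreteness import (
    FitStatus,
    fit_cover_logistic,
    rasterize_cover,
    read_cover_grid,
    subplot_mean_cover,
    write_cover_grid,
)

from conftest import make_tree


class TestRasterizeCover:
    def test_no_trees_all_zero(self, small_spec):
        grid = rasterize_cover([], small_spec)
        assert np.all(grid.values == 0)

    def test_union_idempotence_for_duplicate_crowns(self, small_spec):
        one = rasterize_cover([make_tree(10, 15, 6, crown=8)], small_spec)
        two = rasterize_cover(
            [make_tree(10, 15, 6, crown=8), make_tree(10, 15, 6, crown=8)],
            small_spec,
        )
        assert np.array_equal(one.values, two.values)

    def test_subplot_fully_inside_large_crown(self):
        # 10-m crown centered on a 5 x 5 subplot: every cell fully covered
        spec = TransectSpec(length=30.0, width=20.0)
        grid = rasterize_cover([make_tree(7.5, 12.5, 10, crown=10)], spec)
        sub = subplot_mean_cover(grid, spec)
        row = sub[(sub.belt_index == 3) & (sub.subplot_index == 2)]
        assert row.mean_cover.item() == 1.0

    def test_interior_disk_area_within_two_percent(self, spec180):
        r = 4.0
        grid = rasterize_cover([make_tree(30, 90, 8, crown=2 * r)], spec180, 10)
        area = grid.values.sum() * spec180.cell_size**2
        assert area == pytest.approx(math.pi * r * r, rel=0.02)

    def test_monotone_under_tree_addition(self, small_spec, rng):
        trees = [make_tree(x, y, 5, crown=3)
                 for x, y in zip(rng.uniform(0, 20, 10), rng.uniform(0, 35, 10))]
        before = rasterize_cover(trees, small_spec)
        after = rasterize_cover(trees + [make_tree(10, 10, 5, crown=4)], small_spec)
        assert np.all(after.values >= before.values)
        assert after.values.max() <= 1.0

    def test_translation_invariance_of_total_area(self, spec180):
        base = [make_tree(20, 50, 8, crown=6), make_tree(24, 53, 8, crown=5)]
        moved = [make_tree(t.x + 7, t.y + 13, t.height, crown=t.crown_diameter)
                 for t in base]
        a1 = rasterize_cover(base, spec180).values.sum()
        a2 = rasterize_cover(moved, spec180).values.sum()
        assert a1 == pytest.approx(a2, rel=1e-12)


class TestSubplotMeanCover:
    def test_uniform_grid(self, small_spec):
        grid = rasterize_cover([], small_spec)
        grid.values[:] = 0.4
        sub = subplot_mean_cover(grid, small_spec)
        assert np.allclose(sub.mean_cover, 0.4)
        assert len(sub) == small_spec.n_belts * small_spec.subplots_per_belt

    def test_partial_cover_mean(self, small_spec):
        grid = rasterize_cover([], small_spec)
        grid.values[0:1, 0:5] = 1.0  # 5 of the 25 cells of subplot (1, 1)
        sub = subplot_mean_cover(grid, small_spec)
        assert sub.mean_cover.iloc[0] == pytest.approx(0.2)

    def test_checkerboard(self, small_spec):
        grid = rasterize_cover([], small_spec)
        idx = np.indices(grid.values.shape).sum(axis=0)
        grid.values[:] = idx % 2
        sub = subplot_mean_cover(grid, small_spec)
        assert set(np.round(sub.mean_cover, 6)) <= {12 / 25, 13 / 25}


def _logistic_points(spec, c_max, y_l, s):
    y = np.repeat(spec.belt_midpoints, spec.subplots_per_belt)
    return np.column_stack([y, c_max / (1 + np.exp(s * (y - y_l)))])


class TestLogisticFit:
    def test_exact_recovery_on_noiseless_data(self, spec180):
        fit = fit_cover_logistic(
            _logistic_points(spec180, 0.8, 90.0, 0.3), spec180.length)
        assert fit.status == FitStatus.ok
        assert fit.c_max == pytest.approx(0.8, rel=1e-6)
        assert fit.y_l == pytest.approx(90.0, rel=1e-6)
        assert fit.s == pytest.approx(0.3, rel=1e-6)

    def test_midpoint_is_half_plateau(self, spec180):
        fit = fit_cover_logistic(
            _logistic_points(spec180, 0.8, 90.0, 0.3), spec180.length)
        c_at_yl = fit.c_max / (1 + math.exp(fit.s * (fit.y_l - fit.y_l)))
        assert c_at_yl == pytest.approx(fit.c_max / 2)

    def test_midpoint_below_margin_flagged(self, spec180):
        fit = fit_cover_logistic(
            _logistic_points(spec180, 0.8, 3.0, 0.3), spec180.length)
        assert fit.status == FitStatus.midpoint_below_margin
        assert not fit.interpretable

    def test_midpoint_above_transect_flagged(self, spec180):
        pts = _logistic_points(spec180, 0.8, 195.0, 0.1)
        fit = fit_cover_logistic(pts, spec180.length)
        assert fit.status == FitStatus.midpoint_above_transect

    def test_low_forest_cover_flagged(self, spec180):
        fit = fit_cover_logistic(
            _logistic_points(spec180, 0.28, 90.0, 0.1), spec180.length)
        assert fit.status == FitStatus.low_forest_cover

    def test_c_max_not_capped_at_one(self, spec180):
        # a plateau that keeps rising below the transect can fit C_max > 1
        y = np.repeat(spec180.belt_midpoints, 2)
        c = np.minimum(1.43 / (1 + np.exp(0.05 * (y - 20.0))), 1.0)
        fit = fit_cover_logistic(np.column_stack([y, c]), spec180.length)
        assert fit.c_max > 1.0

    def test_constant_cover_is_not_interpretable(self, spec180):
        y = np.repeat(spec180.belt_midpoints, 2)
        pts = np.column_stack([y, np.full_like(y, 0.3)])
        fit = fit_cover_logistic(pts, spec180.length)
        assert fit.status in (FitStatus.fit_failed, FitStatus.low_forest_cover)

    def test_too_few_y_positions_rejected(self):
        with pytest.raises(ValueError):
            fit_cover_logistic([(10, 0.5), (10, 0.4), (20, 0.3)], 180.0)

    def test_transition_width_formula(self, spec180):
        fit = fit_cover_logistic(
            _logistic_points(spec180, 0.8, 90.0, 0.25), spec180.length)
        assert fit.transition_width() == pytest.approx(2 * math.log(4) / fit.s)
        # at the discreteness cut the 80-20 transition spans <= ~14 m
        assert 2 * math.log(4) / 0.2 <= 13.9


class TestCoverGridIO:
    def test_roundtrip_preserves_downstream_fit(self, tmp_path, spec180):
        from ecotone.synthetic import generate_ecotone, preset

        trees, _ = generate_ecotone(preset("gradual_discrete"), seed=4)
        grid = rasterize_cover(trees, spec180)
        path = tmp_path / "cover.csv"
        write_cover_grid(grid, path)
        back = read_cover_grid(path, spec180)
        assert np.allclose(grid.values, back.values)
        s1 = fit_cover_logistic(subplot_mean_cover(grid, spec180), spec180.length).s
        s2 = fit_cover_logistic(subplot_mean_cover(back, spec180), spec180.length).s
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_cover_above_one_is_format_error(self, tmp_path, spec180):
        path = tmp_path / "bad.csv"
        nx, ny = 60, 180
        xs, ys = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5)
        cov = np.zeros(nx * ny)
        cov[0] = 1.2
        pd.DataFrame(
            {"cell_x": xs.ravel(), "cell_y": ys.ravel(), "cover": cov}
        ).to_csv(path, index=False)
        with pytest.raises(FormatError):
            read_cover_grid(path, spec180)

    def test_incomplete_grid_is_format_error(self, tmp_path, spec180):
        path = tmp_path / "short.csv"
        pd.DataFrame(
            {"cell_x": [0.5, 1.5], "cell_y": [0.5, 0.5], "cover": [0.1, 0.2]}
        ).to_csv(path, index=False)
        with pytest.raises(FormatError):
            read_cover_grid(path, spec180)

    def test_coarser_cells_accepted_when_dividing_subplot(self, tmp_path):
        spec = TransectSpec(length=20.0, width=10.0, cell_size=2.5)
        nx, ny = 4, 8
        xs, ys = np.meshgrid(
            (np.arange(nx) + 0.5) * 2.5, (np.arange(ny) + 0.5) * 2.5)
        path = tmp_path / "coarse.csv"
        pd.DataFrame(
            {"cell_x": xs.ravel(), "cell_y": ys.ravel(),
             "cover": np.full(nx * ny, 0.5)}
        ).to_csv(path, index=False)
        grid = read_cover_grid(path, spec)
        sub = subplot_mean_cover(grid, spec)
        assert np.allclose(sub.mean_cover, 0.5)
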
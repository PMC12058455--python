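"""Truncation, smoothing, difference metrics and the belt-shift scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecotone.abruptness import (
    abruptness_metrics,
    belt_shift_scan,
    smooth,
    truncate,
)
from ecotone.core import NoForestError, TransectSpec
from ecotone.gridding import BeltVector
from ecotone.synthetic import (
    AbruptStepHeight,
    CoverProfile,
    EcotoneScenario,
    generate_ecotone,
    generate_worked_vectors,
)

from conftest import make_tree


def bv(values, label="Max_H"):
    values = np.asarray(values, dtype=float)
    mids = (np.arange(len(values)) + 0.5) * 5.0
    return BeltVector(values, label, mids)


class TestTruncate:
    def test_hand_trace(self):
        tv, y_t = truncate(bv([10, 12, 8, 4, 2, 1, 0]), 3.0)
        assert y_t == 4
        assert tv.values.tolist() == [4, 4, 4, 4, 2, 1, 0]

    def test_all_forest_truncates_to_top_value(self):
        tv, y_t = truncate(bv([5, 6, 7]), 3.0)
        assert y_t == 3
        assert tv.values.tolist() == [7, 7, 7]

    def test_no_forest_raises(self):
        with pytest.raises(NoForestError):
            truncate(bv([2, 2, 1, 0]), 3.0)

    def test_belt_exactly_at_cutoff_does_not_count_as_forest(self):
        # 3 m is not > 3 m: the truncation belt is the lower one
        tv, y_t = truncate(bv([5, 3, 1]), 3.0)
        assert y_t == 1
        assert tv.values.tolist() == [5, 3, 1]


class TestSmooth:
    def test_gap_filled_from_upslope_neighbour(self):
        sv = smooth(bv([4, 4, 4, 4, 0, 2, 0]), y_t=4)
        assert sv.values.tolist() == [4, 4, 4, 4, 2, 2, 0]

    def test_monotone_vector_is_fixed_point(self):
        vals = [6, 6, 6, 5, 3, 1, 0]
        assert smooth(bv(vals), y_t=2).values.tolist() == vals

    def test_interior_gap(self):
        sv = smooth(bv([5, 5, 0, 3, 2, 1]), y_t=2)
        assert sv.values.tolist() == [5, 5, 3, 3, 2, 1]

    def test_never_decreases_and_preserves_truncated_zone(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vals = rng.uniform(0, 10, 12)
            y_t = int(rng.integers(1, 12))
            vals[: y_t] = vals[y_t - 1]
            sv = smooth(bv(vals), y_t)
            assert np.all(sv.values >= vals - 1e-12)
            assert np.array_equal(sv.values[:y_t], vals[:y_t])
            assert sv.values[-1] == vals[-1]


class TestAbruptnessMetrics:
    def run(self, raw, raw2=None, cutoff=3.0):
        spec = TransectSpec(length=5.0 * len(raw), width=10.0)
        m2 = bv(raw2, "Max2_H") if raw2 is not None else None
        return abruptness_metrics(bv(raw), m2, spec, cutoff)

    def test_hand_traced_gap_pipeline(self):
        res = self.run([10, 12, 8, 4, 0, 2, 0])
        assert res.s_max_h.values.tolist() == [4, 4, 4, 4, 2, 2, 0]
        assert res.delta.tolist() == [0, 0, 0, -2, 0, -2]
        assert res.a_abr == 2.0
        assert res.n_abr == pytest.approx(2 / 12)
        assert res.argmax_belt["a_abr"] == 4  # lowest belt on ties

    def test_constant_vector_has_zero_abruptness(self):
        res = self.run([5, 5, 5])
        assert res.a_abr == 0.0 and res.n_abr == 0.0
        assert any("edge" in w for w in res.warnings)

    def test_single_step_drop_normalizes_to_one(self):
        res = self.run([8, 8, 0])
        assert res.a_abr == 8.0
        assert res.n_abr == 1.0

    def test_normalization_uses_raw_untruncated_maximum(self):
        # raw max is 12 even though truncation caps the vector at 4
        res = self.run([10, 12, 8, 4, 2, 1, 0])
        assert res.n_abr == pytest.approx(res.a_abr / 12.0)

    def test_max2_all_zero_leaves_secondary_metrics_undefined(self):
        res = self.run([10, 8, 4, 0], raw2=[0, 0, 0, 0])
        assert res.a_abr2 is None and res.n_abr2 is None
        assert res.a_abr > 0

    def test_max2_below_cutoff_leaves_secondary_metrics_undefined(self):
        res = self.run([10, 8, 4, 0], raw2=[2, 2, 1, 0])
        assert res.a_abr2 is None

    def test_truncation_belts_found_independently(self):
        res = self.run([10, 8, 6, 4, 0], raw2=[9, 7, 2, 1, 0])
        assert res.y_t == 4
        assert res.y_t2 == 2

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        vals=st.lists(
            st.floats(0, 20, allow_nan=False, allow_infinity=False),
            min_size=3,
            max_size=40,
        )
    )
    def test_metric_bounds_and_identity(self, vals):
        """0 <= n_abr <= 1, 0 <= a_abr <= max(Max_H), exact rescaling identity."""
        vals = np.asarray(vals)
        if not np.any(vals > 3.0):
            with pytest.raises(NoForestError):
                self.run(vals)
            return
        res = self.run(vals)
        assert 0.0 <= res.a_abr <= np.max(vals) + 1e-12
        assert 0.0 <= res.n_abr <= 1.0 + 1e-12
        assert res.n_abr == pytest.approx(res.a_abr / np.max(vals), abs=1e-12)

    def test_invariant_to_seedlings_anywhere(self, spec180, rng):
        from ecotone.pipeline import analyze
        from ecotone.synthetic import preset

        trees, _ = generate_ecotone(preset("abrupt_discrete"), seed=5)
        base = analyze(trees, spec180).abruptness
        seedlings = [
            make_tree(x, y, 0.3)
            for x, y in zip(rng.uniform(0, 60, 50), rng.uniform(0, 180, 50))
        ]
        with_seedlings = analyze(trees + seedlings, spec180).abruptness
        assert with_seedlings.a_abr == base.a_abr


class TestBeltShiftScan:
    def test_uniform_forest_has_zero_dispersion(self, spec180, rng):
        # tall forest everywhere: no decline at any offset
        trees = [
            make_tree(x, y, 10.0)
            for x, y in zip(rng.uniform(0, 60, 800), rng.uniform(0, 180, 800))
        ]
        scan = belt_shift_scan(trees, spec180, step=1.0)
        assert len(scan.offsets) == 5
        assert scan.dispersion["a_abr"]["max"] == 0.0
        assert scan.dispersion["a_abr"]["range"] == 0.0

    def test_single_step_decline_is_stable_across_offsets(self, spec180):
        sc = EcotoneScenario(
            spec=spec180,
            height=AbruptStepHeight(h_max=8.0, y_step=100.0),
            cover=CoverProfile(0.6, 95.0, 0.4),
        )
        trees, _ = generate_ecotone(sc, seed=11)
        scan = belt_shift_scan(trees, spec180, step=1.0)
        # the full canopy step is visible at every offset
        assert scan.dispersion["a_abr"]["min"] > 6.0
        assert scan.dispersion["a_abr"]["range"] < 1.5

    def test_step_must_divide_belt_width(self, spec180):
        with pytest.raises(ValueError):
            belt_shift_scan([], spec180, step=1.5)


class TestWorkedVectorFixtures:
    @pytest.mark.parametrize("name", ["trace1", "gap1", "flat"])
    def test_fixture_matches_pipeline(self, name):
        fx = generate_worked_vectors()[name]
        tv, y_t = truncate(bv(fx.raw), fx.forest_cutoff)
        assert y_t == fx.y_t
        assert tv.values.tolist() == list(fx.truncated)
        sv = smooth(tv, y_t)
        assert sv.values.tolist() == list(fx.smoothed)
        spec = TransectSpec(length=5.0 * len(fx.raw), width=10.0)
        res = abruptness_metrics(bv(fx.raw), None, spec, fx.forest_cutoff)
        assert res.a_abr == fx.a_abr
        assert res.n_abr == pytest.approx(fx.n_abr)
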
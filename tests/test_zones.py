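"""Zone classification: calibration shift, coverage states, seven-zone grids."""
import numpy as np
import pytest

from mlczones import (
    BeamModelParameters,
    CoverageState,
    ZoneLabel,
    calibration_shift,
    classify_control_point,
    coverage_state,
    gpf_from_grid,
    zone_transmission_map,
)
from mlczones.synthetic import ApertureSpec, analytic_gpf_oracle

from conftest import make_cp


class TestCalibrationShift:
    def test_offset_only_model_shifts_constant(self, params):
        # offset 0.026 cm, gain and curvature zero
        for p in (-14.0, 0.0, 3.7, 14.0):
            assert calibration_shift(p, params) == pytest.approx(0.026)

    def test_zero_polynomial_is_zero_everywhere(self):
        params = BeamModelParameters(offset=0.0, gain=0.0, curvature=0.0)
        assert calibration_shift(10.0, params) == 0.0

    def test_gain_term_is_linear_in_position(self):
        params = BeamModelParameters(offset=0.0, gain=0.01, curvature=0.0)
        assert calibration_shift(10.0, params) == pytest.approx(0.1)

    def test_curvature_term_is_quadratic(self):
        params = BeamModelParameters(offset=0.0, gain=0.0, curvature=0.001)
        assert calibration_shift(-10.0, params) == pytest.approx(0.1)


class TestCoverageState:
    def test_closed_pair_opens_only_after_calibration(self, params, closed_cp):
        # calibrated gap (-0.026, +0.026) around the closed tips
        assert coverage_state(0.0, 30, closed_cp, params) is CoverageState.OPEN_ONLY_AFTER_CAL

    def test_point_inside_aperture_is_open(self, params, geometry):
        cp = make_cp(geometry, np.full(60, -5.0), np.full(60, 5.0))
        assert coverage_state(0.0, 30, cp, params) is CoverageState.OPEN_NOW

    def test_point_just_past_calibrated_tip_is_tip(self, params, geometry):
        # bank-B tip zone spans [5.026, 5.386] after the 0.026 cm shift
        cp = make_cp(geometry, np.full(60, -5.0), np.full(60, 5.0))
        assert coverage_state(5.1, 30, cp, params) is CoverageState.TIP
        assert coverage_state(5.4, 30, cp, params) is CoverageState.BODY

    def test_pair_index_out_of_range(self, params, closed_cp):
        with pytest.raises(IndexError):
            coverage_state(0.0, 60, closed_cp, params)


class TestClassifyControlPoint:
    def test_fully_retracted_leaves_give_all_open(self, params, geometry):
        cp = make_cp(
            geometry, np.full(60, -14.0), np.full(60, 14.0), jaws=(-5, 5, -5, 5)
        )
        grid = classify_control_point(cp, geometry, params, spacing=0.05)
        counts = grid.zone_counts()
        assert counts[ZoneLabel.OPEN] == grid.labels.size

    def test_zero_width_zones_vanish(self, geometry):
        """tg_width = 0 and a zero calibration polynomial eliminate the
        strip sub-zones and the calibration zone exactly."""
        params = BeamModelParameters(offset=0.0, tg_width=0.0)
        cp = make_cp(geometry, np.full(60, -3.0), np.full(60, 3.0), jaws=(-10, 10, -10, 10))
        counts = classify_control_point(cp, geometry, params, spacing=0.02).zone_counts()
        for z in (ZoneLabel.CALIBRATION, ZoneLabel.PAIRED, ZoneLabel.EXPOSED, ZoneLabel.NEGLECTED):
            assert counts[z] == 0
        assert counts[ZoneLabel.OPEN] > 0 and counts[ZoneLabel.TIP] > 0 and counts[ZoneLabel.BODY] > 0

    def test_validation_beam_matches_analytic_oracle(self, params, validation_plan):
        """The 0.5 x 0.5 cm^2 retracted-leaf beam agrees with the
        interval-counting oracle to better than one part per million."""
        cp = validation_plan.beams[0].control_points[0]
        grid = classify_control_point(cp, validation_plan.geometry, params, spacing=0.01)
        f_tool = gpf_from_grid(grid, 0.0).f
        f_oracle = analytic_gpf_oracle(
            ApertureSpec.from_control_point(cp, validation_plan.geometry), params, 0.01
        )
        assert np.abs(f_tool - f_oracle).max() < 1e-6

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_partition_every_point_labelled_once(self, params, geometry, seed):
        rng = np.random.default_rng(seed)
        a = np.round(rng.uniform(-8, 0, 60), 2)
        b = np.round(a + rng.uniform(0, 8, 60), 2)
        cp = make_cp(geometry, a, b, jaws=(-9.5, 9.5, -9.5, 9.5))
        grid = classify_control_point(cp, geometry, params, spacing=0.05)
        assert grid.zone_counts().sum() == grid.n_x * grid.n_y

    def test_open_fraction_monotone_in_square_side(self, params, validation_plan):
        """With jaws fixed at 30 x 30, a larger centered MLC square never
        shrinks the open fraction."""
        fractions = []
        for beam in validation_plan.beams[1:]:
            cp = beam.control_points[0]
            grid = classify_control_point(cp, validation_plan.geometry, params, spacing=0.1)
            fractions.append(gpf_from_grid(grid, 0.0).f[ZoneLabel.OPEN])
        assert np.all(np.diff(fractions) >= 0)

    def test_zone_fractions_converge_first_order_in_spacing(self, params, validation_plan):
        """Halving the spacing moves each fraction by O(spacing) only."""
        beam = next(b for b in validation_plan.beams if b.name == "square-10x10")
        cp = beam.control_points[0]
        f = {
            s: gpf_from_grid(
                classify_control_point(cp, validation_plan.geometry, params, s), 0.0
            ).f
            for s in (0.02, 0.01, 0.005)
        }
        assert np.abs(f[0.02] - f[0.01]).max() < 2 * 0.02
        assert np.abs(f[0.01] - f[0.005]).max() < 2 * 0.01

    def test_zero_area_jaws_rejected(self, params, geometry, closed_cp):
        closed_cp.jaw_x_high = closed_cp.jaw_x_low
        with pytest.raises(ValueError):
            classify_control_point(closed_cp, geometry, params)

    def test_nonpositive_spacing_rejected(self, params, geometry, closed_cp):
        with pytest.raises(ValueError, match="spacing"):
            classify_control_point(closed_cp, geometry, params, spacing=0.0)


class TestTransmissionMap:
    def test_transmissions_follow_zone_table(self, params, geometry):
        cp = make_cp(geometry, np.full(60, -3.0), np.full(60, 3.0), jaws=(-8, 8, -8, 8))
        grid = classify_control_point(cp, geometry, params, spacing=0.02)
        tmap = zone_transmission_map(grid, params)
        T = params.transmission
        expected = {
            ZoneLabel.OPEN: 1.0,
            ZoneLabel.CALIBRATION: 1.0,
            ZoneLabel.NEGLECTED: 1.0,
            ZoneLabel.TIP: np.sqrt(T),
            ZoneLabel.EXPOSED: np.sqrt(T),
            ZoneLabel.BODY: T,
            ZoneLabel.PAIRED: T,
        }
        for zone, value in expected.items():
            mask = grid.labels == zone
            if np.any(mask):
                assert np.all(tmap[mask] == value)
        # sqrt(0.015) ~ 0.12247 for the tip-type zones
        assert tmap[grid.labels == ZoneLabel.TIP].mean() == pytest.approx(0.1224745, abs=1e-6)
        assert tmap.mean() >= T and tmap.mean() <= 1.0
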
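"""GPF vectors and MU-weighted plan/beam averages."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mlczones import (
    GPFVector,
    Plan,
    ZONE_NAMES,
    ZoneGrid,
    ZoneLabel,
    gpf_from_grid,
    make_random_vmat_plan,
    normalized_weighted_average_gpf,
    plan_gpf_table,
    plan_metrics,
    weighted_average_gpf,
)


def vec(f_open=0.0, f_body=0.0, m=1.0, tip=0.0, **kw):
    f = np.zeros(7)
    f[ZoneLabel.OPEN] = f_open
    f[ZoneLabel.BODY] = f_body
    f[ZoneLabel.TIP] = tip
    f[ZoneLabel.PAIRED] = 1.0 - f.sum()  # pad to the simplex
    return GPFVector(f=f, m=m, **kw)


class TestGPFFromGrid:
    def test_fractions_are_counts_over_total(self):
        labels = np.zeros((10, 10), dtype=np.int8)
        labels[5:] = ZoneLabel.BODY  # 50 OPEN + 50 BODY
        grid = ZoneGrid(labels=labels, x_origin=0, y_origin=0, spacing=0.1)
        g = gpf_from_grid(grid, m=2.0)
        assert g.f[ZoneLabel.OPEN] == 0.5
        assert g.f[ZoneLabel.BODY] == 0.5
        assert g.f.sum() == 1.0
        assert g.o == 0.5 and g.m == 2.0

    def test_all_open_grid(self):
        grid = ZoneGrid(np.zeros((4, 4), dtype=np.int8), 0, 0, 0.1)
        g = gpf_from_grid(grid, 1.0)
        assert g.f[ZoneLabel.OPEN] == 1.0 and g.o == 1.0

    def test_empty_grid_rejected(self):
        grid = ZoneGrid(np.zeros((0, 4), dtype=np.int8), 0, 0, 0.1)
        with pytest.raises(ValueError, match="empty"):
            gpf_from_grid(grid, 1.0)


class TestWeightedAverage:
    def test_weighted_mean_of_fractions(self):
        vs = [vec(f_open=0.2, m=1.0), vec(f_open=0.4, m=3.0)]
        assert weighted_average_gpf(vs)[ZoneLabel.OPEN] == pytest.approx(0.35)

    def test_equal_weights_reduce_to_arithmetic_mean(self):
        vs = [vec(f_open=x, m=2.5) for x in (0.1, 0.2, 0.6)]
        assert weighted_average_gpf(vs)[ZoneLabel.OPEN] == pytest.approx(0.3)

    def test_single_vector_is_identity(self):
        v = vec(f_open=0.3, f_body=0.4, m=7.0)
        np.testing.assert_allclose(weighted_average_gpf([v]), v.f)

    def test_zero_meterset_scope_rejected(self):
        with pytest.raises(ValueError, match="zero meterset"):
            weighted_average_gpf([vec(m=0.0), vec(m=0.0)])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        vs = [vec(f_open=rng.uniform(0.1, 0.5), m=rng.uniform(0, 5)) for _ in range(9)]
        perm = [vs[i] for i in rng.permutation(len(vs))]
        np.testing.assert_allclose(weighted_average_gpf(vs), weighted_average_gpf(perm))
        np.testing.assert_allclose(
            normalized_weighted_average_gpf(vs), normalized_weighted_average_gpf(perm)
        )

    @settings(max_examples=40, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 100))
    def test_weight_scaling_invariance(self, scale, seed):
        """Multiplying all MU weights by a constant changes nothing."""
        rng = np.random.default_rng(seed)
        vs = [vec(f_open=rng.uniform(0.1, 0.5), m=rng.uniform(0.1, 5)) for _ in range(5)]
        scaled = [GPFVector(f=v.f, m=v.m * scale) for v in vs]
        np.testing.assert_allclose(
            weighted_average_gpf(vs), weighted_average_gpf(scaled), rtol=1e-12
        )
        np.testing.assert_allclose(
            normalized_weighted_average_gpf(vs),
            normalized_weighted_average_gpf(scaled),
            rtol=1e-12,
        )


class TestNormalizedAverage:
    def test_divides_by_open_fraction(self):
        v = vec(f_open=0.5, f_body=0.1, m=1.0)
        out = normalized_weighted_average_gpf([v])
        assert out[ZoneLabel.BODY] == pytest.approx(0.2)

    def test_fully_open_equals_unnormalized(self):
        vs = [vec(f_open=1.0 - 1e-15, m=m) for m in (1.0, 2.0)]
        for v in vs:
            v.f[:] = 0
            v.f[ZoneLabel.OPEN] = 1.0
        np.testing.assert_allclose(
            normalized_weighted_average_gpf(vs), weighted_average_gpf(vs)
        )

    def test_two_point_example(self):
        vs = [vec(f_open=0.5, f_body=0.1, m=1.0), vec(f_open=0.6, f_body=0.3, m=1.0)]
        assert normalized_weighted_average_gpf(vs)[ZoneLabel.BODY] == pytest.approx(0.35)

    def test_closed_aperture_with_mu_is_an_error(self):
        vs = [vec(f_open=0.0, f_body=1.0, m=1.0)]
        with pytest.raises(ValueError, match="closed aperture"):
            normalized_weighted_average_gpf(vs)
        # zero-MU closed shapes are fine (they carry no fluence)
        vs = [vec(f_open=0.0, f_body=1.0, m=0.0), vec(f_open=0.5, m=1.0)]
        normalized_weighted_average_gpf(vs)

    def test_skip_closed_downgrades_to_warning(self):
        vs = [vec(f_open=0.0, f_body=1.0, m=1.0), vec(f_open=0.5, f_body=0.1, m=1.0)]
        with pytest.warns(UserWarning, match="closed control point"):
            out = normalized_weighted_average_gpf(vs, skip_closed=True)
        assert out[ZoneLabel.BODY] == pytest.approx(0.2)


@pytest.fixture(scope="module")
def table(params):
    plan = make_random_vmat_plan(11, n_beams=2, n_cp=8)
    return plan, plan_metrics(plan, params, spacing=0.05, skip_closed=True)


class TestPlanMetrics:
    def test_every_control_point_reported(self, table):
        plan, df = table
        n_cp = sum(len(b.control_points) for b in plan.beams)
        assert (df["level"] == "control_point").sum() == n_cp

    def test_plan_average_sums_to_one(self, table):
        _, df = table
        row = df[(df.level == "plan") & (df.kind == "weighted")].iloc[0]
        assert sum(row[z] for z in ZONE_NAMES) == pytest.approx(1.0, abs=1e-12)

    def test_identical_control_points_average_to_themselves(self, params, validation_plan):
        sub = Plan(
            plan_id="one-beam",
            beams=[validation_plan.beams[3]],
            geometry=validation_plan.geometry,
        )
        df = plan_metrics(sub, params, spacing=0.05)
        cp_row = df[df.level == "control_point"].iloc[0]
        plan_row = df[(df.level == "plan") & (df.kind == "weighted")].iloc[0]
        for z in ZONE_NAMES:
            assert plan_row[z] == pytest.approx(cp_row[z], abs=1e-15)

    def test_two_beam_plan_blends_by_meterset(self, params, validation_plan):
        import copy

        b1 = copy.deepcopy(validation_plan.beams[2])
        b2 = copy.deepcopy(validation_plan.beams[12])
        b1.beam_meterset, b2.beam_meterset = 100.0, 300.0
        plan = Plan(plan_id="blend", beams=[b1, b2], geometry=validation_plan.geometry)
        df = plan_metrics(plan, params, spacing=0.05)
        beam_rows = df[(df.level == "beam") & (df.kind == "weighted")].set_index("beam_id")
        plan_row = df[(df.level == "plan") & (df.kind == "weighted")].iloc[0]
        for z in ZONE_NAMES:
            blend = 0.25 * beam_rows.loc[b1.name, z] + 0.75 * beam_rows.loc[b2.name, z]
            assert plan_row[z] == pytest.approx(blend, abs=1e-12)

    def test_plan_gpf_table_collects_plan_rows(self, params):
        dfs = [
            plan_metrics(make_random_vmat_plan(s, 1, 4), params, spacing=0.1, skip_closed=True)
            for s in (21, 22, 23)
        ]
        pt = plan_gpf_table(dfs)
        assert len(pt) == 3
        assert set(ZONE_NAMES) <= set(pt.columns)
        np.testing.assert_allclose(pt[list(ZONE_NAMES)].sum(axis=1), 1.0, atol=1e-12)
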
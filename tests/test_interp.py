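import numpy as np
import pytest
from hypothesis import given, strategies as st

from vmatconv import (builtin_geometry, compute_factors, interpolate_cp,
                      reparameterize_arc, scout_angles)
from vmatconv.plan import ControlPoint, to_arc_position
from vmatconv.synthetic import generate_linear_trajectory_arc


def _cp(index, angle, mw, leaves_b, leaves_a, jaws=(-50, 50, -100, 100)):
    return ControlPoint(index=index, gantry_angle=angle,
                        cumulative_meterset_weight=mw,
                        jaw_x1=jaws[0], jaw_x2=jaws[1],
                        jaw_y1=jaws[2], jaw_y2=jaws[3],
                        bank_b=np.full(60, float(leaves_b)),
                        bank_a=np.full(60, float(leaves_a)))


class TestScoutAngles:
    def test_two_points_are_the_endpoints(self):
        np.testing.assert_allclose(scout_angles(30.0, 120.0, "CW", 2),
                                   [30.0, 120.0])

    def test_full_cw_arc_crosses_zero_uniformly(self):
        """The clinical 181 -> 179 CW arc spans 358 deg through 0 with
        spacing 358/178 and no discontinuity."""
        ang = scout_angles(181.0, 179.0, "CW", 179)
        assert ang[0] == 181.0 and ang[-1] == 179.0
        pos = to_arc_position(ang, 181.0, "CW")
        spacing = np.diff(pos)
        np.testing.assert_allclose(spacing, 358.0 / 178.0, rtol=1e-12)
        # the grid passes through the 0/360 seam without a jump
        assert np.any(ang > 350) and np.any(ang < 10)

    def test_ccw_arc(self):
        ang = scout_angles(179.0, 181.0, "CCW", 90)
        pos = to_arc_position(ang, 179.0, "CCW")
        np.testing.assert_allclose(np.diff(pos), 358.0 / 89.0, rtol=1e-12)

    def test_endpoints_always_exact(self):
        for n in (2, 5, 178):
            ang = scout_angles(200.5, 159.5, "CW", n)
            assert ang[0] == 200.5 and ang[-1] == 159.5

    def test_zero_length_arc_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            scout_angles(90.0, 90.0, "CW", 10)


class TestComputeFactors:
    def test_fraction_from_bracketing_neighbors(self):
        """A target at 1.8 deg between CCW-decreasing sources at 2.8 and
        0.9 deg weights the 0.9-deg neighbor by (2.8-1.8)/(2.8-0.9)."""
        src = [10.0, 2.8, 0.9, 352.0]
        tgt = [10.0, 1.8, 352.0]
        f = compute_factors(src, tgt, "CCW")[1]
        assert f.prev_source_index == 1 and f.next_source_index == 2
        assert f.fraction == pytest.approx((2.8 - 1.8) / (2.8 - 0.9))

    def test_exact_source_angle_reproduced_with_zero_fraction(self):
        src = [0.0, 10.0, 20.0, 30.0]
        f = compute_factors(src, [0.0, 10.0, 30.0], "CW")[1]
        assert f.fraction == 0.0 and f.prev_source_index == 1

    def test_midpoint_is_half(self):
        src = [0.0, 10.0, 20.0]
        f = compute_factors(src, [0.0, 15.0, 20.0], "CW")[1]
        assert f.fraction == pytest.approx(0.5)

    def test_endpoint_targets_pin_to_endpoint_sources(self):
        src = [350.0, 0.0, 10.0]
        facs = compute_factors(src, [350.0, 5.0, 10.0], "CW")
        assert facs[0].fraction == 0.0
        assert facs[0].prev_source_index == 0
        assert facs[-1].fraction == 1.0
        assert facs[-1].next_source_index == 2

    def test_mismatched_endpoints_rejected(self):
        with pytest.raises(ValueError, match="endpoints"):
            compute_factors([0.0, 10.0, 20.0], [0.0, 10.0, 25.0], "CW")


class TestInterpolateCp:
    def test_meterset_blend(self):
        a = _cp(0, 10.0, 0.10, -5, 5)
        b = _cp(1, 12.0, 0.20, -5, 5)
        out = interpolate_cp(a, b, 0.5, 11.0)
        assert out.cumulative_meterset_weight == pytest.approx(0.15)
        assert out.gantry_angle == 11.0

    def test_f_zero_reproduces_prev(self):
        a = _cp(0, 10.0, 0.1, -7, 3)
        b = _cp(1, 12.0, 0.2, -5, 5)
        out = interpolate_cp(a, b, 0.0, 10.5)
        np.testing.assert_array_equal(out.bank_b, a.bank_b)
        np.testing.assert_array_equal(out.bank_a, a.bank_a)
        assert out.cumulative_meterset_weight == a.cumulative_meterset_weight
        assert out.gantry_angle == 10.5

    @given(st.floats(0.0, 1.0))
    def test_gap_stays_nonnegative(self, f):
        a = _cp(0, 10.0, 0.1, -2.0, -2.0)   # closed
        b = _cp(1, 12.0, 0.2, -5.0, 9.0)    # open
        out = interpolate_cp(a, b, f, 11.0)
        assert np.all(out.gaps >= -1e-12)

    def test_linear_leaf_trajectory_recovered_exactly(self):
        """A leaf moving linearly in arc position is hit exactly by the
        interpolant at any intermediate angle."""
        slope, intercept = 0.37, -12.0

        def leaf(posn):
            return intercept + slope * posn

        a = _cp(0, 100.0, 0.0, leaf(0.0), leaf(0.0) + 20)
        b = _cp(1, 140.0, 1.0, leaf(40.0), leaf(40.0) + 20)
        for target_pos in (3.7, 17.0, 31.9):
            out = interpolate_cp(a, b, target_pos / 40.0,
                                 100.0 + target_pos)
            np.testing.assert_allclose(out.bank_b, leaf(target_pos),
                                       rtol=1e-12)


class TestReparameterizeArc:
    def test_uniform_source_grid_is_fixed_point(self, m120):
        from vmatconv import ArcRecipe, generate_vmat_arc
        arc = generate_vmat_arc(ArcRecipe(seed=5, n_cp=40, accel_fraction=0,
                                          decel_fraction=0), m120)
        out = reparameterize_arc(arc)
        for c1, c2 in zip(arc.control_points, out.control_points):
            np.testing.assert_allclose(c2.bank_b, c1.bank_b, atol=1e-9)
            np.testing.assert_allclose(c2.bank_a, c1.bank_a, atol=1e-9)
            assert c2.cumulative_meterset_weight == pytest.approx(
                c1.cumulative_meterset_weight, abs=1e-12)

    def test_target_angle_error_zero_by_construction(self, m120):
        """After reparameterization every CP sits exactly on the scout
        grid, versus up to about a degree if weights were propagated
        without interpolation."""
        arc = generate_linear_trajectory_arc(1, m120, n_cp=80)
        grid = scout_angles(arc.gantry_start, arc.gantry_stop,
                            arc.direction, arc.n_cp)
        out = reparameterize_arc(arc)
        np.testing.assert_allclose(out.gantry_angles(), grid, atol=1e-12)
        naive_err = np.abs(to_arc_position(arc.gantry_angles(),
                                           arc.gantry_start, arc.direction)
                           - to_arc_position(grid, arc.gantry_start,
                                             arc.direction))
        assert naive_err.max() > 0.3   # the error interpolation removes

    @pytest.mark.parametrize("seed", range(5))
    def test_linear_trajectories_roundtrip_exactly(self, m120, seed):
        """Trajectories linear in arc position survive source -> scout ->
        source interpolation to 1e-9 relative tolerance."""
        arc = generate_linear_trajectory_arc(seed, m120, n_cp=60)
        back = reparameterize_arc(reparameterize_arc(arc),
                                  target_angles=arc.gantry_angles())
        for c1, c2 in zip(arc.control_points, back.control_points):
            np.testing.assert_allclose(c2.bank_b, c1.bank_b, rtol=1e-9,
                                       atol=1e-9)
            np.testing.assert_allclose(c2.bank_a, c1.bank_a, rtol=1e-9,
                                       atol=1e-9)
            assert c2.cumulative_meterset_weight == pytest.approx(
                c1.cumulative_meterset_weight, abs=1e-9)

    def test_endpoints_and_metadata_preserved(self, m120):
        from vmatconv import ArcRecipe, generate_vmat_arc
        arc = generate_vmat_arc(ArcRecipe(seed=9, n_cp=50), m120)
        out = reparameterize_arc(arc)
        assert out.n_cp == arc.n_cp
        assert out.direction == arc.direction
        assert out.total_mu == arc.total_mu
        assert out.collimator_angle == arc.collimator_angle
        first, last = out.control_points[0], out.control_points[-1]
        np.testing.assert_array_equal(first.bank_b,
                                      arc.control_points[0].bank_b)
        np.testing.assert_array_equal(last.bank_a,
                                      arc.control_points[-1].bank_a)
        assert first.gantry_angle == arc.gantry_start
        assert last.gantry_angle == arc.gantry_stop

    @pytest.mark.parametrize("seed", range(5))
    def test_meterset_monotone_after_reparameterization(self, m120, seed):
        from vmatconv import ArcRecipe, generate_vmat_arc
        arc = generate_vmat_arc(ArcRecipe(seed=seed, n_cp=80), m120)
        out = reparameterize_arc(arc)
        mw = out.meterset_weights()
        assert mw[0] == 0.0 and mw[-1] == 1.0
        assert np.all(np.diff(mw) >= 0)
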
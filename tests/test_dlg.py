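import numpy as np
import pytest

from vmatconv import (DlgPolicy, MachineConstraints, apply_dlg_correction,
                      classify_dynamic_leaves)
from vmatconv.plan import Arc, ControlPoint

LOOSE = MachineConstraints(max_leaf_span_per_bank=150.0, max_overtravel=150.0,
                           min_dynamic_gap=0.5)


def _arc(bank_b_per_cp, bank_a_per_cp):
    """Tiny arc from per-CP (60,) bank arrays."""
    n = len(bank_b_per_cp)
    mw = np.linspace(0.0, 1.0, n)
    cps = [ControlPoint(index=k, gantry_angle=float(180 + 2 * k),
                        cumulative_meterset_weight=float(mw[k]),
                        jaw_x1=-100, jaw_x2=100, jaw_y1=-100, jaw_y2=100,
                        bank_b=np.asarray(b, float).copy(),
                        bank_a=np.asarray(a, float).copy())
           for k, (b, a) in enumerate(zip(bank_b_per_cp, bank_a_per_cp))]
    return Arc(beam_id="T", machine_id="T", mlc_model="M120",
               collimator_angle=0.0, gantry_start=180.0,
               gantry_stop=cps[-1].gantry_angle, direction="CW",
               isocenter=(0, 0, 0), total_mu=100.0, control_points=cps)


def _moving_pair_arc(gap, moving=True, n_cp=4, travel=2.0):
    """Pair 30 holds ``gap`` mm; if moving, the whole pair translates by
    ``travel`` mm per CP."""
    bs, as_ = [], []
    for k in range(n_cp):
        b = np.zeros(60)
        a = np.zeros(60)
        off = travel * k if moving else 0.0
        b[30] = -gap / 2 + off
        a[30] = gap / 2 + off
        bs.append(b)
        as_.append(a)
    return _arc(bs, as_)


class TestClassifyDynamicLeaves:
    def test_constant_leaf_static_everywhere(self):
        arc = _moving_pair_arc(2.0, moving=False)
        dyn = classify_dynamic_leaves(arc, 0.01)
        assert not dyn.any()

    def test_single_step_flags_both_adjacent_cps(self):
        bs = [np.zeros(60) for _ in range(6)]
        bs = [b.copy() for b in bs]
        for k in range(4, 6):
            bs[k][10] = 1.0     # moves between CP 3 and CP 4 only
        as_ = [np.full(60, 5.0) for _ in range(6)]
        dyn = classify_dynamic_leaves(_arc(bs, as_), 0.01)
        assert list(np.nonzero(dyn[:, 0, 10])[0]) == [3, 4]
        assert not dyn[:, 1, :].any()

    def test_epsilon_dominates_all_motion(self):
        arc = _moving_pair_arc(2.0, moving=True, travel=0.5)
        assert not classify_dynamic_leaves(arc, epsilon=1.0).any()


class TestDlgRule:
    """Exhaustive qualification grid: a leaf is corrected exactly when
    its pair gap exceeds 0.6 mm AND the leaf is dynamic AND no machine
    limit blocks the move."""

    POLICY = DlgPolicy(dlg_source=1.8, dlg_target=1.4)   # delta = 0.4 mm

    @pytest.mark.parametrize("gap", [0.5, 0.6, 0.61, 2.0])
    @pytest.mark.parametrize("moving", [True, False])
    @pytest.mark.parametrize("conflict", [True, False])
    def test_qualification_grid(self, gap, moving, conflict):
        arc = _moving_pair_arc(gap, moving=moving)
        constraints = LOOSE
        if conflict:
            # carriage span limit already saturated by the existing
            # positions, so any further retraction violates it
            constraints = MachineConstraints(
                max_leaf_span_per_bank=0.05,
                max_overtravel=150.0, min_dynamic_gap=0.5)
        out, log = apply_dlg_correction(arc, self.POLICY, constraints)
        should_correct = gap > 0.6 and moving and not conflict
        for cp, orig in zip(out.control_points, arc.control_points):
            expected = gap + (0.4 if should_correct else 0.0)
            assert cp.gaps[30] == pytest.approx(expected, abs=1e-12)
            # untouched pairs are bit-identical
            others = np.arange(60) != 30
            np.testing.assert_array_equal(cp.bank_b[others],
                                          orig.bank_b[others])
            np.testing.assert_array_equal(cp.bank_a[others],
                                          orig.bank_a[others])
            assert not np.any((cp.gaps > 1e-9)
                              & (cp.gaps < constraints.min_dynamic_gap - 1e-9))
        if moving and gap > 0.6 and conflict:
            assert any("carriage" in line for line in log)

    def test_delta_zero_is_identity(self):
        arc = _moving_pair_arc(2.0)
        out, log = apply_dlg_correction(
            arc, DlgPolicy(dlg_source=1.5, dlg_target=1.5), LOOSE)
        assert not log
        for cp, orig in zip(out.control_points, arc.control_points):
            np.testing.assert_array_equal(cp.bank_b, orig.bank_b)
            np.testing.assert_array_equal(cp.bank_a, orig.bank_a)

    def test_symmetric_split_preserves_aperture_center(self):
        arc = _moving_pair_arc(2.0)
        out, _ = apply_dlg_correction(arc, self.POLICY, LOOSE)
        for cp, orig in zip(out.control_points, arc.control_points):
            assert 0.5 * (cp.bank_a[30] + cp.bank_b[30]) == pytest.approx(
                0.5 * (orig.bank_a[30] + orig.bank_b[30]), abs=1e-12)
            assert cp.gaps[30] == pytest.approx(2.4)

    def test_one_sided_correction_when_partner_static(self):
        """One static leaf in a moving pair: only the dynamic side moves,
        by delta/2."""
        bs, as_ = [], []
        for k in range(4):
            b = np.zeros(60)
            a = np.zeros(60)
            b[20] = -1.0            # static
            a[20] = 1.0 + 2.0 * k   # dynamic
            bs.append(b)
            as_.append(a)
        arc = _arc(bs, as_)
        out, _ = apply_dlg_correction(arc, self.POLICY, LOOSE)
        for cp, orig in zip(out.control_points, arc.control_points):
            assert cp.bank_b[20] == orig.bank_b[20]
            assert cp.bank_a[20] == pytest.approx(orig.bank_a[20] + 0.2)

    def test_blocked_leaf_leaves_partner_corrected(self):
        """A span conflict on one bank blocks only that side; the partner
        still gets its independent delta/2."""
        bs, as_ = [], []
        for k in range(4):
            b = np.full(60, 55.0)     # static bank B tips define the span
            a = np.full(60, 60.0)
            b[30] = -70.0 - 2.0 * k   # the pair under test, both dynamic
            a[30] = -60.0 + 2.0 * k
            bs.append(b)
            as_.append(a)
        arc = _arc(bs, as_)
        # bank B span reaches 131 mm at the last CP; retracting B leaf 30
        # by 0.2 mm there would hit 131.2 mm
        constraints = MachineConstraints(max_leaf_span_per_bank=131.05,
                                         max_overtravel=150.0,
                                         min_dynamic_gap=0.5)
        out, log = apply_dlg_correction(arc, self.POLICY, constraints)
        last_out, last_orig = out.control_points[-1], arc.control_points[-1]
        assert last_out.bank_b[30] == last_orig.bank_b[30]
        assert last_out.bank_a[30] == pytest.approx(last_orig.bank_a[30]
                                                    + 0.2)
        # one CP earlier the span still fits, so B is corrected there
        assert out.control_points[2].bank_b[30] == pytest.approx(
            arc.control_points[2].bank_b[30] - 0.2)
        assert any("bank B leaf 30" in line and "carriage" in line
                   for line in log)

    def test_negative_delta_respects_min_dynamic_gap(self):
        """Shrinking corrections that would close a pair below the
        minimum dynamic gap are skipped and logged."""
        policy = DlgPolicy(dlg_source=1.0, dlg_target=1.8)   # delta = -0.8
        arc = _moving_pair_arc(1.0)   # 1.0 - 0.8 = 0.2 < 0.5 min gap
        out, log = apply_dlg_correction(arc, policy, LOOSE)
        for cp, orig in zip(out.control_points, arc.control_points):
            assert cp.gaps[30] == pytest.approx(orig.gaps[30])
        assert any("minimum dynamic gap" in line for line in log)

    def test_open_area_monotone_in_delta(self):
        arc = _moving_pair_arc(3.0)
        areas = []
        for d_src in (1.4, 1.6, 1.8, 2.2):
            out, _ = apply_dlg_correction(
                arc, DlgPolicy(dlg_source=d_src, dlg_target=1.4), LOOSE)
            areas.append(sum(cp.gaps.sum() for cp in out.control_points))
        assert np.all(np.diff(areas) >= 0)

    def test_deliverability_preserved_on_synthetic_arcs(self, hdmlc):
        from vmatconv import ArcRecipe, check_deliverability, \
            generate_vmat_arc
        for seed in range(5):
            arc = generate_vmat_arc(ArcRecipe(seed=seed, n_cp=30,
                                              jaw_window=100.0), hdmlc)
            assert check_deliverability(arc, hdmlc).status == "pass"
            out, _ = apply_dlg_correction(arc, self.POLICY,
                                          hdmlc.constraints)
            assert check_deliverability(out, hdmlc).status == "pass"
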
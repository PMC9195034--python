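"""Selective dosimetric-leaf-gap (DLG) correction.

Rounded leaf ends transmit through a region slightly wider than the
physical gap; treatment planning systems absorb this into a
commissioning-measured DLG that differs between MLC models (HDMLC's is
narrower than the Millennium-120's).  To make a remapped plan
dosimetrically equivalent, each qualifying leaf pair's physical gap is
widened by the DLG difference ``delta = dlg_source - dlg_target``, split
half per bank so the aperture centerline is preserved.

The correction is deliberately selective, mirroring delivery practice:

* only leaves undergoing dynamic motion are moved -- parked and static
  leaves are left bit-identical;
* only pairs whose gap strictly exceeds ``min_gap_to_correct`` (0.6 mm by
  default) are corrected, so deliberately narrow near-closed shielding
  apertures (~0.5 mm) are not widened into extra dose;
* a leaf is skipped when moving it would violate the carriage span or
  overtravel limit, and a pair is skipped when the corrected gap would
  fall below the minimum dynamic gap.  Every skip is logged.

Deliverability is therefore preserved: an arc that satisfies the machine
constraints going in still satisfies them coming out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import MachineConstraints
from .plan import Arc

__all__ = ["DlgPolicy", "classify_dynamic_leaves", "apply_dlg_correction"]


@dataclass(frozen=True)
class DlgPolicy:
    """DLG correction parameters.

    ``dlg_source`` / ``dlg_target`` are the commissioned DLG values (mm)
    of the plan's original MLC and of the deployment MLC; they have no
    defaults because DLG is machine-measured.  ``min_gap_to_correct`` is
    the gap (mm) a pair must strictly exceed to qualify;
    ``motion_epsilon`` (mm) is the position-change threshold that
    distinguishes a dynamic leaf from a static one.
    """

    dlg_source: float
    dlg_target: float
    min_gap_to_correct: float = 0.6
    motion_epsilon: float = 0.01
    respect_limits: bool = True

    def __post_init__(self) -> None:
        if self.dlg_source < 0 or self.dlg_target < 0:
            raise ValueError("DLG values must be >= 0")
        if self.min_gap_to_correct <= 0:
            raise ValueError("min_gap_to_correct must be > 0")

    @property
    def delta(self) -> float:
        return self.dlg_source - self.dlg_target


def classify_dynamic_leaves(arc: Arc, epsilon: float = 0.01) -> np.ndarray:
    """Boolean mask (n_cp, 2, 60) of leaves undergoing motion.

    A leaf is dynamic at control point k if its position differs by more
    than ``epsilon`` from its position at CP k-1 or CP k+1; the endpoints
    use their single neighbor.  Axis 1 is (bank B, bank A).
    """
    pos = np.stack([[cp.bank_b, cp.bank_a] for cp in arc.control_points])
    moved = np.abs(np.diff(pos, axis=0)) > epsilon   # (n_cp-1, 2, 60)
    dyn = np.zeros(pos.shape, dtype=bool)
    dyn[:-1] |= moved
    dyn[1:] |= moved
    return dyn


def apply_dlg_correction(arc: Arc, policy: DlgPolicy,
                         constraints: MachineConstraints
                         ) -> tuple[Arc, list[str]]:
    """Apply the selective DLG correction to ``arc`` (target-MLC indexing).

    Returns the corrected arc and a log of every skipped correction
    (control point, bank, leaf, reason).  ``delta = 0`` returns an
    unchanged copy.
    """
    out = arc.copy()
    delta = policy.delta
    log: list[str] = []
    if delta == 0.0:
        return out, log
    half = delta / 2.0
    dyn = classify_dynamic_leaves(arc, policy.motion_epsilon)

    for k, cp in enumerate(out.control_points):
        gaps = cp.gaps
        pair_ok = gaps > policy.min_gap_to_correct
        b0, a0 = cp.bank_b, cp.bank_a
        b_lo, b_hi = float(b0.min()), float(b0.max())
        a_lo, a_hi = float(a0.min()), float(a0.max())
        new_b, new_a = b0.copy(), a0.copy()
        for i in np.nonzero(pair_ok)[0]:
            # bank B retracts toward -x, bank A toward +x; each leaf
            # qualifies independently on the dynamic test
            if dyn[k, 0, i]:
                cand = b0[i] - half
                reason = _limit_violation(cand, b_lo, b_hi, constraints,
                                          bank="B")
                if policy.respect_limits and reason:
                    log.append(f"CP {k} bank B leaf {i}: skipped ({reason})")
                else:
                    new_b[i] = cand
            if dyn[k, 1, i]:
                cand = a0[i] + half
                reason = _limit_violation(cand, a_lo, a_hi, constraints,
                                          bank="A")
                if policy.respect_limits and reason:
                    log.append(f"CP {k} bank A leaf {i}: skipped ({reason})")
                else:
                    new_a[i] = cand
            gap = new_a[i] - new_b[i]
            if gap < constraints.min_dynamic_gap - 1e-12:
                new_b[i], new_a[i] = b0[i], a0[i]
                log.append(
                    f"CP {k} pair {i}: skipped (corrected gap {gap:.3f} mm "
                    f"below minimum dynamic gap "
                    f"{constraints.min_dynamic_gap} mm)")
        cp.bank_b, cp.bank_a = new_b, new_a
    return out, log


def _limit_violation(candidate: float, lo: float, hi: float,
                     constraints: MachineConstraints, bank: str) -> str | None:
    """Reason the moved leaf would break a carriage limit, or ``None``.

    ``lo``/``hi`` are the bank's original tip extremes; a single moved
    leaf can only widen the span on its own side, so checking the
    candidate against the opposite original extreme bounds the joint span
    of any subset of corrections.
    """
    span = max(hi, candidate) - min(lo, candidate)
    if span > constraints.max_leaf_span_per_bank + 1e-12:
        return (f"bank span {span:.3f} mm would exceed carriage limit "
                f"{constraints.max_leaf_span_per_bank} mm")
    # overtravel: a tip may cross the midline toward the opposing bank by
    # at most max_overtravel
    if bank == "B" and candidate > constraints.max_overtravel + 1e-12:
        return (f"bank B tip {candidate:.3f} mm past midline exceeds "
                f"overtravel limit {constraints.max_overtravel} mm")
    if bank == "A" and candidate < -constraints.max_overtravel - 1e-12:
        return (f"bank A tip {candidate:.3f} mm past midline exceeds "
                f"overtravel limit {constraints.max_overtravel} mm")
    return None
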
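"""End-to-end plan conversion orchestrator.

The pipeline per arc is: uniform scout-grid reparameterization (in source
leaf indexing), deterministic leaf-index remap onto the target MLC, then
the selective DLG correction, followed by a deliverability check against
the target machine constraints.  Interpolation and remapping commute --
both act per-leaf and mapped leaves carry identical extensions -- but the
DLG step runs last so its 0.6 mm gap test sees the final gaps.

The composite map is fully deterministic: identical inputs and
configuration always produce identical outputs.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .dlg import DlgPolicy, apply_dlg_correction
from .geometry import MLCGeometry, builtin_geometry
from .interp import reparameterize_arc
from .plan import Arc, ControlPoint, Plan
from .remap import build_leaf_map, remap_aperture
from .validate import ValidationReport, check_convertibility, \
    check_deliverability

__all__ = ["convert_plan", "convert_arc", "apply_normalization",
           "ConvertibilityError"]


class ConvertibilityError(ValueError):
    """The plan cannot be converted; carries the screening report."""

    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__("plan failed convertibility screening: "
                         + "; ".join(str(f) for f in report.findings
                                     if f.severity == "fail"))


def convert_arc(arc: Arc, src_geom: MLCGeometry, tgt_geom: MLCGeometry,
                policy: DlgPolicy | None,
                target_angles=None) -> tuple[Arc, list[str]]:
    """Convert one arc; returns the converted arc and the correction log."""
    log: list[str] = []
    new_arc = reparameterize_arc(arc, target_angles=target_angles)

    y_low = min(cp.jaw_y1 for cp in new_arc.control_points)
    y_high = max(cp.jaw_y2 for cp in new_arc.control_points)
    leaf_map = build_leaf_map(src_geom, tgt_geom, (y_low, y_high))

    remapped_cps: list[ControlPoint] = []
    for cp in new_arc.control_points:
        bank_b, bank_a = remap_aperture(cp, leaf_map, tgt_geom)
        remapped_cps.append(replace(cp, bank_b=bank_b, bank_a=bank_a))
    new_arc = replace(new_arc, control_points=remapped_cps,
                      mlc_model=tgt_geom.model_name)

    if policy is not None and policy.delta != 0.0:
        new_arc, dlg_log = apply_dlg_correction(new_arc, policy,
                                                tgt_geom.constraints)
        log.extend(f"beam {arc.beam_id}: {line}" for line in dlg_log)
    return new_arc, log


def convert_plan(plan: Plan, policy: DlgPolicy | None = None,
                 target_model: str = "HDMLC",
                 src_geom: MLCGeometry | None = None,
                 tgt_geom: MLCGeometry | None = None,
                 target_angles_by_beam: dict[str, np.ndarray] | None = None,
                 ) -> tuple[Plan, ValidationReport, list[str]]:
    """Convert every arc of ``plan`` onto the target MLC geometry.

    ``policy = None`` disables the DLG correction explicitly (it is a
    commissioned, machine-specific input and is never guessed).
    ``target_angles_by_beam`` optionally injects measured scripted-arc
    angle grids keyed by beam id in place of the exactly-uniform default.

    Returns the converted plan, the aggregated validation report
    (screening + per-arc deliverability), and the correction log.
    Raises :class:`ConvertibilityError` before any modification if the
    screening fails; a deliverability failure after conversion is
    reported, not raised, so the caller decides.
    """
    if tgt_geom is None:
        tgt_geom = builtin_geometry(target_model)
    screen = check_convertibility(plan, tgt_geom)
    if screen.status == "fail":
        raise ConvertibilityError(screen)

    report = screen
    log: list[str] = []
    new_arcs = []
    for arc in plan.arcs:
        sg = src_geom if src_geom is not None else builtin_geometry(
            arc.mlc_model)
        angles = None
        if target_angles_by_beam:
            angles = target_angles_by_beam.get(arc.beam_id)
        new_arc, arc_log = convert_arc(arc, sg, tgt_geom, policy,
                                       target_angles=angles)
        log.extend(arc_log)
        report = report.merge(check_deliverability(new_arc, tgt_geom))
        new_arcs.append(new_arc)

    return replace(plan, arcs=new_arcs), report, log


def apply_normalization(plan: Plan, delta: float) -> Plan:
    """Shift the global plan normalization by ``delta`` percentage points.

    Residual beam-model differences (leaf transmission, interleaf
    leakage, head scatter, ...) between machines are absorbed by a small
    normalization change, typically around 0.5%.  Nothing else in the
    plan is touched.
    """
    new_norm = plan.plan_normalization + delta
    if new_norm <= 0:
        raise ValueError(
            f"normalization shift {delta} would make plan normalization "
            f"non-positive ({new_norm})")
    out = plan.copy()
    out.plan_normalization = new_norm
    return out
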
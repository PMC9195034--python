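"""Convertibility screening and deliverability validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .geometry import MLCGeometry
from .plan import CLOSED_GAP_TOL, Arc, Plan

__all__ = ["Finding", "ValidationReport", "check_convertibility",
           "check_deliverability"]


class Finding(NamedTuple):
    severity: str        # "warn" | "fail"
    beam_id: str
    cp_index: int | None
    rule: str
    value: float
    limit: float

    def __str__(self) -> str:
        where = f"CP {self.cp_index}" if self.cp_index is not None else "plan"
        return (f"[{self.severity.upper()}] beam {self.beam_id} {where}: "
                f"{self.rule} = {self.value:.3f} vs limit {self.limit:.3f}")


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def status(self) -> str:
        if any(f.severity == "fail" for f in self.findings):
            return "fail"
        if any(f.severity == "warn" for f in self.findings):
            return "warn"
        return "pass"

    def merge(self, other: "ValidationReport") -> "ValidationReport":
        return ValidationReport(self.findings + other.findings)

    def to_dict(self) -> dict:
        return {"status": self.status,
                "findings": [f._asdict() for f in self.findings]}


def check_convertibility(plan: Plan, tgt: MLCGeometry) -> ValidationReport:
    """Screen a plan for convertibility onto the target MLC.

    Each Y jaw must stay within the target's hard |Y| limit (fail beyond
    110 mm for HDMLC); positions between the recommended and hard limits
    (105-110 mm) warn, because the MLC shielding margin against scatter
    off the primary collimator becomes insufficient.  Non-arc techniques
    the converter does not support fail outright.
    """
    hard = tgt.constraints.y_jaw_hard_limit
    rec = tgt.constraints.y_jaw_recommended_limit
    findings: list[Finding] = []
    for arc in plan.arcs:
        if arc.technique != "VMAT":
            findings.append(Finding("fail", arc.beam_id, None,
                                    "unsupported_technique", 0.0, 0.0))
            continue
        for cp in arc.control_points:
            for name, val in (("Y1", cp.jaw_y1), ("Y2", cp.jaw_y2)):
                v = abs(val)
                if v > hard:
                    findings.append(Finding("fail", arc.beam_id, cp.index,
                                            f"{name}_jaw_hard_limit", v, hard))
                elif v > rec:
                    findings.append(Finding("warn", arc.beam_id, cp.index,
                                            f"{name}_jaw_recommended_limit",
                                            v, rec))
    return ValidationReport(findings)


def check_deliverability(arc: Arc, geom: MLCGeometry) -> ValidationReport:
    """Check an arc against the machine constraint set of ``geom``.

    Per control point: bank tip span within the carriage group limit,
    overtravel past the midline within limit, every non-closed pair at or
    above the minimum dynamic gap, no negative gaps; across the arc: the
    cumulative meterset weight is non-decreasing.
    """
    c = geom.constraints
    findings: list[Finding] = []
    for cp in arc.control_points:
        for bank_name, bank in (("B", cp.bank_b), ("A", cp.bank_a)):
            span = float(bank.max() - bank.min())
            if span > c.max_leaf_span_per_bank + 1e-9:
                findings.append(Finding("fail", arc.beam_id, cp.index,
                                        f"bank_{bank_name}_span", span,
                                        c.max_leaf_span_per_bank))
        over_b = float(cp.bank_b.max())
        if over_b > c.max_overtravel + 1e-9:
            findings.append(Finding("fail", arc.beam_id, cp.index,
                                    "bank_B_overtravel", over_b,
                                    c.max_overtravel))
        over_a = float(cp.bank_a.min())
        if over_a < -c.max_overtravel - 1e-9:
            findings.append(Finding("fail", arc.beam_id, cp.index,
                                    "bank_A_overtravel", -over_a,
                                    c.max_overtravel))
        gaps = cp.gaps
        neg = np.nonzero(gaps < -CLOSED_GAP_TOL)[0]
        for i in neg:
            findings.append(Finding("fail", arc.beam_id, cp.index,
                                    f"pair_{i}_negative_gap",
                                    float(gaps[i]), 0.0))
        narrow = np.nonzero((gaps > CLOSED_GAP_TOL)
                            & (gaps < c.min_dynamic_gap - 1e-9))[0]
        for i in narrow:
            findings.append(Finding("fail", arc.beam_id, cp.index,
                                    f"pair_{i}_min_dynamic_gap",
                                    float(gaps[i]), c.min_dynamic_gap))
    mw = arc.meterset_weights()
    bad = np.nonzero(np.diff(mw) < -1e-12)[0]
    for k in bad:
        findings.append(Finding("fail", arc.beam_id, int(k) + 1,
                                "meterset_monotonicity",
                                float(mw[k + 1] - mw[k]), 0.0))
    return ValidationReport(findings)
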
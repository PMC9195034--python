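"""In-memory representation of VMAT plans.

A VMAT arc is an ordered sequence of control points: snapshots of machine
state (gantry angle, cumulative meterset weight, jaw positions, 2 x 60 leaf
positions) through the delivery progression.  Gantry angles follow IEC
61217 (degrees in [0, 360)); because clinically common arcs such as
181 deg -> 179 deg CW cross the 0/360 seam, all interpolation arithmetic is
done in *arc-position* space: cumulative degrees traveled from the start
angle along the stated rotation direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ControlPoint",
    "Arc",
    "Plan",
    "arc_length",
    "to_arc_position",
    "from_arc_position",
    "PlanInvariantError",
]

#: leaf pairs per bank for the supported Varian MLCs
N_LEAVES = 60

#: leaf pairs with |gap| below this are treated as physically closed (mm)
CLOSED_GAP_TOL = 1e-6


class PlanInvariantError(ValueError):
    """A plan, arc, or control point violates a structural invariant."""


def arc_length(start: float, stop: float, direction: str) -> float:
    """Degrees traveled from ``start`` to ``stop`` along ``direction``.

    ``direction`` is ``"CW"`` (increasing IEC angle) or ``"CCW"``.
    A zero-length result means start == stop, which is not a valid arc.
    """
    _check_direction(direction)
    if direction == "CW":
        return float((stop - start) % 360.0)
    return float((start - stop) % 360.0)


def to_arc_position(angle, start: float, direction: str):
    """Map IEC gantry angle(s) to cumulative degrees traveled from ``start``."""
    _check_direction(direction)
    angle = np.asarray(angle, dtype=float)
    pos = (angle - start) % 360.0 if direction == "CW" else (start - angle) % 360.0
    return pos if pos.ndim else float(pos)


def from_arc_position(pos, start: float, direction: str):
    """Inverse of :func:`to_arc_position`: IEC angle in [0, 360)."""
    _check_direction(direction)
    pos = np.asarray(pos, dtype=float)
    ang = (start + pos) % 360.0 if direction == "CW" else (start - pos) % 360.0
    return ang if ang.ndim else float(ang)


def _check_direction(direction: str) -> None:
    if direction not in ("CW", "CCW"):
        raise ValueError(f"direction must be 'CW' or 'CCW', got {direction!r}")


@dataclass
class ControlPoint:
    """One delivery snapshot.

    ``bank_b`` / ``bank_a`` hold 60 leaf-tip x-positions each (mm, ascending
    leaf-pair y); the aperture of pair *i* is ``[bank_b[i], bank_a[i]]`` and
    the pair gap ``bank_a[i] - bank_b[i]`` is never negative.
    """

    index: int
    gantry_angle: float
    cumulative_meterset_weight: float
    jaw_x1: float
    jaw_x2: float
    jaw_y1: float
    jaw_y2: float
    bank_b: np.ndarray
    bank_a: np.ndarray

    def __post_init__(self) -> None:
        self.bank_b = np.asarray(self.bank_b, dtype=float)
        self.bank_a = np.asarray(self.bank_a, dtype=float)
        if self.bank_b.shape != (N_LEAVES,) or self.bank_a.shape != (N_LEAVES,):
            raise PlanInvariantError(
                f"CP {self.index}: each bank must hold {N_LEAVES} leaf positions")

    @property
    def gaps(self) -> np.ndarray:
        return self.bank_a - self.bank_b

    def copy(self) -> "ControlPoint":
        return replace(self, bank_b=self.bank_b.copy(), bank_a=self.bank_a.copy())

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if none)."""
        problems = []
        if not 0.0 <= self.gantry_angle < 360.0:
            problems.append(
                f"CP {self.index}: gantry angle {self.gantry_angle} outside [0, 360)")
        if np.any(self.gaps < -CLOSED_GAP_TOL):
            worst = int(np.argmin(self.gaps))
            problems.append(
                f"CP {self.index}: leaf pair {worst} has negative gap "
                f"{self.gaps[worst]:.4f} mm (banks overlap)")
        return problems


@dataclass
class Arc:
    """One VMAT arc: control points plus beam metadata."""

    beam_id: str
    machine_id: str
    mlc_model: str
    collimator_angle: float
    gantry_start: float
    gantry_stop: float
    direction: str          # "CW" | "CCW"
    isocenter: tuple[float, float, float]
    total_mu: float
    control_points: list[ControlPoint]
    technique: str = "VMAT"

    @property
    def n_cp(self) -> int:
        return len(self.control_points)

    def gantry_angles(self) -> np.ndarray:
        return np.array([cp.gantry_angle for cp in self.control_points])

    def meterset_weights(self) -> np.ndarray:
        return np.array([cp.cumulative_meterset_weight
                         for cp in self.control_points])

    def arc_positions(self) -> np.ndarray:
        return to_arc_position(self.gantry_angles(), self.gantry_start,
                               self.direction)

    def copy(self) -> "Arc":
        return replace(self, control_points=[cp.copy()
                                             for cp in self.control_points])

    def validate(self, angle_tol: float = 1e-6) -> list[str]:
        problems: list[str] = []
        if self.n_cp < 2:
            problems.append(f"beam {self.beam_id}: fewer than 2 control points")
            return problems
        cps = self.control_points
        if abs(cps[0].gantry_angle - self.gantry_start) % 360.0 > angle_tol:
            problems.append(
                f"beam {self.beam_id}: first CP angle {cps[0].gantry_angle} "
                f"!= gantry_start {self.gantry_start}")
        if abs(cps[-1].gantry_angle - self.gantry_stop) % 360.0 > angle_tol:
            problems.append(
                f"beam {self.beam_id}: last CP angle {cps[-1].gantry_angle} "
                f"!= gantry_stop {self.gantry_stop}")
        mw = self.meterset_weights()
        if abs(mw[0]) > 1e-9 or abs(mw[-1] - 1.0) > 1e-9:
            problems.append(
                f"beam {self.beam_id}: cumulative meterset must run 0 -> 1 "
                f"(got {mw[0]:.6g} -> {mw[-1]:.6g})")
        bad = np.nonzero(np.diff(mw) < -1e-12)[0]
        if bad.size:
            problems.append(
                f"beam {self.beam_id}: cumulative meterset decreases at "
                f"CP {int(bad[0]) + 1}")
        if self.technique == "VMAT":
            pos = self.arc_positions()
            if np.any(np.diff(pos) < -1e-9):
                problems.append(
                    f"beam {self.beam_id}: gantry progression inconsistent "
                    f"with direction {self.direction}")
        for cp in cps:
            problems.extend(cp.validate())
        return problems


@dataclass
class Plan:
    """A treatment plan: one or more arcs plus prescription metadata."""

    plan_id: str
    prescription_dose: float    # Gy
    fractions: int
    plan_normalization: float   # percent
    arcs: list[Arc] = field(default_factory=list)

    def copy(self) -> "Plan":
        return replace(self, arcs=[a.copy() for a in self.arcs])

    def validate(self) -> list[str]:
        problems = []
        if self.plan_normalization <= 0:
            problems.append("plan_normalization must be > 0")
        if not self.arcs:
            problems.append("plan has no arcs")
        for arc in self.arcs:
            problems.extend(arc.validate())
        return problems

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise PlanInvariantError("; ".join(problems))
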
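"""Control-point interpolation onto a uniform scripted angle grid.

Script-generated arcs carry control points at read-only, (near-)uniformly
spaced gantry angles, while optimizer output arcs show acceleration and
deceleration phases with nonuniform spacing; intermediate angles can
disagree by a degree or so even when endpoints and control-point counts
match.  Propagating apertures and meterset weights verbatim onto the
shifted angles would mis-aim them, so this module computes, for each
scripted ("scout") angle, the aperture, jaws, and cumulative meterset that
the source arc would have had there, by linear interpolation between the
two bracketing source control points in arc-position space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .plan import (Arc, ControlPoint, arc_length, from_arc_position,
                   to_arc_position)

__all__ = [
    "InterpolationFactor",
    "scout_angles",
    "compute_factors",
    "interpolate_cp",
    "reparameterize_arc",
]

#: arc positions closer than this (degrees) are treated as coincident
ANGLE_TIE_TOL = 1e-9


@dataclass(frozen=True)
class InterpolationFactor:
    """Bracketing source control points for one target angle.

    ``fraction`` weights the *next* source CP: 0 reproduces ``prev_index``
    exactly, 1 reproduces ``next_index``.
    """

    target_cp_index: int
    prev_source_index: int
    next_source_index: int
    fraction: float


def scout_angles(start: float, stop: float, direction: str,
                 n_cp: int) -> np.ndarray:
    """Uniform gantry-angle grid a scripted arc would use, IEC degrees.

    ``n_cp`` angles from ``start`` to ``stop`` inclusive, equally spaced in
    arc-position space (spacing = arc_length / (n_cp - 1)), crossing the
    0/360 seam without discontinuity.
    """
    if n_cp < 2:
        raise ValueError("a scout grid needs at least 2 control points")
    length = arc_length(start, stop, direction)
    if length <= 0:
        raise ValueError(
            f"zero-length arc (start = stop = {start} deg); cannot build a "
            "scout grid")
    pos = np.linspace(0.0, length, n_cp)
    ang = from_arc_position(pos, start, direction)
    # keep the endpoints exact despite the modulo round trip
    ang[0], ang[-1] = start % 360.0, stop % 360.0
    return ang


def compute_factors(source_angles, target_angles,
                    direction: str) -> list[InterpolationFactor]:
    """Bracketing neighbors and linear weights for each target angle.

    Both angle lists must be monotone in arc-position space and share
    endpoints.  A target that coincides with a source angle gets
    ``fraction = 0`` against that source CP (exact reproduction).
    """
    source_angles = np.asarray(source_angles, dtype=float)
    target_angles = np.asarray(target_angles, dtype=float)
    start = float(source_angles[0])
    spos = to_arc_position(source_angles, start, direction)
    tpos = to_arc_position(target_angles, start, direction)
    if np.any(np.diff(spos) <= 0):
        raise ValueError("source angles not strictly monotone in "
                         "arc-position space")
    if np.any(np.diff(tpos) < 0):
        raise ValueError("target angles not monotone in arc-position space")
    if abs(tpos[0] - spos[0]) > 1e-6 or abs(tpos[-1] - spos[-1]) > 1e-6:
        raise ValueError("target grid endpoints must match source endpoints")
    # guard numeric drift at the far endpoint
    tpos = np.clip(tpos, spos[0], spos[-1])

    n_src = spos.size
    factors = []
    for t, tp in enumerate(tpos):
        j = int(np.searchsorted(spos, tp, side="right") - 1)
        j = min(max(j, 0), n_src - 2)
        if abs(tp - spos[j]) <= ANGLE_TIE_TOL:
            f = 0.0
        elif abs(tp - spos[j + 1]) <= ANGLE_TIE_TOL:
            f = 1.0
        else:
            f = (tp - spos[j]) / (spos[j + 1] - spos[j])
        factors.append(InterpolationFactor(
            target_cp_index=t, prev_source_index=j,
            next_source_index=j + 1, fraction=float(f)))
    return factors


def interpolate_cp(prev: ControlPoint, next_: ControlPoint, f: float,
                   target_angle: float) -> ControlPoint:
    """Linear blend ``(1 - f) * prev + f * next_`` of every delivery
    parameter, aimed at ``target_angle``.

    Since pair gaps are nonnegative at both neighbors, the blended gap is
    nonnegative too.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"interpolation fraction {f} outside [0, 1]")
    w0, w1 = 1.0 - f, f

    def blend(a, b):
        return w0 * a + w1 * b

    return ControlPoint(
        index=prev.index,
        gantry_angle=float(target_angle) % 360.0,
        cumulative_meterset_weight=blend(prev.cumulative_meterset_weight,
                                         next_.cumulative_meterset_weight),
        jaw_x1=blend(prev.jaw_x1, next_.jaw_x1),
        jaw_x2=blend(prev.jaw_x2, next_.jaw_x2),
        jaw_y1=blend(prev.jaw_y1, next_.jaw_y1),
        jaw_y2=blend(prev.jaw_y2, next_.jaw_y2),
        bank_b=blend(prev.bank_b, next_.bank_b),
        bank_a=blend(prev.bank_a, next_.bank_a),
    )


def reparameterize_arc(arc: Arc,
                       target_angles=None) -> Arc:
    """Re-express ``arc`` on its uniform scout grid.

    The returned arc keeps the control-point count, endpoints, direction,
    collimator angle, isocenter, and total MU; every interior control
    point is replaced by the interpolated state at its scout angle.  The
    first and last control points are copied bitwise (their angles already
    coincide by construction).  ``target_angles`` injects an explicit
    measured grid in place of the exactly-uniform default.
    """
    if target_angles is None:
        target_angles = scout_angles(arc.gantry_start, arc.gantry_stop,
                                     arc.direction, arc.n_cp)
    target_angles = np.asarray(target_angles, dtype=float)
    if target_angles.size != arc.n_cp:
        raise ValueError(
            f"target grid has {target_angles.size} angles for an arc with "
            f"{arc.n_cp} control points")
    factors = compute_factors(arc.gantry_angles(), target_angles,
                              arc.direction)
    cps = arc.control_points
    new_cps = [cps[0].copy()]
    for fac in factors[1:-1]:
        cp = interpolate_cp(cps[fac.prev_source_index],
                            cps[fac.next_source_index],
                            fac.fraction,
                            target_angles[fac.target_cp_index])
        cp.index = fac.target_cp_index
        new_cps.append(cp)
    last = cps[-1].copy()
    last.index = arc.n_cp - 1
    new_cps.append(last)
    return replace(arc, control_points=new_cps)
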
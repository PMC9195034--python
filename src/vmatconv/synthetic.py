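"""Seeded generators for realistic VMAT arcs and analytic dose phantoms.

Optimizer-produced VMAT arcs are not uniformly sampled in gantry angle:
the gantry accelerates over the first stretch of the arc (increasing
angular spacing between control points), cruises, and decelerates near
the end.  :func:`generate_vmat_arc` reproduces that spacing signature --
the deviation between the generated grid and the uniform scripted grid is
nonzero, sign-changing along the arc, and of order a degree for a default
178-point full arc -- together with bounded leaf motion, monotone
cumulative meterset, and machine-limit-respecting apertures, so every
other module can be exercised without patient data.

Dose phantoms are analytic fields (plateau sphere, linear ramp, shifted
pair) whose conformity/heterogeneity/gamma outcomes are known in closed
form.

All randomness flows from a single ``numpy`` generator seeded per recipe,
so identical recipes always produce identical output, and a recipe is a
small serializable record that reproduces any failing case.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .geometry import MLCGeometry
from .metrics import DoseGrid
from .plan import Arc, ControlPoint, Plan, from_arc_position, arc_length

__all__ = ["ArcRecipe", "generate_vmat_arc", "generate_linear_trajectory_arc",
           "generate_plan", "generate_dose_phantom", "generate_grid_pair"]

#: relative gantry speed at the very start/end of the accel/decel ramps.
#: With the default 10% ramp fractions this puts the worst-case deviation
#: from the uniform scripted grid near 0.9 deg on a 178-point 358 deg arc,
#: matching what is observed on clinical optimizer output.
_RAMP_START_SPEED = 0.94


@dataclass(frozen=True)
class ArcRecipe:
    """Serializable description of one synthetic arc."""

    seed: int
    n_cp: int = 178
    gantry_start: float = 181.0
    gantry_stop: float = 179.0
    direction: str = "CW"
    accel_fraction: float = 0.10
    decel_fraction: float = 0.10
    max_leaf_speed_per_cp: float = 5.0   # mm of tip travel per CP
    aperture_style: str = "random-modulated"
    jaw_window: float = 100.0            # |Y| jaw half-opening, mm
    closed_pair_prob: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.accel_fraction <= 0.3
                and 0.0 <= self.decel_fraction <= 0.3):
            raise ValueError("accel/decel fractions must lie in [0, 0.3]")
        if self.aperture_style not in ("conformal-ellipse", "sliding-window",
                                       "random-modulated"):
            raise ValueError(
                f"unknown aperture style {self.aperture_style!r}")
        if self.n_cp < 2:
            raise ValueError("n_cp must be >= 2")
        if self.max_leaf_speed_per_cp <= 0:
            raise ValueError("max_leaf_speed_per_cp must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _source_positions(recipe: ArcRecipe, length: float) -> np.ndarray:
    """Arc positions with accel/decel spacing ramps, endpoints 0 and length."""
    n_int = recipe.n_cp - 1
    w = np.ones(n_int)
    m_a = int(round(recipe.accel_fraction * n_int))
    m_d = int(round(recipe.decel_fraction * n_int))
    w0 = _RAMP_START_SPEED
    if m_a:
        w[:m_a] = w0 + (1.0 - w0) * (np.arange(m_a) + 0.5) / m_a
    if m_d:
        w[n_int - m_d:] = (w0 + (1.0 - w0)
                           * (np.arange(m_d)[::-1] + 0.5) / m_d)
    pos = np.concatenate([[0.0], np.cumsum(w)])
    return pos * (length / pos[-1])


def _meterset(rng: np.random.Generator, n_cp: int) -> np.ndarray:
    inc = rng.uniform(0.5, 1.5, n_cp - 1)
    mw = np.concatenate([[0.0], np.cumsum(inc)])
    return mw / mw[-1]


def _smooth_walk(rng: np.random.Generator, n: int, x0: float,
                 step: float, lo: float, hi: float) -> np.ndarray:
    """Bounded random walk with per-step increments clipped to +/-step."""
    inc = np.clip(rng.normal(0.0, 0.6 * step, n - 1), -step, step)
    x = x0 + np.concatenate([[0.0], np.cumsum(inc)])
    # reflect into [lo, hi]; increments stay bounded by step
    return np.clip(x, lo, hi)


def generate_vmat_arc(recipe: ArcRecipe, geom: MLCGeometry) -> Arc:
    """Generate a deliverable synthetic VMAT arc for ``geom``.

    The arc satisfies every machine constraint of ``geom`` out of the box
    and, for jaw windows within the HDMLC recommended limit, passes the
    convertibility screen.
    """
    rng = np.random.default_rng(recipe.seed)
    length = arc_length(recipe.gantry_start, recipe.gantry_stop,
                        recipe.direction)
    if length <= 0:
        raise ValueError("recipe describes a zero-length arc")
    pos = _source_positions(recipe, length)
    angles = from_arc_position(pos, recipe.gantry_start, recipe.direction)
    angles[0] = recipe.gantry_start % 360.0
    angles[-1] = recipe.gantry_stop % 360.0
    mw = _meterset(rng, recipe.n_cp)

    n_cp = recipe.n_cp
    centers = geom.leaf_centers
    in_window = np.abs(centers) < recipe.jaw_window
    min_gap = geom.constraints.min_dynamic_gap
    speed = recipe.max_leaf_speed_per_cp

    bank_b = np.zeros((n_cp, geom.n_leaf_pairs))
    bank_a = np.zeros((n_cp, geom.n_leaf_pairs))
    open_pairs = in_window & (rng.random(geom.n_leaf_pairs)
                              >= recipe.closed_pair_prob)

    style = recipe.aperture_style
    if style == "random-modulated":
        for i in np.nonzero(open_pairs)[0]:
            c = _smooth_walk(rng, n_cp, rng.uniform(-12, 12),
                             speed / 2, -15.0, 15.0)
            w = _smooth_walk(rng, n_cp, rng.uniform(5, 35),
                             speed, max(min_gap, 1.0), 55.0)
            bank_b[:, i] = c - w / 2
            bank_a[:, i] = c + w / 2
    elif style == "sliding-window":
        width = rng.uniform(10.0, 30.0)
        travel = 50.0 - width
        if travel / (n_cp - 1) > speed:
            raise ValueError(
                "infeasible recipe: sliding-window sweep needs "
                f"{travel / (n_cp - 1):.2f} mm/CP, above the "
                f"{speed} mm/CP leaf speed bound")
        sweep = np.linspace(-25.0, 25.0 - width, n_cp)
        for i in np.nonzero(open_pairs)[0]:
            bank_b[:, i] = sweep
            bank_a[:, i] = sweep + width
    else:  # conformal-ellipse
        cx = _smooth_walk(rng, n_cp, rng.uniform(-5, 5),
                          speed / 2, -10.0, 10.0)
        rx = _smooth_walk(rng, n_cp, rng.uniform(20, 40),
                          speed / 2, 15.0, 45.0)
        ry = 0.85 * recipe.jaw_window
        for i in np.nonzero(open_pairs)[0]:
            u = centers[i] / ry
            if abs(u) >= 1.0:
                open_pairs[i] = False
                continue
            half = rx * np.sqrt(1.0 - u * u)
            narrow = 2 * half < min_gap
            bank_b[:, i] = np.where(narrow, cx, cx - half)
            bank_a[:, i] = np.where(narrow, cx, cx + half)

    # parked pairs (closed or shielded by the Y jaws) sit static at x = 0
    jaw_x1 = float(bank_b.min() - 5.0) if open_pairs.any() else -10.0
    jaw_x2 = float(bank_a.max() + 5.0) if open_pairs.any() else 10.0

    cps = [ControlPoint(
        index=k, gantry_angle=float(angles[k]),
        cumulative_meterset_weight=float(mw[k]),
        jaw_x1=jaw_x1, jaw_x2=jaw_x2,
        jaw_y1=-recipe.jaw_window, jaw_y2=recipe.jaw_window,
        bank_b=bank_b[k].copy(), bank_a=bank_a[k].copy(),
    ) for k in range(n_cp)]

    return Arc(
        beam_id=f"SYN{recipe.seed}",
        machine_id="SYNTH01",
        mlc_model=geom.model_name,
        collimator_angle=30.0,
        gantry_start=recipe.gantry_start % 360.0,
        gantry_stop=recipe.gantry_stop % 360.0,
        direction=recipe.direction,
        isocenter=(0.0, 0.0, 0.0),
        total_mu=float(np.round(rng.uniform(400.0, 700.0), 1)),
        control_points=cps,
    )


def generate_linear_trajectory_arc(seed: int, geom: MLCGeometry,
                                   n_cp: int = 60,
                                   jaw_window: float = 100.0) -> Arc:
    """Arc whose leaf, jaw, and meterset trajectories are exactly linear
    in arc position, sampled on a nonuniform accel/decel grid.

    Linear trajectories are reproduced exactly by linear interpolation at
    any intermediate angle, making these arcs analytic fixtures for
    interpolation round-trip checks.
    """
    rng = np.random.default_rng(seed)
    recipe = ArcRecipe(seed=seed, n_cp=n_cp, jaw_window=jaw_window)
    length = arc_length(recipe.gantry_start, recipe.gantry_stop,
                        recipe.direction)
    pos = _source_positions(recipe, length)
    t = pos / length   # in [0, 1]
    angles = from_arc_position(pos, recipe.gantry_start, recipe.direction)
    angles[0] = recipe.gantry_start % 360.0
    angles[-1] = recipe.gantry_stop % 360.0

    centers = geom.leaf_centers
    in_window = np.abs(centers) < jaw_window
    n = geom.n_leaf_pairs
    c0 = rng.uniform(-10, 10, n)
    c1 = rng.uniform(-10, 10, n)
    w0 = rng.uniform(2, 40, n)
    w1 = rng.uniform(2, 40, n)
    cps = []
    for k in range(n_cp):
        c = c0 + (c1 - c0) * t[k]
        w = w0 + (w1 - w0) * t[k]
        b = np.where(in_window, c - w / 2, 0.0)
        a = np.where(in_window, c + w / 2, 0.0)
        cps.append(ControlPoint(
            index=k, gantry_angle=float(angles[k]),
            cumulative_meterset_weight=float(t[k]),
            jaw_x1=-60.0, jaw_x2=60.0,
            jaw_y1=-jaw_window, jaw_y2=jaw_window,
            bank_b=b, bank_a=a))
    return Arc(beam_id=f"LIN{seed}", machine_id="SYNTH01",
               mlc_model=geom.model_name, collimator_angle=0.0,
               gantry_start=recipe.gantry_start % 360.0,
               gantry_stop=recipe.gantry_stop % 360.0,
               direction=recipe.direction, isocenter=(0.0, 0.0, 0.0),
               total_mu=500.0, control_points=cps)


def generate_plan(seed: int, geom: MLCGeometry, n_arcs: int = 1,
                  **recipe_kwargs) -> Plan:
    """Bundle one or more seeded arcs into a plan with nominal metadata."""
    arcs = []
    for j in range(n_arcs):
        recipe = ArcRecipe(seed=seed + 1000 * j, **recipe_kwargs)
        arcs.append(generate_vmat_arc(recipe, geom))
    return Plan(plan_id=f"SYNPLAN{seed}", prescription_dose=60.0,
                fractions=30, plan_normalization=100.0, arcs=arcs)


# ---------------------------------------------------------------------------
# dose phantoms

def _grid(shape, spacing):
    half = [(s - 1) * sp / 2 for s, sp in zip(shape, spacing)]
    origin = tuple(-h for h in half)
    ax = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    return origin, np.meshgrid(*ax, indexing="ij")


def generate_dose_phantom(kind: str, params: dict | None = None,
                          seed: int = 0):
    """Analytic dose phantoms with known metric outcomes.

    ``kind``:

    * ``"sphere"`` -- dose plateau ``d0`` inside radius ``r_plateau`` with a
      Gaussian falloff outside; spherical PTV mask of radius ``r_ptv``.
      Returns ``(DoseGrid, mask)``.  With ``d0 >= d_pres`` the CI is
      exactly 100.
    * ``"ramp"`` -- dose linear in x from ``lo`` to ``hi`` inside a box PTV
      (uniform background elsewhere); returns ``(DoseGrid, mask)``.  The
      PTV percentiles, hence HI, follow in closed form.
    * ``"shifted-pair"`` -- a smooth multi-Gaussian field and the same
      analytic field displaced by ``shift`` mm along x; returns
      ``(DoseGrid, DoseGrid)``.  A gamma criterion with dta >= shift and
      any dose tolerance passes 100%.
    """
    p = dict(params or {})
    if kind == "sphere":
        shape, spacing = p.get("shape", (28, 28, 12)), p.get("spacing",
                                                             (2.0, 2.0, 2.0))
        d0 = p.get("d0", 60.0)
        r_plateau = p.get("r_plateau", 18.0)
        r_ptv = p.get("r_ptv", 14.0)
        origin, (xx, yy, zz) = _grid(shape, spacing)
        r = np.sqrt(xx ** 2 + yy ** 2 + zz ** 2)
        dose = d0 * np.exp(-np.maximum(r - r_plateau, 0.0) ** 2
                           / (2 * 8.0 ** 2))
        mask = r <= r_ptv
        return DoseGrid(dose, spacing, origin), mask
    if kind == "ramp":
        shape, spacing = p.get("shape", (20, 10, 10)), p.get("spacing",
                                                             (2.0, 2.0, 2.0))
        lo, hi = p.get("lo", 57.3), p.get("hi", 63.3)
        origin, (xx, yy, zz) = _grid(shape, spacing)
        x0, x1 = xx.min(), xx.max()
        dose = lo + (hi - lo) * (xx - x0) / (x1 - x0)
        mask = np.ones(shape, dtype=bool)
        return DoseGrid(dose, spacing, origin), mask
    if kind == "shifted-pair":
        # single compact Gaussian so every above-threshold point keeps its
        # displaced counterpart inside the grid
        shift = p.get("shift", 0.5)
        shape, spacing = p.get("shape", (36, 36, 12)), p.get(
            "spacing", (1.5, 1.5, 1.5))
        amp, sig = p.get("amp", 60.0), p.get("sigma", 7.0)

        def field(dx):
            origin, (xx, yy, zz) = _grid(shape, spacing)
            dose = amp * np.exp(-((xx - dx) ** 2 + yy ** 2 + zz ** 2)
                                / (2 * sig ** 2))
            return DoseGrid(dose, spacing, origin)

        return field(0.0), field(shift)
    raise ValueError(f"unknown phantom kind {kind!r}; "
                     "expected sphere, ramp, or shifted-pair")


def _blob_field(seed: int, shift: float, shape=(24, 24, 10),
                spacing=(2.0, 2.0, 2.0), n_blobs: int = 4) -> DoseGrid:
    rng = np.random.default_rng(seed)
    origin, (xx, yy, zz) = _grid(shape, spacing)
    dose = np.zeros(shape)
    for _ in range(n_blobs):
        cx, cy = rng.uniform(-12, 12, 2)
        cz = rng.uniform(-4, 4)
        amp = rng.uniform(20, 60)
        sig = rng.uniform(10, 16)
        dose += amp * np.exp(-(((xx - shift) - cx) ** 2 + (yy - cy) ** 2
                               + (zz - cz) ** 2) / (2 * sig ** 2))
    return DoseGrid(dose, spacing, origin)


def generate_grid_pair(seed: int, dose_noise: float = 0.005,
                       shift: float = 0.3) -> tuple[DoseGrid, DoseGrid]:
    """Seeded reference/evaluation grid pair with realistic small
    disagreements (sub-mm analytic shift plus a smooth multiplicative
    dose perturbation) for exercising gamma comparisons."""
    rng = np.random.default_rng(seed)
    ref = _blob_field(seed, shift=0.0)
    ev = _blob_field(seed, shift=rng.uniform(-shift, shift))
    _, (xx, yy, zz) = _grid(ev.values.shape, ev.spacing)
    wobble = 1.0 + dose_noise * np.sin(xx / 11.0) * np.cos(yy / 13.0)
    return ref, DoseGrid(ev.values * wobble, ev.spacing, ev.origin)
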
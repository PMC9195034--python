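"""QA metrics for auditing converted plans against originals.

Implements the global (Van Dyk) gamma index pass rate, the conformity
index CI = 100 * V(100% isodose within PTV) / V(PTV), and the
heterogeneity index HI = (D5% - D95%) / D_prescription, reported x100 on
the conventional percent-like scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["DoseGrid", "GammaCriteria", "gamma_pass_rate",
           "conformity_index", "heterogeneity_index"]


@dataclass(frozen=True)
class DoseGrid:
    """Regular 3D dose grid: values in Gy, spacing and origin in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 3:
            raise ValueError("dose grid must be 3-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be strictly positive")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("dose values must be finite and nonnegative")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[i] + self.spacing[i]
                     * np.arange(self.values.shape[i]) for i in range(3))

    def points(self, mask: np.ndarray | None = None) -> np.ndarray:
        ax = self.axes()
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([xx, yy, zz], axis=-1)
        if mask is not None:
            return pts[mask]
        return pts.reshape(-1, 3)


@dataclass(frozen=True)
class GammaCriteria:
    """Global gamma criteria: dose difference as % of the global
    normalization dose, distance-to-agreement in mm, and the low-dose
    threshold (% of normalization) below which reference points are
    excluded.  ``normalization = None`` uses the reference global max."""

    dose_percent: float = 1.0
    dta_mm: float = 1.0
    low_dose_threshold_percent: float = 10.0
    normalization: float | None = None

    def __post_init__(self) -> None:
        if self.dose_percent <= 0 or self.dta_mm <= 0 \
                or self.low_dose_threshold_percent <= 0:
            raise ValueError("gamma criteria must be strictly positive")


def _search_offsets(dta: float, spacing, radius_factor: float,
                    step_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Candidate displacement vectors within radius_factor * dta, sorted
    by distance, sampled at step_fraction * dta along each axis."""
    step = dta * step_fraction
    radius = dta * radius_factor
    n = int(np.floor(radius / step))
    ax = step * np.arange(-n, n + 1)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offsets = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(offsets, axis=1)
    keep = dist <= radius + 1e-12
    offsets, dist = offsets[keep], dist[keep]
    order = np.argsort(dist, kind="stable")
    return offsets[order], dist[order]


def gamma_pass_rate(ref: DoseGrid, eval_: DoseGrid, crit: GammaCriteria,
                    search_radius_factor: float = 3.0,
                    step_fraction: float = 0.1) -> float:
    """Percent of evaluated reference points with gamma <= 1.

    gamma(r) = min over eval positions e of
    sqrt((D_eval(e) - D_ref(r))^2 / (pct * Dnorm)^2 + |r - e|^2 / dta^2),
    with the eval grid interpolated trilinearly.  Reference points below
    the low-dose threshold are excluded.  The search walks candidate
    displacements outward by distance and stops as soon as no still-
    failing point can reach gamma <= 1 (once the distance term alone
    exceeds 1), which leaves the pass rate identical to the exhaustive
    search over the full radius.
    """
    dnorm = float(np.max(ref.values)) if crit.normalization is None \
        else float(crit.normalization)
    if dnorm <= 0:
        raise ValueError("normalization dose must be positive")
    dose_tol = crit.dose_percent / 100.0 * dnorm
    threshold = crit.low_dose_threshold_percent / 100.0 * dnorm

    mask = ref.values >= threshold
    n_eval = int(mask.sum())
    if n_eval == 0:
        raise ValueError("no reference points above the low-dose threshold")
    pts = ref.points(mask)
    ref_dose = ref.values[mask]

    interp = RegularGridInterpolator(eval_.axes(), eval_.values,
                                     bounds_error=False, fill_value=np.nan)

    offsets, dist = _search_offsets(crit.dta_mm, eval_.spacing,
                                    search_radius_factor, step_fraction)
    gamma2 = np.full(n_eval, np.inf)
    active = np.ones(n_eval, dtype=bool)
    for off, d in zip(offsets, dist):
        if not active.any():
            break
        dist2 = (d / crit.dta_mm) ** 2
        if dist2 > 1.0 + 1e-12:
            # still-active points already fail on distance alone
            break
        dd = interp(pts[active] + off)
        g2 = np.where(np.isnan(dd), np.inf,
                      ((dd - ref_dose[active]) / dose_tol) ** 2 + dist2)
        gamma2[active] = np.minimum(gamma2[active], g2)
        active[active] = gamma2[active] > 1.0
    return 100.0 * float(np.count_nonzero(gamma2 <= 1.0)) / n_eval


def _check_mask(dose: DoseGrid, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.values.shape:
        raise ValueError("mask shape does not match the dose grid")
    if not mask.any():
        raise ValueError("PTV mask is empty")
    return mask


def conformity_index(dose: DoseGrid, ptv_mask: np.ndarray,
                     d_pres: float) -> float:
    """CI = 100 x (PTV volume receiving >= d_pres) / (PTV volume)."""
    mask = _check_mask(dose, ptv_mask)
    covered = np.count_nonzero(dose.values[mask] >= d_pres)
    return 100.0 * covered / np.count_nonzero(mask)


def heterogeneity_index(dose: DoseGrid, ptv_mask: np.ndarray,
                        d_pres: float) -> float:
    """HI = (D5% - D95%) / d_pres, reported x100.

    D5 (dose exceeded by the hottest 5% of the PTV) and D95 are the 95th
    and 5th percentiles of the voxel doses inside the PTV, with linear
    interpolation between order statistics.
    """
    mask = _check_mask(dose, ptv_mask)
    d = dose.values[mask]
    d5 = float(np.percentile(d, 95.0))
    d95 = float(np.percentile(d, 5.0))
    return 100.0 * (d5 - d95) / d_pres
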
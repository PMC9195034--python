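"""Deterministic leaf-index remapping between MLC models.

Inside |y| <= 110 mm the Millennium-120 and HDMLC boundary grids align at
every shared leaf edge, so any M120 aperture clipped to the HDMLC extent
can be reproduced exactly: each 5-mm M120 leaf in |y| <= 40 mm maps onto
two 2.5-mm HDMLC leaves extended the same amount, each 5-mm leaf in
40 < |y| <= 100 mm maps one-to-one, and each 10-mm peripheral M120 leaf in
100 < |y| <= 110 mm maps onto two 5-mm HDMLC leaves.  The map is pure
geometry -- it depends only on the two boundary grids and the Y-jaw
window, never on the leaf extensions being remapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MLCGeometry
from .plan import CLOSED_GAP_TOL, ControlPoint

__all__ = ["LeafMap", "build_leaf_map", "remap_aperture", "LeafMapError"]


class LeafMapError(ValueError):
    """The requested remap is geometrically impossible."""


@dataclass(frozen=True)
class LeafMap:
    """Source-leaf correspondence for every target leaf.

    ``source_index[i]`` is the source leaf whose interval contains target
    leaf ``i``; ``overlap_fraction[i]`` is the fraction of target leaf i's
    width covered by that source leaf (1.0 everywhere the grids align).
    ``in_window[i]`` marks target leaves that intersect the Y-jaw field
    window; leaves outside it carry no aperture and are parked on remap.
    """

    source_index: np.ndarray     # (60,) int
    overlap_fraction: np.ndarray  # (60,) float
    in_window: np.ndarray        # (60,) bool
    field_window: tuple[float, float]
    src_model: str
    tgt_model: str


def build_leaf_map(src: MLCGeometry, tgt: MLCGeometry,
                   y_window: tuple[float, float]) -> LeafMap:
    """Build the deterministic source->target leaf correspondence.

    ``y_window`` is the (y_low, y_high) field window from the Y jaws, mm.
    Fails if the window exceeds the target extent or if any target leaf
    inside the window straddles a source leaf edge (grids misaligned).
    """
    y_low, y_high = y_window
    if y_low >= y_high:
        raise LeafMapError(f"empty field window {y_window}")
    if y_low < -tgt.max_half_field_y or y_high > tgt.max_half_field_y:
        raise LeafMapError(
            f"field window {y_window} mm exceeds the {tgt.model_name} "
            f"extent of +/-{tgt.max_half_field_y} mm; plan is not "
            "convertible")

    src_b = src.boundaries
    n = tgt.n_leaf_pairs
    source_index = np.full(n, -1, dtype=int)
    overlap = np.zeros(n)
    in_window = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = tgt.boundaries[i], tgt.boundaries[i + 1]
        in_window[i] = (hi > y_low) and (lo < y_high)
        mid = 0.5 * (lo + hi)
        if mid < src_b[0] or mid >= src_b[-1]:
            continue
        j = int(np.searchsorted(src_b, mid, side="right") - 1)
        if in_window[i] and not (src_b[j] <= lo + 1e-9
                                 and hi <= src_b[j + 1] + 1e-9):
            raise LeafMapError(
                f"target leaf {i} [{lo}, {hi}] mm straddles source leaf "
                f"edge at {src_b[j + 1] if hi > src_b[j + 1] else src_b[j]} "
                "mm; boundary grids misaligned inside the field window")
        source_index[i] = j
        overlap[i] = min(hi, src_b[j + 1]) - max(lo, src_b[j])
        overlap[i] /= (hi - lo)
    return LeafMap(source_index=source_index, overlap_fraction=overlap,
                   in_window=in_window, field_window=(float(y_low), float(y_high)),
                   src_model=src.model_name, tgt_model=tgt.model_name)


def remap_aperture(cp: ControlPoint, leaf_map: LeafMap,
                   tgt: MLCGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Remap one control point's banks onto the target leaf indexing.

    Every mapped in-window target leaf takes exactly its source leaf's
    extension, on both banks, so the open aperture inside the field window
    is reproduced verbatim.  Target leaves outside the window are parked
    closed, co-located with the nearest in-window closed pair (or at x = 0
    if the field has none), so they sit behind the Y jaws with zero
    aperture contribution.
    """
    n = tgt.n_leaf_pairs
    bank_b = np.zeros(n)
    bank_a = np.zeros(n)
    mapped = leaf_map.in_window & (leaf_map.source_index >= 0)
    src_idx = leaf_map.source_index[mapped]
    bank_b[mapped] = cp.bank_b[src_idx]
    bank_a[mapped] = cp.bank_a[src_idx]

    park_x = 0.0
    closed = mapped & (bank_a - bank_b <= CLOSED_GAP_TOL)
    if np.any(closed):
        closed_idx = np.nonzero(closed)[0]
        centers = tgt.leaf_centers
        for i in np.nonzero(~mapped)[0]:
            nearest = closed_idx[np.argmin(np.abs(centers[closed_idx]
                                                  - centers[i]))]
            bank_b[i] = bank_a[i] = bank_b[nearest]
    else:
        bank_b[~mapped] = park_x
        bank_a[~mapped] = park_x
    return bank_b, bank_a
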
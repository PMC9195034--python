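"""MLC leaf-boundary grids and machine constraint tables.

Two Varian MLC models are built in:

* ``M120`` (Millennium-120): 60 leaf pairs spanning y in [-200, +200] mm at
  isocenter -- ten 10-mm peripheral leaves per side and forty 5-mm central
  leaves.
* ``HDMLC`` (high-definition MLC): 60 leaf pairs spanning [-110, +110] mm --
  fourteen 5-mm peripheral leaves per side and thirty-two 2.5-mm central
  leaves.  Every leaf is half the width of the M120 leaf at the same y
  inside +/-100 mm, which is what makes a deterministic one-to-two leaf
  remapping possible.

Leaf intervals are half-open ``[lower, upper)`` so that shared boundaries
(including the midline y = 0) index unambiguously.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "MachineConstraints",
    "MLCGeometry",
    "builtin_geometry",
    "leaf_index_at",
    "load_constraints",
    "KNOWN_MODELS",
]

KNOWN_MODELS = ("M120", "HDMLC")


@dataclass(frozen=True)
class MachineConstraints:
    """Per-machine delivery limits, all in mm at isocenter.

    The vendor does not publish a single authoritative set of numbers; the
    defaults below are conventional values and every one of them can be
    overridden through a constraint config file (see :func:`load_constraints`).

    Parameters
    ----------
    max_leaf_span_per_bank
        Maximum spread between leaf tips within one bank (carriage group
        limit).
    max_overtravel
        How far a leaf tip may cross the beam central axis toward the
        opposing bank.
    min_dynamic_gap
        Smallest allowed opening of a moving, non-closed leaf pair.
    dlg
        Dosimetric leaf gap for this MLC/energy, if commissioned.  There is
        no default: DLG is a measured quantity and correction code refuses
        to guess it.
    y_jaw_hard_limit, y_jaw_recommended_limit
        Per-jaw |Y| limits.  For HDMLC these are 110 / 105 mm; exceeding the
        recommended limit leaves insufficient MLC shielding margin against
        scatter off the primary collimator.
    max_leaf_speed
        mm/s; only meaningful when delivery timing is available (unused by
        the converter itself).
    """

    max_leaf_span_per_bank: float = 150.0
    max_overtravel: float = 20.0
    min_dynamic_gap: float = 0.5
    dlg: float | None = None
    y_jaw_hard_limit: float = 200.0
    y_jaw_recommended_limit: float = 200.0
    max_leaf_speed: float | None = None

    def __post_init__(self) -> None:
        for name in ("max_leaf_span_per_bank", "max_overtravel",
                     "min_dynamic_gap", "y_jaw_hard_limit",
                     "y_jaw_recommended_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.y_jaw_recommended_limit > self.y_jaw_hard_limit:
            raise ValueError(
                "y_jaw_recommended_limit must not exceed y_jaw_hard_limit")
        if self.dlg is not None and self.dlg < 0:
            raise ValueError("dlg must be >= 0")


@dataclass(frozen=True)
class MLCGeometry:
    """Leaf-boundary grid and limits for one MLC model.

    ``boundaries`` holds the 61 leaf-edge y-coordinates shared by both
    banks, strictly increasing and symmetric about y = 0; leaf pair ``i``
    occupies ``[boundaries[i], boundaries[i+1])``.
    """

    model_name: str
    boundaries: np.ndarray
    constraints: MachineConstraints = field(default_factory=MachineConstraints)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", b)
        if b.ndim != 1 or b.size != 61:
            raise ValueError("boundaries must be a flat array of 61 edges")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        if not np.allclose(b, -b[::-1]):
            raise ValueError("boundaries must be symmetric about y = 0")

    @property
    def n_leaf_pairs(self) -> int:
        return self.boundaries.size - 1

    @property
    def max_half_field_y(self) -> float:
        return float(self.boundaries[-1])

    @property
    def leaf_widths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def leaf_centers(self) -> np.ndarray:
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])

    def with_constraints(self, constraints: MachineConstraints) -> "MLCGeometry":
        return replace(self, constraints=constraints)


def _m120_boundaries() -> np.ndarray:
    return np.concatenate([
        np.arange(-200.0, -100.0, 10.0),   # 10 peripheral 10-mm leaves
        np.arange(-100.0, 100.0, 5.0),     # 40 central 5-mm leaves
        np.arange(100.0, 201.0, 10.0),     # 10 peripheral + closing edge
    ])


def _hdmlc_boundaries() -> np.ndarray:
    return np.concatenate([
        np.arange(-110.0, -40.0, 5.0),     # 14 peripheral 5-mm leaves
        np.arange(-40.0, 40.0, 2.5),       # 32 central 2.5-mm leaves
        np.arange(40.0, 111.0, 5.0),       # 14 peripheral + closing edge
    ])


_DEFAULT_CONSTRAINTS = {
    "M120": MachineConstraints(
        max_leaf_span_per_bank=150.0,
        max_overtravel=20.0,
        min_dynamic_gap=0.5,
        y_jaw_hard_limit=200.0,
        y_jaw_recommended_limit=200.0,
    ),
    "HDMLC": MachineConstraints(
        max_leaf_span_per_bank=150.0,
        max_overtravel=80.0,
        min_dynamic_gap=0.5,
        y_jaw_hard_limit=110.0,
        y_jaw_recommended_limit=105.0,
    ),
}


def builtin_geometry(model_name: str,
                     constraints: MachineConstraints | None = None) -> MLCGeometry:
    """Return the built-in geometry for ``model_name`` (``M120`` or ``HDMLC``).

    ``constraints`` overrides the documented defaults, e.g. with values
    loaded from a machine config via :func:`load_constraints`.
    """
    if model_name not in KNOWN_MODELS:
        raise ValueError(
            f"unknown MLC model {model_name!r}; accepted models: "
            + ", ".join(KNOWN_MODELS))
    boundaries = (_m120_boundaries() if model_name == "M120"
                  else _hdmlc_boundaries())
    if constraints is None:
        constraints = _DEFAULT_CONSTRAINTS[model_name]
    return MLCGeometry(model_name=model_name, boundaries=boundaries,
                       constraints=constraints)


def leaf_index_at(geom: MLCGeometry, y: float) -> int:
    """Index of the leaf pair whose half-open interval contains ``y`` mm."""
    b = geom.boundaries
    if y < b[0] or y >= b[-1]:
        raise ValueError(
            f"y = {y} mm outside the physical extent "
            f"[{b[0]}, {b[-1]}) of {geom.model_name}")
    # searchsorted(side='right') respects the [lower, upper) convention
    return int(np.searchsorted(b, y, side="right") - 1)


_CONSTRAINT_KEYS = {
    "max_leaf_span_per_bank": float,
    "max_overtravel": float,
    "min_dynamic_gap": float,
    "dlg": float,
    "y_jaw_hard_limit": float,
    "y_jaw_recommended_limit": float,
    "max_leaf_speed": float,
}


def load_constraints(path: str | Path) -> dict[str, MachineConstraints]:
    """Parse a machine-constraint config file.

    INI format, one section per MLC model::

        [HDMLC]
        max_leaf_span_per_bank = 150
        max_overtravel = 80
        min_dynamic_gap = 0.5
        dlg = 1.2

    Keys omitted from a section keep the documented defaults for that
    model; unknown keys or unknown section names are rejected.
    """
    parser = configparser.ConfigParser()
    text = Path(path).read_text()
    parser.read_string(text, source=str(path))
    out: dict[str, MachineConstraints] = {}
    for section in parser.sections():
        if section not in KNOWN_MODELS:
            raise ValueError(
                f"unknown MLC model section [{section}] in {path}; "
                f"accepted: {', '.join(KNOWN_MODELS)}")
        base = _DEFAULT_CONSTRAINTS[section]
        overrides: dict[str, float] = {}
        for key, raw in parser.items(section):
            if key not in _CONSTRAINT_KEYS:
                raise ValueError(
                    f"unknown constraint key {key!r} in section [{section}] "
                    f"of {path}; accepted: {', '.join(sorted(_CONSTRAINT_KEYS))}")
            overrides[key] = _CONSTRAINT_KEYS[key](raw)
        out[section] = replace(base, **overrides)
    return out
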
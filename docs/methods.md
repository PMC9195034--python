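# Methods

## Problem and model

Two Varian MLC models share 60 leaf pairs per bank but different leaf
widths: the Millennium-120 spans y ∈ [−200, 200] mm with 5 mm central /
10 mm peripheral leaves, the HDMLC spans [−110, 110] mm with 2.5 mm /
5 mm leaves. Inside |y| ≤ 110 mm every M120 leaf edge is also an HDMLC
leaf edge, so an M120 aperture clipped to the HDMLC extent can be
reproduced *exactly* by giving each covering HDMLC leaf its source
leaf's extension. The converter composes three deterministic steps —
reparameterization onto the uniform scripted angle grid, leaf-index
remapping, selective DLG correction — followed by validation. No step
involves randomness or optimization: identical inputs give identical
outputs, which is what makes the converted plan reviewable as a
perturbation of the original.

### Arc-position space

All angular arithmetic uses cumulative degrees traveled from the arc's
start angle along its rotation direction. IEC gantry angles live on
[0°, 360°) and common clinical arcs (181° → 179° CW) cross the seam;
interpolating IEC angles directly would be wrong at the crossing.
Arc-position space is seam-free and monotone by construction.

### Interpolation

The scripted ("scout") grid is taken as exactly uniform: n control
points spaced arc_length/(n−1) apart, sharing the source arc's
endpoints and count. Real scripting environments may quantize this
grid; `reparameterize_arc` therefore accepts an explicit measured angle
list, which decouples the algorithm from any vendor's internals. All
quantities (cumulative meterset weight, four jaws, 120 leaf positions)
are blended linearly between the two bracketing source control points
— linear is the minimal interpolant consistent with a two-neighbor
construction, and it preserves meterset monotonicity and nonnegative
pair gaps automatically. A target angle that coincides with an interior
source angle reproduces that control point exactly (fraction 0 against
it, preferring the earlier neighbor; deterministic tie-break).
Endpoint control points are copied bitwise.

Linear interpolation is exact on trajectories linear in arc position;
on real (curved) trajectories it is the identity at the source knots
and first-order accurate between them. The interpolation round-trip
checks in the test suite use arcs with exactly linear trajectories, for
which the source → scout → source round trip must recover the input to
numerical precision (1e-9); this verifies the machinery, not the
modeling error on curved data, which depends on the plan.

### Remapping

`build_leaf_map` is pure geometry: each target leaf interval must lie
inside a single source leaf interval (verified edge by edge; a
violation raises rather than re-approximating, since sub-leaf
re-approximation is never needed between these two models). The map is
independent of leaf extensions. Target leaves outside the Y-jaw window
carry no aperture; they are parked closed, co-located with the nearest
in-window closed pair when one exists (so the converter is an exact
identity when source and target geometry coincide and all closed pairs
sit at one position) and at x = 0 otherwise. Because mapped leaves copy
their source extension verbatim, the rasterized open area inside the
jaw window is conserved exactly, and remapping commutes with the
per-leaf linear interpolation — the pipeline order (interpolate, then
remap) is therefore equivalent to the reverse, and the DLG step is kept
last so its gap threshold tests final gaps.

### DLG correction

Δ = DLG_source − DLG_target is split half per bank so the aperture
centerline of a symmetrically corrected pair is unchanged. The
qualification is per-pair on the gap (> `min_gap_to_correct`, default
0.6 mm, strict inequality) and per-leaf on motion: a leaf is dynamic at
control point k if its position changes by more than `motion_epsilon`
(default 0.01 mm, machine-precision scale) relative to either temporal
neighbor. A pair with one static leaf receives a one-sided Δ/2
correction on the dynamic side only — the narrowest reading of
"only leaves undergoing motion are extended"; whether one-sided pairs
should be corrected at all is genuinely open, and this choice is
configurable in effect via `motion_epsilon`.

Limit guarding is per-candidate-leaf: the moved tip is checked against
the bank's original tip extremes (a single retraction can only extend
the span on its own side, so individual checks bound the joint span of
any subset of moves) and against the overtravel limit. A blocked leaf
is skipped and logged; its partner is still corrected if it
independently qualifies. Negative Δ (target DLG wider) shrinks gaps; a
pair whose corrected gap would fall below the minimum dynamic gap is
reverted and logged. Together these guarantee that an arc satisfying
the machine constraints before correction still satisfies them after.

### Validation

Convertibility screening is jaw-based: each |Y| jaw beyond the hard
limit (110 mm for HDMLC) fails; between the recommended (105 mm) and
hard limits warns (insufficient MLC shielding margin against scatter
off the primary collimator); non-arc techniques fail. Deliverability
checks per control point: bank tip span ≤ carriage limit, midline
overtravel ≤ limit, every non-closed pair (gap > 1e-6 mm) at or above
the minimum dynamic gap, no negative gaps, and monotone cumulative
meterset across the arc.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `min_gap_to_correct` | 0.6 | mm | gap a pair must strictly exceed to receive DLG correction; protects deliberate ~0.5 mm shielding apertures |
| `motion_epsilon` | 0.01 | mm | dynamic/static discrimination threshold, machine precision scale |
| `dlg_source`, `dlg_target` | — | mm | commissioning measurements; **no defaults**, the CLI refuses to run the correction without both |
| `max_leaf_span_per_bank` | 150 | mm | conventional carriage group limit, both models |
| `max_overtravel` | 20 (M120) / 80 (HDMLC) | mm | conventional vendor values; the HDMLC figure approximates carriage-relative travel as midline overtravel |
| `min_dynamic_gap` | 0.5 | mm | conventional value |
| `y_jaw_hard/recommended_limit` | 110 / 105 (HDMLC) | mm | published HDMLC field-size constraint |

The published description of the conversion names the carriage,
overtravel, and minimum-gap limits without numbers; the values above
are conventional and every one is overridable through the INI-style
constraint config (`load_constraints`), one section per MLC model,
unknown keys rejected.

## Metrics

Gamma uses the global convention: dose differences are scaled by a
fixed percentage of the global normalization dose (reference maximum by
default) and reference points below the low-dose threshold (10% by
default) are excluded. The search evaluates candidate displacements out
to 3 × DTA at DTA/10 steps with trilinear interpolation of the
evaluation grid, walking offsets outward by distance and retiring each
point as soon as γ ≤ 1; once the distance term alone exceeds 1, no
still-failing point's pass/fail status can change, so the search stops.
Reported pass rates are identical to the exhaustive search; γ
magnitudes above 1 are not reported. Gamma is asymmetric; both
directions are computable. D5/D95 for the heterogeneity index use
voxel-dose percentiles with linear interpolation between order
statistics; HI is reported ×100, matching the percent-like scale on
which clinical values (~3–9) are quoted.

## Synthetic data

`generate_vmat_arc` emulates the features of optimizer output that the
converter actually exercises: nonuniform control-point spacing with
acceleration/deceleration ramps over 10% of the arc at a terminal speed
factor of 0.94 — chosen from the closed-form deviation estimate so the
worst-case departure from the uniform grid on a default 178-point 358°
arc is ≈0.9°, the magnitude observed on clinical plans, and in any case
below 2° — plus per-control-point leaf motion bounded by a speed
parameter, strictly monotone meterset, three aperture styles
(random-modulated pair walks, sliding window, conformal ellipse), a
closed-pair probability, and constant jaws at the recipe's Y window.
Apertures are constructed inside conservative tip bounds (centers
within ±15 mm, widths ≤ 55 mm) so every generated arc is deliverable on
either MLC out of the box.

What the generator does *not* emulate: anatomy-driven modulation,
dose-rate/gantry-speed co-optimization, per-control-point jaw tracking,
or apertures operating near carriage limits. Passing tests therefore
demonstrate the correctness of the geometric pipeline and its guards,
not clinical dosimetric equivalence, which in practice is established
by recalculating dose on the converted plan and auditing with the gamma
/ CI / HI metrics.

Dose phantoms are analytic (plateau sphere, linear ramp with closed-
form percentiles, compact Gaussian shifted-pair) so metric tests have
exact expectations; the shifted-pair field is kept compact so every
above-threshold point retains its displaced counterpart inside the
grid.

## Numerical choices and degenerate inputs

- Leaf intervals are half-open [lower, upper); midline y = 0 belongs to
  the upper-half leaf. Shared edges index unambiguously.
- Pair gaps within 1e-6 mm of zero are treated as physically closed and
  exempt from the minimum-dynamic-gap rule.
- DICOM writing rounds to 1e-5 (strings), far below the 0.01 mm / 0.1°
  round-trip contract; reading resolves delta encoding so every
  in-memory control point is self-contained, and normalizes the bank
  sign convention (median pair gap ≥ 0) once at the boundary.
- Plan normalization is a planning-system concept with no standard RT
  Plan attribute; it round-trips through a reserved private block.
- Zero-length arcs, empty PTV masks, empty evaluable gamma sets, and
  windows exceeding the target MLC extent raise immediately with
  specific messages rather than degrading.

## Known limitations

- One-way M120 → HDMLC only; the reverse requires sub-leaf aperture
  re-approximation, which is out of scope by design.
- No dose calculation: the normalization shift is a user input (derived
  clinically from a recalculation), and gamma/CI/HI operate on supplied
  or synthetic dose grids.
- Rounded-leaf-end transmission, tongue-and-groove, and interleaf
  leakage are not modeled; clinically these residuals are absorbed by
  the normalization shift.
- The uniform scout grid is an idealization of scripted-arc behavior;
  inject a measured grid when exactness against a specific scripting
  environment matters.
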
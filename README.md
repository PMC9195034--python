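# vmatconv

Deterministic conversion of VMAT treatment plans from the Varian
Millennium-120 multileaf collimator (M120) to the high-definition MLC
(HDMLC), for medical physicists who need a dosimetrically equivalent
backup plan on a machine with a different MLC without re-optimizing.

A center operating a solitary HDMLC linac alongside M120 units wants any
M120 plan deliverable on the HDMLC (and vice versa, as a backup) with the
*same* leaf motions, so that review and QA treat the converted plan as a
small dosimetric perturbation of the original rather than a new plan.
Vendor DVH-based converters re-optimize stochastically and produce
unrelated leaf patterns; this package instead exploits the fact that the
HDMLC leaf-boundary grid refines the M120 grid everywhere inside
|y| ≤ 11 cm, so any in-field M120 aperture can be reproduced exactly.

## Method

For each arc, in order:

1. **Scout-grid interpolation.** A scripted arc fixes its control points
   at uniform gantry spacing, while optimizer output shows
   acceleration/deceleration phases; intermediate angles disagree by up
   to about ±0.9°. For each uniform ("scout") angle θ the converter finds
   the bracketing source control points in arc-position space (degrees
   traveled along the rotation direction, so a 181°→179° CW arc crosses
   0° without a seam) and forms the linear blend
   (1−f)·CP_prev + f·CP_next of cumulative meterset weight, jaw
   positions, and all 120 leaf positions. Endpoints and control-point
   count are preserved exactly.
2. **Leaf-index remap.** Each M120 leaf inside the Y-jaw window maps to
   one (5 mm → 5 mm) or two (5 mm → 2×2.5 mm centrally,
   10 mm → 2×5 mm peripherally) HDMLC leaves carrying the same
   extension; the open aperture inside the window is reproduced
   verbatim, and out-of-window leaves are parked closed.
3. **Selective DLG correction.** The dosimetric leaf gap (DLG) absorbs
   rounded-leaf-end transmission and is narrower for HDMLC. Each leaf
   pair whose gap exceeds 0.6 mm, on the sides undergoing dynamic
   motion, is widened by Δ = DLG_src − DLG_tgt, split Δ/2 per bank —
   unless the move would violate the carriage span or overtravel limit,
   or push a gap under the minimum dynamic gap. Deliverability is
   thereby preserved; near-closed 0.5 mm shielding apertures are never
   widened.
4. **Validation and normalization.** Convertibility screening (|Y| jaws
   ≤ 11 cm hard, 10.5 cm recommended), per-control-point deliverability
   checks, and an optional global plan-normalization shift (typically
   ~0.5%) that absorbs residual beam-model differences.

QA metrics for auditing a conversion are included: the global (Van Dyk)
gamma pass rate (e.g. 1%/1 mm with a 10% low-dose threshold), the
conformity index CI = 100·V(100% isodose ∩ PTV)/V(PTV), and the
heterogeneity index HI = (D5% − D95%)/D_pres (reported ×100). Seeded
generators provide realistic synthetic arcs and analytic dose phantoms,
so nothing here needs patient data.

## Worked example

```sh
$ vmatconv synth arc --seed 3 --mlc M120 -o syn.dcm
wrote syn.dcm: 1 arc(s), 178 CPs, seed 3
$ vmatconv convert syn.dcm -o conv.dcm --dlg-source 1.8 --dlg-target 1.2
wrote conv.dcm [pass]
```

The first command writes a DICOM RT Plan containing a seeded synthetic
178-control-point M120 arc (nonuniform optimizer-style spacing, bounded
leaf motion, monotone meterset). The second converts it: `[pass]` means
the converted HDMLC plan cleared every deliverability check (carriage
span, overtravel, minimum dynamic gap, meterset monotonicity); the exit
code is 0 for pass, 1 for warnings, 2 for failure, and `--report r.json`
dumps the finding list. DLG values are commissioning measurements, so
the CLI refuses to guess them — pass both values or `--no-dlg`.

The same pipeline from Python:

```python
from vmatconv import builtin_geometry, generate_plan, convert_plan, DlgPolicy

plan = generate_plan(seed=3, geom=builtin_geometry("M120"))
converted, report, log = convert_plan(
    plan, policy=DlgPolicy(dlg_source=1.8, dlg_target=1.2))
print(report.status)        # pass
print(converted.arcs[0].mlc_model)   # HDMLC
```

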
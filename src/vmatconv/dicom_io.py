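"""DICOM RT Plan reader/writer for VMAT arcs.

The reader resolves DICOM delta encoding (control points that omit
attributes inherit them from the most recent control point that set them)
so that every in-memory :class:`~vmatconv.plan.ControlPoint` is
self-contained.  Leaf positions follow the DICOM MLCX convention: 120
values per control point, the first 60 belonging to bank B and the last 60
to bank A, each in ascending leaf-pair y order.  Bank sign conventions
vary between exporters, so the reader normalizes once at the boundary: if
the median pair gap (A - B) comes out negative, the banks are swapped.

Plan normalization (a percentage, an Eclipse-side concept with no standard
RT Plan attribute) is round-tripped through a private block so converted
plans keep it.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .geometry import KNOWN_MODELS, builtin_geometry
from .plan import Arc, ControlPoint, Plan, PlanInvariantError

__all__ = ["read_rtplan", "write_rtplan", "RTPlanParseError"]

RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"
_PRIVATE_GROUP = 0x3261
_PRIVATE_CREATOR = "VMATCONV"


class RTPlanParseError(ValueError):
    """The file is not a usable VMAT RT Plan."""


def _infer_mlc_model(boundaries: np.ndarray) -> str | None:
    for name in KNOWN_MODELS:
        if boundaries.size == 61 and np.allclose(
                boundaries, builtin_geometry(name).boundaries, atol=1e-3):
            return name
    return None


def read_rtplan(path: str | Path) -> Plan:
    """Read a DICOM RT Plan into a fully-resolved :class:`Plan`."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTPLAN":
        raise RTPlanParseError(f"{path}: not an RT Plan (Modality="
                               f"{getattr(ds, 'Modality', None)!r})")
    if not getattr(ds, "BeamSequence", None):
        raise RTPlanParseError(f"{path}: RT Plan has no beams")

    mu_by_beam: dict[int, float] = {}
    fractions = 1
    for fg in getattr(ds, "FractionGroupSequence", []):
        fractions = int(getattr(fg, "NumberOfFractionsPlanned", fractions))
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(rb, "BeamMeterset"):
                mu_by_beam[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    prescription = 0.0
    for dr in getattr(ds, "DoseReferenceSequence", []):
        if hasattr(dr, "TargetPrescriptionDose"):
            prescription = float(dr.TargetPrescriptionDose)
            break

    normalization = 100.0
    try:
        block = ds.private_block(_PRIVATE_GROUP, _PRIVATE_CREATOR)
        normalization = float(block[0x01].value)
    except KeyError:
        pass

    arcs = [_read_beam(beam, mu_by_beam, path) for beam in ds.BeamSequence
            if getattr(beam, "TreatmentDeliveryType", "TREATMENT") == "TREATMENT"]
    if not arcs:
        raise RTPlanParseError(f"{path}: RT Plan has no treatment beams")

    return Plan(
        plan_id=str(getattr(ds, "RTPlanLabel", Path(path).stem)),
        prescription_dose=prescription,
        fractions=fractions,
        plan_normalization=normalization,
        arcs=arcs,
    )


def _read_beam(beam: Dataset, mu_by_beam: dict[int, float],
               path: str | Path) -> Arc:
    beam_id = str(getattr(beam, "BeamName", beam.BeamNumber))
    boundaries = None
    for bld in getattr(beam, "BeamLimitingDeviceSequence", []):
        if bld.RTBeamLimitingDeviceType.startswith("MLC"):
            boundaries = np.asarray(bld.LeafPositionBoundaries, dtype=float)
    if boundaries is None:
        raise RTPlanParseError(
            f"beam {beam_id}: no MLCX device in BeamLimitingDeviceSequence")
    mlc_model = _infer_mlc_model(boundaries)
    if mlc_model is None:
        warnings.warn(
            f"beam {beam_id}: leaf position boundaries match no known MLC "
            "model; recording model as 'UNKNOWN'", stacklevel=3)
        mlc_model = "UNKNOWN"

    cps_raw = beam.ControlPointSequence
    final_cmw = float(getattr(beam, "FinalCumulativeMetersetWeight", 1.0))
    if final_cmw <= 0:
        final_cmw = 1.0

    # delta-encoding state
    state: dict[str, object] = {
        "gantry": None, "mlcx": None, "asymx": None, "asymy": None,
        "direction": None,
    }
    cps: list[ControlPoint] = []
    for k, item in enumerate(cps_raw):
        if hasattr(item, "GantryAngle"):
            state["gantry"] = float(item.GantryAngle)
        rot = getattr(item, "GantryRotationDirection", None)
        if rot in ("CW", "CC"):
            state["direction"] = "CW" if rot == "CW" else "CCW"
        for bldp in getattr(item, "BeamLimitingDevicePositionSequence", []):
            kind = bldp.RTBeamLimitingDeviceType
            vals = np.asarray(bldp.LeafJawPositions, dtype=float)
            if kind.startswith("MLC"):
                if vals.size != 120:
                    raise RTPlanParseError(
                        f"beam {beam_id}, CP {k}: MLCX carries {vals.size} "
                        "leaf positions, expected 120")
                state["mlcx"] = vals
            elif kind in ("ASYMX", "X"):
                state["asymx"] = vals
            elif kind in ("ASYMY", "Y"):
                state["asymy"] = vals
        if state["gantry"] is None or state["mlcx"] is None:
            raise RTPlanParseError(
                f"beam {beam_id}, CP {k}: gantry angle or MLCX positions "
                "never defined")
        if state["asymx"] is None:
            state["asymx"] = np.array([-200.0, 200.0])
        if state["asymy"] is None:
            state["asymy"] = np.array([-200.0, 200.0])
        cmw = float(item.CumulativeMetersetWeight) / final_cmw
        if cps and cmw < cps[-1].cumulative_meterset_weight - 1e-9:
            raise RTPlanParseError(
                f"beam {beam_id}, CP {k}: cumulative meterset weight "
                f"decreases ({cps[-1].cumulative_meterset_weight:.6g} -> "
                f"{cmw:.6g})")
        mlcx = np.asarray(state["mlcx"])
        cps.append(ControlPoint(
            index=k,
            gantry_angle=float(state["gantry"]) % 360.0,
            cumulative_meterset_weight=cmw,
            jaw_x1=float(state["asymx"][0]), jaw_x2=float(state["asymx"][1]),
            jaw_y1=float(state["asymy"][0]), jaw_y2=float(state["asymy"][1]),
            bank_b=mlcx[:60].copy(), bank_a=mlcx[60:].copy(),
        ))

    # normalize bank sign convention so pair gap = A - B >= 0
    med_gap = float(np.median(np.concatenate([cp.gaps for cp in cps])))
    if med_gap < 0:
        for cp in cps:
            cp.bank_b, cp.bank_a = cp.bank_a, cp.bank_b

    direction = state["direction"] or "CW"
    technique = "VMAT" if state["direction"] in ("CW", "CCW") else "STATIC"
    cp0 = cps_raw[0]
    iso = tuple(float(v) for v in getattr(cp0, "IsocenterPosition",
                                          [0.0, 0.0, 0.0]))
    return Arc(
        beam_id=beam_id,
        machine_id=str(getattr(beam, "TreatmentMachineName", "")),
        mlc_model=mlc_model,
        collimator_angle=float(getattr(cp0, "BeamLimitingDeviceAngle", 0.0)),
        gantry_start=cps[0].gantry_angle,
        gantry_stop=cps[-1].gantry_angle,
        direction=direction,
        isocenter=iso,
        total_mu=mu_by_beam.get(int(beam.BeamNumber), 0.0),
        control_points=cps,
        technique=technique,
    )


def write_rtplan(plan: Plan, path: str | Path) -> Path:
    """Write ``plan`` as a valid RT Plan file with a new SOP instance UID.

    Refuses to write a plan that violates structural invariants
    (overlapping leaves, non-monotone meterset, ...), reporting the full
    violation list.
    """
    problems = plan.validate()
    if problems:
        raise PlanInvariantError(
            "refusing to write invalid plan: " + "; ".join(problems))

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = RTPLAN_SOP_CLASS
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=file_meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.PatientName = "ANON"
    ds.PatientID = "ANON"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.RTPlanLabel = plan.plan_id
    ds.RTPlanGeometry = "TREATMENT_DEVICE"

    block = ds.private_block(_PRIVATE_GROUP, _PRIVATE_CREATOR, create=True)
    block.add_new(0x01, "DS", f"{plan.plan_normalization:.6f}")

    dr = Dataset()
    dr.DoseReferenceNumber = 1
    dr.DoseReferenceStructureType = "SITE"
    dr.DoseReferenceType = "TARGET"
    dr.TargetPrescriptionDose = f"{plan.prescription_dose:.6f}"
    ds.DoseReferenceSequence = [dr]

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = plan.fractions
    fg.NumberOfBeams = len(plan.arcs)
    fg.NumberOfBrachyApplicationSetups = 0
    fg.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fg]

    ds.BeamSequence = []
    for n, arc in enumerate(plan.arcs, start=1):
        ds.BeamSequence.append(_write_beam(arc, n))
        rb = Dataset()
        rb.ReferencedBeamNumber = n
        rb.BeamMeterset = f"{arc.total_mu:.4f}"
        fg.ReferencedBeamSequence.append(rb)

    ds.save_as(str(path), enforce_file_format=True)
    return Path(path)


def _fmt(x: float) -> str:
    # DS values are capped at 16 bytes; 0.00001 mm resolution is far below
    # the 0.01 mm round-trip contract
    return f"{x:.5f}".rstrip("0").rstrip(".") or "0"


def _write_beam(arc: Arc, beam_number: int) -> Dataset:
    geom_boundaries = None
    if arc.mlc_model in KNOWN_MODELS:
        geom_boundaries = builtin_geometry(arc.mlc_model).boundaries
    beam = Dataset()
    beam.BeamNumber = beam_number
    beam.BeamName = arc.beam_id
    beam.TreatmentMachineName = arc.machine_id
    beam.RadiationType = "PHOTON"
    beam.BeamType = "DYNAMIC"
    beam.TreatmentDeliveryType = "TREATMENT"
    beam.PrimaryDosimeterUnit = "MU"
    beam.SourceAxisDistance = "1000"
    beam.NumberOfWedges = 0
    beam.NumberOfCompensators = 0
    beam.NumberOfBoli = 0
    beam.NumberOfBlocks = 0

    beam.BeamLimitingDeviceSequence = []
    for kind, n_pairs in (("ASYMX", 1), ("ASYMY", 1), ("MLCX", 60)):
        bld = Dataset()
        bld.RTBeamLimitingDeviceType = kind
        bld.NumberOfLeafJawPairs = n_pairs
        if kind == "MLCX" and geom_boundaries is not None:
            bld.LeafPositionBoundaries = [_fmt(b) for b in geom_boundaries]
        beam.BeamLimitingDeviceSequence.append(bld)

    beam.FinalCumulativeMetersetWeight = "1.0"
    beam.NumberOfControlPoints = arc.n_cp
    beam.ControlPointSequence = []
    rot = "CW" if arc.direction == "CW" else "CC"
    for cp in arc.control_points:
        item = Dataset()
        item.ControlPointIndex = cp.index
        item.CumulativeMetersetWeight = _fmt(cp.cumulative_meterset_weight)
        item.GantryAngle = _fmt(cp.gantry_angle)
        item.GantryRotationDirection = rot
        if cp.index == 0:
            item.NominalBeamEnergy = "6"
            item.DoseRateSet = "600"
            item.BeamLimitingDeviceAngle = _fmt(arc.collimator_angle)
            item.PatientSupportAngle = "0"
            item.IsocenterPosition = [_fmt(v) for v in arc.isocenter]
        seq = []
        for kind, vals in (("ASYMX", [cp.jaw_x1, cp.jaw_x2]),
                           ("ASYMY", [cp.jaw_y1, cp.jaw_y2]),
                           ("MLCX", list(cp.bank_b) + list(cp.bank_a))):
            bldp = Dataset()
            bldp.RTBeamLimitingDeviceType = kind
            bldp.LeafJawPositions = [_fmt(v) for v in vals]
            seq.append(bldp)
        item.BeamLimitingDevicePositionSequence = seq
        beam.ControlPointSequence.append(item)
    return beam
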
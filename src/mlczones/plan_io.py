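"""Treatment-plan model and DICOM RT-Plan input/output.

The internal model keeps everything in cm at the isocenter plane (IEC
61217 beam's-eye view: x along leaf travel, y across leaves).  DICOM
stores positions in mm; conversion happens at the file boundary only.

Per-control-point monitor-unit weights are derived from the cumulative
meterset weights; by default the fluence delivered between two
consecutive shapes is attributed to the earlier one (forward-difference
convention), so the terminal control point of each beam carries zero MU.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .params import MLCGeometry

__all__ = [
    "ControlPoint",
    "Beam",
    "Plan",
    "PlanReadError",
    "NoMLCError",
    "CorruptMetersetError",
    "read_rtplan",
    "write_rtplan",
    "control_point_mu",
]

RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"


class PlanReadError(ValueError):
    """Raised when an RT-Plan file cannot be interpreted."""


class NoMLCError(PlanReadError):
    """Raised when a plan contains no beam with an MLC device."""


class CorruptMetersetError(PlanReadError):
    """Raised when cumulative meterset weights decrease within a beam."""


@dataclass
class ControlPoint:
    """One snapshot of machine state.

    ``bank_a[j]`` is the tip of the bank-A leaf of pair ``j`` (the leaf
    occupies x <= tip); ``bank_b[j]`` the bank-B tip (leaf occupies
    x >= tip).  Jaws bound the classification grid.
    """

    index: int
    bank_a: np.ndarray
    bank_b: np.ndarray
    jaw_x_low: float
    jaw_x_high: float
    jaw_y_low: float
    jaw_y_high: float
    cumulative_weight: float

    def __post_init__(self) -> None:
        self.bank_a = np.asarray(self.bank_a, dtype=float)
        self.bank_b = np.asarray(self.bank_b, dtype=float)

    def validate(self) -> None:
        if self.bank_a.shape != self.bank_b.shape or self.bank_a.ndim != 1:
            raise ValueError("leaf banks must be 1D arrays of equal length")
        if not self.jaw_x_low < self.jaw_x_high:
            raise ValueError(
                f"jaw_x_low must be < jaw_x_high "
                f"({self.jaw_x_low} !< {self.jaw_x_high})"
            )
        if not self.jaw_y_low < self.jaw_y_high:
            raise ValueError(
                f"jaw_y_low must be < jaw_y_high "
                f"({self.jaw_y_low} !< {self.jaw_y_high})"
            )
        if np.any(self.bank_a > self.bank_b):
            j = int(np.argmax(self.bank_a - self.bank_b))
            raise ValueError(
                f"leaf pair {j}: bank A tip {self.bank_a[j]} exceeds "
                f"bank B tip {self.bank_b[j]}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ControlPoint):
            return NotImplemented
        return (
            self.index == other.index
            and np.array_equal(self.bank_a, other.bank_a)
            and np.array_equal(self.bank_b, other.bank_b)
            and (self.jaw_x_low, self.jaw_x_high, self.jaw_y_low, self.jaw_y_high)
            == (other.jaw_x_low, other.jaw_x_high, other.jaw_y_low, other.jaw_y_high)
            and self.cumulative_weight == other.cumulative_weight
        )


@dataclass
class Beam:
    """An ordered sequence of control points plus its meterset."""

    beam_number: int
    name: str
    control_points: list[ControlPoint]
    beam_meterset: float
    final_cumulative_weight: float

    def validate(self) -> None:
        if not self.control_points:
            raise ValueError(f"beam {self.name!r} has no control points")
        if self.final_cumulative_weight <= 0:
            raise ValueError(
                f"beam {self.name!r}: final_cumulative_weight must be > 0"
            )
        w = [cp.cumulative_weight for cp in self.control_points]
        if np.any(np.diff(w) < 0):
            raise CorruptMetersetError(
                f"corrupt meterset: cumulative weights decrease in beam "
                f"{self.name!r}"
            )
        for cp in self.control_points:
            cp.validate()


@dataclass
class Plan:
    """A treatment plan: identifier, beams and the MLC geometry they use."""

    plan_id: str
    beams: list[Beam]
    geometry: MLCGeometry = field(default_factory=MLCGeometry.millennium120)

    def validate(self) -> None:
        if not self.beams:
            raise ValueError("plan has no beams")
        for beam in self.beams:
            beam.validate()
            for cp in beam.control_points:
                if cp.bank_a.size != self.geometry.n_pairs:
                    raise ValueError(
                        f"beam {beam.name!r} CP {cp.index}: "
                        f"{cp.bank_a.size} leaf pairs vs geometry "
                        f"{self.geometry.n_pairs}"
                    )

    # ---- JSON serialization (internal fixture format) -------------------

    def to_dict(self) -> dict:
        return {
            "plan_id": self.plan_id,
            "leaf_boundaries": self.geometry.leaf_boundaries.tolist(),
            "beams": [
                {
                    "beam_number": b.beam_number,
                    "name": b.name,
                    "beam_meterset": b.beam_meterset,
                    "final_cumulative_weight": b.final_cumulative_weight,
                    "control_points": [
                        {
                            "index": cp.index,
                            "bank_a": cp.bank_a.tolist(),
                            "bank_b": cp.bank_b.tolist(),
                            "jaw_x": [cp.jaw_x_low, cp.jaw_x_high],
                            "jaw_y": [cp.jaw_y_low, cp.jaw_y_high],
                            "cumulative_weight": cp.cumulative_weight,
                        }
                        for cp in b.control_points
                    ],
                }
                for b in self.beams
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Plan":
        beams = [
            Beam(
                beam_number=bd["beam_number"],
                name=bd["name"],
                beam_meterset=bd["beam_meterset"],
                final_cumulative_weight=bd["final_cumulative_weight"],
                control_points=[
                    ControlPoint(
                        index=cd["index"],
                        bank_a=np.array(cd["bank_a"], dtype=float),
                        bank_b=np.array(cd["bank_b"], dtype=float),
                        jaw_x_low=cd["jaw_x"][0],
                        jaw_x_high=cd["jaw_x"][1],
                        jaw_y_low=cd["jaw_y"][0],
                        jaw_y_high=cd["jaw_y"][1],
                        cumulative_weight=cd["cumulative_weight"],
                    )
                    for cd in bd["control_points"]
                ],
            )
            for bd in d["beams"]
        ]
        return cls(
            plan_id=d["plan_id"],
            beams=beams,
            geometry=MLCGeometry(np.array(d["leaf_boundaries"], dtype=float)),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict()))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "Plan":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# MU weights
# ---------------------------------------------------------------------------

def control_point_mu(beam: Beam, convention: str = "forward") -> np.ndarray:
    """Per-control-point MU weights ``m_i``.

    ``m_i`` distributes the beam meterset over control points according to
    the differences of cumulative meterset weights.  Conventions:

    - ``forward`` (default): the fluence delivered between shapes i and
      i+1 is attributed to shape i; the last control point gets 0.
    - ``backward``: attributed to shape i+1; the first gets 0.
    - ``midpoint``: split evenly between the two bracketing shapes.

    The weights sum to ``beam_meterset`` for every convention (except the
    degenerate single-control-point beam, which yields ``[0.0]``).
    """
    beam.validate()
    w = np.array([cp.cumulative_weight for cp in beam.control_points], dtype=float)
    n = w.size
    if n == 1:
        return np.zeros(1)
    scale = beam.beam_meterset / beam.final_cumulative_weight
    dw = np.diff(w) * scale
    m = np.zeros(n)
    if convention == "forward":
        m[:-1] = dw
    elif convention == "backward":
        m[1:] = dw
    elif convention == "midpoint":
        m[:-1] += dw / 2.0
        m[1:] += dw / 2.0
    else:
        raise ValueError(f"unknown MU convention {convention!r}")
    return m


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

_JAW_X = {"X", "ASYMX"}
_JAW_Y = {"Y", "ASYMY"}
_MLC = {"MLCX", "MLC"}


def _bld_positions(cp_item: Dataset) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    for item in cp_item.get("BeamLimitingDevicePositionSequence", []):
        out[str(item.RTBeamLimitingDeviceType)] = [
            float(v) for v in item.LeafJawPositions
        ]
    return out


def read_rtplan(
    path: str | Path, geometry_override: MLCGeometry | None = None
) -> Plan:
    """Parse a DICOM RT-Plan into the internal :class:`Plan` model.

    Positions are converted to cm at the isocenter plane.  Leaf
    boundaries come from the file's ``LeafPositionBoundaries`` when
    present, else from ``geometry_override``, else the Millennium 120
    default.  Jaw and leaf positions omitted on later control points are
    carried forward from the last control point that specified them.
    Beams without an MLC device (e.g. setup fields) are skipped with a
    warning; a plan with no MLC beam at all raises :class:`NoMLCError`.
    """
    ds = pydicom.dcmread(str(path), force=True)
    if "BeamSequence" not in ds:
        raise PlanReadError(f"{path}: no BeamSequence")

    metersets: dict[int, float] = {}
    for fg in ds.get("FractionGroupSequence", []):
        for rb in fg.get("ReferencedBeamSequence", []):
            if "BeamMeterset" in rb:
                metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    geometry: MLCGeometry | None = None
    beams: list[Beam] = []
    for beam_ds in ds.BeamSequence:
        number = int(beam_ds.BeamNumber)
        name = str(beam_ds.get("BeamName", f"beam{number}"))
        mlc_item = None
        for dev in beam_ds.get("BeamLimitingDeviceSequence", []):
            if str(dev.RTBeamLimitingDeviceType) in _MLC:
                mlc_item = dev
        if mlc_item is None:
            warnings.warn(f"beam {name!r}: no MLC device, skipped", stacklevel=2)
            continue
        if "LeafPositionBoundaries" in mlc_item:
            beam_geom = MLCGeometry(
                np.array([float(v) for v in mlc_item.LeafPositionBoundaries]) / 10.0
            )
        elif geometry_override is not None:
            beam_geom = geometry_override
        else:
            beam_geom = MLCGeometry.millennium120()
        if geometry is None:
            geometry = beam_geom
        elif geometry != beam_geom:
            raise PlanReadError("beams use different MLC geometries")

        if number not in metersets:
            raise PlanReadError(f"beam {name!r}: no BeamMeterset in FractionGroup")

        n_pairs = beam_geom.n_pairs
        jaw_x: list[float] | None = None
        jaw_y: list[float] | None = None
        leaves: list[float] | None = None
        cps: list[ControlPoint] = []
        prev_w = -np.inf
        for i, cp_item in enumerate(beam_ds.ControlPointSequence):
            pos = _bld_positions(cp_item)
            for key in pos:
                if key in _JAW_X:
                    jaw_x = pos[key]
                elif key in _JAW_Y:
                    jaw_y = pos[key]
                elif key in _MLC:
                    leaves = pos[key]
            if jaw_x is None or jaw_y is None:
                raise PlanReadError(
                    f"beam {name!r} CP {i}: jaw positions never specified"
                )
            if leaves is None:
                raise NoMLCError(f"no MLC positions in beam {name!r} CP {i}")
            if len(leaves) != 2 * n_pairs:
                raise PlanReadError(
                    f"beam {name!r} CP {i}: {len(leaves)} leaf positions, "
                    f"expected {2 * n_pairs}"
                )
            w = float(cp_item.CumulativeMetersetWeight)
            if w < prev_w:
                raise CorruptMetersetError(
                    f"corrupt meterset: cumulative weight decreases at "
                    f"beam {name!r} CP {i}"
                )
            prev_w = w
            cp = ControlPoint(
                index=i,
                bank_a=np.array(leaves[:n_pairs]) / 10.0,
                bank_b=np.array(leaves[n_pairs:]) / 10.0,
                jaw_x_low=jaw_x[0] / 10.0,
                jaw_x_high=jaw_x[1] / 10.0,
                jaw_y_low=jaw_y[0] / 10.0,
                jaw_y_high=jaw_y[1] / 10.0,
                cumulative_weight=w,
            )
            cp.validate()
            cps.append(cp)
        beams.append(
            Beam(
                beam_number=number,
                name=name,
                control_points=cps,
                beam_meterset=metersets[number],
                final_cumulative_weight=float(beam_ds.FinalCumulativeMetersetWeight),
            )
        )

    if not beams:
        raise NoMLCError(f"{path}: no MLC beam in plan")
    plan = Plan(
        plan_id=str(ds.get("RTPlanLabel", Path(str(path)).stem)),
        beams=beams,
        geometry=geometry,  # type: ignore[arg-type]
    )
    plan.validate()
    return plan


def _mm(values: Iterable[float]) -> list[float]:
    # round to 1e-5 mm so cm round-trips survive the DS encoding
    return [round(float(v) * 10.0, 5) for v in values]


def write_rtplan(plan: Plan, path: str | Path) -> Path:
    """Write a minimal, valid RT-Plan file readable by :func:`read_rtplan`.

    Jaw positions are emitted on the first control point of each beam and
    thereafter only when they change (the standard DICOM omission rule);
    MLC positions and the cumulative meterset weight are emitted on every
    control point.  Refuses to write a plan violating its invariants.
    """
    plan.validate()
    path = Path(path)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTPLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[plan.plan_id])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.PatientName = "synthetic^plan"
    ds.PatientID = plan.plan_id
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[plan.plan_id, "study"])
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[plan.plan_id, "series"])
    ds.RTPlanLabel = plan.plan_id
    ds.RTPlanGeometry = "TREATMENT_DEVICE"

    boundaries_mm = _mm(plan.geometry.leaf_boundaries)
    n_pairs = plan.geometry.n_pairs

    beam_seq = []
    ref_beam_seq = []
    for beam in plan.beams:
        b = Dataset()
        b.BeamNumber = beam.beam_number
        b.BeamName = beam.name
        b.BeamType = "DYNAMIC" if len(beam.control_points) > 2 else "STATIC"
        b.RadiationType = "PHOTON"
        b.TreatmentDeliveryType = "TREATMENT"
        b.NumberOfControlPoints = len(beam.control_points)
        b.FinalCumulativeMetersetWeight = beam.final_cumulative_weight

        devs = []
        for dtype, n in (("ASYMX", 1), ("ASYMY", 1), ("MLCX", n_pairs)):
            d = Dataset()
            d.RTBeamLimitingDeviceType = dtype
            d.NumberOfLeafJawPairs = n
            if dtype == "MLCX":
                d.LeafPositionBoundaries = boundaries_mm
            devs.append(d)
        b.BeamLimitingDeviceSequence = devs

        cp_seq = []
        prev_jaws: tuple | None = None
        for cp in beam.control_points:
            item = Dataset()
            item.ControlPointIndex = cp.index
            item.CumulativeMetersetWeight = cp.cumulative_weight
            jaws = (cp.jaw_x_low, cp.jaw_x_high, cp.jaw_y_low, cp.jaw_y_high)
            positions = []
            if jaws != prev_jaws:
                for dtype, pair in (
                    ("ASYMX", jaws[:2]),
                    ("ASYMY", jaws[2:]),
                ):
                    p = Dataset()
                    p.RTBeamLimitingDeviceType = dtype
                    p.LeafJawPositions = _mm(pair)
                    positions.append(p)
                prev_jaws = jaws
            p = Dataset()
            p.RTBeamLimitingDeviceType = "MLCX"
            p.LeafJawPositions = _mm(np.concatenate([cp.bank_a, cp.bank_b]))
            positions.append(p)
            item.BeamLimitingDevicePositionSequence = positions
            cp_seq.append(item)
        b.ControlPointSequence = cp_seq
        beam_seq.append(b)

        rb = Dataset()
        rb.ReferencedBeamNumber = beam.beam_number
        rb.BeamMeterset = beam.beam_meterset
        ref_beam_seq.append(rb)

    ds.BeamSequence = beam_seq
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.ReferencedBeamSequence = ref_beam_seq
    ds.FractionGroupSequence = [fg]

    ds.save_as(str(path), enforce_file_format=True)
    return path
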
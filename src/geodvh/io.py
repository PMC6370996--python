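"""DICOM-RT ingestion and case-bundle persistence.

A *case bundle* is a directory holding a JSON manifest (grid, labels, plan
list, absence flags) plus one ``.npy`` raster per structure mask and per dose
grid.  DICOM-RT Structure Sets are rasterized onto the dose grid so every
downstream operation sees a single shared grid.

Array axis convention throughout: (x = left-right, y = anterior-posterior,
z = superior-inferior), i.e. DICOM dose ``pixel_array`` (frame, row, col) is
transposed to (col, row, frame).
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import generate_uid

from .geometry import StructureMask, VoxelGrid, rasterize_structure
from .model import Case, DistanceBinSpec, ModelConfig


class DicomReadError(ValueError):
    pass


@dataclass
class RunConfig:
    """Reusable run configuration: paths, naming, model and seed settings.

    Round-trips losslessly through JSON so a run can be reproduced from its
    recorded configuration alone.
    """

    case_paths: list[str] = field(default_factory=list)
    output_dir: str = "."
    name_mapping: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_NAME_MAPPING))
    bins: DistanceBinSpec = field(default_factory=DistanceBinSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    constraint_version: str = "v1-pancreas-sbrt-5fx"
    seed: int = 0

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        model = d.pop("model")
        bins_model = DistanceBinSpec(**model.pop("bins"))
        d["model"] = ModelConfig(bins=bins_model, **model)
        d["bins"] = DistanceBinSpec(**d["bins"])
        return cls(**d)

    def validate_constraints(self, constraints, absent: set[str] = frozenset()) -> None:
        """Every constrained label must be resolvable or explicitly absent."""
        resolvable = set(self.name_mapping.values()) | set(absent) | {"kidney"}
        missing = {c.structure for c in constraints} - resolvable
        if missing:
            raise DicomReadError(
                f"constraint structures not resolvable by the name mapping: {sorted(missing)}"
            )


DEFAULT_NAME_MAPPING = {
    "gtv": "GTV", "ctvgeom": "CTVgeom", "ctvprop": "CTVprop", "boostctv": "boostCTV",
    "ptv1": "PTV1", "ptv2": "PTV2", "ptv3": "PTV3",
    "stomach": "stomach", "duodenum": "duodenum", "bowel": "bowel",
    "small bowel": "bowel", "smallbowel": "bowel",
    "kidney l": "kidney_L", "kidney_l": "kidney_L", "lt kidney": "kidney_L",
    "kidney r": "kidney_R", "kidney_r": "kidney_R", "rt kidney": "kidney_R",
    "liver": "liver", "cord": "cord", "spinal cord": "cord", "spinalcord": "cord",
}


def _canonical_label(roi_name: str, mapping: dict[str, str]) -> str | None:
    key = roi_name.strip().lower()
    if key in mapping:
        return mapping[key]
    # tolerate suffixes like "Stomach_1"
    base = key.rstrip("0123456789").rstrip("_- ")
    return mapping.get(base)


def _grid_from_rtdose(ds: pydicom.Dataset) -> tuple[VoxelGrid, np.ndarray]:
    rows_sp, cols_sp = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if len(dz) and not np.allclose(dz, dz[0]):
        raise DicomReadError("non-uniform dose grid frame offsets are unsupported")
    z_sp = float(dz[0]) if len(dz) else 1.0
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    dose = ds.pixel_array.astype(np.float64) * float(ds.DoseGridScaling)
    dose = np.transpose(dose, (2, 1, 0))  # (frame,row,col) -> (x,y,z)
    grid = VoxelGrid(dose.shape, (cols_sp, rows_sp, abs(z_sp)), origin)
    if z_sp < 0:
        dose = dose[:, :, ::-1]
    return grid, np.ascontiguousarray(dose)


def read_case_dicom(
    rtstruct_path,
    rtdose_path,
    mapping: dict[str, str] | None = None,
    plan_type: str = "InitPlan",
    required: tuple[str, ...] = (),
    case_id: str = "",
) -> Case:
    """Read one patient's RT Structure Set + RT Dose into a Case.

    Structures are rasterized onto the dose grid; ROI names resolve to
    canonical labels through ``mapping`` (case-insensitive, numeric suffixes
    tolerated), unmapped ROIs are reported with a warning, and ``required``
    structures missing from the file are flagged absent rather than failing.
    """
    mapping = {k.lower(): v for k, v in (mapping or DEFAULT_NAME_MAPPING).items()}
    rtstruct = pydicom.dcmread(rtstruct_path)
    rtdose = pydicom.dcmread(rtdose_path)

    for_struct = getattr(rtstruct, "FrameOfReferenceUID", None) or (
        rtstruct.ReferencedFrameOfReferenceSequence[0].FrameOfReferenceUID
        if "ReferencedFrameOfReferenceSequence" in rtstruct
        else None
    )
    for_dose = getattr(rtdose, "FrameOfReferenceUID", None)
    if for_struct and for_dose and for_struct != for_dose:
        raise DicomReadError("frame-of-reference mismatch between RTSTRUCT and RTDOSE")

    grid, dose = _grid_from_rtdose(rtdose)

    roi_names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in rtstruct.StructureSetROISequence
    }
    masks: dict[str, StructureMask] = {}
    for rc in rtstruct.ROIContourSequence:
        name = roi_names.get(int(rc.ReferencedROINumber), "?")
        label = _canonical_label(name, mapping)
        if label is None:
            warnings.warn(f"unmapped ROI {name!r} skipped", stacklevel=2)
            continue
        contours = []
        for c in getattr(rc, "ContourSequence", []):
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            contours.append(pts)
        masks[label] = rasterize_structure(contours, grid, label)

    absent = {r for r in required if r not in masks}
    case = Case(
        case_id=case_id or Path(str(rtstruct_path)).stem,
        grid=grid,
        masks=masks,
        doses={plan_type: dose},
        absent=absent,
    )
    return case


# ---------------------------------------------------------------------------
# DICOM-RT writing (round-trip support for exported cases)
# ---------------------------------------------------------------------------

def _mask_contours(mask: StructureMask) -> list[np.ndarray]:
    """Closed boundary polygons (patient mm) of a mask, slice by slice."""
    from skimage import measure

    grid = mask.grid
    contours = []
    for k in range(grid.dims[2]):
        sl = mask.inside[:, :, k]
        if not sl.any():
            continue
        padded = np.pad(sl.astype(float), 1)
        for poly in measure.find_contours(padded, 0.5):
            xy = poly - 1.0  # undo padding; (row=x index, col=y index)
            xs = grid.origin[0] + xy[:, 0] * grid.spacing[0]
            ys = grid.origin[1] + xy[:, 1] * grid.spacing[1]
            zs = np.full(len(xy), grid.origin[2] + k * grid.spacing[2])
            contours.append(np.column_stack([xs, ys, zs]))
    return contours


def _base_dataset(sop_class_uid: str, frame_uid: str) -> pydicom.FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds = pydicom.FileDataset(None, Dataset(), file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientName = "synthetic"
    ds.PatientID = "synthetic"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = frame_uid
    ds.Modality = ""
    now = datetime.datetime(2000, 1, 1)
    ds.StudyDate = now.strftime("%Y%m%d")
    ds.StudyTime = now.strftime("%H%M%S")
    return ds


def write_case_dicom(case: Case, plan_type: str, out_dir) -> tuple[Path, Path]:
    """Export a case as a minimal RTSTRUCT + RTDOSE pair (synthetic data).

    Intended for round-trip testing and interoperability smoke checks, not for
    clinical transfer.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame_uid = generate_uid()

    # --- RTDOSE ---
    dose = np.asarray(case.doses[plan_type], dtype=np.float64)
    scaling = float(dose.max()) / 65535.0 if dose.max() > 0 else 1.0
    quant = np.round(dose / scaling).astype(np.uint16)
    dd = _base_dataset("1.2.840.10008.5.1.4.1.1.481.2", frame_uid)
    dd.Modality = "RTDOSE"
    dd.DoseUnits = "GY"
    dd.DoseType = "PHYSICAL"
    dd.DoseSummationType = "PLAN"
    dd.SamplesPerPixel = 1
    dd.PhotometricInterpretation = "MONOCHROME2"
    dd.BitsAllocated = 16
    dd.BitsStored = 16
    dd.HighBit = 15
    dd.PixelRepresentation = 0
    nx, ny, nz = case.grid.dims
    dd.Columns = nx
    dd.Rows = ny
    dd.NumberOfFrames = nz
    dd.PixelSpacing = [case.grid.spacing[1], case.grid.spacing[0]]  # [row, col]
    dd.GridFrameOffsetVector = [k * case.grid.spacing[2] for k in range(nz)]
    dd.ImagePositionPatient = list(case.grid.origin)
    dd.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    dd.DoseGridScaling = scaling
    dd.PixelData = np.transpose(quant, (2, 1, 0)).tobytes()  # (x,y,z)->(frame,row,col)
    dose_path = out_dir / f"rtdose_{plan_type}.dcm"
    dd.save_as(dose_path, enforce_file_format=True)

    # --- RTSTRUCT ---
    sd = _base_dataset("1.2.840.10008.5.1.4.1.1.481.3", frame_uid)
    sd.Modality = "RTSTRUCT"
    sd.StructureSetLabel = case.case_id
    roi_seq, contour_seq = [], []
    for num, (label, mask) in enumerate(case.masks.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = label
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        cs = []
        for poly in _mask_contours(mask):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(poly)
            c.ContourData = [float(v) for v in poly.ravel()]
            cs.append(c)
        rc.ContourSequence = cs
        contour_seq.append(rc)
    sd.StructureSetROISequence = roi_seq
    sd.ROIContourSequence = contour_seq
    struct_path = out_dir / "rtstruct.dcm"
    sd.save_as(struct_path, enforce_file_format=True)
    return struct_path, dose_path


# ---------------------------------------------------------------------------
# Case bundles
# ---------------------------------------------------------------------------

BUNDLE_VERSION = 1


def save_case_bundle(case: Case, out_dir) -> Path:
    """Persist a case losslessly: JSON manifest + one .npy per raster."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "bundle_version": BUNDLE_VERSION,
        "case_id": case.case_id,
        "grid": {
            "dims": list(case.grid.dims),
            "spacing": list(case.grid.spacing),
            "origin": list(case.grid.origin),
        },
        "masks": sorted(case.masks),
        "doses": sorted(case.doses),
        "absent": sorted(case.absent),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for label, mask in case.masks.items():
        np.save(out_dir / f"mask_{label}.npy", np.packbits(mask.inside))
    for plan, dose in case.doses.items():
        np.save(out_dir / f"dose_{plan}.npy", np.asarray(dose, dtype=np.float32))
    return out_dir


def load_case_bundle(bundle_dir) -> Case:
    bundle_dir = Path(bundle_dir)
    manifest = json.loads((bundle_dir / "manifest.json").read_text())
    g = manifest["grid"]
    grid = VoxelGrid(tuple(g["dims"]), tuple(g["spacing"]), tuple(g["origin"]))
    n_vox = int(np.prod(grid.dims))
    masks = {}
    for label in manifest["masks"]:
        bits = np.load(bundle_dir / f"mask_{label}.npy")
        inside = np.unpackbits(bits, count=n_vox).astype(bool).reshape(grid.dims)
        masks[label] = StructureMask(grid, inside, label)
    doses = {
        plan: np.load(bundle_dir / f"dose_{plan}.npy") for plan in manifest["doses"]
    }
    return Case(
        case_id=manifest["case_id"],
        grid=grid,
        masks=masks,
        doses=doses,
        absent=set(manifest["absent"]),
    )
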
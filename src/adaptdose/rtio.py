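"""Radiotherapy file I/O: DICOM RT Dose / RT Structure Set and the native
case-bundle format.

The native bundle (a directory holding ``manifest.yaml`` plus one ``.npz``
array container) is the canonical test format; DICOM-RT is the interchange
format.  Grids are axis-aligned: oblique DICOM orientations are rejected,
not resampled, so the geometry stays auditable.

DICOM pixel arrays are stored frame-major (z, y, x); in memory all arrays
use (x, y, z) axis order, so readers and writers transpose.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pydicom
import yaml
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import (
    CaseBundle,
    ConsistencyError,
    DoseGrid,
    FormatError,
    ImageGrid3D,
    OrganClass,
    Structure,
    StructureSet,
    UnsupportedGeometryError,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_rtdose",
    "write_rtdose",
    "read_rtstruct",
    "write_rtstruct",
    "read_bundle",
    "write_bundle",
]

_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
_IDENTITY_ORIENT = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _require(ds: Dataset, tag_name: str) -> object:
    if tag_name not in ds:
        raise FormatError(f"required DICOM tag missing: {tag_name}")
    return getattr(ds, tag_name)


# ---------------------------------------------------------------------------
# RT Dose


def read_rtdose(path: str | Path) -> DoseGrid:
    """Read a DICOM RT Dose file into a :class:`DoseGrid` (values in Gy).

    The stored integer array is multiplied by ``DoseGridScaling``.  Only
    identity (axis-aligned) orientation and a uniform frame spacing are
    supported.
    """
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "SOPClassUID", None) != _RTDOSE_SOP and getattr(ds, "Modality", "") != "RTDOSE":
        raise FormatError(f"{path} is not an RT Dose object")
    scaling = float(_require(ds, "DoseGridScaling"))
    origin = [float(v) for v in _require(ds, "ImagePositionPatient")]
    pixel_spacing = [float(v) for v in _require(ds, "PixelSpacing")]
    orient = tuple(float(v) for v in _require(ds, "ImageOrientationPatient"))
    if not np.allclose(orient, _IDENTITY_ORIENT, atol=1e-6):
        raise UnsupportedGeometryError(
            f"oblique ImageOrientationPatient {orient} is not supported"
        )
    offsets = np.asarray([float(v) for v in _require(ds, "GridFrameOffsetVector")])
    if len(offsets) > 1:
        dz = np.diff(offsets)
        if not np.allclose(dz, dz[0], atol=1e-6):
            raise UnsupportedGeometryError("non-uniform frame spacing is not supported")
        dz = float(dz[0])
    else:
        dz = 1.0
    raw = ds.pixel_array  # (frames, rows, cols) == (z, y, x)
    if raw.ndim == 2:
        raw = raw[None]
    dose = np.ascontiguousarray(raw.astype(float).transpose(2, 1, 0)) * scaling
    grid = ImageGrid3D(
        origin=(origin[0], origin[1], origin[2] + float(offsets[0])),
        # PixelSpacing is (row spacing, column spacing) = (dy, dx)
        spacing=(pixel_spacing[1], pixel_spacing[0], abs(dz)),
        shape=dose.shape,
    )
    return DoseGrid(grid, dose)


def write_rtdose(dose: DoseGrid, path: str | Path) -> None:
    """Write a :class:`DoseGrid` as a standard RT Dose object.

    Doses are stored as scaled 32-bit integers; the scaling factor is chosen
    so the round trip is exact to well below 1e-4 Gy.
    """
    grid = dose.grid
    max_dose = float(dose.dose.max())
    scaling = max(max_dose, 1.0) / (2**31 - 1)
    stored = np.round(dose.dose / scaling).astype(np.uint32)

    ds = Dataset()
    ds.SOPClassUID = _RTDOSE_SOP
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.ImagePositionPatient = [grid.origin[0], grid.origin[1], grid.origin[2]]
    ds.ImageOrientationPatient = list(_IDENTITY_ORIENT)
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]  # (dy, dx)
    ds.GridFrameOffsetVector = [grid.spacing[2] * k for k in range(grid.shape[2])]
    ds.DoseGridScaling = scaling
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = grid.shape[2]
    ds.Rows = grid.shape[1]
    ds.Columns = grid.shape[0]
    ds.FrameOfReferenceUID = generate_uid()
    ds.PixelData = np.ascontiguousarray(stored.transpose(2, 1, 0)).tobytes()

    ds.file_meta = _file_meta(_RTDOSE_SOP, ds.SOPInstanceUID)
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


# ---------------------------------------------------------------------------
# RT Structure Set

_CLASS_TO_TYPE = {
    OrganClass.TARGET: "CTV",
    OrganClass.GI_OAR: "ORGAN",
    OrganClass.OTHER: "AVOIDANCE",
}
_TYPE_TO_CLASS = {v: k for k, v in _CLASS_TO_TYPE.items()}


def read_rtstruct(path: str | Path) -> StructureSet:
    """Read a DICOM RT Structure Set with planar contours.

    Contours with fewer than 3 vertices are rejected with a warning; a file
    yielding zero usable ROIs is a format error, as is a duplicate ROI name.
    ROI order follows the file.
    """
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "SOPClassUID", None) != _RTSTRUCT_SOP and getattr(ds, "Modality", "") != "RTSTRUCT":
        raise FormatError(f"{path} is not an RT Structure Set object")
    roi_names: dict[int, str] = {}
    for roi in _require(ds, "StructureSetROISequence"):
        num = int(roi.ROINumber)
        name = str(roi.ROIName)
        if name in roi_names.values():
            raise FormatError(f"duplicate ROI name {name!r}")
        roi_names[num] = name
    roi_class: dict[int, OrganClass] = {}
    for obs in getattr(ds, "RTROIObservationsSequence", []):
        num = int(obs.ReferencedROINumber)
        rt_type = str(getattr(obs, "RTROIInterpretedType", ""))
        roi_class[num] = _TYPE_TO_CLASS.get(rt_type, OrganClass.OTHER)

    structures: list[Structure] = []
    for roi_contour in _require(ds, "ROIContourSequence"):
        num = int(roi_contour.ReferencedROINumber)
        name = roi_names.get(num, f"roi_{num}")
        by_z: dict[float, list[np.ndarray]] = {}
        for contour in getattr(roi_contour, "ContourSequence", []):
            data = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            if data.shape[0] < 3:
                log.warning(
                    "ROI %r: contour with %d vertices rejected", name, data.shape[0]
                )
                continue
            z = round(float(data[0, 2]), 6)
            by_z.setdefault(z, []).append(data[:, :2])
        if not by_z:
            log.warning("ROI %r has no usable contours; skipped", name)
            continue
        contours = sorted(by_z.items(), key=lambda t: t[0])
        structures.append(
            Structure(name, roi_class.get(num, OrganClass.OTHER), list(contours))
        )
    if not structures:
        raise FormatError(f"{path} contains no usable ROIs")
    return StructureSet(structures)


def write_rtstruct(
    structures: StructureSet, grid: ImageGrid3D, path: str | Path
) -> None:
    """Write a :class:`StructureSet` as a standard RT Structure Set."""
    if len(structures) == 0:
        raise ValueError("refusing to write an empty structure set")
    frame_uid = generate_uid()
    ds = Dataset()
    ds.SOPClassUID = _RTSTRUCT_SOP
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "adaptdose"

    roi_seq, contour_seq, obs_seq = [], [], []
    for num, s in enumerate(structures, start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = s.name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = num
        cseq = []
        for z, polys in s.contours:
            for p in polys:
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = len(p)
                pts = np.column_stack([p, np.full(len(p), z)])
                c.ContourData = [f"{v:.6f}" for v in pts.ravel()]
                cseq.append(c)
        rc.ContourSequence = cseq
        contour_seq.append(rc)

        obs = Dataset()
        obs.ObservationNumber = num
        obs.ReferencedROINumber = num
        obs.RTROIInterpretedType = _CLASS_TO_TYPE[s.organ_class]
        obs.ROIInterpreter = ""
        obs_seq.append(obs)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq
    ds.file_meta = _file_meta(_RTSTRUCT_SOP, ds.SOPInstanceUID)
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


# ---------------------------------------------------------------------------
# Native case bundle


def _anatomy_manifest(anatomy: StructureSet) -> list[dict]:
    return [
        {
            "name": s.name,
            "organ_class": s.organ_class.value,
            "n_slices": len(s.contours),
        }
        for s in anatomy
    ]


def _pack_anatomy(prefix: str, anatomy: StructureSet, arrays: dict) -> None:
    for s in anatomy:
        for i, (z, polys) in enumerate(s.contours):
            for j, p in enumerate(polys):
                key = f"{prefix}/{s.name}/{i:04d}/{j:02d}"
                arrays[key] = np.column_stack([p, np.full(len(p), z)])


def _unpack_anatomy(
    prefix: str, manifest: list[dict], arrays: dict
) -> StructureSet:
    structures = []
    for entry in manifest:
        name = entry["name"]
        keys = sorted(k for k in arrays if k.startswith(f"{prefix}/{name}/"))
        if not keys:
            raise ConsistencyError(
                f"organ {name!r} listed in manifest but absent from arrays"
            )
        by_slice: dict[str, list[np.ndarray]] = {}
        for k in keys:
            by_slice.setdefault(k.rsplit("/", 1)[0], []).append(arrays[k])
        if len(by_slice) != int(entry["n_slices"]):
            raise ConsistencyError(
                f"organ {name!r}: manifest lists {entry['n_slices']} slices, "
                f"arrays hold {len(by_slice)}"
            )
        contours = []
        for _, polys in sorted(by_slice.items()):
            z = float(polys[0][0, 2])
            contours.append((z, [p[:, :2] for p in polys]))
        structures.append(
            Structure(name, OrganClass(entry["organ_class"]), contours)
        )
    return StructureSet(structures)


def write_bundle(case: CaseBundle, path: str | Path) -> None:
    """Write a :class:`CaseBundle` as ``manifest.yaml`` + ``arrays.npz``.

    The round trip is exact for dose arrays and vertex coordinates.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    grid = case.grid
    manifest = {
        "format": "adaptdose-bundle",
        "version": 1,
        "patient_id": case.patient_id,
        "fraction_index": case.fraction_index,
        "grid": {
            "origin": list(grid.origin),
            "spacing": list(grid.spacing),
            "shape": list(grid.shape),
        },
        "pre_anatomy": _anatomy_manifest(case.pre_anatomy),
        "post_anatomy": _anatomy_manifest(case.post_anatomy),
        "metadata": dict(case.metadata),
    }
    arrays: dict[str, np.ndarray] = {
        "scheduled_dose": case.scheduled_dose.dose,
        "adapted_dose": case.adapted_dose.dose,
    }
    _pack_anatomy("pre", case.pre_anatomy, arrays)
    _pack_anatomy("post", case.post_anatomy, arrays)
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    np.savez_compressed(path / "arrays.npz", **arrays)


def read_bundle(path: str | Path) -> CaseBundle:
    """Read a native case bundle written by :func:`write_bundle`."""
    path = Path(path)
    manifest_path = path / "manifest.yaml"
    if not manifest_path.exists():
        raise FormatError(f"{path} is not a case bundle (no manifest.yaml)")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if manifest.get("format") != "adaptdose-bundle":
        raise FormatError(f"{manifest_path} is not an adaptdose bundle manifest")
    with np.load(path / "arrays.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    for key in ("scheduled_dose", "adapted_dose"):
        if key not in arrays:
            raise ConsistencyError(f"array {key!r} missing from bundle")
    g = manifest["grid"]
    grid = ImageGrid3D(tuple(g["origin"]), tuple(g["spacing"]), tuple(g["shape"]))
    pre = _unpack_anatomy("pre", manifest["pre_anatomy"], arrays)
    post = _unpack_anatomy("post", manifest["post_anatomy"], arrays)
    return CaseBundle(
        patient_id=str(manifest["patient_id"]),
        fraction_index=int(manifest["fraction_index"]),
        pre_anatomy=pre,
        post_anatomy=post,
        scheduled_dose=DoseGrid(grid, arrays["scheduled_dose"]),
        adapted_dose=DoseGrid(grid, arrays["adapted_dose"]),
        metadata=manifest.get("metadata", {}),
    )
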
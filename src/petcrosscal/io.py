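"""Reading image series and reading/writing calibration-record tables.

``read_series`` accepts a directory of single-frame DICOM files (PET or
CT) or a NIfTI volume with its JSON sidecar as written by the simulator.
Slices are sorted by physical position, rescale slope/intercept applied,
and geometry and timing recorded; missing geometry is an error, never a
default.

Calibration records are persisted as a CSV with a fixed, documented column
order plus a JSON sidecar carrying the full per-record metadata (including
ROI provenance), so a round trip is lossless.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import RecordMismatchError, SeriesReadError
from .metrics import CalibrationRecord
from .volume import ImageVolume

__all__ = ["read_series", "write_records", "read_records", "RECORD_COLUMNS"]

#: documented column order of the records CSV
RECORD_COLUMNS = [
    "site_id",
    "scanner_id",
    "dose_calibrator_id",
    "measurement_datetime",
    "phantom_r",
    "dose_calibrator_r",
    "suv_bias",
    "acf",
    "phantom_age_days",
    "roi_mean",
    "roi_sd",
    "roi_max",
    "roi_min",
    "roi_n_voxels",
    "roi_u_percent",
]

RECORDS_SCHEMA_VERSION = 1

_DICOM_UNITS = {"BQML": "Bq/mL", "KBQML": "kBq/mL", "GML": "SUV"}


def _parse_dicom_dt(value: str) -> Optional[datetime]:
    if not value:
        return None
    for fmt in ("%Y%m%d%H%M%S.%f%z", "%Y%m%d%H%M%S%z", "%Y%m%d%H%M%S.%f", "%Y%m%d%H%M%S"):
        try:
            return datetime.strptime(str(value), fmt)
        except ValueError:
            continue
    return None


def read_series(path: Union[str, Path]) -> ImageVolume:
    """Read one coherent image series into an :class:`ImageVolume`.

    ``path`` is a directory of ``.dcm`` slice files (one series), a
    directory holding one NIfTI volume, or a NIfTI file itself.
    """
    path = Path(path)
    if not path.exists():
        raise SeriesReadError(f"no such series path: {path}")
    if path.is_file():
        if path.name.endswith((".nii", ".nii.gz")):
            return _read_nifti(path)
        raise SeriesReadError(f"unrecognized series file: {path}")
    dcm_files = sorted(path.glob("*.dcm"))
    if dcm_files:
        return _read_dicom_series(dcm_files)
    nii_files = sorted(p for p in path.iterdir() if p.name.endswith((".nii", ".nii.gz")))
    if len(nii_files) == 1:
        return _read_nifti(nii_files[0])
    raise SeriesReadError(
        f"directory {path} holds neither a DICOM series nor a single NIfTI volume"
    )


def _read_nifti(nii_path: Path) -> ImageVolume:
    import nibabel as nib

    img = nib.load(nii_path)
    affine = img.affine
    # simulator writes axis-aligned affines; anything else is out of scope here
    if not np.allclose(affine[:3, :3], np.diag(np.diag(affine[:3, :3]))):
        raise SeriesReadError(f"{nii_path}: only axis-aligned volumes are supported")
    spacing = tuple(float(affine[i, i]) for i in range(3))
    if any(s <= 0 for s in spacing):
        raise SeriesReadError(f"{nii_path}: non-positive voxel spacing in affine")
    origin = tuple(float(affine[i, 3]) for i in range(3))
    sidecar_path = nii_path.parent / (nii_path.name.split(".")[0] + ".json")
    if not sidecar_path.exists():
        raise SeriesReadError(
            f"{nii_path}: missing JSON sidecar with modality/units/timestamps"
        )
    side = json.loads(sidecar_path.read_text())
    # sidecar geometry is authoritative (full precision); the float32 NIfTI
    # header must agree with it to single-precision accuracy
    if "spacing_mm" in side:
        exact_spacing = tuple(float(s) for s in side["spacing_mm"])
        exact_origin = tuple(float(o) for o in side["origin_mm"])
        if not np.allclose(exact_spacing, spacing, rtol=1e-5) or not np.allclose(
            exact_origin, origin, rtol=1e-5, atol=1e-3
        ):
            raise SeriesReadError(f"{nii_path}: sidecar geometry contradicts the header")
        spacing, origin = exact_spacing, exact_origin
    acq = side.get("acquisition_datetime")
    ref = side.get("decay_reference_datetime")
    return ImageVolume(
        values=np.asarray(img.dataobj, dtype=float),
        spacing=spacing,
        origin=origin,
        modality=side["modality"],
        value_units=side["value_units"],
        acquisition_datetime=datetime.fromisoformat(acq) if acq else None,
        decay_reference_datetime=datetime.fromisoformat(ref) if ref else None,
        meta=side.get("meta", {}),
    )


def _read_dicom_series(files: Sequence[Path]) -> ImageVolume:
    import pydicom

    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:  # pragma: no cover - corrupt input path
            raise SeriesReadError(f"cannot read {f}: {exc}") from exc
        slices.append(ds)

    series_uids = {ds.SeriesInstanceUID for ds in slices}
    if len(series_uids) != 1:
        raise SeriesReadError(
            f"directory mixes {len(series_uids)} series; point at a single series"
        )
    for ds in slices:
        if "PixelSpacing" not in ds or "ImagePositionPatient" not in ds:
            raise SeriesReadError("slice lacks PixelSpacing or ImagePositionPatient")

    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    z = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(slices) > 1:
        gaps = np.diff(z)
        if gaps.min() <= 0:
            raise SeriesReadError("duplicate or non-increasing slice positions")
        if (gaps.max() - gaps.min()) > 0.01 * gaps.mean():
            raise SeriesReadError(
                f"inconsistent slice spacing ({gaps.min():.4g}..{gaps.max():.4g} mm)"
            )
        dz = float(gaps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 0) or 0)
        if dz <= 0:
            raise SeriesReadError("single-slice series without SliceThickness")

    first = slices[0]
    sy, sx = (float(v) for v in first.PixelSpacing)  # row spacing, column spacing
    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(float) * slope + intercept)
    # DICOM planes are (row=y, col=x); volume axis order is (x, y, z)
    values = np.transpose(np.stack(planes, axis=0), (2, 1, 0))

    modality = {"PT": "PET", "CT": "CT"}.get(first.Modality)
    if modality is None:
        raise SeriesReadError(f"unsupported modality {first.Modality!r}")
    if modality == "CT":
        units = "HU"
    else:
        units = _DICOM_UNITS.get(str(getattr(first, "Units", "")), None)
        if units is None:
            raise SeriesReadError(
                f"PET series lacks a recognized Units tag (got {getattr(first, 'Units', None)!r})"
            )

    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        float(z[0]),
    )
    meta: dict = {}
    comments = getattr(first, "ImageComments", "")
    if comments:
        try:
            meta = json.loads(comments)
        except (json.JSONDecodeError, TypeError):
            meta = {"image_comments": str(comments)}
    return ImageVolume(
        values=values,
        spacing=(sx, sy, dz),
        origin=origin,
        modality=modality,
        value_units=units,
        acquisition_datetime=_parse_dicom_dt(getattr(first, "AcquisitionDateTime", "")),
        decay_reference_datetime=_parse_dicom_dt(
            getattr(first, "DecayCorrectionDateTime", "")
        ),
        meta=meta,
    )


def _record_row(rec: CalibrationRecord) -> dict:
    roi = rec.roi or {}
    return {
        "site_id": rec.site_id,
        "scanner_id": rec.scanner_id,
        "dose_calibrator_id": rec.dose_calibrator_id,
        "measurement_datetime": rec.measurement_datetime.isoformat(),
        "phantom_r": rec.phantom_r,
        "dose_calibrator_r": rec.dose_calibrator_r,
        "suv_bias": rec.suv_bias,
        "acf": rec.acf,
        "phantom_age_days": rec.phantom_age_days,
        "roi_mean": roi.get("mean"),
        "roi_sd": roi.get("sd"),
        "roi_max": roi.get("max"),
        "roi_min": roi.get("min"),
        "roi_n_voxels": roi.get("n_voxels"),
        "roi_u_percent": roi.get("u_percent"),
    }


def write_records(records: Sequence[CalibrationRecord], path: Union[str, Path]) -> Path:
    """Write records as CSV (columns :data:`RECORD_COLUMNS`) plus a JSON sidecar.

    The sidecar (``<name>.json``) carries the schema version and the full
    record dictionaries, including ROI provenance that has no CSV column.
    An empty record list produces a header-only CSV.  Output depends only
    on the records, so identical inputs give byte-identical files.
    """
    path = Path(path)
    df = pd.DataFrame([_record_row(r) for r in records], columns=RECORD_COLUMNS)
    df.to_csv(path, index=False)
    sidecar = {
        "schema_version": RECORDS_SCHEMA_VERSION,
        "records": [
            {**_record_row(r), "roi": r.roi, "measurement_datetime": r.measurement_datetime.isoformat()}
            for r in records
        ],
    }
    side_path = path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_records(path: Union[str, Path]) -> list[CalibrationRecord]:
    """Read records back from CSV (+ sidecar if present); lossless round trip.

    Each record's SUV bias is recomputed from its recovery coefficients at
    construction time; a mismatch raises :class:`RecordMismatchError`.
    """
    path = Path(path)
    if not path.exists():
        raise SeriesReadError(f"records file not found: {path}")
    df = pd.read_csv(path)
    rois: dict[int, Optional[dict]] = {}
    side_path = path.with_suffix(".json")
    if side_path.exists():
        side = json.loads(side_path.read_text())
        for i, entry in enumerate(side.get("records", [])):
            rois[i] = entry.get("roi")
    records = []
    for i, row in df.iterrows():
        rec = CalibrationRecord(
            site_id=str(row["site_id"]),
            scanner_id=str(row["scanner_id"]),
            dose_calibrator_id=str(row["dose_calibrator_id"]),
            measurement_datetime=datetime.fromisoformat(row["measurement_datetime"]),
            phantom_r=float(row["phantom_r"]),
            dose_calibrator_r=float(row["dose_calibrator_r"]),
            acf=float(row["acf"]) if pd.notna(row["acf"]) else None,
            phantom_age_days=float(row["phantom_age_days"])
            if pd.notna(row["phantom_age_days"])
            else None,
            roi=rois.get(i),
        )
        # the CSV stores the bias at text precision; verify it against the
        # exact recomputation (which the constructor already performed)
        if pd.notna(row["suv_bias"]):
            stored = float(row["suv_bias"])
            if abs(stored - rec.suv_bias) > 1e-9 + 1e-9 * abs(rec.suv_bias):
                raise RecordMismatchError(
                    f"row {i}: stored SUV bias {stored!r} does not match "
                    f"R_P/R_D - 1 = {rec.suv_bias!r}"
                )
        records.append(rec)
    return records
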
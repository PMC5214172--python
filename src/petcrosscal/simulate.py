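"""Synthetic phantom scenes and rendered PET/CT volumes.

The simulator emulates a sealed cylindrical calibration insert (45 mm
diameter and height, nominally 250 kBq/mL) mounted inside a 20-cm
water-filled flood cylinder, imaged on one of two reconstruction grids
(5.5 x 5.5 x 3.3 mm or 2.7 x 2.7 x 3.3 mm voxels) and smoothed with an
anisotropic Gaussian point-spread function (8 mm FWHM transaxially,
4.6 mm axially).  It produces ground-truth activity maps, a companion
CT-like volume in HU, optional measurement noise, mispositioning
(translation / rotation about the flood axis), and writes series the
reader round-trips — so the whole analysis chain runs with no scanner.

It deliberately does not model tomographic reconstruction, attenuation or
scatter physics; a single multiplicative ``recon_bias`` knob stands in
for such net calibration effects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, GeometryError
from .volume import ImageVolume

__all__ = [
    "PhantomScene",
    "PsfSpec",
    "NoiseSpec",
    "BATCH1_SPACING",
    "BATCH2_SPACING",
    "build_scene",
    "apply_psf",
    "add_noise",
    "misposition",
    "render_series",
    "simulate_measurement",
]

#: coarse reconstruction grid (first production batch)
BATCH1_SPACING = (5.5, 5.5, 3.3)
#: fine reconstruction grid (second production batch)
BATCH2_SPACING = (2.7, 2.7, 3.3)

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...

_BACKGROUND_MEDIA = {"water", "air", "activity"}


@dataclass(frozen=True)
class PhantomScene:
    """Ground-truth geometry and activity of the mounted phantom.

    ``background_medium`` sets what fills the flood cylinder: plain water
    (no activity), air, or radioactive water ("activity", defaulting to
    15% of the insert's concentration).  ``phantom_center_mm`` of ``None``
    centers the insert on the grid; ``rotation_deg`` rotates the insert's
    position about the flood cylinder's axis (the insert itself is
    rotationally symmetric about its own axis).
    """

    active_diameter_mm: float = 45.0
    active_height_mm: float = 45.0
    active_concentration_kbq_ml: float = 250.0
    flood_diameter_mm: float = 200.0
    flood_height_mm: float = 120.0
    background_medium: str = "water"
    background_concentration_kbq_ml: Optional[float] = None
    phantom_center_mm: Optional[tuple[float, float, float]] = None
    rotation_deg: float = 0.0
    voxel_spacing: tuple[float, float, float] = BATCH2_SPACING
    grid_shape: tuple[int, int, int] = (84, 84, 46)
    recon_bias: float = 1.0
    hu_water: float = 0.0
    hu_epoxy: float = 150.0
    hu_air: float = -1000.0

    def __post_init__(self) -> None:
        for name in ("active_diameter_mm", "active_height_mm", "flood_diameter_mm",
                     "flood_height_mm"):
            if not (getattr(self, name) > 0):
                raise ConfigurationError(f"{name} must be > 0")
        if self.background_medium not in _BACKGROUND_MEDIA:
            raise ConfigurationError(
                f"background_medium must be one of {sorted(_BACKGROUND_MEDIA)}"
            )
        if self.background_concentration_kbq_ml is not None and (
            self.background_concentration_kbq_ml < 0
        ):
            raise ConfigurationError("background concentration must be >= 0")
        if not (self.recon_bias > 0):
            raise ConfigurationError("recon_bias must be > 0")

    @property
    def origin_mm(self) -> tuple[float, float, float]:
        """Grid origin (center of voxel 0,0,0) placing the grid center at (0,0,0)."""
        return tuple(
            -(n - 1) / 2.0 * s for n, s in zip(self.grid_shape, self.voxel_spacing)
        )

    @property
    def background_kbq_ml(self) -> float:
        """Effective background activity concentration for the chosen medium."""
        if self.background_medium in ("water", "air"):
            return 0.0
        if self.background_concentration_kbq_ml is not None:
            return self.background_concentration_kbq_ml
        return 0.15 * self.active_concentration_kbq_ml

    @property
    def effective_center_mm(self) -> tuple[float, float, float]:
        """Insert center after applying the rotation about the flood axis."""
        cx, cy, cz = self.phantom_center_mm if self.phantom_center_mm is not None else (0.0, 0.0, 0.0)
        if self.rotation_deg:
            th = math.radians(self.rotation_deg)
            cx, cy = cx * math.cos(th) - cy * math.sin(th), cx * math.sin(th) + cy * math.cos(th)
        return (cx, cy, cz)


@dataclass(frozen=True)
class PsfSpec:
    """Anisotropic Gaussian point-spread function, FWHM in mm per axis class."""

    fwhm_transaxial_mm: float = 8.0
    fwhm_axial_mm: float = 4.6

    def __post_init__(self) -> None:
        if self.fwhm_transaxial_mm < 0 or self.fwhm_axial_mm < 0:
            raise ConfigurationError("PSF FWHMs must be >= 0")

    def sigmas_mm(self) -> tuple[float, float, float]:
        s_t = self.fwhm_transaxial_mm / _FWHM_TO_SIGMA
        s_a = self.fwhm_axial_mm / _FWHM_TO_SIGMA
        return (s_t, s_t, s_a)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model applied to a rendered volume.

    ``gaussian``: i.i.d. noise with SD = ``magnitude`` x the plateau value
    (the volume's 99.9th percentile).  ``scaled-poisson``: voxel values are
    scaled so the plateau corresponds to ``magnitude`` counts, Poisson
    sampled, and scaled back.  The default magnitude (0.01 for gaussian,
    i.e. 1% of plateau) is calibrated so the intra-ROI uniformity metric u
    on default smoothed scenes lands in the ~1% range observed on real
    reconstructions.  ``seed`` is mandatory for any stochastic model and
    recorded in the output metadata.
    """

    model: str = "gaussian"
    magnitude: float = 0.01
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.model not in {"none", "gaussian", "scaled-poisson"}:
            raise ConfigurationError(f"unknown noise model {self.model!r}")
        if self.magnitude < 0:
            raise ConfigurationError("noise magnitude must be >= 0")


def _cylinder_fraction(
    scene: PhantomScene,
    center: Sequence[float],
    radius: float,
    half_height: float,
    subsample: int = 2,
) -> np.ndarray:
    """Fractional voxel occupancy of an axial cylinder via sub-voxel sampling.

    Each voxel is probed at ``subsample**3`` regularly spaced interior
    points (2x2x2 by default: cheap, and accurate enough because analysis
    ROIs keep away from object edges).
    """
    shape = scene.grid_shape
    spacing = np.asarray(scene.voxel_spacing)
    origin = np.asarray(scene.origin_mm)
    offsets = (np.arange(subsample) + 0.5) / subsample - 0.5  # fractions of a voxel
    frac = np.zeros(shape, dtype=float)
    ax_x = origin[0] + np.arange(shape[0]) * spacing[0]
    ax_y = origin[1] + np.arange(shape[1]) * spacing[1]
    ax_z = origin[2] + np.arange(shape[2]) * spacing[2]
    r2 = radius * radius
    for ox in offsets:
        dx2 = (ax_x + ox * spacing[0] - center[0]) ** 2
        for oy in offsets:
            dy2 = (ax_y + oy * spacing[1] - center[1]) ** 2
            in_disk = dx2[:, None] + dy2[None, :] <= r2
            for oz in offsets:
                in_z = np.abs(ax_z + oz * spacing[2] - center[2]) <= half_height
                frac += in_disk[:, :, None] & in_z[None, None, :]
    frac /= subsample**3
    return frac


def build_scene(
    scene: PhantomScene,
    acquisition_datetime: Optional[datetime] = None,
) -> tuple[ImageVolume, ImageVolume]:
    """Render ground-truth PET (kBq/mL) and companion CT (HU) volumes.

    Interior voxels of the active insert hold exactly the scene's
    concentration (times ``recon_bias``); boundary voxels hold the
    partial-volume fraction.  The CT assigns configured HU to the flood
    medium, the epoxy insert and the air outside the flood cylinder.
    """
    center = scene.effective_center_mm
    r_active = scene.active_diameter_mm / 2.0
    r_flood = scene.flood_diameter_mm / 2.0
    # active insert must stay inside the flood cylinder
    radial = math.hypot(center[0], center[1])
    if radial + r_active > r_flood or (
        abs(center[2]) + scene.active_height_mm / 2.0 > scene.flood_height_mm / 2.0
    ):
        raise GeometryError("active insert extends outside the flood phantom")
    # grid must cover the flood phantom
    half_extent = [
        (n - 1) / 2.0 * s + s / 2.0 for n, s in zip(scene.grid_shape, scene.voxel_spacing)
    ]
    if r_flood > half_extent[0] or r_flood > half_extent[1] or (
        scene.flood_height_mm / 2.0 > half_extent[2]
    ):
        raise GeometryError("grid does not cover the flood phantom")

    active = _cylinder_fraction(scene, center, r_active, scene.active_height_mm / 2.0)
    flood = _cylinder_fraction(scene, (0.0, 0.0, 0.0), r_flood, scene.flood_height_mm / 2.0)
    flood = np.maximum(flood, active)  # insert is inside the flood by construction

    bg = scene.background_kbq_ml
    pet_values = scene.recon_bias * (
        active * scene.active_concentration_kbq_ml + (flood - active) * bg
    )

    medium_hu = scene.hu_air if scene.background_medium == "air" else scene.hu_water
    ct_values = (
        scene.hu_air
        + flood * (medium_hu - scene.hu_air)
        + active * (scene.hu_epoxy - medium_hu)
    )

    when = acquisition_datetime or datetime(2013, 4, 1, 12, 0, tzinfo=timezone.utc)
    meta = {"scene": "synthetic", "background_medium": scene.background_medium}
    pet = ImageVolume(
        values=pet_values,
        spacing=scene.voxel_spacing,
        origin=scene.origin_mm,
        modality="PET",
        value_units="kBq/mL",
        acquisition_datetime=when,
        decay_reference_datetime=when,
        meta=dict(meta),
    )
    ct = ImageVolume(
        values=ct_values,
        spacing=scene.voxel_spacing,
        origin=scene.origin_mm,
        modality="CT",
        value_units="HU",
        acquisition_datetime=when,
        meta=dict(meta),
    )
    return pet, ct


def apply_psf(vol: ImageVolume, psf: PsfSpec) -> ImageVolume:
    """Separable Gaussian smoothing with per-axis FWHM converted to voxel units."""
    sigmas_vox = [s / sp for s, sp in zip(psf.sigmas_mm(), vol.spacing)]
    if all(s == 0 for s in sigmas_vox):
        return replace(vol, values=vol.values.copy(), meta=dict(vol.meta))
    smoothed = ndimage.gaussian_filter(vol.values, sigma=sigmas_vox, mode="constant")
    meta = dict(vol.meta)
    meta["psf_fwhm_mm"] = [psf.fwhm_transaxial_mm, psf.fwhm_transaxial_mm, psf.fwhm_axial_mm]
    return replace(vol, values=smoothed, meta=meta)


def add_noise(vol: ImageVolume, noise: NoiseSpec) -> ImageVolume:
    """Apply the configured noise model; reproducible given (model, magnitude, seed)."""
    if noise.model == "none" or noise.magnitude == 0:
        return replace(vol, values=vol.values.copy(), meta=dict(vol.meta))
    if noise.seed is None:
        raise ConfigurationError("stochastic noise models require a seed")
    rng = np.random.default_rng(noise.seed)
    plateau = float(np.percentile(vol.values, 99.9))
    if plateau <= 0:
        plateau = float(np.abs(vol.values).max()) or 1.0
    if noise.model == "gaussian":
        out = vol.values + rng.normal(0.0, noise.magnitude * plateau, size=vol.shape)
    else:  # scaled-poisson: plateau maps to `magnitude` expected counts
        lam = np.clip(vol.values, 0.0, None) * (noise.magnitude / plateau)
        out = rng.poisson(lam).astype(float) * (plateau / noise.magnitude)
    meta = dict(vol.meta)
    meta["noise"] = {"model": noise.model, "magnitude": noise.magnitude, "seed": noise.seed}
    return replace(vol, values=out, meta=meta)


def misposition(
    scene: PhantomScene,
    translation_mm: Sequence[float] = (0.0, 0.0, 0.0),
    rotation_deg: float = 0.0,
) -> PhantomScene:
    """New scene with the insert translated and/or rotated about the flood axis.

    "Directly upward" in the field of view is the transaxial-y axis.  The
    transformed insert must stay inside the flood phantom (checked when
    the scene is rendered, and eagerly here).
    """
    if not any(translation_mm) and rotation_deg == 0.0:
        return scene
    base = scene.phantom_center_mm if scene.phantom_center_mm is not None else (0.0, 0.0, 0.0)
    moved = replace(
        scene,
        phantom_center_mm=tuple(b + t for b, t in zip(base, translation_mm)),
        rotation_deg=scene.rotation_deg + rotation_deg,
    )
    center = moved.effective_center_mm
    if math.hypot(center[0], center[1]) + moved.active_diameter_mm / 2.0 > (
        moved.flood_diameter_mm / 2.0
    ) or abs(center[2]) + moved.active_height_mm / 2.0 > moved.flood_height_mm / 2.0:
        raise GeometryError("mispositioned insert leaves the flood phantom")
    return moved


def simulate_measurement(
    scene: PhantomScene,
    psf: PsfSpec = PsfSpec(),
    noise: NoiseSpec = NoiseSpec(model="none", magnitude=0.0),
    acquisition_datetime: Optional[datetime] = None,
) -> tuple[ImageVolume, ImageVolume]:
    """Standard rendering chain: build, smooth, then add measurement noise.

    The noise model applies to the smoothed (reconstruction-like) image,
    mirroring where the residual voxel noise of an averaged reconstruction
    lives; the CT companion stays noiseless.
    """
    pet, ct = build_scene(scene, acquisition_datetime=acquisition_datetime)
    pet = apply_psf(pet, psf)
    pet = add_noise(pet, noise)
    return pet, ct


def _dt_to_dicom(dt: datetime) -> str:
    return dt.strftime("%Y%m%d%H%M%S.%f%z")


def render_series(vol: ImageVolume, out_dir, format: str = "dicom") -> list[Path]:
    """Write a volume as an image series readable by :func:`petcrosscal.io.read_series`.

    ``format="dicom"`` writes one minimal-but-valid single-frame file per
    slice (activity stored in Bq/mL with a 16-bit rescale, so values
    round-trip within 0.1% of the volume maximum); ``format="nifti"``
    writes a float32 NIfTI plus a JSON sidecar carrying modality, units,
    timestamps and provenance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if format == "nifti":
        return _write_nifti(vol, out_dir)
    if format == "dicom":
        return _write_dicom(vol, out_dir)
    raise ConfigurationError(f"unknown series format {format!r}")


def _write_nifti(vol: ImageVolume, out_dir: Path) -> list[Path]:
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.values.astype(np.float32), affine)
    img.header.set_xyzt_units("mm")
    nii_path = out_dir / "volume.nii.gz"
    nib.save(img, nii_path)
    sidecar = {
        # geometry at full precision (the NIfTI header stores float32)
        "spacing_mm": list(vol.spacing),
        "origin_mm": list(vol.origin),
        "modality": vol.modality,
        "value_units": vol.value_units,
        "acquisition_datetime": vol.acquisition_datetime.isoformat()
        if vol.acquisition_datetime
        else None,
        "decay_reference_datetime": vol.decay_reference_datetime.isoformat()
        if vol.decay_reference_datetime
        else None,
        "meta": vol.meta,
    }
    json_path = out_dir / "volume.json"
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return [nii_path, json_path]


def _write_dicom(vol: ImageVolume, out_dir: Path) -> list[Path]:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import (
        CTImageStorage,
        ExplicitVRLittleEndian,
        PositronEmissionTomographyImageStorage,
        generate_uid,
    )

    is_pet = vol.modality == "PET"
    if is_pet:
        if vol.value_units == "kBq/mL":
            stored = vol.values * 1000.0  # store Bq/mL (BQML)
        elif vol.value_units == "Bq/mL":
            stored = vol.values
        else:
            raise ConfigurationError(
                f"DICOM PET writer needs activity units, got {vol.value_units!r}"
            )
        vmax = float(stored.max())
        slope = vmax / 60000.0 if vmax > 0 else 1.0
        intercept = 0.0
        pixels = np.round(stored / slope).astype(np.uint16)
    else:
        stored = vol.values
        slope, intercept = 1.0, -1024.0
        pixels = np.round(np.clip(stored - intercept, 0, 65535)).astype(np.uint16)

    series_uid = generate_uid()
    frame_uid = generate_uid()
    study_uid = generate_uid()
    nx, ny, nz = vol.shape
    paths = []
    for k in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = (
            PositronEmissionTomographyImageStorage if is_pet else CTImageStorage
        )
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "PT" if is_pet else "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = "PHANTOM^SYNTHETIC"
        ds.PatientID = "SYNTH"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            vol.origin[0],
            vol.origin[1],
            vol.origin[2] + k * vol.spacing[2],
        ]
        ds.PixelSpacing = [vol.spacing[1], vol.spacing[0]]  # row (y), column (x)
        ds.SliceThickness = vol.spacing[2]
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        if vol.acquisition_datetime is not None:
            ds.AcquisitionDateTime = _dt_to_dicom(vol.acquisition_datetime)
        if is_pet:
            ds.Units = "BQML"
            if vol.decay_reference_datetime is not None:
                ds.DecayCorrectionDateTime = _dt_to_dicom(vol.decay_reference_datetime)
        if vol.meta:
            ds.ImageComments = json.dumps(vol.meta, sort_keys=True)[:1024]
        ds.PixelData = np.ascontiguousarray(pixels[:, :, k].T).tobytes()
        path = out_dir / f"slice_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
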
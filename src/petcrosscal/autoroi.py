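"""Automated phantom ROI extraction and PET/CT alignment checking.

The analysis is fully automatic: the compact hot region of the phantom is
located with no user intervention, and a region of interest of only whole
voxels fitting inside a cubic bounding box (default 15 mm side) is placed
at the detected center.  The box is deliberately small and central so the
ROI mean is insensitive to partial-volume losses at the phantom edges.

Center finding: take a robust maximum (high percentile, so single hot
voxels cannot dominate), threshold at a fraction of it, keep the largest
26-connected component above a minimum physical volume, and return its
intensity-weighted centroid in physical space.  All knobs are exposed via
:class:`RoiConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import AnalysisError, GeometryError, PhantomNotFoundError
from .volume import ImageVolume

__all__ = [
    "RoiConfig",
    "RoiResult",
    "locate_active_center",
    "whole_voxel_roi",
    "roi_statistics",
    "check_alignment",
]


@dataclass(frozen=True)
class RoiConfig:
    """Knobs of the automated analysis.

    ``box_mm`` is the side length of the cubic bounding box.
    ``threshold_fraction`` of the robust maximum defines the hot-region
    mask; ``robust_max_percentile`` guards against isolated hot voxels;
    components smaller than ``min_component_ml`` are rejected as noise.
    ``ct_window_hu`` is the (exclusive-low, inclusive-high) HU window that
    isolates the epoxy/acrylic insert against water when localizing the
    phantom on CT.  ``alignment_tolerance_mm`` flags PET/CT misalignment
    in reports.
    """

    box_mm: float = 15.0
    threshold_fraction: float = 0.5
    robust_max_percentile: float = 99.9
    min_component_ml: float = 5.0
    ct_window_hu: tuple[float, float] = (0.0, 300.0)
    alignment_tolerance_mm: float = 3.0


@dataclass(frozen=True)
class RoiResult:
    """Summary statistics of one ROI, in the input volume's units.

    ``u_percent`` is the coefficient of variation of voxel values within
    the ROI (100 * sd / mean), the spatial-uniformity metric; the standard
    deviation here is the population SD over the enclosed voxel set.
    """

    mean: float
    sd: float
    max: float
    min: float
    n_voxels: int
    u_percent: Optional[float]
    value_units: str
    center_mm: tuple[float, float, float]
    box_mm: float
    index_ranges: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "max": self.max,
            "min": self.min,
            "n_voxels": self.n_voxels,
            "u_percent": self.u_percent,
            "value_units": self.value_units,
            "center_mm": list(self.center_mm),
            "box_mm": self.box_mm,
            "index_ranges": [list(r) for r in self.index_ranges],
        }


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _largest_component_centroid(
    weights: np.ndarray, mask: np.ndarray, vol: ImageVolume, min_component_ml: float
) -> np.ndarray:
    """Intensity-weighted centroid (mm) of the largest 26-connected mask component."""
    if not mask.any():
        raise PhantomNotFoundError("no voxel above the detection threshold")
    labels, n_labels = ndimage.label(mask, structure=_CONN26)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n_labels + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] * vol.voxel_volume_ml < min_component_ml:
        raise PhantomNotFoundError(
            f"largest connected component is {sizes[best - 1] * vol.voxel_volume_ml:.2f} mL, "
            f"below the {min_component_ml} mL minimum: phantom not found"
        )
    component = labels == best
    w = np.where(component, weights, 0.0)
    total = w.sum()
    if total <= 0:
        raise PhantomNotFoundError("detected component has no positive signal")
    idx = np.asarray(ndimage.center_of_mass(w), dtype=float)
    return vol.index_to_physical(idx)


def locate_active_center(vol: ImageVolume, config: RoiConfig = RoiConfig()) -> np.ndarray:
    """Find the physical-space center (mm) of the phantom's active region.

    Works on a PET volume containing one compact hot region.  Raises
    :class:`PhantomNotFoundError` when nothing qualifies (all-zero input,
    or the hot component is smaller than ``config.min_component_ml``).
    """
    if vol.modality != "PET":
        raise AnalysisError(f"active-region detection expects a PET volume, got {vol.modality}")
    values = vol.values
    robust_max = float(np.percentile(values, config.robust_max_percentile))
    if not (robust_max > 0):
        raise PhantomNotFoundError("volume has no positive signal")
    mask = values >= config.threshold_fraction * robust_max
    return _largest_component_centroid(values, mask, vol, config.min_component_ml)


def locate_phantom_on_ct(vol: ImageVolume, config: RoiConfig = RoiConfig()) -> np.ndarray:
    """Center (mm) of the phantom insert on CT via the epoxy/acrylic HU window.

    The insert sits in water (~0 HU); a window with an exclusive lower
    bound just above water and an upper bound below bone/metal isolates
    it.  The centroid weights each in-window voxel by its HU excess above
    the window floor, so partially filled boundary voxels pull the
    estimate sub-voxel accurately when the surrounding medium sits at the
    floor (water).
    """
    if vol.modality != "CT":
        raise AnalysisError(f"CT localization expects a CT volume, got {vol.modality}")
    lo, hi = config.ct_window_hu
    mask = (vol.values > lo) & (vol.values <= hi)
    weights = np.where(mask, vol.values - lo, 0.0)
    return _largest_component_centroid(weights, mask, vol, config.min_component_ml)


def whole_voxel_roi(
    vol: ImageVolume, center_mm: Sequence[float], box_mm: float
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Select the whole voxels that fit inside a cubic box around a center.

    Along each axis ``n = floor(box_mm / spacing)`` whole voxels fit; the
    contiguous run of ``n`` voxels whose centers lie nearest the detected
    center is chosen (when the run is equidistant between two placements,
    the lower indices win).  Returns per-axis half-open index ranges
    ``((x0, x1), (y0, y1), (z0, z1))``; total voxel count is the product
    of the range lengths.
    """
    if not (box_mm > 0):
        raise GeometryError(f"box side must be > 0 mm, got {box_mm!r}")
    ranges = []
    for ax in range(3):
        spacing = vol.spacing[ax]
        # tiny epsilon so an exact integer multiple of the pitch is not
        # lost to floating-point (15 mm box / 3 mm voxels must give 5)
        n = int(math.floor(box_mm / spacing + 1e-9))
        if n < 1:
            raise GeometryError(
                f"box of {box_mm} mm holds no whole voxel along axis {ax} "
                f"(spacing {spacing} mm)"
            )
        frac = (float(center_mm[ax]) - vol.origin[ax]) / spacing
        # start index of the run whose center sits nearest the target;
        # ties (exact half-integer) resolve to the lower index
        start = int(math.ceil(frac - (n - 1) / 2.0 - 0.5))
        if start < 0 or start + n > vol.shape[ax]:
            raise GeometryError(
                f"ROI box extends outside the volume along axis {ax} "
                f"(indices [{start}, {start + n}) of {vol.shape[ax]})"
            )
        ranges.append((start, start + n))
    return tuple(ranges)  # type: ignore[return-value]


def roi_voxel_count(
    spacing: Sequence[float], box_mm: float
) -> int:
    """Number of whole voxels the cubic box holds for a given voxel pitch."""
    n_total = 1
    for s in spacing:
        n = int(math.floor(box_mm / float(s) + 1e-9))
        if n < 1:
            raise GeometryError(
                f"box of {box_mm} mm holds no whole voxel at {s} mm pitch"
            )
        n_total *= n
    return n_total


def extract_roi_values(vol: ImageVolume, roi) -> np.ndarray:
    (x0, x1), (y0, y1), (z0, z1) = roi
    return vol.values[x0:x1, y0:y1, z0:z1]


def roi_statistics(
    vol: ImageVolume,
    roi,
    center_mm: Optional[Sequence[float]] = None,
    box_mm: float = float("nan"),
) -> RoiResult:
    """Mean, SD, max, min and uniformity of the voxels in an ROI.

    The SD is the population SD (divide by N): it describes the enclosed
    voxel set itself, not an estimate from a sample.  ``u_percent`` is
    100 * sd / mean, reported only for a positive mean.
    """
    block = extract_roi_values(vol, roi)
    if block.size == 0:
        raise AnalysisError("ROI is empty")
    mean = float(block.mean())
    sd = float(block.std(ddof=0))
    u = 100.0 * sd / mean if mean > 0 else None
    if center_mm is None:
        mid = [(r[0] + r[1] - 1) / 2.0 for r in roi]
        center_mm = vol.index_to_physical(np.array(mid))
    return RoiResult(
        mean=mean,
        sd=sd,
        max=float(block.max()),
        min=float(block.min()),
        n_voxels=int(block.size),
        u_percent=u,
        value_units=vol.value_units,
        center_mm=tuple(float(c) for c in center_mm),
        box_mm=float(box_mm),
        index_ranges=tuple((int(a), int(b)) for a, b in roi),  # type: ignore[arg-type]
    )


def check_alignment(
    pet: ImageVolume, ct: ImageVolume, config: RoiConfig = RoiConfig()
) -> tuple[np.ndarray, bool]:
    """Offset (mm, PET minus CT) between the phantom centers of the two modalities.

    Both centers are found with the same threshold-centroid machinery (the
    CT via the epoxy HU window).  Returns the offset triple and whether its
    euclidean norm exceeds ``config.alignment_tolerance_mm``.
    """
    pet_center = locate_active_center(pet, config)
    ct_center = locate_phantom_on_ct(ct, config)
    offset = np.asarray(pet_center) - np.asarray(ct_center)
    misaligned = bool(np.linalg.norm(offset) > config.alignment_tolerance_mm)
    return offset, misaligned


def analyze_volume(
    vol: ImageVolume, config: RoiConfig = RoiConfig()
) -> RoiResult:
    """Locate the active region and extract the whole-voxel box ROI statistics."""
    center = locate_active_center(vol, config)
    roi = whole_voxel_roi(vol, center, config.box_mm)
    return roi_statistics(vol, roi, center_mm=center, box_mm=config.box_mm)
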
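"""Geometry-aware image volumes and voxel-value conversions.

Conventions (fixed, because the whole-voxel ROI rule depends on them):

* voxel indices are 0-based and the array axis order is
  ``(transaxial-x, transaxial-y, axial-z)``;
* ``spacing`` is the voxel pitch in mm per axis, ``origin`` is the physical
  position (mm) of the *center* of voxel ``(0, 0, 0)``;
* internal activity math uses kBq/mL, MBq and kg; SUV carries g/mL.

Geometry is never defaulted: constructing a volume without spacing or
origin is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Optional

import numpy as np

from .errors import ConfigurationError, ModalityError
from .sources import DecaySpec, decay_factor

__all__ = ["ImageVolume", "InjectionRecord", "to_concentration", "to_suv"]

_MODALITIES = {"PET", "CT"}
_UNITS = {"Bq/mL", "kBq/mL", "HU", "SUV"}


@dataclass
class ImageVolume:
    """A 3D voxel grid with physical geometry and value semantics.

    ``decay_reference_datetime`` (PET only) is the instant the stored
    activity values are decay-corrected to; scanners commonly correct to
    the series or acquisition start.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    modality: str
    value_units: str
    acquisition_datetime: Optional[datetime] = None
    decay_reference_datetime: Optional[datetime] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ConfigurationError(
                f"volume values must be a 3D grid, got shape {self.values.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(not (s > 0) for s in self.spacing):
            raise ConfigurationError(f"spacing must be three positive mm, got {self.spacing}")
        if len(self.origin) != 3:
            raise ConfigurationError(f"origin must be a mm triple, got {self.origin}")
        if self.modality not in _MODALITIES:
            raise ConfigurationError(f"modality must be one of {sorted(_MODALITIES)}")
        if self.value_units not in _UNITS:
            raise ConfigurationError(f"value_units must be one of {sorted(_UNITS)}")
        if (self.value_units == "HU") != (self.modality == "CT"):
            raise ConfigurationError(
                f"units {self.value_units!r} inconsistent with modality {self.modality!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Physical position (mm) of voxel-center(s) at (possibly fractional) indices."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing
        )

    def physical_to_index(self, point_mm: np.ndarray) -> np.ndarray:
        """Fractional voxel index of a physical position (mm)."""
        return (np.asarray(point_mm, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical center coordinates of all voxels along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]


@dataclass(frozen=True)
class InjectionRecord:
    """Injected activity and patient weight entering the SUV denominator.

    ``injected_activity_mbq`` must already be decay-corrected to the same
    reference instant as the image values it is combined with.
    """

    injected_activity_mbq: float
    assay_datetime: Optional[datetime] = None
    patient_weight_kg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.injected_activity_mbq > 0):
            raise ConfigurationError("injected activity must be > 0 MBq")
        if not (self.patient_weight_kg > 0):
            raise ConfigurationError("patient weight must be > 0 kg")


def to_concentration(vol: ImageVolume, spec: DecaySpec, at: datetime) -> ImageVolume:
    """Convert a PET volume to kBq/mL decay-corrected to ``at``.

    The stored values represent concentration at
    ``vol.decay_reference_datetime``; the returned volume carries the
    physical concentration at ``at`` (so the factor is < 1 for ``at``
    after the reference).
    """
    if vol.modality != "PET":
        raise ModalityError(f"concentration conversion needs a PET volume, got {vol.modality}")
    if vol.value_units == "Bq/mL":
        scale = 1e-3
    elif vol.value_units == "kBq/mL":
        scale = 1.0
    else:
        raise ModalityError(
            f"cannot convert {vol.value_units!r} values to activity concentration"
        )
    if vol.decay_reference_datetime is None:
        raise ConfigurationError(
            "volume has no decay_reference_datetime; supply it when reading the series"
        )
    factor = scale * decay_factor(spec, at - vol.decay_reference_datetime)
    return replace(
        vol,
        values=vol.values * factor,
        value_units="kBq/mL",
        decay_reference_datetime=at,
        meta=dict(vol.meta),
    )


def to_suv(vol: ImageVolume, inj: InjectionRecord) -> ImageVolume:
    """Body-weight SUV (g/mL): voxel concentration over injected activity per weight.

    SUV = A / (I / W) with A in kBq/mL, I in MBq and W in kg; the unit
    factors cancel to give g/mL, so SUV = A * W / I numerically.  The
    image and the injected activity must be decay-corrected to a common
    instant; applying the same correction to both leaves the SUV unchanged.
    """
    if vol.modality != "PET":
        raise ModalityError(f"SUV conversion needs a PET volume, got {vol.modality}")
    if vol.value_units == "Bq/mL":
        conc = vol.values * 1e-3
    elif vol.value_units == "kBq/mL":
        conc = vol.values
    else:
        raise ModalityError(f"cannot convert {vol.value_units!r} values to SUV")
    suv = conc * inj.patient_weight_kg / inj.injected_activity_mbq
    return replace(vol, values=suv, value_units="SUV", meta=dict(vol.meta))
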
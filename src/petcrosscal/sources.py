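"""Sealed calibration sources: decay math and material-consistency checks.

Long-lived Ge-68/Ga-68 sources ship with a traceable certificate stating
activity (MBq) and, for the imaging phantom, activity concentration
(kBq/mL) at a reference datetime.  All "known" values used as the
denominators of recovery coefficients are the certificate values decayed
to the measurement time; the parent Ge-68 half-life governs the sealed
source (the daughter is in secular equilibrium and is not modelled).

Timestamps are timezone-aware throughout; naive datetimes are rejected so
that a site's local clock convention can never silently shift a decay
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import ConfigurationError, InvalidMeasurementError

__all__ = [
    "DecaySpec",
    "SourceCertificate",
    "GE68",
    "F18",
    "decay_factor",
    "known_concentration_at",
    "expected_dose_reading",
    "density_from_weighing",
    "percent_change",
    "round_half_away",
    "load_certificates",
]

_UNIT_SECONDS = {
    "seconds": 1.0,
    "minutes": 60.0,
    "hours": 3600.0,
    "days": 86400.0,
}

Duration = Union[timedelta, float, int]


@dataclass(frozen=True)
class DecaySpec:
    """Radioactive decay parameters for one nuclide.

    Parameters
    ----------
    nuclide:
        Display name, e.g. ``"Ge-68"``.
    half_life:
        Half-life value in the unit given by ``unit``.
    unit:
        One of ``seconds``, ``minutes``, ``hours``, ``days``.
    """

    nuclide: str
    half_life: float
    unit: str = "days"

    def __post_init__(self) -> None:
        if self.unit not in _UNIT_SECONDS:
            raise ConfigurationError(
                f"unknown half-life unit {self.unit!r}; use one of {sorted(_UNIT_SECONDS)}"
            )
        if not (self.half_life > 0):
            raise ConfigurationError(
                f"half-life must be positive, got {self.half_life!r} {self.unit}"
            )

    @property
    def half_life_seconds(self) -> float:
        return self.half_life * _UNIT_SECONDS[self.unit]


#: Default parent half-life for the sealed Ge-68/Ga-68 sources (reference value).
GE68 = DecaySpec("Ge-68", 270.95, "days")
#: F-18, for decay handling of clinical FDG inputs.
F18 = DecaySpec("F-18", 109.77, "minutes")

_NUCLIDE_DEFAULTS = {"Ge-68": GE68, "F-18": F18}


@dataclass(frozen=True)
class SourceCertificate:
    """Traceable known activity of a sealed source at a reference datetime.

    ``reference_concentration_kbq_ml`` is present only for imaging-phantom
    sources; dose-calibrator sources state total activity alone.
    ``stated_uncertainty`` is the fractional uncertainty of the traceable
    value (0.025 means +/-2.5% at the certificate's confidence level);
    it is carried into reports but never propagated.
    """

    source_id: str
    nuclide: str
    reference_datetime: datetime
    reference_activity_mbq: float
    reference_concentration_kbq_ml: Optional[float] = None
    stated_uncertainty: float = 0.025
    active_diameter_mm: Optional[float] = None
    active_height_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.reference_datetime.tzinfo is None:
            raise ConfigurationError(
                f"certificate {self.source_id!r}: reference_datetime must be timezone-aware"
            )
        if not (self.reference_activity_mbq > 0):
            raise ConfigurationError(
                f"certificate {self.source_id!r}: reference activity must be > 0 MBq"
            )
        if self.reference_concentration_kbq_ml is not None and not (
            self.reference_concentration_kbq_ml > 0
        ):
            raise ConfigurationError(
                f"certificate {self.source_id!r}: reference concentration must be > 0 kBq/mL"
            )
        if not (0.0 < self.stated_uncertainty < 1.0):
            raise ConfigurationError(
                f"certificate {self.source_id!r}: stated uncertainty must be a fraction in (0, 1)"
            )


def _elapsed_seconds(elapsed: Duration) -> float:
    if isinstance(elapsed, timedelta):
        return elapsed.total_seconds()
    return float(elapsed)


def decay_factor(spec: DecaySpec, elapsed: Duration) -> float:
    """Fraction of activity remaining after ``elapsed``.

    ``elapsed`` is a :class:`~datetime.timedelta` or a number of seconds;
    negative durations back-correct.  Returns ``2**(-elapsed / half_life)``,
    which is multiplicative over concatenated intervals.
    """
    t = _elapsed_seconds(elapsed)
    return math.exp2(-t / spec.half_life_seconds)


def known_concentration_at(
    cert: SourceCertificate, spec: DecaySpec, when: datetime
) -> float:
    """Traceable activity concentration (kBq/mL) decayed to ``when``.

    This is the known value A_K in the denominator of the imaging-phantom
    recovery coefficient.
    """
    if cert.reference_concentration_kbq_ml is None:
        raise ConfigurationError(
            f"certificate {cert.source_id!r} states no concentration: it describes a "
            "dose-calibrator-style source, not an imaging phantom"
        )
    return cert.reference_concentration_kbq_ml * decay_factor(
        spec, when - cert.reference_datetime
    )


def expected_dose_reading(
    cert: SourceCertificate,
    spec: DecaySpec,
    when: datetime,
    response_factor: float,
) -> float:
    """Expected dose-calibrator reading (MBq, F-18-equivalent) at ``when``.

    The dose-calibrator source is assayed on the instrument's F-18 setting,
    so the certificate's Ge-68 activity is multiplied by the manufacturer's
    relative response factor converting stated Ge-68 activity to equivalent
    F-18 activity.  That factor is instrument-protocol specific and has no
    default: it must be supplied.  The result is the denominator of the
    dose-calibrator recovery coefficient R_D.
    """
    if not (response_factor > 0):
        raise ConfigurationError(
            f"response factor must be > 0, got {response_factor!r}"
        )
    return (
        cert.reference_activity_mbq
        * decay_factor(spec, when - cert.reference_datetime)
        * response_factor
    )


def density_from_weighing(
    mass_air: float, mass_water: float, water_density: float = 1.0
) -> float:
    """Density (g/mL) of a sample weighed in air and submerged in water.

    Archimedes: the buoyant loss ``mass_air - mass_water`` weighs the
    displaced water, so density = mass_air * water_density / loss.
    ``mass_water`` may be zero (neutral buoyancy limit, density equals the
    water density) but must be smaller than ``mass_air``.
    """
    if not (mass_air > 0):
        raise InvalidMeasurementError(f"mass in air must be > 0 g, got {mass_air!r}")
    if not (water_density > 0):
        raise InvalidMeasurementError(
            f"water density must be > 0 g/mL, got {water_density!r}"
        )
    if not (mass_air > mass_water >= 0):
        raise InvalidMeasurementError(
            "weighing requires mass_air > mass_water >= 0 "
            f"(got air {mass_air!r} g, water {mass_water!r} g)"
        )
    return mass_air * water_density / (mass_air - mass_water)


def percent_change(old: float, new: float) -> float:
    """Relative change from ``old`` to ``new`` in percent: 100 * (new - old) / old."""
    if old == 0:
        raise InvalidMeasurementError("percent change from zero is undefined")
    return 100.0 * (new - old) / old


def round_half_away(value: float, ndigits: int) -> float:
    """Round with ties going away from zero, as printed QC reports do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


_CERT_KEYS = {
    "source_id",
    "nuclide",
    "reference_datetime",
    "reference_activity_mbq",
    "reference_concentration_kbq_ml",
    "stated_uncertainty",
    "active_diameter_mm",
    "active_height_mm",
}


def _parse_certificate(entry: dict) -> SourceCertificate:
    unknown = set(entry) - _CERT_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown certificate keys {sorted(unknown)}; known keys: {sorted(_CERT_KEYS)}"
        )
    missing = {"source_id", "nuclide", "reference_datetime", "reference_activity_mbq"} - set(
        entry
    )
    if missing:
        raise ConfigurationError(f"certificate missing required keys {sorted(missing)}")
    ref = entry["reference_datetime"]
    if isinstance(ref, str):
        ref = datetime.fromisoformat(ref)
    if ref.tzinfo is None:
        raise ConfigurationError(
            f"certificate {entry['source_id']!r}: reference_datetime must carry a "
            "timezone offset (ISO-8601, e.g. 2013-03-03T12:00:00+00:00)"
        )
    kwargs = {k: v for k, v in entry.items() if k not in {"reference_datetime"}}
    return SourceCertificate(reference_datetime=ref, **kwargs)


def load_certificates(path: Union[str, Path]) -> dict[str, SourceCertificate]:
    """Read source certificates from a YAML file.

    The file holds a list of mappings (or a single mapping) with keys
    ``source_id``, ``nuclide``, ``reference_datetime`` (ISO-8601 with
    timezone), ``reference_activity_mbq``, and optionally
    ``reference_concentration_kbq_ml``, ``stated_uncertainty``,
    ``active_diameter_mm``, ``active_height_mm``.  Returns certificates
    keyed by source id.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"certificate file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        raise ConfigurationError(f"certificate file is empty: {path}")
    entries = doc if isinstance(doc, list) else [doc]
    certs: dict[str, SourceCertificate] = {}
    for entry in entries:
        if not isinstance(entry, dict):
            raise ConfigurationError(f"certificate entries must be mappings, got {entry!r}")
        cert = _parse_certificate(entry)
        if cert.source_id in certs:
            raise ConfigurationError(f"duplicate source_id {cert.source_id!r}")
        certs[cert.source_id] = cert
    return certs


def default_decay_spec(nuclide: str) -> DecaySpec:
    """Built-in half-life for a nuclide name, if we ship one."""
    try:
        return _NUCLIDE_DEFAULTS[nuclide]
    except KeyError:
        raise ConfigurationError(
            f"no built-in half-life for nuclide {nuclide!r}; supply a DecaySpec"
        ) from None
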
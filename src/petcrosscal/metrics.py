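"""Calibration metrics: recovery coefficients, SUV bias, COV and reports.

The central quantities of the cross-calibration method:

* recovery coefficient ``R = A_M / A_K`` — measured over known (traceable)
  activity concentration, dimensionless;
* SUV bias ``b = R_P / R_D - 1`` — the net bias propagating into SUVs when
  the scanner (R_P) and the site's dose calibrator (R_D) each carry their
  own recovery; any scale common to both cancels;
* COV — standard deviation over mean, as a percent.

Two SD conventions coexist deliberately: within an ROI the population SD
describes the voxel set (see :mod:`.autoroi`); across repeated
measurements the sample SD (ddof=1) estimates variability.  ``cov`` here
is the across-measurement flavor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RecordMismatchError

__all__ = [
    "CalibrationRecord",
    "SummaryStats",
    "recovery_coefficient",
    "suv_bias",
    "cov",
    "summarize",
    "time_series_report",
]

#: relative tolerance for the load-time b = R_P/R_D - 1 consistency check
_BIAS_CHECK_ATOL = 1e-9


@dataclass
class CalibrationRecord:
    """One paired phantom + dose-calibrator measurement.

    ``phantom_r`` (R_P) and ``dose_calibrator_r`` (R_D) are the two
    recovery coefficients; ``suv_bias`` is always R_P/R_D - 1 and is
    recomputed on load — a stored mismatch is an error, not a warning.
    ``acf`` is the scanner's activity calibration factor, an opaque global
    scale recorded to segment the time series at recalibrations.
    """

    site_id: str
    scanner_id: str
    dose_calibrator_id: str
    measurement_datetime: datetime
    phantom_r: float
    dose_calibrator_r: float
    suv_bias: Optional[float] = None
    acf: Optional[float] = None
    phantom_age_days: Optional[float] = None
    roi: Optional[dict] = None

    def __post_init__(self) -> None:
        if not (self.phantom_r > 0):
            raise ConfigurationError(f"phantom R must be > 0, got {self.phantom_r!r}")
        if not (self.dose_calibrator_r > 0):
            raise ConfigurationError(
                f"dose-calibrator R must be > 0, got {self.dose_calibrator_r!r}"
            )
        expected = suv_bias(self.phantom_r, self.dose_calibrator_r)
        if self.suv_bias is None:
            self.suv_bias = expected
        elif abs(self.suv_bias - expected) > _BIAS_CHECK_ATOL + 1e-9 * abs(expected):
            raise RecordMismatchError(
                f"stored SUV bias {self.suv_bias!r} does not match R_P/R_D - 1 = {expected!r} "
                f"for site {self.site_id!r} at {self.measurement_datetime}"
            )


@dataclass(frozen=True)
class SummaryStats:
    """n / mean / SD / COV / min / max of one group of measurements.

    SD and COV are reported only for n >= 2 (sample SD is undefined for a
    single measurement).
    """

    n: int
    mean: float
    sd: Optional[float]
    cov_percent: Optional[float]
    min: float
    max: float


def recovery_coefficient(measured: float, known: float) -> float:
    """R = measured / known activity concentration (both kBq/mL, or both MBq)."""
    if not (known > 0):
        raise ConfigurationError(f"known value must be > 0, got {known!r}")
    return measured / known


def suv_bias(r_p: float, r_d: float) -> float:
    """SUV bias b = R_P / R_D - 1.

    R_P is the imaging-phantom recovery coefficient, R_D the
    dose-calibrator one.  A calibration scale shared by scanner and dose
    calibrator divides out, which is exactly the cancellation this metric
    interrogates.
    """
    if not (r_d > 0):
        raise ConfigurationError(f"dose-calibrator recovery must be > 0, got {r_d!r}")
    return r_p / r_d - 1.0


def cov(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sample SD / mean.

    Characterizes variability across independent measurements, hence the
    sample SD (ddof=1); needs at least two values and a positive mean.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ConfigurationError(f"COV needs at least 2 values, got {arr.size}")
    mean = arr.mean()
    if not (mean > 0):
        raise ConfigurationError(f"COV needs a positive mean, got {mean!r}")
    return float(100.0 * arr.std(ddof=1) / mean)


def _stats_from_values(values: np.ndarray) -> SummaryStats:
    n = int(values.size)
    mean = float(values.mean())
    if n >= 2:
        sd = float(values.std(ddof=1))
        cov_pct = 100.0 * sd / mean if mean > 0 else None
    else:
        sd = None
        cov_pct = None
    return SummaryStats(
        n=n, mean=mean, sd=sd, cov_percent=cov_pct,
        min=float(values.min()), max=float(values.max()),
    )


def summarize(
    records: Iterable,
    group_by: Optional[str] = None,
    value: str = "phantom_r",
) -> dict[str, SummaryStats]:
    """Per-group summary statistics of one record field (or of raw numbers).

    ``records`` is a list of :class:`CalibrationRecord` (or mappings), or,
    with ``group_by=None``, simply a list of numbers summarized under the
    single key ``"all"``.  Groups are returned in lexicographic order.
    """
    if group_by is None:
        first = list(records)
        if first and isinstance(first[0], (int, float, np.floating)):
            return {"all": _stats_from_values(np.asarray(first, dtype=float))}
        records = first
    groups: dict[str, list[float]] = {}
    for rec in records:
        getter = rec.get if isinstance(rec, dict) else lambda k, r=rec: getattr(r, k)
        if group_by is None:
            key = "all"
        else:
            try:
                key = str(getter(group_by))
            except (AttributeError, KeyError):
                raise ConfigurationError(f"unknown group key {group_by!r}") from None
        try:
            val = float(getter(value))
        except (AttributeError, KeyError):
            raise ConfigurationError(f"unknown value field {value!r}") from None
        groups.setdefault(key, []).append(val)
    return {
        key: _stats_from_values(np.asarray(vals, dtype=float))
        for key, vals in sorted(groups.items())
    }


def time_series_report(
    records: Sequence[CalibrationRecord],
    acf_rtol: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Longitudinal table of R and b with calibration-period segmentation.

    Scanner recalibrations change the activity calibration factor (ACF),
    the global scale the scanner applies; recovery coefficients shift with
    it.  Within each site the series is split into segments wherever the
    ACF changes by more than ``acf_rtol`` relative (the default segments
    on any change), and within-segment COV of R is reported next to the
    overall per-site COV.

    Returns ``(per_record, per_segment)`` data frames.  Duplicate
    (site, datetime) pairs are kept (flagged in the ``duplicate`` column).
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "site_id": rec.site_id,
                "scanner_id": rec.scanner_id,
                "measurement_datetime": rec.measurement_datetime,
                "phantom_r": rec.phantom_r,
                "dose_calibrator_r": rec.dose_calibrator_r,
                "suv_bias": rec.suv_bias,
                "acf": rec.acf,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df, pd.DataFrame(
            columns=["site_id", "segment", "n", "start", "end", "r_mean", "r_sd", "r_cov_percent"]
        )
    df = df.sort_values(["site_id", "measurement_datetime"], kind="stable").reset_index(drop=True)
    df["duplicate"] = df.duplicated(subset=["site_id", "measurement_datetime"], keep=False)

    segments = []
    seg_ids = np.zeros(len(df), dtype=int)
    for site, idx in df.groupby("site_id", sort=True).groups.items():
        idx = list(idx)
        seg = 0
        prev_acf = None
        for i in idx:
            acf = df.at[i, "acf"]
            if prev_acf is not None and acf is not None and not pd.isna(acf):
                if abs(acf - prev_acf) > acf_rtol * max(abs(prev_acf), 1e-300):
                    seg += 1
            if acf is not None and not pd.isna(acf):
                prev_acf = acf
            seg_ids[i] = seg
    df["segment"] = seg_ids

    for (site, seg), grp in df.groupby(["site_id", "segment"], sort=True):
        r = grp["phantom_r"].to_numpy(dtype=float)
        stats = _stats_from_values(r)
        segments.append(
            {
                "site_id": site,
                "segment": seg,
                "n": stats.n,
                "start": grp["measurement_datetime"].min(),
                "end": grp["measurement_datetime"].max(),
                "r_mean": stats.mean,
                "r_sd": stats.sd,
                "r_cov_percent": stats.cov_percent,
            }
        )
    return df, pd.DataFrame(segments)
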
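"""End-to-end QC workflows: analyze a scan, pair it with an assay, report.

These are the library functions behind the command-line interface: read a
series, locate the phantom and extract the ROI, compute the phantom
recovery coefficient against the certificate's decayed concentration, pair
with a dose-calibrator assay to get the SUV bias, and aggregate records
into site / segment summaries.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .autoroi import RoiConfig, RoiResult, analyze_volume
from .errors import ConfigurationError, PairingWindowError
from .io import read_series
from .metrics import CalibrationRecord, summarize, suv_bias, time_series_report
from .sources import (
    DecaySpec,
    GE68,
    SourceCertificate,
    expected_dose_reading,
    known_concentration_at,
)
from .volume import ImageVolume, to_concentration

__all__ = ["PhantomMeasurement", "analyze_series", "pair_measurement", "report_records"]


class PhantomMeasurement:
    """Result of analyzing one phantom scan: R_P plus its provenance."""

    def __init__(
        self,
        phantom_r: float,
        roi: RoiResult,
        measured_kbq_ml: float,
        known_kbq_ml: float,
        measurement_datetime: datetime,
        source_id: str,
        phantom_age_days: float,
    ) -> None:
        self.phantom_r = phantom_r
        self.roi = roi
        self.measured_kbq_ml = measured_kbq_ml
        self.known_kbq_ml = known_kbq_ml
        self.measurement_datetime = measurement_datetime
        self.source_id = source_id
        self.phantom_age_days = phantom_age_days


def analyze_series(
    series: Union[str, Path, ImageVolume],
    cert: SourceCertificate,
    decay_spec: DecaySpec = GE68,
    when: Optional[datetime] = None,
    roi_config: RoiConfig = RoiConfig(),
) -> PhantomMeasurement:
    """Measure the phantom recovery coefficient R_P from one PET series.

    The measured ROI-mean concentration (decay-corrected to ``when``,
    defaulting to the acquisition time) is divided by the certificate
    concentration decayed to the same instant — decaying both to a common
    time makes R_P insensitive to the choice of ``when``.
    """
    vol = read_series(series) if not isinstance(series, ImageVolume) else series
    if when is None:
        when = vol.acquisition_datetime
    if when is None:
        raise ConfigurationError(
            "no measurement time: series lacks an acquisition datetime, pass `when`"
        )
    conc = to_concentration(vol, decay_spec, when)
    roi = analyze_volume(conc, roi_config)
    known = known_concentration_at(cert, decay_spec, when)
    r_p = roi.mean / known
    age_days = (when - cert.reference_datetime).total_seconds() / 86400.0
    return PhantomMeasurement(
        phantom_r=r_p,
        roi=roi,
        measured_kbq_ml=roi.mean,
        known_kbq_ml=known,
        measurement_datetime=when,
        source_id=cert.source_id,
        phantom_age_days=age_days,
    )


def pair_measurement(
    phantom: PhantomMeasurement,
    dose_reading_mbq: float,
    reading_datetime: datetime,
    cert: SourceCertificate,
    response_factor: float,
    decay_spec: DecaySpec = GE68,
    site_id: str = "site",
    scanner_id: str = "scanner",
    dose_calibrator_id: str = "dose-calibrator",
    acf: Optional[float] = None,
    pairing_window: timedelta = timedelta(hours=24),
    same_calendar_day: bool = True,
    force: bool = False,
) -> CalibrationRecord:
    """Form a calibration pair: compute R_D from the assay, then the SUV bias b.

    A phantom scan and a dose-calibrator assay only form a pair when taken
    close together (by default the same UTC calendar day and within the
    window); ``force`` overrides for retrospective analyses.
    """
    if not force:
        apart = abs((reading_datetime - phantom.measurement_datetime).total_seconds())
        same_day = reading_datetime.astimezone(timezone.utc).date() == (
            phantom.measurement_datetime.astimezone(timezone.utc).date()
        )
        if apart > pairing_window.total_seconds() or (same_calendar_day and not same_day):
            raise PairingWindowError(
                f"assay at {reading_datetime} and scan at {phantom.measurement_datetime} "
                "are too far apart to form a calibration pair (use force to override)"
            )
    expected = expected_dose_reading(cert, decay_spec, reading_datetime, response_factor)
    r_d = dose_reading_mbq / expected
    return CalibrationRecord(
        site_id=site_id,
        scanner_id=scanner_id,
        dose_calibrator_id=dose_calibrator_id,
        measurement_datetime=phantom.measurement_datetime,
        phantom_r=phantom.phantom_r,
        dose_calibrator_r=r_d,
        suv_bias=suv_bias(phantom.phantom_r, r_d),
        acf=acf,
        phantom_age_days=phantom.phantom_age_days,
        roi=phantom.roi.as_dict(),
    )


def report_records(
    records: Sequence[CalibrationRecord],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Summaries for a QC report: per-site stats, overall stats, per-segment series.

    Returns ``(per_site, overall, per_segment)`` data frames; the
    per-segment table comes from :func:`petcrosscal.metrics.time_series_report`
    and splits each site's series at activity-calibration-factor changes.
    """

    def frame(stats_by_key: dict) -> pd.DataFrame:
        rows = []
        for key, st in stats_by_key.items():
            rows.append(
                {
                    "group": key,
                    "n": st.n,
                    "r_mean": st.mean,
                    "r_sd": st.sd,
                    "r_cov_percent": st.cov_percent,
                    "r_min": st.min,
                    "r_max": st.max,
                }
            )
        return pd.DataFrame(
            rows, columns=["group", "n", "r_mean", "r_sd", "r_cov_percent", "r_min", "r_max"]
        )

    per_site = frame(summarize(records, group_by="site_id"))
    overall = frame({"overall": summarize(list(records), group_by=None, value="phantom_r").get("all")}
                    if records else {})
    _, per_segment = time_series_report(list(records))
    return per_site, overall, per_segment
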
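"""Exception hierarchy for the cross-calibration toolkit.

Exit-code mapping used by the CLI: ``AnalysisError`` subclasses map to
exit code 1 (the measurement could not be made), ``ConfigurationError``
subclasses to exit code 2 (bad inputs or configuration).
"""


class CrossCalError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(CrossCalError):
    """Invalid configuration: bad half-life, missing certificate fields, unknown keys."""


class InvalidMeasurementError(CrossCalError):
    """Physically impossible measurement inputs (e.g. weight in water >= weight in air)."""


class AnalysisError(CrossCalError):
    """The analysis could not produce a result from otherwise valid inputs."""


class PhantomNotFoundError(AnalysisError):
    """No compact hot region detected in the volume."""


class SeriesReadError(CrossCalError):
    """Image series could not be read coherently (mixed series, missing geometry...)."""


class ModalityError(CrossCalError):
    """Operation applied to the wrong modality (e.g. SUV conversion of a CT)."""


class GeometryError(CrossCalError):
    """Scene or ROI geometry is inconsistent (box too small, phantom out of grid...)."""


class PairingWindowError(CrossCalError):
    """Phantom scan and dose-calibrator assay are too far apart in time to pair."""


class RecordMismatchError(CrossCalError):
    """Stored SUV bias does not match the bias recomputed from its recovery coefficients."""
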
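"""Exception hierarchy shared across the package."""


class HFLDError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(HFLDError, ValueError):
    """A generator or model specification violates its invariants."""


class InfeasibleHistoryError(HFLDError, ValueError):
    """Requested deforestation exceeds the available forest pool."""


class DegenerateSeriesError(HFLDError, ValueError):
    """An annual series cannot support log-scale calibration (e.g. all zero)."""


class CalibrationError(HFLDError, ValueError):
    """A regression design is singular (e.g. constant gold price)."""


class DegenerateTrainingError(HFLDError, ValueError):
    """Location-model training labels contain a single class."""


class SaturationError(HFLDError, ValueError):
    """Allocation demand exceeds the remaining forest pixel pool."""


class SchemaError(HFLDError, ValueError):
    """Mismatched covariate names, horizons or territory identifiers."""


class AmbiguousZonesError(HFLDError, ValueError):
    """Territory zones overlap instead of partitioning the grid."""
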
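"""Exception hierarchy shared across the pipeline."""


class AlertFmriError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AlertFmriError, ValueError):
    """Invalid configuration value (counts, durations, thresholds...)."""


class DimensionError(AlertFmriError, ValueError):
    """Array/scan dimensions incompatible with the requested operation."""


class GeometryError(AlertFmriError, ValueError):
    """Mismatched or unsupported spatial geometry (affine, shape, grid)."""


class RankDeficientDesignError(AlertFmriError, ValueError):
    """Design matrix is rank deficient; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class ValidationError(AlertFmriError, ValueError):
    """Invalid data values (questionnaire items out of range, ...)."""


class MissingDataError(AlertFmriError, ValueError):
    """Required observations absent (incomplete questionnaire, empty log)."""


class AlignmentError(AlertFmriError, ValueError):
    """Subject sets of two tables do not match; carries unmatched ids."""

    def __init__(self, unmatched):
        self.unmatched = sorted(unmatched)
        super().__init__(
            "subject sets do not align; unmatched ids: "
            + ", ".join(map(str, self.unmatched))
        )
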
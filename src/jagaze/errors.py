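"""Exception hierarchy used across the package."""


class JagazeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(JagazeError):
    """A file does not conform to the expected format (missing columns, bad header)."""


class DataError(JagazeError):
    """A file parses but violates a data invariant (e.g. non-monotone timestamps)."""


class ConfigError(JagazeError):
    """A task/AOI/study configuration is invalid."""


class CalibrationError(JagazeError):
    """Requested generator calibration targets are infeasible."""


class AnalysisError(JagazeError):
    """A statistical analysis cannot be carried out on the given data."""
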
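"""Exception hierarchy for mzjoint."""


class MzjointError(Exception):
    """Base class for all mzjoint errors."""


class FormatError(MzjointError):
    """A file could not be parsed in its declared format."""


class EmptyRunError(MzjointError):
    """An mzML file contained no MS1 scans."""


class SchemaError(MzjointError):
    """A tabular input is missing mandatory columns."""


class ApexNotFoundError(MzjointError):
    """No nonzero EIC point was found when searching for a peak apex."""


class ConfigError(MzjointError):
    """An invalid or inconsistent configuration was supplied."""


class MissingRunError(MzjointError):
    """A raw run required for gap filling was not provided."""


class UndefinedScoreError(MzjointError):
    """Spectral similarity requested on an empty spectrum."""


class InsufficientPointsError(MzjointError):
    """Too few detected points to fit a calibration curve."""


class DegenerateFitError(MzjointError):
    """Calibration points have zero concentration variance."""


class InvalidFitError(MzjointError):
    """Calibration fit unusable for LOD estimation (non-positive slope)."""
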
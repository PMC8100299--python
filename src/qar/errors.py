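"""Exception hierarchy for the QAR pipeline.

Config problems (bad parameters, mismatched sensors) and data problems
(corrupt files, impossible shapes) are kept distinct so the CLI can map
them to different exit codes.
"""


class QarError(Exception):
    """Base class for all package errors."""


class ConfigError(QarError):
    """Invalid parameter values or inconsistent configuration (CLI exit 2)."""


class DataError(QarError):
    """Invalid, corrupt or inconsistent input data (CLI exit 3)."""


class ShapeError(DataError):
    """Array dimensions do not match what an operation requires."""


class CalibrationError(DataError):
    """Threshold calibration is impossible (e.g. too few frames)."""


class ContractError(DataError):
    """An input violates a documented contract (e.g. non-binary mask)."""


class FormatError(DataError):
    """A recording container is structurally malformed (missing sidecar,
    missing field, inconsistent metadata)."""


class CorruptFileError(FormatError):
    """Byte counts of a stored matrix disagree with its metadata."""
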
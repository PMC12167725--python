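"""Exception hierarchy for the split-renal-function pipeline."""


class SrfError(Exception):
    """Base class for all package errors."""


class FormatError(SrfError):
    """A file does not have the expected structure (e.g. not a 3D NIfTI)."""


class DataError(SrfError):
    """Voxel data violates a contract (non-finite values, illegal labels)."""


class ConfigError(SrfError):
    """Invalid configuration (ranges, fractions, spacings, ...)."""


class ContractError(SrfError):
    """Mismatched arguments between paired inputs (shape/geometry)."""


class MeasurementError(SrfError):
    """A measurement is undefined on the given input (e.g. no renal uptake)."""
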
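"""Exception hierarchy for the sersdx pipeline."""


class SersdxError(Exception):
    """Base class for all sersdx errors."""


class ParseError(SersdxError):
    """A spectrum or manifest file could not be parsed."""


class FormatError(SersdxError):
    """A file parsed but violates the expected spectral format."""


class ValidationError(SersdxError):
    """Cohort metadata violates an invariant (labels, patient mapping)."""


class RangeError(SersdxError):
    """Spectral axes cannot be harmonized (insufficient overlap)."""


class ConfigError(SersdxError):
    """A configuration object is internally inconsistent."""


class StateError(SersdxError):
    """An operation was applied to a spectrum in the wrong processing state."""


class DegenerateInputError(SersdxError):
    """Input is structurally valid but degenerate (all-zero, empty, one class)."""
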
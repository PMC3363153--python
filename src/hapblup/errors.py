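"""Exception hierarchy for validation and configuration failures."""


class HapblupError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HapblupError):
    """Invalid simulation or run configuration."""


class ValidationError(HapblupError):
    """An input file or in-memory structure violates its invariants."""


class PedigreeError(ValidationError):
    """Pedigree-specific violation (cycle, missing parent, bad order)."""


class ModelError(HapblupError):
    """A model cannot be fitted on the given inputs."""
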
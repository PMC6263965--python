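"""Exception hierarchy for gaitcfar."""


class GaitCfarError(Exception):
    """Base class for all gaitcfar errors."""


class ConfigError(GaitCfarError, ValueError):
    """Invalid parameter or configuration value."""


class SchemaError(GaitCfarError, ValueError):
    """Input data does not provide the expected columns/channels."""


class ParseError(GaitCfarError, ValueError):
    """Input file could not be parsed as numeric data."""


class InternalConsistencyError(GaitCfarError, RuntimeError):
    """A state that validated parameters should make unreachable."""
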
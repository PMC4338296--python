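"""Exception hierarchy shared across the pipeline."""


class OxbsError(Exception):
    """Base class for all package errors."""


class ConfigError(OxbsError):
    """Invalid configuration value; the message names the offending field."""


class ValidationError(OxbsError):
    """Input data violates a documented precondition."""


class MissingArtifactError(OxbsError):
    """A pipeline stage requires an artifact a prior stage has not produced."""
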
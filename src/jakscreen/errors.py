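"""Exception hierarchy shared across the package."""


class JakscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(JakscreenError):
    """A configuration value is invalid; the message names the offending field."""


class IntegrityError(JakscreenError):
    """Input data contradicts itself or the reference sequence."""


class VcfFormatError(JakscreenError):
    """A VCF could not be parsed; carries file and record context."""


class BedFormatError(JakscreenError):
    """A BED interval is malformed (e.g. start >= end)."""


class AnnotationError(JakscreenError):
    """A variant falls outside the packaged reference or transcript model."""
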
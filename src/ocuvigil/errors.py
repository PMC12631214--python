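"""Exception types shared across the pipeline."""


class OcuvigilError(Exception):
    """Base class for package errors."""


class ConfigurationError(OcuvigilError):
    """Invalid user configuration (bad probability, empty drug list, ...)."""


class FormatError(OcuvigilError):
    """Malformed input table: missing mandatory column, unreadable file."""


class StandardizationError(OcuvigilError):
    """Unmapped verbatim terms under the ``error`` policy."""
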
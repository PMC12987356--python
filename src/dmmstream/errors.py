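"""Exception hierarchy."""


class DmmStreamError(Exception):
    """Base class for all package errors."""


class CorpusFormatError(DmmStreamError):
    """Malformed corpus / code-matrix / manifest input."""


class SchemaViolationError(DmmStreamError):
    """Token or stream not representable under the governing schema."""


class IntegrityError(DmmStreamError):
    """Model state fails its count-table invariants."""


class ConfigError(DmmStreamError):
    """Invalid configuration value (domain error)."""
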
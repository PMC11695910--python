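"""Exception hierarchy."""


class BliptaError(Exception):
    """Base class for all package errors."""


class LibraryError(BliptaError, ValueError):
    """A model-library config file violates the schema or an invariant."""

    def __init__(self, message: str, *, source: str | None = None, field: str | None = None):
        self.source = source
        self.field = field
        prefix = ""
        if source:
            prefix += f"{source}: "
        if field:
            prefix += f"[{field}] "
        super().__init__(prefix + message)


class UnknownPenetrationError(BliptaError, KeyError):
    """No tissue penetration ratio is resolvable for a compound at a site."""


class ConfigurationError(BliptaError, RuntimeError):
    """A simulation setting is unusable (e.g. no steady state within 30 days)."""
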
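"""Exception hierarchy for the gistint pipeline."""


class GistintError(Exception):
    """Base class for all gistint errors."""


class ParseError(GistintError):
    """A file could not be parsed; the message names the offending line."""

    def __init__(self, path, line, message):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


class ValidationError(GistintError):
    """A parsed record violates a data-model invariant."""


class DomainError(GistintError, ValueError):
    """An operation was called with arguments outside its domain."""


class ConfigurationError(GistintError):
    """A required piece of configuration (e.g. a transcript sequence) is missing."""


class AnnotationError(GistintError):
    """Annotation failed, e.g. a fusion partner gene is absent from the gene model."""
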
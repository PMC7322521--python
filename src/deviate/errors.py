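"""Exception hierarchy shared across the package."""


class DeviateError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DeviateError, ValueError):
    """A file could not be parsed in the declared dialect."""


class IntegrityError(DeviateError, ValueError):
    """A mesh, map or volume violates a structural invariant."""


class DataError(DeviateError, ValueError):
    """Input data values are unusable (non-finite, mismatched, ...)."""


class PipelineError(DeviateError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
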
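"""Exception hierarchy.

All package errors derive from :class:`SpectromapError` so callers can catch
one base class; I/O and configuration problems are distinguished because the
batch driver treats them differently (a bad file skips the file, a bad config
aborts the run).
"""


class SpectromapError(Exception):
    """Base class for all spectromap errors."""


class ImageIOError(SpectromapError):
    """A file could not be read or written."""


class ConfigError(SpectromapError):
    """A run-configuration value is invalid or inconsistent."""


class AxisAmbiguityError(ConfigError):
    """The axis layout of an input image cannot be inferred.

    Carries the candidate interpretations so the caller can present them.
    """

    def __init__(self, message: str, candidates: tuple[str, ...] = ()):
        super().__init__(message)
        self.candidates = candidates


class DegenerateInputError(SpectromapError):
    """An input is formally valid but degenerate (e.g. constant image)."""


class ExpressionError(ConfigError):
    """A beta-value expression failed to parse or bind.

    ``position`` is the 0-based character offset of the problem, or -1.
    """

    def __init__(self, message: str, position: int = -1):
        super().__init__(message)
        self.position = position
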
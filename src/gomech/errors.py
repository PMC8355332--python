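"""Exception hierarchy shared across the pipeline."""


class GomechError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(GomechError, ValueError):
    """A parameter violates a documented precondition."""


class ParseError(GomechError, ValueError):
    """A file could not be parsed; the message carries the line number."""


class NoContactError(GomechError, RuntimeError):
    """A force curve shows no rising segment above the baseline noise."""


class InsufficientDataError(GomechError, RuntimeError):
    """Too few samples to perform the requested fit or statistic."""


class EmptyMaskError(GomechError, RuntimeError):
    """An intensity mask came out empty."""


class AmbiguityError(GomechError, RuntimeError):
    """A periodic-geometry operation has no unique answer (group too large)."""
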
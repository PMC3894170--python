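"""Exception hierarchy shared across the package."""


class CanidPopgenError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CanidPopgenError, ValueError):
    """A numeric argument violates its documented domain."""


class ModelError(CanidPopgenError, ValueError):
    """A demographic model is structurally malformed."""


class InfiniteSitesError(CanidPopgenError, RuntimeError):
    """More mutations requested than sites available within a locus.

    Raised when expected mutations per locus exceed the locus length;
    reduce the mutation rate, the locus length, or the tree depth.
    """


class UndefinedStatisticError(CanidPopgenError, ZeroDivisionError):
    """A statistic's denominator (or its variance) is exactly zero."""


class InsufficientBlocksError(CanidPopgenError, ValueError):
    """Too few non-empty jackknife blocks for a stable variance estimate."""


class EmptyOverlapError(CanidPopgenError, ValueError):
    """Two genotype tracks share no called sites."""


class SampleLookupError(CanidPopgenError, KeyError):
    """A requested sample name is absent from the dataset."""


class LabelingError(CanidPopgenError, ValueError):
    """Samples lack the dog/wolf group labels a mode requires."""


class ShapeError(CanidPopgenError, ValueError):
    """Two tables that must align (quartets, configurations) do not."""


class ParseError(CanidPopgenError, ValueError):
    """A data file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(CanidPopgenError, ValueError):
    """A run configuration is invalid or references missing files."""


class StageError(CanidPopgenError, RuntimeError):
    """A pipeline stage failed; message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
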
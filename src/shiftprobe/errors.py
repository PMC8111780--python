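"""Exception hierarchy.

All shiftprobe errors derive from :class:`ShiftprobeError`; validation-type
errors (bad user input, malformed files) derive from :class:`ValidationError`
so the command-line layer can map them to exit code 2.
"""


class ShiftprobeError(Exception):
    """Base class for all package errors."""


class ValidationError(ShiftprobeError, ValueError):
    """Invalid user input or configuration."""


class FormatError(ValidationError):
    """A file does not match the expected dialect/format."""


class DuplicateResidueError(FormatError):
    """More than one peak/row for the same residue index."""


class ConsistencyError(ValidationError):
    """Two inputs disagree (e.g. sequence vs shift-table residue codes)."""


class InfeasibleTitrationError(ValidationError):
    """The requested ligand:protein ratios cannot be reached from the stock."""


class InsufficientDataError(ValidationError):
    """Too few usable data points for the requested operation."""


class UnderdeterminedError(InsufficientDataError):
    """Fewer data points than free parameters."""


class DataError(ValidationError):
    """A data value is unusable (e.g. non-positive reference intensity)."""


class FitError(ShiftprobeError):
    """Nonlinear fit failed to converge from every start."""


class StageError(ShiftprobeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
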
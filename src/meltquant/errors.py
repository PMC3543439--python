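"""Exception hierarchy.

``MeltQuantError`` is the common base; ``ValidationError`` covers anything a
user can fix in their input files (the CLI maps it to exit code 2).
"""


class MeltQuantError(Exception):
    """Base class for all meltquant errors."""


class ValidationError(MeltQuantError):
    """Invalid user input (bad file, bad sheet, bad config)."""


class GridError(ValidationError):
    """Temperature grid is not strictly increasing and uniform."""


class ParseError(ValidationError):
    """A cell in an input table could not be parsed."""


class DegenerateBaselineError(MeltQuantError):
    """Upper and lower melt baselines cross; normalization undefined."""

    def __init__(self, well: str, message: str | None = None):
        self.well = well
        super().__init__(message or f"degenerate baselines for well {well!r}: "
                         "upper baseline does not exceed lower baseline on the grid")


class CalibrationError(MeltQuantError):
    """Standard curve cannot be fitted (duplicate or non-monotone standards)."""
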
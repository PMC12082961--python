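"""Exception hierarchy for the veinmod pipeline."""


class VeinmodError(Exception):
    """Base class for all veinmod errors."""


class ConfigError(VeinmodError):
    """Invalid configuration or rejected input parameters."""


class DegenerateRegionError(VeinmodError):
    """Binary region too small (< 5 pixels) for a moment-based ellipse fit."""


class DegenerateSeriesError(VeinmodError):
    """Series has zero variance after detrending; no spectrum can be estimated."""


class UnsupportedConditionError(VeinmodError):
    """Requested an analysis band for a condition that has none (spontaneous breathing)."""


class AlignmentError(VeinmodError):
    """Inspiration-onset alignment requested but no onsets are available."""


class DegenerateTestError(VeinmodError):
    """Test statistic undefined (zero-variance differences or zero error mean square)."""


class MissingCellError(VeinmodError):
    """A (participant, condition) cell has no observations."""

    def __init__(self, cells):
        self.cells = list(cells)
        super().__init__(f"empty cohort cells: {self.cells}")


class PipelineError(VeinmodError):
    """A pipeline stage failed; message names the stage and offending input."""
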
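"""Exception hierarchy for the redcam pipeline."""


class RedcamError(Exception):
    """Base class for all redcam errors."""


class ConfigurationError(RedcamError):
    """A design, profile or config block is invalid or incomplete."""


class GenerationError(RedcamError):
    """Synthetic scene generation could not satisfy its target."""


class CalibrationError(RedcamError):
    """White balance or color-correction fitting is impossible."""


class ScoringError(RedcamError):
    """Redness scoring cannot proceed (empty ROI, unreadable input)."""


class StatisticError(RedcamError):
    """A statistical routine received degenerate or unbalanced input."""


class RenderError(RedcamError):
    """Report rendering failed because required tables are absent."""
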
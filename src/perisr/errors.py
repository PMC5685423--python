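"""Exception hierarchy for the perisr pipeline."""


class PerisrError(Exception):
    """Base class for all perisr errors."""


class ParameterError(PerisrError, ValueError):
    """A numeric parameter is outside its valid domain."""


class UsageError(PerisrError, ValueError):
    """An operation was called on inputs it is not defined for."""


class ConfigurationError(PerisrError, ValueError):
    """Inconsistent observer/experiment configuration."""


class DegenerateStimulusError(PerisrError, ValueError):
    """Requested optotype is too small to rasterize (empty glyph)."""


class ClippingError(PerisrError, ValueError):
    """Stimulus would extend beyond the rendering canvas."""


class CoverageError(PerisrError, ValueError):
    """Target path leaves the occluder-mask extent."""


class UndefinedCorrelationError(PerisrError, ValueError):
    """Cross-correlation undefined (zero-variance input frame)."""


class NonIdentifiableError(PerisrError, ValueError):
    """Psychometric fit is not identifiable from the supplied trials."""


class UnstableFitError(PerisrError, RuntimeError):
    """Too many bootstrap refits failed for a trustworthy interval."""
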
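"""Exception hierarchy shared across the package."""

from __future__ import annotations


class EndoquantError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(EndoquantError, ValueError):
    """A simulation spec or input record violated an invariant.

    Carries the name of the offending field so callers (and the CLI) can
    point at exactly what was wrong.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DegenerateFrameError(EndoquantError, ValueError):
    """Raised when a frame has MAD 0 and cannot be robustly normalized.

    ``median`` is the frame median so the caller can decide on a fallback
    (e.g. centre-only normalization).
    """

    def __init__(self, median: float):
        self.median = float(median)
        super().__init__(
            f"frame is degenerate (MAD = 0, median = {self.median}); "
            "cannot scale by the median absolute deviation"
        )


class UndefinedNormalizationError(EndoquantError, ValueError):
    """Control and self anchors coincide; percent blocking is undefined."""


class MissingAnchorError(EndoquantError, KeyError):
    """A competition pair lacks its control or self anchor."""


class InfeasibleSpecError(EndoquantError, ValueError):
    """A sequence-pair spec cannot be satisfied (e.g. not enough codons
    admitting a synonymous single-base change)."""


class FormatError(EndoquantError, ValueError):
    """A file could not be parsed as the expected on-disk format."""


class UndefinedCorrelationError(EndoquantError, ValueError):
    """Rank correlation is undefined (constant input vector)."""
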
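"""Exception hierarchy shared across the package."""


class SongRhythmError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SongRhythmError):
    """Malformed input text or bytes; carries the offending location."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(SongRhythmError):
    """Structurally well-formed input that violates a domain invariant."""


class PolyphonyError(ValidationError):
    """More than one simultaneous note in a track that must be monophonic."""

    def __init__(self, onsets):
        self.onsets = list(onsets)
        super().__init__(
            "polyphonic overlap at onsets (beats): "
            + ", ".join(str(o) for o in self.onsets)
        )


class NoPairsError(SongRhythmError):
    """A duration sequence has fewer than two elements, so the pairwise
    statistic is undefined (distinct from a value of zero)."""


class UndefinedStatisticError(SongRhythmError):
    """No phrase of a song contributes a single adjacent duration pair."""


class DegenerateDataError(SongRhythmError):
    """Statistical input with no usable variance or rank-deficient design."""
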
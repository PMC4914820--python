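"""The nPVI durational-contrast statistic and the mean-note-duration tempo
measure.

The normalized pairwise variability index of a duration sequence
``d_1 .. d_m`` is the mean over the ``m - 1`` adjacent pairs of

    100 * |d_k - d_{k+1}| / ((d_k + d_{k+1}) / 2)

It is 0 for a perfectly isochronous sequence and approaches (never reaches)
200 as the contrast within a pair grows without bound. At the song level,
pairs that straddle a phrase boundary are excluded: only within-phrase
adjacent pairs enter the statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import NoPairsError, UndefinedStatisticError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DurationSeries",
    "NPVIResult",
    "pair_contrast",
    "npvi_series",
    "npvi_song",
    "mean_note_duration_ms",
    "npvi_table",
]


@dataclass(frozen=True)
class DurationSeries:
    """Preprocessed duration sequence of one phrase (the ``d_k``)."""

    song_id: str
    phrase_index: int
    durations: tuple

    def __post_init__(self):
        object.__setattr__(self, "durations", tuple(self.durations))
        if len(self.durations) < 1:
            raise ValidationError("DurationSeries must hold at least one element")
        if any(d <= 0 for d in self.durations):
            raise ValidationError("all durations must be positive")

    def __len__(self) -> int:
        return len(self.durations)

    def as_array(self) -> np.ndarray:
        return np.asarray([float(d) for d in self.durations], dtype=float)


@dataclass(frozen=True)
class NPVIResult:
    """Song-level nPVI with pair bookkeeping."""

    song_id: str
    npvi: float
    n_pairs_used: int
    n_pairs_excluded_at_boundaries: int

    def __post_init__(self):
        if not 0.0 <= self.npvi < 200.0:
            raise ValidationError(f"nPVI out of range [0, 200): {self.npvi}")
        if self.n_pairs_used < 1:
            raise ValidationError("at least one pair must contribute")


def pair_contrast(d1: float, d2: float) -> float:
    """Normalized contrast of one duration pair: 100*|d1-d2|/((d1+d2)/2).

    Symmetric in its arguments and scale-invariant; lies in [0, 200).
    """
    d1, d2 = float(d1), float(d2)
    if d1 <= 0 or d2 <= 0:
        raise ValidationError(f"durations must be positive, got ({d1}, {d2})")
    return 100.0 * abs(d1 - d2) / ((d1 + d2) / 2.0)


def _pair_contrasts(durations: np.ndarray) -> np.ndarray:
    return 200.0 * np.abs(np.diff(durations)) / (durations[:-1] + durations[1:])


def npvi_series(series) -> tuple[float, int]:
    """nPVI of a single duration sequence; returns ``(npvi, n_pairs)``.

    ``series`` may be a :class:`DurationSeries` or any sequence of positive
    durations. Raises :class:`NoPairsError` for fewer than two elements —
    an undefined value, deliberately distinct from 0.
    """
    if isinstance(series, DurationSeries):
        values = series.as_array()
    else:
        values = np.asarray([float(d) for d in series], dtype=float)
    if values.size < 2:
        raise NoPairsError(f"need at least 2 elements, got {values.size}")
    if np.any(values <= 0):
        raise ValidationError("all durations must be positive")
    contrasts = _pair_contrasts(values)
    return float(contrasts.mean()), int(contrasts.size)


def npvi_song(
    song,
    policy=None,
    aggregation: Literal["pooled_pairs", "phrase_mean"] = "pooled_pairs",
) -> NPVIResult:
    """Song-level nPVI with phrase-boundary pair exclusion.

    ``pooled_pairs`` (default) averages every within-phrase adjacent pair,
    pooled across phrases — the junction pairs are simply left out.
    ``phrase_mean`` instead averages per-phrase nPVIs, each phrase weighted
    equally. Phrases with a single element contribute no pairs and are
    skipped with a log message.
    """
    from .score_io import DEFAULT_POLICY, preprocess

    series_list = preprocess(song, policy if policy is not None else DEFAULT_POLICY)
    per_phrase: list[tuple[float, int]] = []
    for series in series_list:
        if len(series) < 2:
            logger.info(
                "song %r phrase %d has a single element; no pairs",
                song.id,
                series.phrase_index,
            )
            continue
        per_phrase.append(npvi_series(series))
    if not per_phrase:
        raise UndefinedStatisticError(
            f"song {song.id!r}: no phrase contributes an adjacent duration pair"
        )
    n_pairs = sum(n for _, n in per_phrase)
    if aggregation == "pooled_pairs":
        value = sum(v * n for v, n in per_phrase) / n_pairs
    elif aggregation == "phrase_mean":
        value = sum(v for v, _ in per_phrase) / len(per_phrase)
    else:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    # one junction (= one excluded pair) between each pair of contributing phrases
    n_excluded = max(len(series_list) - 1, 0)
    return NPVIResult(
        song_id=song.id,
        npvi=float(value),
        n_pairs_used=n_pairs,
        n_pairs_excluded_at_boundaries=n_excluded,
    )


def mean_note_duration_ms(song, policy=None, default_bpm: float = 100.0) -> float:
    """Mean element duration in milliseconds — the tempo measure.

    Elements are the preprocessed durations (ties merged, graces dropped);
    beats are converted to ms with the song's notated tempo, or the 600 ms
    per quarter default when no tempo is notated.
    """
    from .score_io import DEFAULT_POLICY, effective_ms_per_quarter, preprocess

    series_list = preprocess(song, policy if policy is not None else DEFAULT_POLICY)
    durations = [d for series in series_list for d in series.durations]
    if not durations:
        raise UndefinedStatisticError(f"song {song.id!r} has no elements")
    mean_beats = float(sum(durations)) / len(durations)
    return mean_beats * effective_ms_per_quarter(song, default_bpm)


def npvi_table(
    corpus,
    policy=None,
    aggregation: Literal["pooled_pairs", "phrase_mean"] = "pooled_pairs",
    default_bpm: float = 100.0,
) -> pd.DataFrame:
    """Per-song rhythm statistics for a whole corpus.

    Returns a DataFrame with columns ``song_id, language, song_type, npvi,
    n_pairs_used, n_pairs_excluded, mean_note_duration_ms``. Songs whose
    nPVI is undefined (no adjacent pairs anywhere) get NaN and a warning
    rather than aborting the batch.
    """
    rows = []
    for song in corpus:
        try:
            result = npvi_song(song, policy=policy, aggregation=aggregation)
            npvi, used, excluded = (
                result.npvi,
                result.n_pairs_used,
                result.n_pairs_excluded_at_boundaries,
            )
        except UndefinedStatisticError as exc:
            logger.warning("%s", exc)
            npvi, used, excluded = np.nan, 0, 0
        try:
            tempo = mean_note_duration_ms(song, policy=policy, default_bpm=default_bpm)
        except UndefinedStatisticError:
            tempo = np.nan
        rows.append(
            {
                "song_id": song.id,
                "language": song.language,
                "song_type": song.song_type,
                "npvi": npvi,
                "n_pairs_used": used,
                "n_pairs_excluded": excluded,
                "mean_note_duration_ms": tempo,
            }
        )
    return pd.DataFrame(rows)
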
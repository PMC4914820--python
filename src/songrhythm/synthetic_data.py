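"""Synthetic song corpora and listener panels with controlled rhythm.

The corpus is undeposited, so every pipeline stage is exercised on
generated data whose rhythm statistics are analytically controlled.

Durational contrast is injected by long–short alternation — the musical
analogue of vowel reduction in stress-timed speech. Each song draws a
target nPVI ``v`` from its cell's normal distribution (cell defaults are
the published cell means, with dispersion back-computed as SEM*sqrt(n)
from the published standard errors). A strictly alternating sequence of
durations ``r, 1, r, 1, ...`` with ``r = (200+c)/(200-c)`` has nPVI
exactly ``c``; here each adjacent element flips between the long and
short state with probability ``alternation_prob`` (else repeats), so a
pair contributes contrast ``c`` when it flips and 0 when it repeats. With
``c = v / alternation_prob`` the expected pooled song nPVI is exactly the
drawn ``v``. Phrase durations are rescaled (a scale-invariance no-op for
the statistic) so each phrase fills a whole number of measures of the
song's sampled meter.

Rater panels endorse songs as "for children" through a logistic model on
(1, familiarity, tempo, nPVI); familiarity loads on own-culture songs and
children's songs, and liking is familiarity-correlated. All randomness
flows from a single integer seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import ValidationError
from .rhythm_metrics import npvi_table
from .score_io import Corpus, NoteEvent, Phrase, Song

logger = logging.getLogger(__name__)

__all__ = [
    "CellConfig",
    "SynthConfig",
    "RaterModel",
    "default_config",
    "default_rater_models",
    "npvi_to_ratio",
    "expected_npvi",
    "generate_corpus",
    "generate_ratings",
]

#: largest per-pair contrast the generator will realize (the statistic's
#: supremum of 200 is unreachable: it would need an infinite ratio)
MAX_CONTRAST = 199.0

# published cell sizes, mean nPVIs, and standard errors of the corpus
_CELL_DEFAULTS = {
    ("English", "children"): (68, 40.43, 1.90),
    ("French", "children"): (61, 33.80, 2.26),
    ("English", "folk"): (72, 43.60, 1.80),
    ("French", "folk"): (68, 40.10, 2.13),
}

# meter marginals of the corpus per language (counts), renormalized; the
# published French counts cover 121 of 129 songs, the remainder unreported
_METER_COUNTS = {
    "English": {(2, 2): 2, (2, 4): 26, (3, 4): 29, (3, 8): 1, (6, 8): 6, (4, 4): 76},
    "French": {(2, 4): 55, (3, 4): 23, (3, 8): 3, (6, 8): 20, (4, 4): 20},
}

_C_MAJOR_SCALE = (60, 62, 64, 65, 67, 69, 71, 72)


def _normalize(dist: dict) -> dict:
    total = float(sum(dist.values()))
    if total <= 0:
        raise ValidationError("distribution weights must sum to a positive value")
    return {k: v / total for k, v in dist.items()}


@dataclass(frozen=True)
class CellConfig:
    """One language x song-type cell of the generated corpus."""

    n_songs: int
    target_npvi: float
    npvi_sd: float

    def __post_init__(self):
        if self.n_songs < 0:
            raise ValidationError(f"n_songs must be non-negative, got {self.n_songs}")
        if not 0 <= self.target_npvi < 200:
            raise ValidationError(f"target_npvi must be in [0, 200), got {self.target_npvi}")
        if self.npvi_sd < 0:
            raise ValidationError("npvi_sd must be non-negative")


def _default_cells() -> dict:
    return {
        key: CellConfig(n, mean, sem * math.sqrt(n))
        for key, (n, mean, sem) in _CELL_DEFAULTS.items()
    }


def _default_meters() -> dict:
    return {lang: _normalize(counts) for lang, counts in _METER_COUNTS.items()}


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters for a synthetic corpus.

    Defaults emulate the published corpus: cell sizes and mean nPVIs from
    the corpus results, dispersion SEM*sqrt(n), and per-language meter
    marginals. ``alternation_prob`` is the per-pair probability of a
    long/short flip; the realized per-flip contrast is compensated so the
    expected song nPVI equals the drawn target.
    """

    cells: dict = field(default_factory=_default_cells)
    alternation_prob: float = 0.85
    phrase_count_dist: dict = field(
        default_factory=lambda: {2: 0.20, 3: 0.35, 4: 0.30, 5: 0.15}
    )
    phrase_length_dist: dict = field(
        default_factory=lambda: {m: 1.0 for m in range(8, 17)}
    )
    meter_dist: dict = field(default_factory=_default_meters)
    base_duration_dist: dict = field(
        default_factory=lambda: {
            Fraction(1, 4): 0.20,
            Fraction(1, 2): 0.45,
            Fraction(3, 4): 0.10,
            Fraction(1, 1): 0.25,
        }
    )
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alternation_prob <= 1.0:
            raise ValidationError("alternation_prob must be in [0, 1]")
        for name in ("phrase_count_dist", "phrase_length_dist", "base_duration_dist"):
            object.__setattr__(self, name, _normalize(getattr(self, name)))
        object.__setattr__(
            self, "meter_dist", {k: _normalize(v) for k, v in self.meter_dist.items()}
        )
        for (language, song_type), cell in self.cells.items():
            if not isinstance(cell, CellConfig):
                raise ValidationError(f"cell {(language, song_type)} is not a CellConfig")
            if language not in self.meter_dist:
                raise ValidationError(f"no meter distribution for language {language!r}")


def default_config(**overrides) -> SynthConfig:
    return replace(SynthConfig(), **overrides) if overrides else SynthConfig()


def npvi_to_ratio(v: float) -> float:
    """Long:short ratio whose strict alternation realizes nPVI ``v``.

    Inverts the pair-contrast formula: a series r, 1, r, 1, ... has every
    pair contrast 200(r-1)/(r+1), so r = (200+v)/(200-v).
    """
    if not 0 <= v < 200:
        raise ValidationError(f"nPVI target must be in [0, 200), got {v}")
    return (200.0 + v) / (200.0 - v)


def _per_flip_contrast(target: float, alternation_prob: float) -> float:
    if alternation_prob == 0.0:
        return 0.0
    return min(target / alternation_prob, MAX_CONTRAST)


def expected_npvi(config: SynthConfig) -> dict:
    """Analytic expected pooled nPVI per cell under the generator.

    Each within-phrase pair independently flips with probability ``p`` and
    then carries contrast ``c = min(target/p, cap)``, else 0, so the
    pair-count-weighted expectation is ``p * c`` — the cell target except
    when the compensation hits the contrast cap. Clamping of the per-song
    normal draw at 0 adds a bias that is negligible for the default cells.
    """
    p = config.alternation_prob
    return {
        key: p * _per_flip_contrast(cell.target_npvi, p)
        for key, cell in config.cells.items()
    }


def _sample(rng: np.random.Generator, dist: dict):
    keys = list(dist.keys())
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs)]


def _quantize(x: float) -> Fraction:
    return Fraction(round(x * 1000), 1000)


def _generate_song(
    song_id: str,
    language: str,
    song_type: str,
    cell: CellConfig,
    config: SynthConfig,
    rng: np.random.Generator,
) -> Song:
    p = config.alternation_prob
    v = float(np.clip(rng.normal(cell.target_npvi, cell.npvi_sd), 0.0, MAX_CONTRAST))
    contrast = _quantize(_per_flip_contrast(v, p))
    ratio = (200 + contrast) / (200 - contrast)  # exact Fraction
    base = _sample(rng, config.base_duration_dist)
    meter = _sample(rng, config.meter_dist[language])
    measure_beats = Fraction(meter[0] * 4, meter[1])

    n_phrases = _sample(rng, config.phrase_count_dist)
    phrases = []
    clock = Fraction(0)
    for phrase_index in range(n_phrases):
        m = _sample(rng, config.phrase_length_dist)
        while m < 2:  # an infeasible (pairless) phrase length; redraw
            logger.info("song %s: resampling phrase length %d", song_id, m)
            m = _sample(rng, config.phrase_length_dist)
        long_state = bool(rng.integers(0, 2))
        durations = []
        for k in range(m):
            if k > 0 and rng.random() < p:
                long_state = not long_state
            durations.append(base * ratio if long_state else base)
        total = sum(durations)
        n_measures = max(1, round(total / measure_beats))
        scale = (n_measures * measure_beats) / total
        durations = [d * scale for d in durations]
        events = []
        for d in durations:
            pitch = int(_C_MAJOR_SCALE[rng.integers(0, len(_C_MAJOR_SCALE))])
            events.append(NoteEvent(onset=clock, duration=d, pitch=pitch))
            clock += d
        phrases.append(Phrase(index=phrase_index, events=events))
    return Song(
        id=song_id,
        language=language,
        song_type=song_type,
        meter=meter,
        key="C",
        tempo_ms_per_quarter=None,
        phrases=phrases,
    )


def generate_corpus(config: SynthConfig | None = None, seed: int | None = None) -> Corpus:
    """Generate a corpus; deterministic for a fixed config and seed."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    songs = []
    for (language, song_type) in sorted(config.cells):
        cell = config.cells[(language, song_type)]
        for i in range(cell.n_songs):
            songs.append(
                _generate_song(
                    f"{language}_{song_type}_{i:03d}", language, song_type, cell, config, rng
                )
            )
    return Corpus(songs=songs, provenance=f"synthetic (seed={config.seed if seed is None else seed})")


# ---------------------------------------------------------------------------
# rater panels


@dataclass(frozen=True)
class RaterModel:
    """Generative model of one listener group's rating behavior.

    ``beta`` are the logistic endorsement weights on (1, familiarity,
    tempo in ms, nPVI). Familiarity rises for songs of the rater's own
    culture and for children's songs; liking tracks familiarity with
    independent noise. Confidence encodes the latent endorsement
    probability on the 1-7 scale (it is stored but analyzed nowhere).
    """

    group: str
    n_participants: int
    own_language: str
    beta: tuple[float, float, float, float]
    familiarity_base: float = 2.6
    own_culture_bonus: float = 1.3
    children_bonus: float = 0.7
    familiarity_noise_sd: float = 1.2
    liking_base: float = 3.8
    liking_weight: float = 0.6
    liking_noise_sd: float = 1.3
    music_years_mean: float = 2.5
    music_years_sd: float = 3.5
    dance_years_mean: float = 1.4
    dance_years_sd: float = 2.5

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if min(self.familiarity_noise_sd, self.liking_noise_sd) < 0:
            raise ValidationError("noise scales must be non-negative")
        if len(self.beta) != 4:
            raise ValidationError("beta must be (intercept, familiarity, tempo, npvi)")


def default_rater_models() -> list[RaterModel]:
    """Panels mirroring the rating study: 70 monolingual Americans, 30
    bilingual Americans, 40 French listeners. Tempo loads negatively for
    all groups; nPVI loads negatively for the syllable-timed-language
    groups (strongly for French, weakly for bilingual Americans, not at
    all for monolingual Americans)."""
    return [
        RaterModel(
            group="monolingual_american",
            n_participants=70,
            own_language="English",
            beta=(1.0, 0.5, -0.006, 0.0),
        ),
        RaterModel(
            group="bilingual_american",
            n_participants=30,
            own_language="English",
            beta=(1.8, 0.5, -0.006, -0.02),
        ),
        RaterModel(
            group="french",
            n_participants=40,
            own_language="French",
            beta=(2.9, 0.5, -0.006, -0.05),
        ),
    ]


def generate_ratings(
    corpus: Corpus,
    rater_models: list[RaterModel] | None = None,
    seed: int = 0,
    rhythm_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate a full rating study; one row per participant x song.

    Every participant rates every song. Endorsement of song ``s`` by a
    participant with familiarity rating ``f`` is Bernoulli with
    probability ``logistic(b0 + b1*f + b2*tempo_s + b3*npvi_s)``.
    Deterministic for fixed inputs and seed.
    """
    rater_models = rater_models if rater_models is not None else default_rater_models()
    if rhythm_table is None:
        rhythm_table = npvi_table(corpus)
    rhythm = rhythm_table.dropna(subset=["npvi"]).set_index("song_id")
    song_ids = [s.id for s in corpus if s.id in rhythm.index]
    n_songs = len(song_ids)
    if n_songs == 0:
        raise ValidationError("no songs with defined rhythm statistics")
    npvi = rhythm["npvi"].reindex(song_ids).to_numpy(dtype=float)
    tempo = rhythm["mean_note_duration_ms"].reindex(song_ids).to_numpy(dtype=float)
    own = {s.id: s.language for s in corpus}
    child = np.array(
        [corpus.get(sid).song_type == "children" for sid in song_ids], dtype=float
    )

    rng = np.random.default_rng(seed)
    frames = []
    for model in rater_models:
        n_p = model.n_participants
        own_culture = np.array(
            [own[sid] == model.own_language for sid in song_ids], dtype=float
        )
        fam_mean = (
            model.familiarity_base
            + model.own_culture_bonus * own_culture
            + model.children_bonus * child
        )
        fam = fam_mean[None, :] + rng.normal(0.0, model.familiarity_noise_sd, (n_p, n_songs))
        fam = np.clip(np.rint(fam), 1, 7).astype(int)
        lik = (
            model.liking_base
            + model.liking_weight * (fam - fam.mean())
            + rng.normal(0.0, model.liking_noise_sd, (n_p, n_songs))
        )
        lik = np.clip(np.rint(lik), 1, 7).astype(int)
        b0, b_fam, b_tempo, b_npvi = model.beta
        logit = b0 + b_fam * fam + (b_tempo * tempo + b_npvi * npvi)[None, :]
        prob = 1.0 / (1.0 + np.exp(-logit))
        endorsed = (rng.random((n_p, n_songs)) < prob).astype(int)
        confidence = np.clip(np.rint(4.0 + 6.0 * (prob - 0.5)), 1, 7).astype(int)
        music = np.round(np.clip(rng.normal(model.music_years_mean, model.music_years_sd, n_p), 0, None), 1)
        dance = np.round(np.clip(rng.normal(model.dance_years_mean, model.dance_years_sd, n_p), 0, None), 1)
        pid = np.array([f"{model.group}-p{j:03d}" for j in range(n_p)])
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(pid, n_songs),
                    "group": model.group,
                    "song_id": np.tile(song_ids, n_p),
                    "familiarity": fam.ravel(),
                    "liking": lik.ravel(),
                    "endorsed": endorsed.ravel(),
                    "confidence": confidence.ravel(),
                    "music_years": np.repeat(music, n_songs),
                    "dance_years": np.repeat(dance, n_songs),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
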
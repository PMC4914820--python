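"""Listener-rating aggregation and the child-directedness regression.

Ratings arrive as one record per participant x song (familiarity 1-7,
liking 1-7, a binary "for children" endorsement, confidence 1-7, listener
group, training years). Analyses aggregate to the song level per listener
group and regress the group's endorsement proportion on four song-level
predictors — mean familiarity, mean liking (preference), tempo (mean note
duration in ms) and nPVI — reporting each predictor's simple correlation
and its R² change: the drop in the full model's R² when that predictor is
removed, i.e. its unique contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "GROUPS",
    "PREDICTORS",
    "RatingRecord",
    "RegressionResult",
    "validate_ratings",
    "participant_category_proportions",
    "aggregate_by_song",
    "regress_child_directedness",
    "correlate",
    "read_ratings_csv",
    "write_ratings_csv",
]

GROUPS = ("monolingual_american", "bilingual_american", "french")
PREDICTORS = ("familiarity", "preference", "tempo", "npvi")

RATINGS_COLUMNS = [
    "participant_id",
    "group",
    "song_id",
    "familiarity",
    "liking",
    "endorsed",
    "confidence",
    "music_years",
    "dance_years",
]


@dataclass(frozen=True)
class RatingRecord:
    """One participant's response to one song."""

    participant_id: str
    group: str
    song_id: str
    familiarity: int
    liking: int
    endorsed_for_children: bool
    confidence: int
    music_training_years: float = 0.0
    dance_training_years: float = 0.0

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        for name in ("familiarity", "liking", "confidence"):
            value = getattr(self, name)
            if not 1 <= value <= 7:
                raise ValidationError(f"{name} must be in 1..7, got {value}")
        if self.music_training_years < 0 or self.dance_training_years < 0:
            raise ValidationError("training years must be non-negative")


def validate_ratings(records: pd.DataFrame) -> pd.DataFrame:
    """Check scale bounds and uniqueness of participant x song pairs."""
    missing = set(RATINGS_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"ratings table missing columns: {sorted(missing)}")
    if records.empty:
        raise ValidationError("ratings table is empty")
    for name in ("familiarity", "liking", "confidence"):
        col = records[name]
        if col.min() < 1 or col.max() > 7:
            raise ValidationError(f"{name} outside the 1..7 scale")
    unknown = set(records["group"].unique()) - set(GROUPS)
    if unknown:
        raise ValidationError(f"unknown listener groups: {sorted(unknown)}")
    if records.duplicated(["participant_id", "song_id"]).any():
        raise ValidationError("duplicate participant x song records")
    return records


def read_ratings_csv(path) -> pd.DataFrame:
    return validate_ratings(pd.read_csv(path))


def write_ratings_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def participant_category_proportions(
    records: pd.DataFrame, song_categories: pd.DataFrame
) -> pd.DataFrame:
    """Per-participant endorsement proportion in each song category.

    ``song_categories`` maps ``song_id`` to ``language`` and ``song_type``;
    a category is a language x song_type cell. Participants with no
    presented songs in a category get NaN (missing), never 0.
    """
    cats = song_categories.set_index("song_id")[["language", "song_type"]]
    unknown = set(records["song_id"]) - set(cats.index)
    if unknown:
        raise ValidationError(f"ratings reference unknown songs: {sorted(unknown)[:5]}")
    merged = records.merge(cats, left_on="song_id", right_index=True)
    merged["category"] = merged["language"] + "/" + merged["song_type"]
    table = merged.pivot_table(
        index="participant_id",
        columns="category",
        values="endorsed",
        aggfunc="mean",
    )
    return table


def aggregate_by_song(records: pd.DataFrame, rhythm_table: pd.DataFrame) -> pd.DataFrame:
    """Song x group aggregates joined with rhythm predictors.

    Returns one row per (song_id, group) with ``familiarity`` and
    ``preference`` means, the ``endorsement`` proportion, ``n_raters``,
    and the song's ``npvi`` and ``tempo`` (mean note duration, ms).
    Songs missing from the rhythm table raise an error naming them.
    """
    rhythm = rhythm_table.set_index("song_id")
    missing = set(records["song_id"]) - set(rhythm.index)
    if missing:
        raise ValidationError(
            f"no rhythm statistics for songs: {sorted(missing)[:5]}"
        )
    grouped = records.groupby(["song_id", "group"], sort=True).agg(
        familiarity=("familiarity", "mean"),
        preference=("liking", "mean"),
        endorsement=("endorsed", "mean"),
        n_raters=("endorsed", "size"),
    )
    out = grouped.reset_index()
    out["npvi"] = rhythm["npvi"].reindex(out["song_id"]).to_numpy()
    out["tempo"] = rhythm["mean_note_duration_ms"].reindex(out["song_id"]).to_numpy()
    return out


@dataclass(frozen=True)
class RegressionResult:
    """Four-predictor OLS fit of a group's endorsement proportions."""

    group: str
    n_songs: int
    coefficients: dict  # intercept + one per predictor
    r_simple: dict
    r2_full: float
    r2_change: dict
    f_change: dict
    p_change: dict

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_songs": self.n_songs,
            "coefficients": dict(self.coefficients),
            "r_simple": dict(self.r_simple),
            "r2_full": self.r2_full,
            "r2_change": dict(self.r2_change),
            "f_change": dict(self.f_change),
            "p_change": dict(self.p_change),
        }


def correlate(x, y) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need two equal-length samples of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in a correlation input")
    return float(sps.pearsonr(x, y).statistic)


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the predictors involved in the collinearity via pairwise checks
        suspects = []
        centered = design[:, 1:] - design[:, 1:].mean(axis=0)
        corr = np.corrcoef(centered, rowvar=False)
        k = len(names)
        for i in range(k):
            for j in range(i + 1, k):
                if abs(corr[i, j]) > 1 - 1e-10:
                    suspects.append((names[i], names[j]))
        detail = f"; collinear pairs: {suspects}" if suspects else ""
        raise DegenerateDataError(f"rank-deficient design matrix{detail}")


def regress_child_directedness(
    aggregates: pd.DataFrame, group: str, min_songs: int = 10
) -> RegressionResult:
    """Fit the four-predictor child-directedness regression for one group.

    Ordinary least squares of the group's per-song endorsement proportion
    on familiarity, preference, tempo and nPVI (entered raw; R²-based
    quantities are scale-invariant). R² change for each predictor is
    computed by refitting the model without it; its significance is the
    F-test for the one-degree nested comparison. Rows with any missing
    value are dropped listwise.
    """
    sub = aggregates[aggregates["group"] == group] if "group" in aggregates else aggregates
    cols = list(PREDICTORS) + ["endorsement"]
    sub = sub.dropna(subset=cols)
    n = len(sub)
    if n < min_songs:
        raise DegenerateDataError(
            f"group {group!r}: only {n} complete songs (< {min_songs})"
        )
    y = sub["endorsement"].to_numpy(dtype=float)
    X = sub[list(PREDICTORS)].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    _check_rank(design, list(PREDICTORS))

    full = sm.OLS(y, design).fit()
    r2_full = float(full.rsquared)
    k = len(PREDICTORS)
    dof_resid = n - k - 1

    r_simple, r2_change, f_change, p_change = {}, {}, {}, {}
    for i, name in enumerate(PREDICTORS):
        r_simple[name] = correlate(X[:, i], y)
        reduced_design = np.delete(design, i + 1, axis=1)
        reduced = sm.OLS(y, reduced_design).fit()
        change = max(r2_full - float(reduced.rsquared), 0.0)
        r2_change[name] = change
        if r2_full >= 1.0 - 1e-14:
            f = np.inf if change > 1e-14 else 0.0
        else:
            f = change / ((1.0 - r2_full) / dof_resid)
        f_change[name] = float(f)
        p_change[name] = float(sps.f.sf(f, 1, dof_resid)) if np.isfinite(f) else 0.0

    coefficients = {"intercept": float(full.params[0])}
    coefficients.update({name: float(b) for name, b in zip(PREDICTORS, full.params[1:])})
    return RegressionResult(
        group=group,
        n_songs=n,
        coefficients=coefficients,
        r_simple=r_simple,
        r2_full=r2_full,
        r2_change=r2_change,
        f_change=f_change,
        p_change=p_change,
    )
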
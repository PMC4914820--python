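"""Group summaries and two-sample comparisons for corpus rhythm statistics.

Works from summary statistics (n, mean, SD or SEM) as well as raw values,
because published group contrasts are often only recoverable from printed
means and standard errors. The pooled two-sample t here, fed printed
summaries, reproduces published t values to within rounding of the inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "summarize",
    "t_independent",
    "t_independent_from_values",
    "weighted_pooled_mean",
    "compare_report",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError(f"group {self.label!r}: need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(self.n)

    @classmethod
    def from_mean_sem(cls, label: str, n: int, mean: float, sem: float) -> "GroupSummary":
        """Build from a printed mean and standard error (SD = SEM * sqrt(n))."""
        return cls(label=label, n=n, mean=mean, sd=sem * math.sqrt(n))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    tail: Literal["one", "two"]
    method: Literal["pooled", "welch"]


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    """Sample mean and SD (n-1 denominator) of a group of values."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError(f"need at least 2 values to summarize, got {arr.size}")
    return GroupSummary(label=label, n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def t_independent(
    g1: GroupSummary,
    g2: GroupSummary,
    method: Literal["pooled", "welch"] = "pooled",
    tail: Literal["one", "two"] = "two",
) -> TTestResult:
    """Independent-samples t-test from group summaries.

    ``pooled`` uses the classical equal-variance form with df = n1 + n2 - 2;
    ``welch`` the unpooled form with Welch–Satterthwaite df. One-tailed p
    is for the directional hypothesis matching the observed sign of t.
    """
    n1, n2 = g1.n, g2.n
    v1, v2 = g1.sd**2, g2.sd**2
    diff = g1.mean - g2.mean
    if method == "pooled":
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    elif method == "welch":
        se = math.sqrt(v1 / n1 + v2 / n2)
        if se > 0:
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        else:
            df = float(n1 + n2 - 2)
    else:
        raise ValidationError(f"unknown method {method!r}")
    if se == 0.0:
        if diff == 0.0:
            t = 0.0
        else:
            raise DegenerateDataError(
                "zero within-group variance with unequal means: t is infinite"
            )
    else:
        t = diff / se
    p_two = 2.0 * float(sps.t.sf(abs(t), df))
    p = p_two / 2.0 if tail == "one" else p_two
    return TTestResult(t=float(t), df=df, p=min(p, 1.0), tail=tail, method=method)


def t_independent_from_values(
    values1: Sequence[float],
    values2: Sequence[float],
    method: Literal["pooled", "welch"] = "pooled",
    tail: Literal["one", "two"] = "two",
    labels: tuple[str, str] = ("group1", "group2"),
) -> TTestResult:
    return t_independent(
        summarize(values1, labels[0]), summarize(values2, labels[1]), method=method, tail=tail
    )


def weighted_pooled_mean(summaries: Sequence[GroupSummary]) -> float:
    """n-weighted mean of group means: sum(n_i m_i) / sum(n_i)."""
    if not summaries:
        raise ValidationError("need at least one summary")
    total_n = sum(g.n for g in summaries)
    return sum(g.n * g.mean for g in summaries) / total_n


def compare_report(table) -> dict:
    """Cell summaries and the two planned language contrasts from a per-song
    rhythm table (columns ``language, song_type, npvi``).

    Mirrors the corpus analysis: per-cell (language x song_type) n/mean/SEM,
    per-language and per-type pooled means, and the English-vs-French pooled
    two-tailed t within each song type.
    """
    import pandas as pd

    df = pd.DataFrame(table).dropna(subset=["npvi"])
    cells: dict[str, GroupSummary] = {}
    for (language, song_type), sub in df.groupby(["language", "song_type"], sort=True):
        if len(sub) >= 2:
            cells[f"{language}/{song_type}"] = summarize(
                sub["npvi"].to_numpy(), f"{language}/{song_type}"
            )

    languages = sorted(df["language"].unique())
    song_types = sorted(df["song_type"].unique())
    report: dict = {
        "cells": {
            k: {"n": g.n, "mean": g.mean, "sd": g.sd, "sem": g.sem}
            for k, g in cells.items()
        },
        "language_means": {},
        "contrasts": {},
    }
    for language in languages:
        members = [g for k, g in cells.items() if k.startswith(f"{language}/")]
        if members:
            report["language_means"][language] = weighted_pooled_mean(members)
    if len(languages) != 2:
        raise DegenerateDataError(
            f"need exactly 2 language groups for contrasts, got {languages}"
        )
    for song_type in song_types:
        pair = [cells.get(f"{lang}/{song_type}") for lang in languages]
        if any(g is None for g in pair):
            raise DegenerateDataError(
                f"missing cell for contrast within song_type {song_type!r}"
            )
        res = t_independent(pair[0], pair[1], method="pooled", tail="two")
        report["contrasts"][song_type] = {
            "groups": [g.label for g in pair],
            "t": res.t,
            "df": res.df,
            "p": res.p,
            "tail": res.tail,
            "method": res.method,
        }
    return report
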
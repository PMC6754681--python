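"""Aggregate lexicon matches into daily and windowed total scores, and
interpret scores against quartile-derived norms.

The screening statistic is the *total score*: the tally of typed words
matched by the depression lexicon over a scoring window, one point per
matched occurrence.  Windows of 7 and 14 days mirror the recall frames of
the CES-D (past week) and BDI-II (past two weeks).  Interpretation norms
are quartile cuts over a reference cohort's scores, yielding four levels
(normal, above normal, high, critical); the built-in default table carries
the published cuts 19/38/65 with an observed maximum of 164.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .lexicon import Category, Lexicon, TextEvent, match_text

__all__ = [
    "DailyEvaluation",
    "WindowScore",
    "NormTable",
    "ScreeningLevel",
    "LEVELS",
    "aggregate_daily",
    "compute_window_score",
    "derive_norms",
    "classify_score",
    "window_scores_to_frame",
]

#: Interpretation levels, ordered from least to most severe.
LEVELS = ("normal", "above_normal", "high", "critical")


@dataclass
class DailyEvaluation:
    """Per-participant, per-local-calendar-day tally of lexicon matches."""

    participant_id: str
    date: date
    total: int
    per_category: dict[Category, int] = field(default_factory=dict)


@dataclass
class WindowScore:
    """Total score over a closed calendar-day window.

    ``total`` is the sum of daily totals inside [start_date, end_date];
    days with no recorded text contribute zero.
    """

    participant_id: str
    window_days: int
    start_date: date
    end_date: date
    total: int
    per_category: dict[Category, int] = field(default_factory=dict)


@dataclass(frozen=True)
class ScreeningLevel:
    """One interpretation level with its integer score interval."""

    label: str
    low: int
    high: int  # inclusive; the critical level is open-ended above max_observed


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class NormTable:
    """Quartile cut points partitioning scores into four levels.

    Intervals are [0, q1], (q1, q2], (q2, q3], (q3, max_observed]; scores
    above ``max_observed`` still classify as critical (a norm table caps
    what was observed in the reference cohort, not what a new participant
    can type).
    """

    q1: int
    q2: int
    q3: int
    max_observed: int
    source: str = "reference"
    n_reference: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.q1 < self.q2 < self.q3 <= self.max_observed):
            raise ValueError(
                f"invalid norm boundaries: need 0 <= q1 < q2 < q3 <= max, "
                f"got {self.q1}/{self.q2}/{self.q3}/{self.max_observed}"
            )

    @classmethod
    def default(cls) -> "NormTable":
        """The published interpretation table (cuts 19/38/65, max 164)."""
        return cls(q1=19, q2=38, q3=65, max_observed=164, source="published")

    def levels(self) -> list[ScreeningLevel]:
        return [
            ScreeningLevel("normal", 0, self.q1),
            ScreeningLevel("above_normal", self.q1 + 1, self.q2),
            ScreeningLevel("high", self.q2 + 1, self.q3),
            ScreeningLevel("critical", self.q3 + 1, self.max_observed),
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "q1": self.q1,
                "q2": self.q2,
                "q3": self.q3,
                "max_observed": self.max_observed,
                "source": self.source,
                "n_reference": self.n_reference,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NormTable":
        d = json.loads(text)
        return cls(
            q1=d["q1"],
            q2=d["q2"],
            q3=d["q3"],
            max_observed=d["max_observed"],
            source=d.get("source", "reference"),
            n_reference=d.get("n_reference"),
        )


def aggregate_daily(
    events: Iterable[TextEvent],
    lexicon: Lexicon,
    timezone: str = "UTC",
    include_pronouns: bool = True,
) -> list[DailyEvaluation]:
    """Group events by participant and local calendar day, matching each.

    Each day's counts are the sum of ``match_text`` over that day's events.
    Days with no events are simply absent (downstream windowing treats them
    as zero).  Events are bucketed by the *local* day in ``timezone``, so an
    event at 23:59 and one at 00:01 the next day land in different
    evaluations.
    """
    tz = ZoneInfo(timezone)
    buckets: dict[tuple[str, date], DailyEvaluation] = {}
    for ev in events:
        local_day = ev.timestamp.astimezone(tz).date()
        key = (ev.participant_id, local_day)
        if key not in buckets:
            buckets[key] = DailyEvaluation(ev.participant_id, local_day, 0, {})
        m = match_text(ev.text, lexicon, include_pronouns=include_pronouns)
        b = buckets[key]
        b.total += m.total
        for cat, n in m.per_category.items():
            b.per_category[cat] = b.per_category.get(cat, 0) + n
    return [buckets[k] for k in sorted(buckets, key=lambda k: (k[0], k[1]))]


def compute_window_score(
    dailies: Sequence[DailyEvaluation],
    participant_id: str,
    end_date: date,
    window_days: int,
) -> WindowScore:
    """Sum a participant's daily totals over the closed window ending at
    ``end_date``; missing days contribute zero."""
    if window_days < 1:
        raise ValueError(f"window_days must be >= 1, got {window_days}")
    start = end_date - timedelta(days=window_days - 1)
    total = 0
    per_category: dict[Category, int] = {}
    for d in dailies:
        if d.participant_id != participant_id or not (start <= d.date <= end_date):
            continue
        total += d.total
        for cat, n in d.per_category.items():
            per_category[cat] = per_category.get(cat, 0) + n
    return WindowScore(participant_id, window_days, start, end_date, total, per_category)


def derive_norms(
    reference_scores: Sequence[float],
    source: str = "reference",
) -> NormTable:
    """Derive quartile interpretation norms from a reference cohort.

    Cut points are the 25th/50th/75th percentiles under the linear-
    interpolation quantile definition, rounded half-up to integers.  A
    sample that is too small (< 8) or degenerate (all equal, or quartiles
    that collapse after rounding) cannot be normed.
    """
    scores = np.asarray(list(reference_scores), dtype=float)
    if scores.size < 8:
        raise ValueError(
            f"need at least 8 reference scores to derive norms, got {scores.size}"
        )
    if np.any(scores < 0):
        raise ValueError("reference scores must be non-negative")
    if np.all(scores == scores[0]):
        raise ValueError("reference scores are all identical; sample cannot be normed")
    q1, q2, q3 = (
        _round_half_up(v) for v in np.percentile(scores, [25, 50, 75])
    )
    max_obs = int(scores.max())
    if not (0 <= q1 < q2 < q3 <= max_obs):
        raise ValueError(
            f"degenerate quartiles {q1}/{q2}/{q3} (max {max_obs}); "
            "sample cannot be normed"
        )
    return NormTable(q1, q2, q3, max_obs, source=source, n_reference=scores.size)


def classify_score(total: float, norms: NormTable | None = None) -> ScreeningLevel:
    """Map a total score to its interpretation level.

    Scores above the table's observed maximum classify as critical.
    """
    if norms is None:
        norms = NormTable.default()
    if total < 0:
        raise ValueError(f"total score must be non-negative, got {total}")
    for level in norms.levels():
        if total <= level.high:
            return level
    return norms.levels()[-1]


def window_scores_to_frame(windows: Sequence[WindowScore]) -> pd.DataFrame:
    """Tabulate window scores: one row per (participant, window), one
    column per symptom category (absent categories fill with zero)."""
    rows = []
    for w in windows:
        row: dict[str, object] = {
            "participant_id": w.participant_id,
            "window_days": w.window_days,
            "start_date": w.start_date.isoformat(),
            "end_date": w.end_date.isoformat(),
            "total": w.total,
        }
        for cat in Category:
            row[cat.value] = w.per_category.get(cat, 0)
        rows.append(row)
    columns = [
        "participant_id",
        "window_days",
        "start_date",
        "end_date",
        "total",
        *[c.value for c in Category],
    ]
    return pd.DataFrame(rows, columns=columns)
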
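"""Synthetic cohorts for end-to-end exercise of the screening pipeline.

No raw study data is available for this kind of screening method (free-text
keystrokes are privacy-sensitive and the published lexicon is proprietary),
so validation of the *pipeline* relies on simulation: each participant
carries a latent depression severity ``theta`` that drives both

* keyword emission — per day and symptom category, a Poisson count with
  log-mean ``a_c + b_c * theta`` (optionally gamma-mixed for extra
  overdispersion), embedded among filler words across a random number of
  timestamped text events; and
* questionnaire responses — item scores discretized from a latent
  ``loading * theta + noise`` through equal-probability thresholds, with
  signed loadings (positive for BDI-II, CES-D and ABS negative affect;
  negative for ABS positive affect and SWLS).

This reproduces the qualitative structure the validation statistics are
meant to detect — positive congruent/convergent correlations, negative
divergent ones, overdispersed window totals — without pretending to be
linguistically realistic text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from typing import Mapping

import numpy as np
import pandas as pd

from .lexicon import (
    Category,
    Language,
    Lexicon,
    LexiconEntry,
    TextEvent,
    VariantKind,
)
from .questionnaires import ITEM_SPECS, CESD_REVERSE_ITEMS, Instrument, InstrumentResponse

__all__ = [
    "CohortConfig",
    "SimulatedDataset",
    "make_demo_lexicon",
    "simulate_cohort",
    "apply_attrition",
]

# A small built-in lexicon covering all 14 categories, with English and
# Tagalog keywords, derivatives, textolog shortenings, a multi-word phrase
# and emoticons — enough surface diversity to exercise the matcher.
_DEMO_ROWS: tuple[tuple[str, Category, Language, VariantKind], ...] = (
    ("sad", Category.MOOD, Language.EN, VariantKind.MAIN),
    ("sadness", Category.MOOD, Language.EN, VariantKind.DERIVATIVE),
    ("lungkot", Category.MOOD, Language.TL, VariantKind.MAIN),
    ("malungkot", Category.MOOD, Language.TL, VariantKind.DERIVATIVE),
    (":(", Category.MOOD, Language.MIXED, VariantKind.EMOTICON),
    (":'(", Category.MOOD, Language.MIXED, VariantKind.EMOTICON),
    ("bored", Category.INTEREST, Language.EN, VariantKind.MAIN),
    ("walang gana", Category.INTEREST, Language.TL, VariantKind.MAIN),
    ("appetite", Category.APPETITE_WEIGHT, Language.EN, VariantKind.MAIN),
    ("gutom", Category.APPETITE_WEIGHT, Language.TL, VariantKind.MAIN),
    ("insomnia", Category.SLEEP, Language.EN, VariantKind.MAIN),
    ("puyat", Category.SLEEP, Language.TL, VariantKind.MAIN),
    ("restless", Category.PSYCHOMOTOR_AGITATION, Language.EN, VariantKind.MAIN),
    ("balisa", Category.PSYCHOMOTOR_AGITATION, Language.TL, VariantKind.MAIN),
    ("sluggish", Category.PSYCHOMOTOR_RETARDATION, Language.EN, VariantKind.MAIN),
    ("makupad", Category.PSYCHOMOTOR_RETARDATION, Language.TL, VariantKind.MAIN),
    ("tired", Category.FATIGUE, Language.EN, VariantKind.MAIN),
    ("pagod", Category.FATIGUE, Language.TL, VariantKind.MAIN),
    ("pgod", Category.FATIGUE, Language.TL, VariantKind.TEXTOLOG),
    ("worthless", Category.GUILT_SELF_ESTEEM, Language.EN, VariantKind.MAIN),
    ("sisi", Category.GUILT_SELF_ESTEEM, Language.TL, VariantKind.MAIN),
    ("distracted", Category.CONCENTRATION, Language.EN, VariantKind.MAIN),
    ("tulala", Category.CONCENTRATION, Language.TL, VariantKind.MAIN),
    ("suicidal", Category.SUICIDE, Language.EN, VariantKind.MAIN),
    ("wakas", Category.SUICIDE, Language.TL, VariantKind.MAIN),
    ("drunk", Category.ALCOHOL_SUBSTANCE, Language.EN, VariantKind.MAIN),
    ("lasing", Category.ALCOHOL_SUBSTANCE, Language.TL, VariantKind.MAIN),
    ("worried", Category.ANXIETY, Language.EN, VariantKind.MAIN),
    ("kaba", Category.ANXIETY, Language.TL, VariantKind.MAIN),
    ("dramatic", Category.HISTRIONIC, Language.EN, VariantKind.MAIN),
    ("arte", Category.HISTRIONIC, Language.TL, VariantKind.MAIN),
    ("i", Category.FIRST_PERSON_PRONOUN, Language.EN, VariantKind.MAIN),
    ("me", Category.FIRST_PERSON_PRONOUN, Language.EN, VariantKind.MAIN),
    ("myself", Category.FIRST_PERSON_PRONOUN, Language.EN, VariantKind.MAIN),
    ("ako", Category.FIRST_PERSON_PRONOUN, Language.TL, VariantKind.MAIN),
)

_FILLER_BASE = (
    "the", "and", "to", "of", "a", "in", "is", "it", "you", "that",
    "he", "was", "for", "on", "are", "with", "as", "his", "they", "at",
    "be", "this", "have", "from", "or", "one", "had", "by", "word", "but",
)


def make_demo_lexicon() -> Lexicon:
    """A compact two-language lexicon covering all 14 categories."""
    return Lexicon(LexiconEntry(*row) for row in _DEMO_ROWS)


#: Default signed loadings of each instrument measure on latent severity.
DEFAULT_LOADINGS: dict[str, float] = {
    "bdi2": 0.9,
    "cesd": 0.9,
    "abs_negative": 0.6,
    "abs_positive": -0.6,
    "swls": -0.8,
}


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one synthetic study cohort.

    Defaults emulate a two-week screening administration: 14 days of free
    text at ~3 events/day, with category keyword emission at baseline rate
    exp(base_rate) ~ 0.39/day/category and severity coupling 0.75.  Under a
    standard-normal severity these give 14-day totals with mean near 100
    and a between-person coefficient of variation near 1 (heavy dispersion,
    SD comparable to the mean), followed by the four instruments.
    """

    n_participants: int = 53
    n_days: int = 14
    start_date: date = date(2023, 11, 6)
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    base_rate: float = float(np.log(0.39))
    coupling: float | Mapping[Category, float] = 0.75
    overdispersion: float = 0.3
    events_per_day: float = 3.0
    filler_words_per_event: float = 8.0
    filler_vocab_size: int = 60
    loadings: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOADINGS)
    )
    noise_sd: float = 1.0
    attrition: float = 0.0
    timezone_offset_hours: int = 8  # Philippine Standard Time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError(f"n_participants must be >= 0, got {self.n_participants}")
        if self.n_days < 1:
            raise ValueError(f"n_days must be >= 1, got {self.n_days}")
        if self.theta_sd < 0 or self.noise_sd < 0:
            raise ValueError("theta_sd and noise_sd must be non-negative")
        if self.events_per_day < 0 or self.filler_words_per_event < 0:
            raise ValueError("event and filler rates must be non-negative")
        if self.filler_vocab_size < 1:
            raise ValueError("filler_vocab_size must be >= 1")
        if not (0.0 <= self.attrition <= 1.0):
            raise ValueError(f"attrition must be in [0,1], got {self.attrition}")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        for cat in Category:
            if self.coupling_for(cat) < 0:
                raise ValueError(f"coupling for {cat.value} must be >= 0")

    def coupling_for(self, cat: Category) -> float:
        if isinstance(self.coupling, Mapping):
            return float(self.coupling.get(cat, 0.0))
        return float(self.coupling)


@dataclass
class SimulatedDataset:
    """A generated cohort: lexicon, event stream, responses and ground truth.

    ``truth`` has one row per participant: participant_id, theta, dropped.
    """

    config: CohortConfig
    lexicon: Lexicon
    events: list[TextEvent]
    responses: list[InstrumentResponse]
    truth: pd.DataFrame

    @property
    def end_date(self) -> date:
        return self.config.start_date + timedelta(days=self.config.n_days - 1)


def _filler_vocab(size: int) -> list[str]:
    vocab = list(_FILLER_BASE[:size])
    k = 0
    while len(vocab) < size:
        vocab.append(f"zz{k:03d}")
        k += 1
    return vocab


def _discretize(latent: np.ndarray, levels: int, scale: float) -> np.ndarray:
    """Map latent values onto 0..levels-1 via equal-probability thresholds.

    Thresholds are normal quantiles of the latent's marginal distribution
    (sd = ``scale``), so every level is equally likely a priori.
    """
    from scipy.stats import norm

    cuts = norm.ppf(np.arange(1, levels) / levels, scale=scale)
    return np.searchsorted(cuts, latent, side="right")


def _simulate_items(
    theta: float,
    instrument: Instrument,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    n_items, lo, hi = ITEM_SPECS[instrument]
    levels = hi - lo + 1
    noise_sd, theta_sd = config.noise_sd, config.theta_sd

    def draw(loading: float, k: int, n_levels: int) -> np.ndarray:
        latent = loading * theta + rng.normal(0.0, noise_sd, size=k)
        scale = float(np.hypot(loading * theta_sd, noise_sd))
        return _discretize(latent, n_levels, scale)

    if instrument is Instrument.ABS:
        # convention: items 1-5 positive affect, 6-10 negative affect,
        # each driven by its own signed loading
        half = n_items // 2
        pos = draw(float(config.loadings.get("abs_positive", 0.0)), half, 2)
        neg = draw(float(config.loadings.get("abs_negative", 0.0)), half, 2)
        return tuple(int(v) for v in np.concatenate([pos, neg]))

    key = {Instrument.BDI2: "bdi2", Instrument.CESD: "cesd", Instrument.SWLS: "swls"}[
        instrument
    ]
    items = draw(float(config.loadings.get(key, 0.0)), n_items, levels) + lo
    if instrument is Instrument.CESD:
        # stored answers are on the response scale: positive-affect items
        # are answered low when severity is high, so invert them here and
        # let the scorer's reverse coding recover severity
        for pos_idx in CESD_REVERSE_ITEMS:
            items[pos_idx - 1] = 3 - items[pos_idx - 1]
    return tuple(int(v) for v in items)


def simulate_cohort(config: CohortConfig) -> SimulatedDataset:
    """Generate a full synthetic cohort, reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    lexicon = make_demo_lexicon()
    surfaces_by_cat: dict[Category, list[str]] = {}
    for e in lexicon.entries:
        surfaces_by_cat.setdefault(e.category, []).append(e.surface)
    fillers = _filler_vocab(config.filler_vocab_size)
    tz = timezone(timedelta(hours=config.timezone_offset_hours))

    theta = rng.normal(config.theta_mean, config.theta_sd, size=config.n_participants)
    pids = [f"P{i:04d}" for i in range(config.n_participants)]

    events: list[TextEvent] = []
    responses: list[InstrumentResponse] = []
    for i, pid in enumerate(pids):
        for day in range(config.n_days):
            day_date = config.start_date + timedelta(days=day)
            keywords: list[str] = []
            for cat in Category:
                mu = float(
                    np.exp(config.base_rate + config.coupling_for(cat) * theta[i])
                )
                if config.overdispersion > 0:
                    shape = 1.0 / config.overdispersion
                    mu *= rng.gamma(shape, config.overdispersion)
                count = rng.poisson(mu)
                if count:
                    keywords.extend(rng.choice(surfaces_by_cat[cat], size=count))
            n_events = int(rng.poisson(config.events_per_day))
            if keywords and n_events == 0:
                n_events = 1
            if n_events == 0:
                continue
            assignment = rng.integers(0, n_events, size=len(keywords))
            seconds = np.sort(rng.integers(0, 86400, size=n_events))
            for j in range(n_events):
                words = [keywords[k] for k in np.flatnonzero(assignment == j)]
                n_fill = int(rng.poisson(config.filler_words_per_event))
                words.extend(rng.choice(fillers, size=n_fill))
                if not words:
                    words = list(rng.choice(fillers, size=1))
                rng.shuffle(words)
                ts = datetime.combine(day_date, time(0, 0), tz) + timedelta(
                    seconds=int(seconds[j])
                )
                events.append(TextEvent(pid, ts, " ".join(words)))
        for inst in Instrument:
            responses.append(
                InstrumentResponse(
                    pid, inst, _simulate_items(float(theta[i]), inst, config, rng)
                )
            )

    truth = pd.DataFrame(
        {"participant_id": pids, "theta": theta, "dropped": False}
    )
    return SimulatedDataset(config, lexicon, events, responses, truth)


def apply_attrition(dataset: SimulatedDataset, config: CohortConfig | None = None) -> SimulatedDataset:
    """Drop each participant's questionnaire responses with the configured
    probability, keeping their text events (mirrors completers-only
    analysis: dropouts typed but never returned the instruments)."""
    cfg = config or dataset.config
    rng = np.random.default_rng([cfg.seed, 0xA77])
    dropped_flags = rng.random(len(dataset.truth)) < cfg.attrition
    dropped_ids = set(dataset.truth.participant_id[dropped_flags])
    truth = dataset.truth.copy()
    truth["dropped"] = truth.participant_id.isin(dropped_ids)
    responses = [r for r in dataset.responses if r.participant_id not in dropped_ids]
    return SimulatedDataset(
        dataset.config, dataset.lexicon, list(dataset.events), responses, truth
    )
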
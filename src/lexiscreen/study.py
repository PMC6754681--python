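"""One-call replica of the external-validation study design on synthetic data.

Pipeline: simulate a cohort -> apply attrition -> match and aggregate the
text stream into daily tallies -> 1-week and 2-week window totals (windows
end on the last study day, mirroring the instruments' recall frames) ->
score the questionnaires -> construct-validation correlations and
Bland-Altman agreement between the 2-week total and the BDI-II.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .questionnaires import Instrument, InstrumentScore, score_response
from .scoring import aggregate_daily, compute_window_score, window_scores_to_frame
from .simulate import CohortConfig, SimulatedDataset, apply_attrition, simulate_cohort
from .validation import (
    BlandAltmanResult,
    ConstructValidationReport,
    bland_altman,
    run_construct_validation,
)

__all__ = ["StudyResult", "study_replica", "score_dataset"]

#: Window lengths (days) matching CES-D's one-week and BDI-II's two-week recall.
STUDY_WINDOWS = (7, 14)


@dataclass
class StudyResult:
    """Everything the replicated study produces."""

    dataset: SimulatedDataset
    windows: pd.DataFrame
    scores: list[InstrumentScore]
    report: ConstructValidationReport
    bland_altman: BlandAltmanResult | None


def score_dataset(
    dataset: SimulatedDataset, timezone: str | None = None
) -> tuple[pd.DataFrame, list[InstrumentScore]]:
    """Window-score the event stream and score the questionnaires.

    Participants who produced no text still get (zero) window scores:
    dropping silent participants is a study-level exclusion, not a scoring
    rule.
    """
    tzname = timezone or f"Etc/GMT{-dataset.config.timezone_offset_hours:+d}"
    dailies = aggregate_daily(dataset.events, dataset.lexicon, timezone=tzname)
    windows = []
    for pid in dataset.truth.participant_id:
        for wdays in STUDY_WINDOWS:
            windows.append(
                compute_window_score(dailies, pid, dataset.end_date, wdays)
            )
    scores = [score_response(r) for r in dataset.responses]
    return window_scores_to_frame(windows), scores


def study_replica(
    config: CohortConfig, alpha: float = 0.05, z: float = 1.96, conf: float = 0.95
) -> StudyResult:
    """Run the full simulate -> score -> validate pipeline once."""
    dataset = apply_attrition(simulate_cohort(config))
    windows, scores = score_dataset(dataset)
    report = run_construct_validation(windows, scores, alpha=alpha)
    ba = None
    bdi = {
        s.participant_id: s.total
        for s in scores
        if s.instrument is Instrument.BDI2
    }
    two_week = windows[windows.window_days == 14].set_index("participant_id")["total"]
    common = [p for p in two_week.index if p in bdi]
    if len(common) >= 3:
        ba = bland_altman(
            [float(two_week[p]) for p in common],
            [float(bdi[p]) for p in common],
            z=z,
            conf=conf,
        )
    return StudyResult(dataset, windows, scores, report, ba)
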
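"""Scoring for the four validation instruments.

* BDI-II — 21 items, each 0-3; total 0-63 with severity bands minimal
  (0-13), mild (14-19), moderate (20-28), severe (29-63).
* CES-D — 20 items, each 0-3; the four positive-affect items (positions
  4, 8, 12, 16, 1-based) are reverse-coded before summing; total 0-60 with
  a cutoff of 16 for clinically significant symptoms.
* ABS (Affect Balance Scale) — 10 binary items, 5 positive-affect then 5
  negative-affect by file convention; balance = positive - negative + 5,
  so 0 is low and 10 high affect balance.
* SWLS — 5 items on a 1-7 scale; total 5-35; 30-35 marks high life
  satisfaction, 5-9 extreme dissatisfaction.

Band classification accepts fractional totals (cohort means are
fractional) by comparing against the printed integer cut points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import pandas as pd

__all__ = [
    "Instrument",
    "InstrumentResponse",
    "InstrumentScore",
    "score_bdi2",
    "score_cesd",
    "score_abs",
    "score_swls",
    "score_response",
    "abs_balance",
    "bdi2_band",
    "swls_band",
    "CESD_REVERSE_ITEMS",
    "load_questionnaires_csv",
    "responses_to_frame",
    "scores_to_frame",
]


class Instrument(str, Enum):
    BDI2 = "bdi2"
    CESD = "cesd"
    ABS = "abs"
    SWLS = "swls"


#: (item count, minimum item value, maximum item value) per instrument.
ITEM_SPECS: dict[Instrument, tuple[int, int, int]] = {
    Instrument.BDI2: (21, 0, 3),
    Instrument.CESD: (20, 0, 3),
    Instrument.ABS: (10, 0, 1),
    Instrument.SWLS: (5, 1, 7),
}

#: CES-D positive-affect items, reverse-coded before summing (1-based).
CESD_REVERSE_ITEMS = (4, 8, 12, 16)


@dataclass(frozen=True)
class InstrumentResponse:
    """Item-level answers from one administration of one instrument."""

    participant_id: str
    instrument: Instrument
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        n, lo, hi = ITEM_SPECS[self.instrument]
        if len(self.items) != n:
            raise ValueError(
                f"{self.instrument.value} expects {n} items, "
                f"got {len(self.items)} for participant {self.participant_id!r}"
            )
        for i, v in enumerate(self.items, start=1):
            if not (lo <= v <= hi):
                raise ValueError(
                    f"{self.instrument.value} item {i} out of range "
                    f"[{lo},{hi}]: {v!r} (participant {self.participant_id!r})"
                )


@dataclass
class InstrumentScore:
    """A scored administration with its interpretation band."""

    participant_id: str
    instrument: Instrument
    total: float
    band: str
    subscores: dict[str, float] = field(default_factory=dict)


def bdi2_band(total: float) -> str:
    """Severity band for a (possibly fractional) BDI-II total."""
    if not (0 <= total <= 63):
        raise ValueError(f"BDI-II total out of range [0,63]: {total}")
    if total < 14:
        return "minimal"
    if total < 20:
        return "mild"
    if total < 29:
        return "moderate"
    return "severe"


def swls_band(total: float) -> str:
    if not (5 <= total <= 35):
        raise ValueError(f"SWLS total out of range [5,35]: {total}")
    if total <= 9:
        return "extreme dissatisfaction"
    if total >= 30:
        return "high satisfaction"
    return "intermediate"


def abs_balance(positive: float, negative: float) -> float:
    """Affect balance: positive affect minus negative affect plus 5.

    The +5 constant shifts the score into [0, 10] so it cannot go below
    zero: 0 is low affect balance, 10 high.
    """
    return positive - negative + 5


def score_bdi2(resp: InstrumentResponse) -> InstrumentScore:
    if resp.instrument is not Instrument.BDI2:
        raise ValueError(f"expected a bdi2 response, got {resp.instrument.value}")
    total = sum(resp.items)
    return InstrumentScore(resp.participant_id, Instrument.BDI2, total, bdi2_band(total))


def score_cesd(resp: InstrumentResponse) -> InstrumentScore:
    """CES-D total with positions 4/8/12/16 reverse-coded (3 - response)."""
    if resp.instrument is not Instrument.CESD:
        raise ValueError(f"expected a cesd response, got {resp.instrument.value}")
    total = 0
    for pos, v in enumerate(resp.items, start=1):
        total += (3 - v) if pos in CESD_REVERSE_ITEMS else v
    band = "significant symptoms" if total >= 16 else "below cutoff"
    score = InstrumentScore(resp.participant_id, Instrument.CESD, total, band)
    score.subscores["significant"] = float(total >= 16)
    return score


def score_abs(resp: InstrumentResponse) -> InstrumentScore:
    """Affect balance from 10 binary items (5 positive then 5 negative)."""
    if resp.instrument is not Instrument.ABS:
        raise ValueError(f"expected an abs response, got {resp.instrument.value}")
    positive = sum(resp.items[:5])
    negative = sum(resp.items[5:])
    balance = abs_balance(positive, negative)
    if balance <= 3:
        band = "low affect balance"
    elif balance >= 8:
        band = "high affect balance"
    else:
        band = "average affect balance"
    return InstrumentScore(
        resp.participant_id,
        Instrument.ABS,
        balance,
        band,
        subscores={"positive": positive, "negative": negative, "balance": balance},
    )


def score_swls(resp: InstrumentResponse) -> InstrumentScore:
    if resp.instrument is not Instrument.SWLS:
        raise ValueError(f"expected a swls response, got {resp.instrument.value}")
    total = sum(resp.items)
    return InstrumentScore(resp.participant_id, Instrument.SWLS, total, swls_band(total))


_SCORERS = {
    Instrument.BDI2: score_bdi2,
    Instrument.CESD: score_cesd,
    Instrument.ABS: score_abs,
    Instrument.SWLS: score_swls,
}


def score_response(resp: InstrumentResponse) -> InstrumentScore:
    """Dispatch to the instrument's scorer."""
    return _SCORERS[resp.instrument](resp)


def load_questionnaires_csv(source) -> list[InstrumentResponse]:
    """Read item-level responses: participant_id, instrument, item_1..item_k.

    One row per administration; columns beyond an instrument's item count
    must be empty for that row.
    """
    df = pd.read_csv(source, dtype={"participant_id": str})
    if "participant_id" not in df.columns or "instrument" not in df.columns:
        raise ValueError(
            "questionnaire CSV needs 'participant_id' and 'instrument' columns"
        )
    responses = []
    for idx, row in df.iterrows():
        try:
            inst = Instrument(str(row["instrument"]).strip())
        except ValueError:
            raise ValueError(
                f"row {idx + 2}: unknown instrument {row['instrument']!r}"
            ) from None
        n, _, _ = ITEM_SPECS[inst]
        items = []
        for k in range(1, n + 1):
            col = f"item_{k}"
            if col not in df.columns or pd.isna(row[col]):
                raise ValueError(
                    f"row {idx + 2}: missing {col} for {inst.value}"
                )
            items.append(int(row[col]))
        responses.append(InstrumentResponse(str(row["participant_id"]), inst, tuple(items)))
    return responses


def responses_to_frame(responses: Sequence[InstrumentResponse]) -> pd.DataFrame:
    """Tabulate responses in the on-disk CSV layout."""
    max_items = max(n for n, _, _ in ITEM_SPECS.values())
    rows = []
    for r in responses:
        row: dict[str, object] = {
            "participant_id": r.participant_id,
            "instrument": r.instrument.value,
        }
        for k in range(1, max_items + 1):
            row[f"item_{k}"] = r.items[k - 1] if k <= len(r.items) else pd.NA
        rows.append(row)
    cols = ["participant_id", "instrument"] + [f"item_{k}" for k in range(1, max_items + 1)]
    return pd.DataFrame(rows, columns=cols)


def scores_to_frame(scores: Sequence[InstrumentScore]) -> pd.DataFrame:
    """Long-format score table; ABS contributes positive/negative subscores."""
    rows = []
    for s in scores:
        row = {
            "participant_id": s.participant_id,
            "instrument": s.instrument.value,
            "total": s.total,
            "band": s.band,
        }
        for k, v in s.subscores.items():
            row[f"sub_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
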
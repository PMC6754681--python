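"""Construct-validation correlations and Bland-Altman agreement analysis.

The external validation of a new screening measure proceeds in two steps:

1. **Construct validity** (H1): Pearson product-moment correlations of the
   screening total score with established instruments.  Congruent pairs
   (same construct: BDI-II, CES-D) and convergent pairs (related construct:
   ABS negative affect) expect positive correlations; divergent pairs
   (contrary constructs: ABS positive affect, SWLS) expect negative ones.
   Coefficients carry a Hinkle-style magnitude label and an effect-size
   label (|r| read directly against the 0.10/0.30/0.50 small/medium/large
   thresholds).

2. **Concordance** (H2): Bland-Altman analysis of the paired differences
   between the new measure and the gold standard.  Limits of agreement
   (LoA) use a fixed normal coverage factor z (default 1.96); confidence
   intervals around the mean difference and around each LoA use Student t
   with n-1 degrees of freedom, with Var(LoA) = sd^2 * (1/n + z^2/(2(n-1))).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .questionnaires import Instrument, InstrumentScore

__all__ = [
    "CorrelationResult",
    "BlandAltmanResult",
    "PairingResult",
    "ConstructValidationReport",
    "PAIRINGS",
    "pearson_correlation",
    "interpret_correlation",
    "interpret_effect_size",
    "bland_altman",
    "bland_altman_from_summary",
    "run_construct_validation",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """A Pearson correlation with its test and interpretation labels."""

    r: float
    n: int
    t_stat: float
    p_two_tailed: float
    hinkle_label: str
    es_label: str
    significant: bool
    alpha: float = 0.05


def interpret_correlation(r: float) -> str:
    """Hinkle-style magnitude label for a correlation coefficient.

    Bands on |r| are lower-inclusive/upper-exclusive — negligible [0, 0.30),
    low [0.30, 0.50), moderate [0.50, 0.70), high [0.70, 0.90), very high
    [0.90, 1.00] — with the sign word attached for non-negligible r.
    """
    a = abs(r)
    if a > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if a < 0.30:
        return "negligible"
    if a < 0.50:
        band = "low"
    elif a < 0.70:
        band = "moderate"
    elif a < 0.90:
        band = "high"
    else:
        band = "very high"
    return f"{band} {'negative' if r < 0 else 'positive'}"


def interpret_effect_size(r: float, significant: bool) -> str:
    """Effect-size label for a correlation treated as its own effect size.

    |r| >= 0.50 large, >= 0.30 medium, >= 0.10 small, else negligible; a
    non-significant correlation gets no effect size ("not applicable").
    """
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if not significant:
        return "not applicable"
    a = abs(r)
    if a >= 0.50:
        return "large"
    if a >= 0.30:
        return "medium"
    if a >= 0.10:
        return "small"
    return "negligible"


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> CorrelationResult:
    """Pearson product-moment correlation with a two-tailed t test (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    r, _ = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0:
        t_stat = math.copysign(math.inf, r)
        p = 0.0
    else:
        t_stat = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        p = float(2 * stats.t.sf(abs(t_stat), n - 2))
    significant = p < alpha
    return CorrelationResult(
        r=r,
        n=n,
        t_stat=t_stat,
        p_two_tailed=p,
        hinkle_label=interpret_correlation(r),
        es_label=interpret_effect_size(r, significant),
        significant=significant,
        alpha=alpha,
    )


@dataclass
class BlandAltmanResult:
    """Agreement between two measurements of the same quantity.

    Differences are taken as a - b.  ``ci_mean`` bounds the bias;
    ``ci_loa_lower``/``ci_loa_upper`` bound each limit of agreement.
    A zero-variance difference vector yields a degenerate result with the
    LoA collapsed onto the mean and no confidence intervals.
    """

    n: int
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_mean: tuple[float, float] | None
    ci_loa_lower: tuple[float, float] | None
    ci_loa_upper: tuple[float, float] | None
    n_outliers: int | None
    z: float = 1.96
    conf: float = 0.95
    degenerate: bool = False


def _ba_from_moments(
    mean_diff: float,
    sd_diff: float,
    n: int,
    z: float,
    conf: float,
    n_outliers: int | None,
) -> BlandAltmanResult:
    loa_lower = mean_diff - z * sd_diff
    loa_upper = mean_diff + z * sd_diff
    if sd_diff == 0:
        return BlandAltmanResult(
            n, mean_diff, 0.0, mean_diff, mean_diff,
            None, None, None, n_outliers, z, conf, degenerate=True,
        )
    t_crit = float(stats.t.ppf((1 + conf) / 2, n - 1))
    se_mean = sd_diff / math.sqrt(n)
    # Var(LoA) = sd^2 * (1/n + z^2 / (2 (n-1)))
    se_loa = sd_diff * math.sqrt(1 / n + z * z / (2 * (n - 1)))
    return BlandAltmanResult(
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_lower=loa_lower,
        loa_upper=loa_upper,
        ci_mean=(mean_diff - t_crit * se_mean, mean_diff + t_crit * se_mean),
        ci_loa_lower=(loa_lower - t_crit * se_loa, loa_lower + t_crit * se_loa),
        ci_loa_upper=(loa_upper - t_crit * se_loa, loa_upper + t_crit * se_loa),
        n_outliers=n_outliers,
        z=z,
        conf=conf,
    )


def bland_altman(
    a: Sequence[float],
    b: Sequence[float],
    z: float = 1.96,
    conf: float = 0.95,
) -> BlandAltmanResult:
    """Bland-Altman analysis of paired measurements ``a`` and ``b``.

    Outliers are differences strictly outside the limits of agreement.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    n = a.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    res = _ba_from_moments(mean_diff, sd_diff, n, z, conf, n_outliers=None)
    res.n_outliers = int(np.sum((d < res.loa_lower) | (d > res.loa_upper)))
    return res


def bland_altman_from_summary(
    mean_diff: float,
    loa_lower: float,
    loa_upper: float,
    n: int,
    z: float = 1.96,
    conf: float = 0.95,
) -> BlandAltmanResult:
    """Reconstruct a full Bland-Altman result from published summary numbers.

    Recovers sd_diff = (loa_upper - loa_lower) / (2 z) and fills the
    confidence intervals by the same formulas as :func:`bland_altman`; the
    outlier count cannot be recovered from a summary and is left unset.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if not loa_lower < loa_upper:
        raise ValueError(
            f"limits of agreement must satisfy lower < upper, "
            f"got {loa_lower} >= {loa_upper}"
        )
    if not (loa_lower <= mean_diff <= loa_upper):
        raise ValueError(
            f"mean difference {mean_diff} lies outside the stated limits "
            f"of agreement [{loa_lower}, {loa_upper}]"
        )
    sd_diff = (loa_upper - loa_lower) / (2 * z)
    res = _ba_from_moments(mean_diff, sd_diff, n, z, conf, n_outliers=None)
    # keep the printed limits verbatim (they may be asymmetric after rounding)
    res.loa_lower = loa_lower
    res.loa_upper = loa_upper
    if res.ci_loa_lower is not None:
        t_crit = float(stats.t.ppf((1 + conf) / 2, n - 1))
        se_loa = sd_diff * math.sqrt(1 / n + z * z / (2 * (n - 1)))
        res.ci_loa_lower = (loa_lower - t_crit * se_loa, loa_lower + t_crit * se_loa)
        res.ci_loa_upper = (loa_upper - t_crit * se_loa, loa_upper + t_crit * se_loa)
    return res


# The five validation pairings: (name, instrument measure, construct type,
# expected sign, hypothesis id, window lengths correlated).  CES-D recalls
# one week and BDI-II two, so each congruent pairing uses its matching
# window; the affect/satisfaction pairings use both windows.
PAIRINGS: tuple[tuple[str, str, str, int, str, tuple[int, ...]], ...] = (
    ("CES-D", "cesd_total", "congruent", +1, "H1.1", (7,)),
    ("BDI-II", "bdi2_total", "congruent", +1, "H1.1", (14,)),
    ("ABS-Negative Affect", "abs_negative", "convergent", +1, "H1.2", (7, 14)),
    ("ABS-Positive Affect", "abs_positive", "divergent", -1, "H1.3", (7, 14)),
    ("SWLS", "swls_total", "divergent", -1, "H1.3", (7, 14)),
)


@dataclass
class PairingResult:
    """One instrument pairing with its per-window correlations."""

    instrument: str
    measure: str
    construct_type: str
    expected_sign: int
    hypothesis_id: str
    correlations: dict[int, CorrelationResult] = field(default_factory=dict)
    supported: bool = False

    def evaluate(self) -> None:
        """Supported iff any window shows a significant correlation whose
        sign matches the expectation."""
        self.supported = any(
            c.significant and math.copysign(1, c.r) == self.expected_sign
            for c in self.correlations.values()
        )


@dataclass
class ConstructValidationReport:
    """All pairings at one significance level, plus skipped-pair notes."""

    pairs: list[PairingResult]
    alpha: float
    n_participants: int
    warnings: list[str] = field(default_factory=list)


def _measure_frame(scores: Sequence[InstrumentScore]) -> pd.DataFrame:
    """Wide per-participant table of instrument measures used in pairings."""
    rows: dict[str, dict[str, float]] = {}
    for s in scores:
        row = rows.setdefault(s.participant_id, {})
        if s.instrument is Instrument.ABS:
            row["abs_positive"] = s.subscores["positive"]
            row["abs_negative"] = s.subscores["negative"]
        else:
            row[f"{s.instrument.value}_total"] = s.total
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "participant_id"
    return df


def run_construct_validation(
    windows: pd.DataFrame,
    scores: Sequence[InstrumentScore] | pd.DataFrame,
    alpha: float = 0.05,
) -> ConstructValidationReport:
    """Evaluate the five construct-validity pairings.

    ``windows`` is a window-score table (``window_scores_to_frame`` layout:
    participant_id, window_days, total).  ``scores`` is a list of
    InstrumentScore (or an equivalent wide measure frame).  A pairing whose
    instrument is missing, or with fewer than 3 complete cases, is skipped
    with a logged warning rather than failing the whole report.
    """
    if isinstance(scores, pd.DataFrame):
        measures = scores
    else:
        measures = _measure_frame(scores)
    pts = windows.pivot_table(
        index="participant_id", columns="window_days", values="total"
    )
    if pts.shape[0] < 2:
        raise ValueError(
            f"need at least 2 participants with window scores, got {pts.shape[0]}"
        )
    joined = pts.join(measures, how="inner")
    report = ConstructValidationReport(
        pairs=[], alpha=alpha, n_participants=int(joined.shape[0])
    )
    for name, measure, ctype, sign, hyp, window_list in PAIRINGS:
        pair = PairingResult(name, measure, ctype, sign, hyp)
        if measure not in joined.columns:
            msg = f"instrument measure {measure!r} missing; pairing {name} skipped"
            logger.warning(msg)
            report.warnings.append(msg)
            continue
        for wdays in window_list:
            if wdays not in pts.columns:
                msg = f"no {wdays}-day window scores; {name} @ {wdays}d skipped"
                logger.warning(msg)
                report.warnings.append(msg)
                continue
            sub = joined[[wdays, measure]].dropna()
            if sub.shape[0] < 3:
                msg = (
                    f"{name} @ {wdays}d has {sub.shape[0]} complete cases "
                    "(need >= 3); skipped"
                )
                logger.warning(msg)
                report.warnings.append(msg)
                continue
            try:
                pair.correlations[wdays] = pearson_correlation(
                    sub[wdays].to_numpy(), sub[measure].to_numpy(), alpha=alpha
                )
            except ValueError as exc:
                msg = f"{name} @ {wdays}d: {exc}; skipped"
                logger.warning(msg)
                report.warnings.append(msg)
        pair.evaluate()
        report.pairs.append(pair)
    return report
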
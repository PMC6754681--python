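"""Render validation results as machine JSON, human Markdown, and plot data.

Display rounding follows reporting convention (r to 2 d.p., p to 2-3 d.p.);
the JSON keeps full precision — rounding is presentation, never computation.
"""

from __future__ import annotations

import json
from typing import Any

import numpy as np
import pandas as pd

from .validation import BlandAltmanResult, ConstructValidationReport

__all__ = [
    "report_to_dict",
    "ba_to_dict",
    "render_markdown",
    "ba_plot_frame",
]


def _fmt_p(p: float) -> str:
    if p < 0.001:
        return "<.001"
    if p < 0.01:
        return f".{round(p, 3) * 1000:03.0f}".replace("0.", ".")
    return f"{p:.2f}".replace("0.", ".")


def report_to_dict(report: ConstructValidationReport) -> dict[str, Any]:
    pairs = []
    for pr in report.pairs:
        entry: dict[str, Any] = {
            "instrument": pr.instrument,
            "measure": pr.measure,
            "construct_type": pr.construct_type,
            "expected_sign": pr.expected_sign,
            "hypothesis_id": pr.hypothesis_id,
            "supported": pr.supported,
            "correlations": {},
        }
        for wdays, c in sorted(pr.correlations.items()):
            entry["correlations"][f"{wdays}d"] = {
                "r": c.r,
                "n": c.n,
                "t_stat": c.t_stat,
                "p_two_tailed": c.p_two_tailed,
                "hinkle_label": c.hinkle_label,
                "es_label": c.es_label,
                "significant": c.significant,
            }
        pairs.append(entry)
    return {
        "alpha": report.alpha,
        "n_participants": report.n_participants,
        "pairs": pairs,
        "warnings": list(report.warnings),
    }


def ba_to_dict(ba: BlandAltmanResult) -> dict[str, Any]:
    return {
        "n": ba.n,
        "mean_diff": ba.mean_diff,
        "sd_diff": ba.sd_diff,
        "loa_lower": ba.loa_lower,
        "loa_upper": ba.loa_upper,
        "ci_mean": list(ba.ci_mean) if ba.ci_mean else None,
        "ci_loa_lower": list(ba.ci_loa_lower) if ba.ci_loa_lower else None,
        "ci_loa_upper": list(ba.ci_loa_upper) if ba.ci_loa_upper else None,
        "n_outliers": ba.n_outliers,
        "z": ba.z,
        "conf": ba.conf,
        "degenerate": ba.degenerate,
    }


def render_markdown(
    report: ConstructValidationReport, ba: BlandAltmanResult | None = None
) -> str:
    """Human-readable validation report, one block per hypothesis pairing."""
    lines = [
        "# External validation report",
        "",
        f"Participants with joined scores: {report.n_participants}; "
        f"alpha = {report.alpha}",
        "",
    ]
    for pr in report.pairs:
        lines.append(
            f"## {pr.instrument} ({pr.construct_type}, expected "
            f"{'positive' if pr.expected_sign > 0 else 'negative'}, "
            f"{pr.hypothesis_id})"
        )
        for wdays, c in sorted(pr.correlations.items()):
            flag = "significant" if c.significant else "not significant"
            note = ""
            if 0.25 <= abs(c.r) < 0.30 and c.significant:
                note = "  (borderline: |r| just below the medium threshold)"
            lines.append(
                f"- {wdays}-day total: r={c.r:.2f}, n={c.n}, "
                f"P={_fmt_p(c.p_two_tailed)} ({flag}); {c.hinkle_label}; "
                f"effect size: {c.es_label}{note}"
            )
        lines.append(f"- hypothesis supported: {'yes' if pr.supported else 'no'}")
        lines.append("")
    if ba is not None:
        lines.append("## Agreement with the gold standard (Bland-Altman)")
        lines.append(
            f"- n={ba.n}; mean difference {ba.mean_diff:.2f} "
            f"(SD of differences {ba.sd_diff:.2f})"
        )
        lines.append(
            f"- limits of agreement: {ba.loa_lower:.1f} to {ba.loa_upper:.1f} "
            f"(z={ba.z})"
        )
        if ba.ci_mean:
            lines.append(
                f"- CI of mean difference: {ba.ci_mean[0]:.4f} to {ba.ci_mean[1]:.4f}"
            )
            lines.append(
                f"- CI of lower limit: {ba.ci_loa_lower[0]:.4f} to "
                f"{ba.ci_loa_lower[1]:.4f}; CI of upper limit: "
                f"{ba.ci_loa_upper[0]:.4f} to {ba.ci_loa_upper[1]:.4f}"
            )
        if ba.n_outliers is not None:
            lines.append(f"- differences outside the limits: {ba.n_outliers}")
        if ba.degenerate:
            lines.append("- degenerate: zero variance of differences")
        lines.append("")
    if report.warnings:
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in report.warnings)
        lines.append("")
    return "\n".join(lines)


def ba_plot_frame(a, b) -> pd.DataFrame:
    """(mean, difference) pairs for an external Bland-Altman plot."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return pd.DataFrame({"mean": (a + b) / 2.0, "difference": a - b})


def report_to_json(
    report: ConstructValidationReport, ba: BlandAltmanResult | None = None
) -> str:
    payload: dict[str, Any] = {"construct_validation": report_to_dict(report)}
    if ba is not None:
        payload["bland_altman"] = ba_to_dict(ba)
    return json.dumps(payload, indent=2)
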
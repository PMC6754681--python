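"""Correlation tests, interpretation labels, Bland-Altman agreement."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lexiscreen.questionnaires import Instrument, InstrumentResponse, score_response
from lexiscreen.validation import (
    PAIRINGS,
    bland_altman,
    bland_altman_from_summary,
    interpret_correlation,
    interpret_effect_size,
    pearson_correlation,
    run_construct_validation,
)


class TestPearson:
    def test_identity_vector(self):
        x = [1.0, 2.0, 5.0, 7.0]
        res = pearson_correlation(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p_two_tailed == pytest.approx(0.0, abs=1e-12)

    def test_t_statistic_identity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = pearson_correlation(x, y)
        assert res.t_stat == pytest.approx(
            res.r * math.sqrt(res.n - 2) / math.sqrt(1 - res.r**2)
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            pearson_correlation([1, 2, 3], [1, 2])

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15)
        base = pearson_correlation(x, y)
        scaled = pearson_correlation(3.0 * x + 7.0, y)
        assert scaled.r == pytest.approx(base.r)
        assert scaled.p_two_tailed == pytest.approx(base.p_two_tailed)
        flipped = pearson_correlation(-x, y)
        assert flipped.r == pytest.approx(-base.r)

    @pytest.mark.parametrize("trial", [0, 1, 2])
    def test_against_exhaustive_permutation_oracle(self, trial):
        """The t-based two-sided p approximates the exact permutation p
        (all 720 orderings at n=6); frozen oracle values computed with the
        brute-force enumeration below."""
        rng = np.random.default_rng(42)
        datasets = []
        for _ in range(3):
            x = rng.normal(size=6)
            y = 0.6 * x + rng.normal(size=6)
            datasets.append((x, y))
        x, y = datasets[trial]
        res = pearson_correlation(x, y)
        count = 0
        for perm in itertools.permutations(y):
            r = np.corrcoef(x, perm)[0, 1]
            if abs(r) >= abs(res.r) - 1e-12:
                count += 1
        p_perm = count / 720
        # frozen from the enumeration at test-writing time
        expected_p_perm = [0.344444, 0.094444, 0.630556][trial]
        assert p_perm == pytest.approx(expected_p_perm, abs=1e-6)
        # t approximation tracks the exact p; agreement is tight for
        # moderate |r| and loosens for weak correlations at this tiny n
        assert res.p_two_tailed == pytest.approx(p_perm, abs=0.12)

    @pytest.mark.parametrize(
        "r,printed",
        [
            (0.50, "<.001"),
            (0.42, ".002"),
            (0.25, ".07"),
            (0.19, ".17"),
            (-0.29, ".04"),
            (-0.20, ".15"),
            (-0.32, ".02"),
        ],
    )
    def test_reported_p_values_at_n_53(self, r, printed):
        """Each reported (r, n=53) pair reproduces its printed p rounding
        under the two-tailed t test with df = 51."""
        n = 53
        t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        p = 2 * stats.t.sf(abs(t), n - 2)
        if printed == "<.001":
            assert p < 0.001
        else:
            digits = len(printed) - 1
            assert round(p, digits) == pytest.approx(float("0" + printed))


class TestInterpretationLabels:
    @pytest.mark.parametrize(
        "r,label",
        [
            (0.42, "low positive"),
            (0.50, "moderate positive"),
            (-0.95, "very high negative"),
            (0.29, "negligible"),
            (0.70, "high positive"),
            (1.0, "very high positive"),
            (-0.30, "low negative"),
        ],
    )
    def test_hinkle_bands(self, r, label):
        assert interpret_correlation(r) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            interpret_correlation(1.01)

    @pytest.mark.parametrize(
        "r,sig,label",
        [
            (0.50, True, "large"),
            (0.42, True, "medium"),
            (0.19, False, "not applicable"),
            (0.15, True, "small"),
            (0.05, True, "negligible"),
            (-0.32, True, "medium"),
        ],
    )
    def test_effect_size_labels(self, r, sig, label):
        assert interpret_effect_size(r, sig) == label


class TestBlandAltman:
    def test_identical_methods(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = bland_altman(a, a)
        assert res.mean_diff == 0
        assert res.loa_lower == res.loa_upper == 0
        assert res.degenerate and res.ci_mean is None

    def test_spreadsheet_style_oracle_on_random_pairs(self):
        """All fields match a direct step-by-step recomputation."""
        rng = np.random.default_rng(9)
        a = rng.normal(50, 10, size=10)
        b = rng.normal(45, 12, size=10)
        res = bland_altman(a, b)
        d = a - b
        n = 10
        mean = d.sum() / n
        sd = math.sqrt(((d - mean) ** 2).sum() / (n - 1))
        t_crit = stats.t.ppf(0.975, n - 1)
        assert res.mean_diff == pytest.approx(mean)
        assert res.sd_diff == pytest.approx(sd)
        assert res.loa_lower == pytest.approx(mean - 1.96 * sd)
        assert res.loa_upper == pytest.approx(mean + 1.96 * sd)
        assert res.ci_mean[0] == pytest.approx(mean - t_crit * sd / math.sqrt(n))
        se_loa = sd * math.sqrt(1 / n + 1.96**2 / (2 * (n - 1)))
        assert res.ci_loa_upper[1] == pytest.approx(mean + 1.96 * sd + t_crit * se_loa)
        assert res.ci_loa_lower[0] == pytest.approx(mean - 1.96 * sd - t_crit * se_loa)
        expected_out = int(np.sum((d < res.loa_lower) | (d > res.loa_upper)))
        assert res.n_outliers == expected_out

    def test_loa_symmetry_and_ci_containment(self):
        rng = np.random.default_rng(3)
        res = bland_altman(rng.normal(size=25), rng.normal(size=25))
        assert res.loa_upper - res.mean_diff == pytest.approx(
            res.mean_diff - res.loa_lower
        )
        assert res.ci_mean[0] < res.mean_diff < res.ci_mean[1]
        assert res.ci_loa_lower[0] < res.loa_lower < res.ci_loa_lower[1]
        assert res.ci_loa_upper[0] < res.loa_upper < res.ci_loa_upper[1]

    def test_ci_width_scales_inverse_sqrt_n(self):
        """Quadrupling n with the same per-pair dispersion roughly halves
        the CI width (checked on resampled synthetic differences)."""
        rng = np.random.default_rng(12)
        d_small = rng.normal(5, 2, size=50)
        d_big = np.tile(d_small, 4)  # same sd, 4x the pairs
        z = np.zeros_like(d_small)
        res_small = bland_altman(d_small, z)
        res_big = bland_altman(d_big, np.zeros_like(d_big))
        w_small = res_small.ci_mean[1] - res_small.ci_mean[0]
        w_big = res_big.ci_mean[1] - res_big.ci_mean[0]
        # 1/sqrt(n) up to the finite-sample t-quantile and ddof corrections
        assert w_big == pytest.approx(w_small / 2, rel=0.05)

    def test_n_too_small(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [3, 4])

    def test_from_summary_unit_case(self):
        res = bland_altman_from_summary(0.0, -1.96, 1.96, n=100)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.n_outliers is None

    def test_from_summary_roundtrips_full_analysis(self):
        rng = np.random.default_rng(4)
        a = rng.normal(100, 30, size=40)
        b = rng.normal(20, 10, size=40)
        full = bland_altman(a, b)
        back = bland_altman_from_summary(
            full.mean_diff, full.loa_lower, full.loa_upper, n=40
        )
        assert back.sd_diff == pytest.approx(full.sd_diff)
        assert back.ci_mean == pytest.approx(full.ci_mean)
        assert back.ci_loa_lower == pytest.approx(full.ci_loa_lower)
        assert back.ci_loa_upper == pytest.approx(full.ci_loa_upper)

    def test_from_summary_inconsistent_mean_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bland_altman_from_summary(10.0, -2.0, 2.0, n=10)
        with pytest.raises(ValueError, match="lower < upper"):
            bland_altman_from_summary(0.0, 2.0, -2.0, n=10)


def _make_scores(rng, pids, theta):
    """Questionnaire scores driven by theta, for validation-report tests."""
    scores = []
    for pid, th in zip(pids, theta):
        sev3 = int(np.clip(round(1.5 + th), 0, 3))
        scores.append(
            score_response(InstrumentResponse(pid, Instrument.BDI2, (sev3,) * 21))
        )
        scores.append(
            score_response(InstrumentResponse(pid, Instrument.CESD, (sev3,) * 20))
        )
        pos = 1 if th < 0 else 0
        scores.append(
            score_response(
                InstrumentResponse(pid, Instrument.ABS, (pos,) * 5 + (1 - pos,) * 5)
            )
        )
        sat = int(np.clip(round(4 - 2 * th), 1, 7))
        scores.append(
            score_response(InstrumentResponse(pid, Instrument.SWLS, (sat,) * 5))
        )
    return scores


def _make_windows(pids, totals7, totals14):
    rows = []
    for pid, t7, t14 in zip(pids, totals7, totals14):
        rows.append({"participant_id": pid, "window_days": 7, "total": t7})
        rows.append({"participant_id": pid, "window_days": 14, "total": t14})
    return pd.DataFrame(rows)


class TestRunConstructValidation:
    def test_strong_coupling_supports_congruent_pairs(self):
        rng = np.random.default_rng(0)
        n = 60
        theta = rng.normal(size=n)
        pids = [f"p{i}" for i in range(n)]
        totals14 = np.round(50 * np.exp(0.8 * theta)).astype(int)
        totals7 = np.round(totals14 / 2 + rng.normal(0, 2, size=n)).clip(0)
        report = run_construct_validation(
            _make_windows(pids, totals7, totals14), _make_scores(rng, pids, theta)
        )
        by_name = {p.instrument: p for p in report.pairs}
        assert len(report.pairs) == 5
        assert by_name["CES-D"].supported
        assert by_name["BDI-II"].supported
        assert by_name["SWLS"].correlations[14].r < 0

    def test_independent_noise_supports_nothing(self):
        """With totals independent of the instruments, |r| stays small and
        no pairing finds support (checked across seeds)."""
        n_supported = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 40
            theta = rng.normal(size=n)
            pids = [f"p{i}" for i in range(n)]
            totals14 = rng.poisson(50, size=n)
            totals7 = rng.poisson(25, size=n)
            report = run_construct_validation(
                _make_windows(pids, totals7, totals14),
                _make_scores(rng, pids, theta),
                alpha=0.01,
            )
            n_supported += sum(p.supported for p in report.pairs)
        assert n_supported <= 2  # ~alpha-level false positives at most

    def test_single_participant_errors(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="at least 2"):
            run_construct_validation(
                _make_windows(["p0"], [5], [9]), _make_scores(rng, ["p0"], [0.0])
            )

    def test_missing_instrument_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        n = 12
        theta = rng.normal(size=n)
        pids = [f"p{i}" for i in range(n)]
        scores = [
            s
            for s in _make_scores(rng, pids, theta)
            if s.instrument is not Instrument.SWLS
        ]
        report = run_construct_validation(
            _make_windows(pids, rng.poisson(20, n), rng.poisson(40, n)), scores
        )
        assert any("swls" in w for w in report.warnings)
        assert {p.instrument for p in report.pairs} < {p[0] for p in PAIRINGS} | set()

    def test_pairing_structure(self):
        """The five pairings carry the expected construct types and signs."""
        expected = {
            "CES-D": ("congruent", +1, (7,)),
            "BDI-II": ("congruent", +1, (14,)),
            "ABS-Negative Affect": ("convergent", +1, (7, 14)),
            "ABS-Positive Affect": ("divergent", -1, (7, 14)),
            "SWLS": ("divergent", -1, (7, 14)),
        }
        assert {p[0]: (p[2], p[3], p[5]) for p in PAIRINGS} == expected
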
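"""Statistical battery for cohort tables and the two assay helpers.

Normality gate (Shapiro–Wilk + Levene variance check), Wilcoxon rank-sum
comparisons against a control with Bonferroni correction, Pearson
correlation of intensity vs shape, χ² independence of condensation state
and cell-cycle phase, comparative-Ct (ΔΔCt) fold changes, reporter
repression and population intensity ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    alpha_cutoff: float
    decision: str                      # "reject" | "fail_to_reject"
    adjusted_p: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    def as_dict(self) -> dict:
        d = {
            "test_name": self.test_name, "statistic": self.statistic,
            "p_value": self.p_value, "alpha_cutoff": self.alpha_cutoff,
            "decision": self.decision,
        }
        if self.adjusted_p is not None:
            d["adjusted_p"] = self.adjusted_p
        d.update(self.extras)
        return d


def _decision(p: float, cutoff: float) -> str:
    return "reject" if p < cutoff else "fail_to_reject"


# ---------------------------------------------------------------------------
# normality and variance gate
# ---------------------------------------------------------------------------

@dataclass
class NormalityReport:
    per_cohort: dict[str, TestResult]
    variance_test: TestResult
    recommend_nonparametric: bool


def normality_gate(cohorts: Mapping[str, Sequence[float]], alpha: float = 0.05
                   ) -> NormalityReport:
    """Shapiro–Wilk per cohort plus a Levene variance-equivalence check.

    Recommends nonparametric testing when any cohort rejects normality or
    the cohorts reject variance equivalence. The variance-equivalence test
    is a Levene-type stand-in (the exact flavour behind published
    "variance equivalence" gates is rarely stated).
    """
    results: dict[str, TestResult] = {}
    arrays = {}
    for label, values in cohorts.items():
        v = np.asarray(values, dtype=float)
        if len(v) < 3:
            raise ValueError(f"cohort {label!r} needs n >= 3 for Shapiro–Wilk")
        if np.ptp(v) == 0:
            raise ValueError(f"cohort {label!r} is constant; normality undefined")
        arrays[label] = v
        w, p = sps.shapiro(v)
        results[label] = TestResult(
            test_name="shapiro_wilk", statistic=float(w), p_value=float(p),
            alpha_cutoff=alpha, decision=_decision(p, alpha),
        )
    if len(arrays) >= 2:
        stat, p = sps.levene(*arrays.values(), center="median")
    else:
        stat, p = 0.0, 1.0
    var_res = TestResult(
        test_name="levene_variance_equivalence", statistic=float(stat),
        p_value=float(p), alpha_cutoff=alpha, decision=_decision(p, alpha),
        extras={"note": "Levene-type stand-in for variance equivalence"},
    )
    nonparam = any(r.decision == "reject" for r in results.values()) \
        or var_res.decision == "reject"
    return NormalityReport(per_cohort=results, variance_test=var_res,
                           recommend_nonparametric=nonparam)


# ---------------------------------------------------------------------------
# rank-sum comparisons with Bonferroni correction
# ---------------------------------------------------------------------------

def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value, min(1, m·p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null distribution for combined n ≤ 10 without ties, otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_vs_control(
    control: Sequence[float],
    tests: Mapping[str, Sequence[float]],
    m: int = 7,
    alpha: float = 0.05,
) -> dict[str, TestResult]:
    """Rank-sum test of each cohort against the control, Bonferroni corrected.

    ``m`` defaults to 7 contrasts, giving the conventional cutoff
    alpha/m = 0.05/7 ≈ 0.007.
    """
    control = np.asarray(control, dtype=float)
    if len(control) < 4:
        raise ValueError("control cohort needs n >= 4")
    cutoff = alpha / m
    out: dict[str, TestResult] = {}
    for label, sample in tests.items():
        sample = np.asarray(sample, dtype=float)
        if len(sample) < 4:
            raise ValueError(f"cohort {label!r} needs n >= 4")
        u, p = rank_sum_test(sample, control)
        out[label] = TestResult(
            test_name="wilcoxon_rank_sum", statistic=u, p_value=p,
            adjusted_p=bonferroni(p, m), alpha_cutoff=cutoff,
            decision=_decision(p, cutoff),
            extras={"m": m, "cutoff_note": f"alpha/m = {alpha}/{m}"},
        )
    return out


def exact_rank_sum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Brute-force two-sided rank-sum p by enumerating all rank assignments.

    Independent oracle for small samples (no tie handling); O(C(n1+n2, n1)).
    """
    from itertools import combinations

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    n1 = len(a)
    observed = ranks[:n1].sum()
    mu = n1 * (len(combined) + 1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(combined)), n1):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# correlation and contingency
# ---------------------------------------------------------------------------

def pearson_intensity_vs_shape(cohort: pd.DataFrame, alpha: float = 0.05,
                               x: str = "normalized_intensity",
                               y: str = "surface_factor") -> TestResult:
    """Pearson correlation of calibrated array intensity vs surface factor."""
    xv = np.asarray(cohort[x], dtype=float)
    yv = np.asarray(cohort[y], dtype=float)
    if len(xv) < 3:
        raise ValueError("need n >= 3 for a correlation")
    if not (np.all(np.isfinite(xv)) and np.all(np.isfinite(yv))):
        raise ValueError("values must be finite")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(xv, yv)
    return TestResult(
        test_name="pearson_correlation", statistic=float(r), p_value=float(p),
        alpha_cutoff=alpha, decision=_decision(p, alpha),
        extras={"r": float(r), "n": int(len(xv))},
    )


def chi_square_independence(table: Sequence[Sequence[float]],
                            yates: bool = False,
                            alpha: float = 0.05) -> TestResult:
    """Pearson χ² test of independence on a 2×2 contingency table.

    Default is the uncorrected statistic (1 df); Yates continuity correction
    is available by flag. Used to ask whether array condensation state is
    independent of cell-cycle phase.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if t.sum() == 0:
        raise ValueError("empty table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal: test undefined")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=yates)
    decision = _decision(p, alpha)
    return TestResult(
        test_name="chi_square_independence", statistic=float(stat),
        p_value=float(p), alpha_cutoff=alpha, decision=decision,
        extras={"dof": int(dof), "yates": yates,
                "interpretation": ("independent of cell-cycle stage"
                                   if decision == "fail_to_reject"
                                   else "associated with cell-cycle stage")},
    )


# ---------------------------------------------------------------------------
# assay helpers
# ---------------------------------------------------------------------------

@dataclass
class DdctResult:
    ddct: float
    fold_change: float
    sd_ddct: float
    fold_low: float
    fold_high: float


def ddct_fold_change(
    target_ct: Sequence[float],
    reference_ct: Sequence[float],
    calibrator_target_ct: Sequence[float],
    calibrator_reference_ct: Sequence[float],
) -> DdctResult:
    """Comparative-Ct relative quantification: fold change = 2^(−ΔΔCt).

    ΔCt = mean(target) − mean(reference) per sample; ΔΔCt subtracts the
    calibrator's ΔCt. Replicate scatter propagates as the root sum of
    squared standard errors of the four means; the fold interval is
    2^(−ΔΔCt ± sd).
    """
    groups = [np.asarray(g, dtype=float) for g in
              (target_ct, reference_ct, calibrator_target_ct, calibrator_reference_ct)]
    for g in groups:
        if g.size == 0:
            raise ValueError("replicate sets must be non-empty")
        if not np.all(np.isfinite(g)):
            raise ValueError("Ct values must be finite")
    means = [g.mean() for g in groups]
    ddct = (means[0] - means[1]) - (means[2] - means[3])
    sems_sq = [g.var(ddof=1) / g.size if g.size > 1 else 0.0 for g in groups]
    sd = math.sqrt(sum(sems_sq))
    return DdctResult(
        ddct=float(ddct), fold_change=float(2.0 ** -ddct), sd_ddct=float(sd),
        fold_low=float(2.0 ** -(ddct + sd)), fold_high=float(2.0 ** -(ddct - sd)),
    )


def reporter_repression(sample_luc: float, sample_ref: float,
                        control_luc: float, control_ref: float) -> float:
    """Percent repression of a reporter, normalized to an internal reference.

    activity = luc/ref; repression % = 100·(1 − activity_sample /
    activity_control). Negative values mean activation.
    """
    if sample_ref <= 0 or control_ref <= 0:
        raise ValueError("reference signals must be positive")
    control_activity = control_luc / control_ref
    if control_activity == 0:
        raise ZeroDivisionError("zero control activity")
    return 100.0 * (1.0 - (sample_luc / sample_ref) / control_activity)


def population_intensity_ratio(
    group_a_means: Sequence[float],
    group_b_means: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Percent difference of group-A mean over group-B mean with bootstrap CI.

    100·(mean_a − mean_b)/mean_b; CI from ``n_boot`` seeded resamples of
    both groups.
    """
    a = np.asarray(group_a_means, dtype=float)
    b = np.asarray(group_b_means, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if b.mean() == 0:
        raise ZeroDivisionError("group-B mean is zero")
    point = 100.0 * (a.mean() - b.mean()) / b.mean()
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = rng.choice(a, size=a.size, replace=True)
        rb = rng.choice(b, size=b.size, replace=True)
        boots[i] = 100.0 * (ra.mean() - rb.mean()) / rb.mean()
    lo, hi = np.percentile(boots, [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100])
    return {"percent_difference": float(point), "ci_low": float(lo),
            "ci_high": float(hi), "n_boot": n_boot, "seed": seed}
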
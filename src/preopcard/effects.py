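"""Contingency analysis, nonparametric comparison, and E-value sensitivity.

Conventions follow the SPSS-style analysis the pipeline emulates: Pearson
chi-square without continuity correction, switching to the Fisher exact
test for 2x2 tables with any expected cell below 5; Bonferroni-adjusted
pairwise post hoc comparisons when an omnibus test on a >2-level variable
is significant; two-sided alpha of .05 throughout.

The E-value for an observed association is the minimum strength of
association (on the risk-ratio scale) an unmeasured confounder would need
with both exposure and outcome to explain the association away:

    E = RR + sqrt(RR * (RR - 1)),   with RR inverted first if RR < 1.

Odds ratios are converted to approximate risk ratios before the formula:
``RR ~ sqrt(OR)`` when the outcome is common (pooled prevalence >= 15% by
default) and ``RR ~ OR`` when rare. An E-value of 1 means no unmeasured
confounding is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class ContingencyResult:
    table: np.ndarray
    test_used: str                     # "pearson_chi2" | "fisher_exact"
    statistic: float
    p_value: float
    posthoc: list = field(default_factory=list)   # (level_i, level_j, p_adj)


@dataclass
class EffectSensitivity:
    or_value: float
    rr_approx: float
    evalue: float
    outcome_common: bool


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    t = t.astype(np.int64)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has an all-zero margin")
    return t


def contingency_test(table, fisher_threshold: float = 5.0) -> ContingencyResult:
    """Chi-square (or small-sample Fisher) test of independence.

    Pearson chi-square without continuity correction by default; a 2x2
    table with any expected cell below ``fisher_threshold`` uses the Fisher
    exact test instead. For tables with more than two columns and omnibus
    p < .05, Bonferroni-adjusted pairwise column comparisons are attached.
    """
    t = _validate_table(table)
    expected = stats.contingency.expected_freq(t)
    if t.shape == (2, 2) and expected.min() < fisher_threshold:
        res = stats.fisher_exact(t)
        out = ContingencyResult(t, "fisher_exact", float(res.statistic), float(res.pvalue))
    else:
        chi2 = stats.chi2_contingency(t, correction=False)
        out = ContingencyResult(t, "pearson_chi2", float(chi2.statistic), float(chi2.pvalue))

    n_levels = t.shape[1]
    if n_levels > 2 and out.p_value < ALPHA:
        pairs = [(i, j) for i in range(n_levels) for j in range(i + 1, n_levels)]
        for i, j in pairs:
            sub = t[:, [i, j]]
            try:
                p = contingency_test(sub, fisher_threshold).p_value
            except ValueError:
                continue
            out.posthoc.append((i, j, min(1.0, p * len(pairs))))
    return out


def odds_ratio(table2x2) -> float:
    """Cross-product odds ratio ``(a*d)/(b*c)``.

    Rows are exposure groups (pre, post), columns outcome (yes, no). Any
    zero cell triggers the Haldane-Anscombe 0.5 correction on all cells.
    """
    t = np.asarray(table2x2, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("odds ratio needs a 2x2 table")
    if np.any(t == 0):
        t = t + 0.5
    return float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))


def odds_ratio_ci(table2x2, alpha: float = ALPHA) -> tuple[float, float, float]:
    """Odds ratio with a Woolf (log-scale Wald) confidence interval."""
    t = np.asarray(table2x2, dtype=float)
    if np.any(t == 0):
        t = t + 0.5
    orv = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    se = math.sqrt((1.0 / t).sum())
    z = stats.norm.ppf(1 - alpha / 2)
    return orv, orv * math.exp(-z * se), orv * math.exp(z * se)


def evalue(or_value: float, outcome_common: bool) -> EffectSensitivity:
    """E-value for an odds ratio.

    The OR is first converted to an approximate risk ratio (square root for
    a common outcome, identity for a rare one), inverted if below 1, and
    then ``E = RR + sqrt(RR*(RR-1))``. A null association gives E = 1.
    """
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    rr = math.sqrt(or_value) if outcome_common else or_value
    if rr < 1.0:
        rr = 1.0 / rr
    e = 1.0 if rr == 1.0 else rr + math.sqrt(rr * (rr - 1.0))
    return EffectSensitivity(or_value=or_value, rr_approx=rr, evalue=e,
                             outcome_common=outcome_common)


def mann_whitney(group_a, group_b) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's automatic method selection). Degenerate
    comparisons with zero rank variance return p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)


def format_pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage with half-up rounding (the report tables' convention).

    Returns NaN for an empty denominator.
    """
    if denominator == 0:
        return float("nan")
    pct = 100.0 * numerator / denominator
    scale = 10 ** decimals
    return math.floor(pct * scale + 0.5) / scale


def utilization_report(
    pre_flags: pd.DataFrame,
    post_flags: pd.DataFrame,
    services=None,
    fisher_threshold: float = 5.0,
    common_outcome_prevalence: float = 0.15,
) -> pd.DataFrame:
    """Per-service utilization comparison (a Table-2-style summary).

    ``pre_flags``/``post_flags`` are boolean frames with one column per
    service for the matched pre and post arms. For each service the report
    gives per-arm counts and percents, the chi-square (or Fisher) p-value,
    the odds ratio, and the E-value with the common/rare OR-to-RR switch at
    ``common_outcome_prevalence`` pooled prevalence. Services with zero
    pooled utilization report null p and E.
    """
    if services is None:
        services = [c for c in pre_flags.columns if c in post_flags.columns]
    n_pre, n_post = len(pre_flags), len(post_flags)
    rows = []
    for svc in services:
        a = int(pre_flags[svc].sum())
        c = int(post_flags[svc].sum())
        total = a + c
        pooled_n = n_pre + n_post
        row = {
            "service": svc,
            "total_n": total,
            "total_pct": format_pct(total, pooled_n),
            "pre_n": a,
            "pre_pct": format_pct(a, n_pre),
            "post_n": c,
            "post_pct": format_pct(c, n_post),
        }
        if total == 0 or total == pooled_n:
            row.update({"p_value": np.nan, "odds_ratio": np.nan,
                        "e_value": np.nan, "outcome_common": np.nan,
                        "test_used": "degenerate"})
        else:
            table = np.array([[a, n_pre - a], [c, n_post - c]])
            res = contingency_test(table, fisher_threshold)
            orv = odds_ratio(table)
            common = (total / pooled_n) >= common_outcome_prevalence
            sens = evalue(orv, outcome_common=common)
            row.update({"p_value": res.p_value, "odds_ratio": orv,
                        "e_value": sens.evalue, "outcome_common": common,
                        "test_used": res.test_used})
        rows.append(row)
    return pd.DataFrame(rows)
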
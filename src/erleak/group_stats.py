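"""Condition-level aggregation and group comparisons.

Covers the statistics used downstream of the per-cell metrics: mean +/- SEM
summaries, two-sample Kolmogorov-Smirnov comparisons (exact enumeration for
small samples, asymptotic otherwise), percent changes between condition
means, normalised densitometry ratios, and the viability linear
correlation.  No multiple-testing correction is applied; censored
half-times are excluded from means with their count reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

EXACT_KS_MAX_NM = 100   # n*m at or below this uses exact enumeration

METRIC_COLUMNS = ("pre_tg_ca_er_uM", "post_tg_t_half_s", "auc_uM_s",
                  "delta_uM", "pre_tg_loss_pct_min")


@dataclass(frozen=True)
class ConditionSummary:
    scenario: str
    n_cells: int
    means: Dict[str, float]
    sems: Dict[str, float]
    n_censored_pre_tg: int = 0
    n_no_decay: int = 0
    comparisons: List[dict] = field(default_factory=list)


@dataclass(frozen=True)
class NormalizedSignal:
    """Target/reference signal ratio expressed relative to a control."""

    sample: str
    target: float
    reference: float
    ratio: float
    relative_to_control: float


def _exact_ks_pvalue(n: int, m: int, h_obs: int) -> float:
    """Exact P(D >= h_obs / (n*m)) under H0 for continuous data.

    Counts, by dynamic programming over the (n+1) x (m+1) interleaving
    lattice, the orderings whose running ECDF gap |i*m - j*n| stays
    strictly below ``h_obs`` everywhere; exact integer arithmetic.
    """
    if h_obs <= 0:
        return 1.0
    counts = [[0] * (m + 1) for _ in range(n + 1)]
    counts[0][0] = 1
    for i in range(n + 1):
        for j in range(m + 1):
            if abs(i * m - j * n) >= h_obs:
                counts[i][j] = 0
                continue
            if i or j:
                counts[i][j] = (counts[i - 1][j] if i else 0) + \
                    (counts[i][j - 1] if j else 0)
    return 1.0 - counts[n][m] / math.comb(n + m, n)


def ks_two_sample(a: Sequence[float], b: Sequence[float]
                  ) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF_a - ECDF_b|; the p-value uses exact enumeration over all
    interleavings when n*m <= EXACT_KS_MAX_NM (assumes continuous data;
    with ties the exact p is conservative) and the asymptotic two-sample
    formula otherwise.
    """
    a = np.sort(np.asarray(list(a), dtype=float))
    b = np.sort(np.asarray(list(b), dtype=float))
    n, m = a.size, b.size
    if n < 5 or m < 5:
        raise ValueError("each sample needs >= 5 values")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / n
    cdf_b = np.searchsorted(b, grid, side="right") / m
    d_stat = float(np.max(np.abs(cdf_a - cdf_b)))
    if n * m <= EXACT_KS_MAX_NM:
        h_obs = int(round(d_stat * n * m))
        p = _exact_ks_pvalue(n, m, h_obs)
    else:
        p = float(stats.ks_2samp(a, b, method="asymp").pvalue)
    return d_stat, min(max(p, 0.0), 1.0)


def percent_change(treated_mean: float, control_mean: float) -> float:
    """100 * (treated - control) / control."""
    if control_mean == 0:
        raise ValueError("control mean must be non-zero")
    return 100.0 * (treated_mean - control_mean) / control_mean


def normalized_signal(target: float, reference: float,
                      control_ratio: float,
                      sample: str = "") -> NormalizedSignal:
    """Densitometry normalisation: target/reference, then relative to the
    control condition's ratio (control maps to exactly 1)."""
    if reference <= 0 or control_ratio <= 0:
        raise ValueError("reference and control ratio must be > 0")
    ratio = target / reference
    return NormalizedSignal(sample=sample, target=target, reference=reference,
                            ratio=ratio,
                            relative_to_control=ratio / control_ratio)


def viability_correlation(x: Sequence[float], y: Sequence[float]
                          ) -> Tuple[float, float, float]:
    """OLS line and Pearson r between paired normalised viabilities.

    Returns (slope, intercept, r); r is NaN (flagged by the caller) when
    either sample is constant.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired cell lines")
    if np.ptp(x) == 0:
        raise ValueError("constant x: regression undefined")
    res = stats.linregress(x, y)
    r = math.nan if np.ptp(y) == 0 else float(res.rvalue)
    return float(res.slope), float(res.intercept), r


# ---------------------------------------------------------------------------
# Condition summaries from the per-cell metric table
# ---------------------------------------------------------------------------


def _mean_sem(values: np.ndarray) -> Tuple[float, float]:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return math.nan, math.nan
    sem = float(np.std(values, ddof=1) / math.sqrt(values.size)) \
        if values.size > 1 else math.nan
    return float(np.mean(values)), sem


def summarize_condition(metrics: pd.DataFrame,
                        scenario: Optional[str] = None) -> ConditionSummary:
    """Mean +/- SEM of the per-cell metrics for one condition.

    Censored pre-TG half-times and no-decay cells are excluded from the
    corresponding means and counted.
    """
    df = metrics if scenario is None else metrics[metrics["scenario"] == scenario]
    if len(df) == 0:
        raise ValueError(f"no cells for scenario {scenario!r}")
    name = scenario if scenario is not None else str(df["scenario"].iloc[0])
    means, sems = {}, {}
    for col in METRIC_COLUMNS:
        if col in df.columns:
            means[col], sems[col] = _mean_sem(df[col].to_numpy(dtype=float))
    if "pre_tg_t_half_s" in df.columns:
        vals = df.loc[~df["pre_tg_censored"].astype(bool),
                      "pre_tg_t_half_s"].to_numpy(dtype=float)
        means["pre_tg_t_half_s"], sems["pre_tg_t_half_s"] = _mean_sem(vals)
    return ConditionSummary(
        scenario=name, n_cells=int(len(df)), means=means, sems=sems,
        n_censored_pre_tg=int(df.get("pre_tg_censored",
                                     pd.Series(dtype=bool)).sum()),
        n_no_decay=int(df.get("no_decay", pd.Series(dtype=bool)).sum()))


def compare_conditions(metrics: pd.DataFrame, treated: str, control: str,
                       columns: Sequence[str] = ("post_tg_t_half_s",
                                                 "delta_uM", "auc_uM_s")
                       ) -> List[dict]:
    """KS test and percent change of condition means, per metric."""
    out = []
    for col in columns:
        a = metrics.loc[metrics["scenario"] == treated, col].dropna().to_numpy()
        b = metrics.loc[metrics["scenario"] == control, col].dropna().to_numpy()
        if a.size < 5 or b.size < 5:
            continue
        d_stat, p = ks_two_sample(a, b)
        out.append({
            "metric": col, "treated": treated, "control": control,
            "ks_D": d_stat, "ks_p": p,
            "percent_change": percent_change(float(np.mean(a)),
                                             float(np.mean(b)))})
    return out


def summary_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"scenario": s.scenario, "n_cells": s.n_cells,
               "n_censored_pre_tg": s.n_censored_pre_tg,
               "n_no_decay": s.n_no_decay}
        for col, val in s.means.items():
            row[f"{col}_mean"] = val
            row[f"{col}_sem"] = s.sems.get(col, math.nan)
        rows.append(row)
    return pd.DataFrame(rows)
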
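"""Factor-stratified comparison of per-subject measurement errors.

The cohort is split at each factor's cut-off into two *independent* subject
groups and a two-sided Wilcoxon rank-sum test (midrank ties; exact
permutation distribution for combined n <= 20, normal approximation with
continuity and tie correction otherwise) asks whether the error
distributions differ in location.  A rank-sum test is used because the two
subsets are different participants — a signed-rank (paired) test is
inapplicable to disjoint groups.  Sex/age sleep-pattern comparisons use the
unequal-variance (Welch) t test for the same reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .hypnogram import FOUR_STAGES
from .agreement import ErrorMatrix
from .transitions import STAGE_INDEX


@dataclass(frozen=True)
class FactorSpec:
    """Cut-off and boundary policy for one stratification factor.

    ``boundary`` names the group that receives values equal to the cut-off:
    ``"high"`` means low = {x < cutoff}, high = {x >= cutoff}; ``"low"``
    means low = {x <= cutoff}, high = {x > cutoff} (used for SE, reported
    as SE>90 vs SE<=90).
    """

    column: str
    cutoff: Optional[float]
    boundary: str = "high"
    nominal: bool = False


#: stratification factors with their conventional cut-offs
FACTOR_SPECS: Dict[str, FactorSpec] = {
    "age": FactorSpec("age", 25),
    "sex": FactorSpec("sex", None, nominal=True),
    "psqi": FactorSpec("psqi", 5),
    "tst": FactorSpec("tst", 360),
    "waso": FactorSpec("waso", 30),
    "sol": FactorSpec("sol", 30),
    "se": FactorSpec("se", 90.0, boundary="low"),
    "light_pct": FactorSpec("light_pct", 65.0),
    "sws_pct": FactorSpec("sws_pct", 20.0),
    "rem_pct": FactorSpec("rem_pct", 20.0),
    "t_avg": FactorSpec("t_avg", 90),
}


def split_by_factor(
    factors: pd.DataFrame,
    factor: str,
    cutoff: Optional[float] = None,
) -> Tuple[Set[str], Set[str], int]:
    """Partition subject ids at a factor's cut-off.

    Returns ``(low_ids, high_ids, n_missing)``; subjects with a missing
    factor value are excluded and counted.  For the nominal factor ``sex``
    the "low" group is female and the "high" group male.
    """
    try:
        spec = FACTOR_SPECS[factor]
    except KeyError:
        raise ValueError(
            f"unknown factor {factor!r}; valid factors: {', '.join(sorted(FACTOR_SPECS))}"
        ) from None
    col = factors[spec.column]
    missing = col.isna()
    n_missing = int(missing.sum())
    ids = factors["subject_id"].astype(str)
    if spec.nominal:
        low = set(ids[(col == "female") & ~missing])
        high = set(ids[(col == "male") & ~missing])
        return low, high, n_missing
    cut = spec.cutoff if cutoff is None else cutoff
    values = col.astype(float)
    if spec.boundary == "low":
        low_mask = values <= cut
    else:
        low_mask = values < cut
    low = set(ids[low_mask & ~missing])
    high = set(ids[~low_mask & ~missing])
    return low, high, n_missing


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum with midranks: exact enumeration / normal approximation
# ---------------------------------------------------------------------------

#: combined sample size up to which the exact permutation distribution is used
EXACT_MAX_N = 20


def rank_sum_test(x: Sequence[float], y: Sequence[float], method: str = "auto") -> Tuple[float, float]:
    """Two-sided rank-sum test of location between two independent samples.

    Ties receive midranks.  ``method="exact"`` enumerates all ways of
    assigning the pooled ranks to the first sample and is the default for
    combined n <= 20; larger samples use the normal approximation with
    continuity correction and the standard tie correction of the variance.
    Returns ``(rank_sum_of_x, p_value)``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    w_obs = float(ranks[:nx].sum())
    mean_w = nx * (n + 1) / 2.0

    if method == "auto":
        method = "exact" if n <= EXACT_MAX_N else "normal"
    if method == "exact":
        dev = abs(w_obs - mean_w)
        hits = 0
        total = 0
        for idx in combinations(range(n), nx):
            total += 1
            w = ranks[list(idx)].sum()
            if abs(w - mean_w) >= dev - 1e-9:
                hits += 1
        return w_obs, hits / total
    if method != "normal":
        raise ValueError(f"unknown method {method!r}")

    # tie-corrected variance of the rank sum under permutation
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:  # all values tied
        return w_obs, 1.0
    dev = abs(w_obs - mean_w)
    z = max(dev - 0.5, 0.0) / math.sqrt(var_w)  # continuity correction
    return w_obs, float(min(1.0, 2.0 * stats.norm.sf(z)))


@dataclass(frozen=True)
class StratifiedComparison:
    """Rank-sum comparison of one error cell between two factor subsets."""

    factor: str
    cutoff: Optional[float]
    cell: Tuple[str, str]
    n_low: int
    n_high: int
    group_low_mean: float
    group_low_sd: float
    group_high_mean: float
    group_high_sd: float
    p_value: float
    testable: bool


def rank_test_errors(
    errors_low: Sequence[float],
    errors_high: Sequence[float],
    factor: str = "",
    cutoff: Optional[float] = None,
    cell: Tuple[str, str] = ("", ""),
) -> StratifiedComparison:
    """Compare one cell's absolute percent errors between two subject groups.

    Group means ± SD are reported on the percent scale.  Groups with fewer
    than 2 defined values (or an empty side) make the cell untestable.
    """
    lo = np.asarray([v for v in errors_low if np.isfinite(v)], dtype=float)
    hi = np.asarray([v for v in errors_high if np.isfinite(v)], dtype=float)

    def _mean_sd(a: np.ndarray) -> Tuple[float, float]:
        if len(a) == 0:
            return math.nan, math.nan
        return float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else math.nan

    lo_mean, lo_sd = _mean_sd(lo)
    hi_mean, hi_sd = _mean_sd(hi)
    if len(lo) < 2 or len(hi) < 2:
        return StratifiedComparison(factor, cutoff, cell, len(lo), len(hi),
                                    lo_mean, lo_sd, hi_mean, hi_sd,
                                    math.nan, testable=False)
    _, p = rank_sum_test(lo, hi)
    return StratifiedComparison(factor, cutoff, cell, len(lo), len(hi),
                                lo_mean, lo_sd, hi_mean, hi_sd, p, testable=True)


def stratification_report(
    error_matrices: Dict[str, ErrorMatrix],
    factors: pd.DataFrame,
    factor_names: Optional[Sequence[str]] = None,
    cutoffs: Optional[Dict[str, float]] = None,
) -> pd.DataFrame:
    """Rank-sum comparisons for every factor × transition cell.

    Columns: factor,cutoff,from,to,n_low,n_high,mean_low,sd_low,mean_high,
    sd_high,p.  Untestable cells carry NaN p.
    """
    if factor_names is None:
        factor_names = list(FACTOR_SPECS)
    cutoffs = cutoffs or {}
    records = []
    for factor in factor_names:
        cut = cutoffs.get(factor, FACTOR_SPECS[factor].cutoff)
        low_ids, high_ids, _ = split_by_factor(factors, factor, cut)
        for i, frm in enumerate(FOUR_STAGES):
            for j, to in enumerate(FOUR_STAGES):
                lo = [error_matrices[s].errors[i, j] for s in low_ids if s in error_matrices]
                hi = [error_matrices[s].errors[i, j] for s in high_ids if s in error_matrices]
                res = rank_test_errors(lo, hi, factor=factor, cutoff=cut, cell=(frm, to))
                records.append({
                    "factor": factor, "cutoff": cut, "from": frm, "to": to,
                    "n_low": res.n_low, "n_high": res.n_high,
                    "mean_low": res.group_low_mean, "sd_low": res.group_low_sd,
                    "mean_high": res.group_high_mean, "sd_high": res.group_high_sd,
                    "p": res.p_value,
                })
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class DemographicComparison:
    """Welch t comparison of a sleep metric between two demographic groups."""

    metric: str
    grouping: str
    n_low: int
    n_high: int
    mean_low: float
    mean_high: float
    t_stat: float
    p_value: float
    testable: bool


def compare_demographics(
    factors: pd.DataFrame,
    metric: str,
    by: str = "sex",
    cutoff: Optional[float] = None,
) -> DemographicComparison:
    """Compare a sleep metric between demographic groups (sex, or a factor split).

    Uses the two-sided unequal-variance t test on independent groups.
    Groups smaller than 2 make the comparison untestable.
    """
    low_ids, high_ids, _ = split_by_factor(factors, by, cutoff)
    sub = factors.set_index(factors["subject_id"].astype(str))
    lo = sub.loc[sub.index.isin(low_ids), metric].astype(float).dropna()
    hi = sub.loc[sub.index.isin(high_ids), metric].astype(float).dropna()
    n_lo, n_hi = len(lo), len(hi)
    mean_lo = float(lo.mean()) if n_lo else math.nan
    mean_hi = float(hi.mean()) if n_hi else math.nan
    if n_lo < 2 or n_hi < 2:
        return DemographicComparison(metric, by, n_lo, n_hi, mean_lo, mean_hi,
                                     math.nan, math.nan, testable=False)
    t, p = stats.ttest_ind(lo, hi, equal_var=False)
    return DemographicComparison(metric, by, n_lo, n_hi, mean_lo, mean_hi,
                                 float(t), float(p), testable=True)
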
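"""Tracker-vs-reference disagreement: absolute percent error, cell-wise
paired t tests, and Bland-Altman bias with limits of agreement.

All public outputs are on the percent scale (0-100); transition
probabilities enter on [0, 1] and are converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .hypnogram import FOUR_STAGES
from .transitions import TransitionMatrix

#: Bland-Altman limits-of-agreement multiplier (the conventional normal
#: quantile, not the small-sample t multiplier).
LOA_MULTIPLIER = 1.96

#: default acceptable-bias threshold: |mean bias| <= 5 percentage points
ACCEPTABLE_BIAS_PCT = 5.0


@dataclass(frozen=True)
class ErrorMatrix:
    """Per-subject absolute percent errors e_{X->Y} (percent scale, NaN = undefined)."""

    subject_id: str
    errors: np.ndarray  # (4, 4) float >= 0 or NaN

    def __post_init__(self) -> None:
        e = np.asarray(self.errors, dtype=float)
        object.__setattr__(self, "errors", e)
        if e.shape != (4, 4):
            raise ValueError("errors must be 4x4")
        if np.nanmin(e, initial=0.0) < 0:
            raise ValueError("absolute percent errors cannot be negative")


def absolute_percent_error(
    F: TransitionMatrix, M: TransitionMatrix, subject_id: str = ""
) -> ErrorMatrix:
    """e_{X->Y} = |s^F - s^M| / s^M * 100 for one subject-night.

    ``F`` is the tracker (field) matrix, ``M`` the medical reference.  Cells
    are undefined where the reference probability is 0 or either matrix is
    undefined; the error is scale-free in the pair (F, M).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.abs(F.probs - M.probs) / M.probs * 100.0
    e[~np.isfinite(e)] = np.nan
    e[M.probs == 0] = np.nan
    return ErrorMatrix(subject_id=subject_id, errors=e)


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary for one transition-matrix cell (percent scale).

    ``scatter`` holds the per-subject (x, difference) table behind the plot;
    by convention here the x-axis is the reference (medical) value, with the
    classical pair-mean variant available via ``xaxis="mean"``.
    """

    cell: Tuple[str, str]
    n: int
    mean_bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    t_stat: float
    p_value: float
    acceptable: bool
    scatter: pd.DataFrame = field(repr=False, default=None)


def _paired_t(diffs: np.ndarray) -> Tuple[float, float]:
    """Two-sided paired t on differences; zero-variance handled explicitly.

    All-zero differences are the exact null: t undefined, p = 1.  A constant
    nonzero difference is a deterministic systematic offset: p = 0.
    """
    n = len(diffs)
    sd = float(np.std(diffs, ddof=1)) if n > 1 else 0.0
    mean = float(np.mean(diffs))
    if sd == 0.0:
        return (np.nan, 1.0 if mean == 0.0 else 0.0)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return (float(t), float(min(p, 1.0)))


def bland_altman_cell(
    tracker_vals: Sequence[float],
    reference_vals: Sequence[float],
    cell: Tuple[str, str] = ("", ""),
    xaxis: str = "reference",
    acceptable_threshold: float = ACCEPTABLE_BIAS_PCT,
) -> AgreementResult:
    """Bland-Altman agreement for one cell from matched per-subject values.

    Inputs are percent-scale values; pairs with a missing member are dropped.
    Bias = mean(tracker - reference); limits of agreement = bias ± 1.96·SD.
    """
    if xaxis not in ("reference", "mean"):
        raise ValueError("xaxis must be 'reference' or 'mean'")
    t = np.asarray(tracker_vals, dtype=float)
    r = np.asarray(reference_vals, dtype=float)
    if t.shape != r.shape:
        raise ValueError("tracker and reference values must be matched")
    ok = np.isfinite(t) & np.isfinite(r)
    t, r = t[ok], r[ok]
    n = len(t)
    if n < 2:
        raise ValueError("Bland-Altman needs at least 2 complete pairs")
    d = t - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    tstat, p = _paired_t(d)
    x = r if xaxis == "reference" else (t + r) / 2.0
    scatter = pd.DataFrame({"x": x, "difference": d})
    return AgreementResult(
        cell=cell, n=n, mean_bias=bias, sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd, loa_high=bias + LOA_MULTIPLIER * sd,
        t_stat=tstat, p_value=p,
        acceptable=abs(bias) <= acceptable_threshold, scatter=scatter,
    )


def acceptable_bias(r: AgreementResult, threshold: float = ACCEPTABLE_BIAS_PCT) -> bool:
    """True when the systematic bias is inside the acceptable range |bias| <= threshold."""
    return bool(abs(r.mean_bias) <= threshold)


def _cell_values(mats: Sequence[TransitionMatrix], i: int, j: int) -> np.ndarray:
    return np.array([m.probs[i, j] for m in mats], dtype=float) * 100.0


def paired_t_matrix(
    tracker_mats: Sequence[TransitionMatrix],
    reference_mats: Sequence[TransitionMatrix],
    alpha: float = 0.05,
    multiple_testing: str = "none",
) -> pd.DataFrame:
    """Cell-wise two-sided paired t tests of tracker vs reference probabilities.

    Subjects must be in matched order.  Cells with fewer than 3 complete
    pairs are flagged untestable.  Raw p-values are reported by default;
    Bonferroni or Benjamini-Hochberg adjustment over the testable cells is
    optional (``multiple_testing`` in {"none", "bonferroni", "bh"}).
    """
    if len(tracker_mats) != len(reference_mats):
        raise ValueError("tracker and reference cohorts must be matched")
    if multiple_testing not in ("none", "bonferroni", "bh"):
        raise ValueError(f"unknown multiple_testing {multiple_testing!r}")
    records = []
    for i, frm in enumerate(FOUR_STAGES):
        for j, to in enumerate(FOUR_STAGES):
            tv = _cell_values(tracker_mats, i, j)
            rv = _cell_values(reference_mats, i, j)
            ok = np.isfinite(tv) & np.isfinite(rv)
            n = int(ok.sum())
            rec = {"from": frm, "to": to, "n": n,
                   "mean_tracker": float(np.mean(tv[ok])) if n else np.nan,
                   "mean_reference": float(np.mean(rv[ok])) if n else np.nan}
            if n < 3:
                rec.update(t=np.nan, p=np.nan, testable=False)
            else:
                t, p = _paired_t(tv[ok] - rv[ok])
                rec.update(t=t, p=p, testable=True)
            records.append(rec)
    table = pd.DataFrame.from_records(records)

    p_adj = table["p"].copy()
    testable = table["testable"].to_numpy()
    if multiple_testing != "none" and testable.any():
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[multiple_testing]
        _, adj, _, _ = multipletests(table.loc[testable, "p"], method=method)
        p_adj.loc[testable] = adj
    table["p_adjusted"] = p_adj
    table["significant"] = (table["p_adjusted"] < alpha) & table["testable"]
    return table


def agreement_table(
    tracker_mats: Sequence[TransitionMatrix],
    reference_mats: Sequence[TransitionMatrix],
    xaxis: str = "reference",
    acceptable_threshold: float = ACCEPTABLE_BIAS_PCT,
) -> Tuple[pd.DataFrame, dict]:
    """Per-cell agreement CSV table plus the AgreementResult objects.

    Returns ``(table, results)`` where ``results`` maps (from, to) to the
    :class:`AgreementResult` (with its scatter table) and ``table`` has
    columns from,to,n,mean_tracker,mean_reference,t,p,bias,loa_low,loa_high,
    acceptable.  Cells with < 2 complete pairs are omitted from ``results``
    and reported with NaN agreement fields.
    """
    records = []
    results = {}
    for i, frm in enumerate(FOUR_STAGES):
        for j, to in enumerate(FOUR_STAGES):
            tv = _cell_values(tracker_mats, i, j)
            rv = _cell_values(reference_mats, i, j)
            ok = np.isfinite(tv) & np.isfinite(rv)
            n = int(ok.sum())
            base = {"from": frm, "to": to, "n": n,
                    "mean_tracker": float(np.mean(tv[ok])) if n else np.nan,
                    "mean_reference": float(np.mean(rv[ok])) if n else np.nan}
            if n < 2:
                base.update(t=np.nan, p=np.nan, bias=np.nan, loa_low=np.nan,
                            loa_high=np.nan, acceptable=False)
            else:
                res = bland_altman_cell(tv[ok], rv[ok], cell=(frm, to), xaxis=xaxis,
                                        acceptable_threshold=acceptable_threshold)
                results[(frm, to)] = res
                base.update(t=res.t_stat, p=res.p_value, bias=res.mean_bias,
                            loa_low=res.loa_low, loa_high=res.loa_high,
                            acceptable=res.acceptable)
            records.append(base)
    return pd.DataFrame.from_records(records), results


def plot_bland_altman(results: dict, outdir, xaxis_label: str = "reference value (%)") -> list:
    """Write one Bland-Altman scatter per cell; returns the file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (frm, to), res in results.items():
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(res.scatter["x"], res.scatter["difference"], s=18)
        for y, style in ((res.mean_bias, "--"), (res.loa_low, ":"), (res.loa_high, ":")):
            ax.axhline(y, linestyle=style, color="gray")
        ax.set_xlabel(xaxis_label)
        ax.set_ylabel("tracker − reference (%)")
        ax.set_title(f"s {frm}→{to}")
        fig.tight_layout()
        path = outdir / f"bland_altman_{frm}_{to}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
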
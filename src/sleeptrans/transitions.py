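"""Sleep-stage transition counting and first-order transition matrices.

The central statistic: for each ordered stage pair (X, Y) over the order
(W, L, D, R), the transition probability

    s_{X->Y} = n_{X->Y} / sum_B n_{X->B}

where n_{X->Y} counts adjacent epoch pairs staged X then Y (self-transitions
included).  Each defined row of the matrix therefore sums to 1.  Rows whose
stage never occurs (zero outgoing transitions) are *undefined* and propagate
as missing — they are never imputed as 0 or uniform, which would bias cohort
averages of rare stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hypnogram import FOUR_STAGES, Hypnogram

STAGE_INDEX = {s: i for i, s in enumerate(FOUR_STAGES)}


def stages_to_indices(stages: Sequence[str]) -> np.ndarray:
    """Encode 4-stage symbols as integer indices over (W, L, D, R)."""
    try:
        return np.array([STAGE_INDEX[s] for s in stages], dtype=np.int64)
    except KeyError as err:
        raise ValueError(f"not a 4-stage symbol: {err.args[0]!r}") from None


@dataclass(frozen=True)
class TransitionCounts:
    """4x4 table of adjacent-epoch transition counts for one device-night."""

    counts: np.ndarray  # (4, 4) int, indexed (from-stage, to-stage)
    n_epochs: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.shape != (4, 4):
            raise ValueError("counts must be 4x4")
        if (c < 0).any():
            raise ValueError("negative transition count")
        if c.sum() != self.n_epochs - 1:
            raise ValueError(
                f"counts sum to {c.sum()} but a {self.n_epochs}-epoch night has "
                f"{self.n_epochs - 1} transitions"
            )

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 4x4 transition probabilities; unsupported rows are NaN."""

    probs: np.ndarray        # (4, 4) float in [0, 1], NaN on zero-support rows
    row_support: np.ndarray  # (4,) int, outgoing transitions per from-stage

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        s = np.asarray(self.row_support, dtype=np.int64)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "row_support", s)
        if p.shape != (4, 4) or s.shape != (4,):
            raise ValueError("probs must be 4x4 and row_support length 4")
        for i in range(4):
            if s[i] > 0:
                row = p[i]
                if np.isnan(row).any() or abs(row.sum() - 1.0) > 1e-12:
                    raise ValueError(f"supported row {FOUR_STAGES[i]} must sum to 1")
            elif not np.isnan(p[i]).all():
                raise ValueError(f"zero-support row {FOUR_STAGES[i]} must be undefined (NaN)")

    @property
    def defined(self) -> np.ndarray:
        """Boolean 4x4 mask of defined cells."""
        return ~np.isnan(self.probs)


def count_transitions(h: Hypnogram) -> TransitionCounts:
    """Count adjacent-epoch transitions (self-transitions included).

    The 16 cells always sum to ``n_epochs - 1``; every epoch pair in the
    aligned record participates, including pre- and mid-sleep wake.
    """
    if not h.is_four_stage:
        raise ValueError("count_transitions requires a 4-stage hypnogram")
    if h.n_epochs < 2:
        raise ValueError("need at least 2 epochs to count transitions")
    idx = stages_to_indices(h.stages)
    flat = idx[:-1] * 4 + idx[1:]
    counts = np.bincount(flat, minlength=16).reshape(4, 4)
    return TransitionCounts(counts=counts, n_epochs=h.n_epochs)


def transition_probabilities(c: TransitionCounts) -> TransitionMatrix:
    """Row-normalise transition counts; zero-support rows become NaN."""
    support = c.row_totals
    probs = np.full((4, 4), np.nan)
    pos = support > 0
    probs[pos] = c.counts[pos] / support[pos, None]
    return TransitionMatrix(probs=probs, row_support=support)


def estimate_matrix(h: Hypnogram) -> TransitionMatrix:
    """Per-night maximum-likelihood transition matrix (convenience)."""
    return transition_probabilities(count_transitions(h))


@dataclass(frozen=True)
class CohortSummary:
    """Cell-wise cohort mean and 95% CI of transition probabilities (percent).

    Cells are averaged over the subjects for whom they are defined (pairwise
    deletion).  The CI is the Student-t interval mean ± t_{0.975,n-1}·SD/√n;
    it is undefined (NaN) where fewer than 2 subjects contribute.
    """

    mean: np.ndarray              # (4, 4) percent
    ci_low: np.ndarray            # (4, 4) percent
    ci_high: np.ndarray           # (4, 4) percent
    n_subjects_per_cell: np.ndarray  # (4, 4) int


def cohort_average(matrices: Sequence[TransitionMatrix]) -> CohortSummary:
    """Average per-subject transition matrices across a cohort.

    Undefined (zero-support) cells are excluded pairwise; a cell defined for
    a single subject reports its mean with an undefined CI.
    """
    if len(matrices) < 2:
        raise ValueError("cohort_average needs at least 2 subjects")
    stack = np.stack([m.probs for m in matrices]) * 100.0  # percent scale
    defined = ~np.isnan(stack)
    n = defined.sum(axis=0)

    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # single-subject cells legitimately have no variance estimate
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(defined, stack, np.nan), axis=0)
        sd = np.nanstd(np.where(defined, stack, np.nan), axis=0, ddof=1)
    mean[n == 0] = np.nan

    ci_low = np.full((4, 4), np.nan)
    ci_high = np.full((4, 4), np.nan)
    ok = n >= 2
    tcrit = np.full((4, 4), np.nan)
    tcrit[ok] = stats.t.ppf(0.975, n[ok] - 1)
    half = tcrit * sd / np.sqrt(np.where(ok, n, np.nan))
    ci_low[ok] = (mean - half)[ok]
    ci_high[ok] = (mean + half)[ok]
    return CohortSummary(mean=mean, ci_low=ci_low, ci_high=ci_high, n_subjects_per_cell=n)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def transitions_long_table(
    subject_ids: Sequence[str],
    counts: Sequence[TransitionCounts],
    matrices: Sequence[TransitionMatrix],
    device: str,
) -> pd.DataFrame:
    """Long-format per-subject table: subject_id, device, from, to, count, prob_pct."""
    records = []
    for sid, c, m in zip(subject_ids, counts, matrices):
        for i, frm in enumerate(FOUR_STAGES):
            for j, to in enumerate(FOUR_STAGES):
                p = m.probs[i, j]
                records.append({
                    "subject_id": sid, "device": device, "from": frm, "to": to,
                    "count": int(c.counts[i, j]),
                    "prob_pct": float(p * 100.0) if np.isfinite(p) else np.nan,
                })
    return pd.DataFrame.from_records(records)


def cohort_summary_table(summary: CohortSummary, device: str) -> pd.DataFrame:
    """Long-format cohort summary: from, to, mean, ci_low, ci_high, n (percent)."""
    records = []
    for i, frm in enumerate(FOUR_STAGES):
        for j, to in enumerate(FOUR_STAGES):
            records.append({
                "device": device, "from": frm, "to": to,
                "mean_pct": summary.mean[i, j],
                "ci_low_pct": summary.ci_low[i, j],
                "ci_high_pct": summary.ci_high[i, j],
                "n": int(summary.n_subjects_per_cell[i, j]),
            })
    return pd.DataFrame.from_records(records)


def matrices_from_long_table(table: pd.DataFrame, device: str) -> "tuple[list, list]":
    """Rebuild per-subject ``TransitionMatrix`` objects from a long-format table.

    Inverse of :func:`transitions_long_table` for one device; returns
    ``(subject_ids, matrices)`` in first-appearance order.
    """
    sub = table[table["device"] == device]
    ids: List[str] = []
    mats: List[TransitionMatrix] = []
    for sid, grp in sub.groupby("subject_id", sort=False):
        counts = np.zeros((4, 4), dtype=np.int64)
        for _, row in grp.iterrows():
            counts[STAGE_INDEX[row["from"]], STAGE_INDEX[row["to"]]] = row["count"]
        support = counts.sum(axis=1)
        probs = np.full((4, 4), np.nan)
        pos = support > 0
        probs[pos] = counts[pos] / support[pos, None]
        ids.append(str(sid))
        mats.append(TransitionMatrix(probs=probs, row_support=support))
    return ids, mats
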
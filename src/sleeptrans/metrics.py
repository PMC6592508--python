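"""Sleep-quality metrics derived from the reference hypnogram.

Definitions (record = the in-bed interval the devices captured):

* SOL (sleep onset latency): minutes from record start to the first
  non-wake epoch, which defines sleep onset.
* TST (total sleep time): minutes in any sleep stage between onset and the
  final awakening (last non-wake epoch), inclusive.
* WASO (wake after sleep onset): wake minutes strictly between onset and
  the final awakening; TST + WASO spans that interval exactly.
* SE (sleep efficiency): TST as a percentage of the full record duration.
* Stage ratios: stage minutes as a percentage of TST.
* T_avg (average sleep cycle): mean interval between the end epochs of
  successive REM episodes (maximal runs of R); needs >= 2 episodes.

Sleep onset uses the simplest rule — the first epoch of any sleep stage —
rather than multi-epoch clinical variants; undefined quantities are NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, map_five_to_four


@dataclass(frozen=True)
class SleepMetrics:
    """Per-night sleep-quality metrics (minutes / percent; NaN = undefined)."""

    tst_min: float
    waso_min: float
    sol_min: float
    se_pct: float
    light_pct: float
    sws_pct: float
    rem_pct: float
    t_avg_min: float
    n1_pct: float = math.nan  # defined only for 5-stage input

    @property
    def defined(self) -> bool:
        return not math.isnan(self.tst_min)


_UNDEFINED = SleepMetrics(*(math.nan,) * 8)


def average_sleep_cycle(h: Hypnogram) -> float:
    """Mean sleep-cycle length in minutes, cycles delimited by REM-episode ends.

    A REM episode is a maximal run of R epochs.  With fewer than 2 episodes
    the quantity is undefined (NaN).
    """
    epm = h.epoch_seconds / 60.0
    is_rem = np.array([s == "R" for s in h.stages])
    # episode end positions: R epochs whose successor is not R
    ends = np.where(is_rem & ~np.append(is_rem[1:], False))[0]
    if len(ends) < 2:
        return math.nan
    return float(np.diff(ends).mean() * epm)


def compute_metrics(h: Hypnogram) -> SleepMetrics:
    """Derive the factor metrics from one (reference) hypnogram.

    Accepts 4- or 5-stage input; N1 percentage is reported only for 5-stage
    scoring.  An all-wake record yields undefined metrics.
    """
    n1_pct = math.nan
    five_stage = h.is_five_stage
    h4 = map_five_to_four(h)
    stages = np.array(h4.stages)
    epm = h4.epoch_seconds / 60.0

    sleep = stages != "W"
    if not sleep.any():
        return _UNDEFINED
    onset = int(np.argmax(sleep))
    final = int(len(sleep) - 1 - np.argmax(sleep[::-1]))

    span = stages[onset:final + 1]
    tst_epochs = int((span != "W").sum())
    waso_epochs = int((span == "W").sum())
    tst = tst_epochs * epm
    waso = waso_epochs * epm
    sol = onset * epm
    se = tst / (len(stages) * epm) * 100.0

    light = float((stages == "L").sum()) * epm / tst * 100.0
    sws = float((stages == "D").sum()) * epm / tst * 100.0
    rem = float((stages == "R").sum()) * epm / tst * 100.0
    if five_stage:
        n1 = sum(s == "N1" for s in h.stages)
        n1_pct = n1 * epm / tst * 100.0

    return SleepMetrics(
        tst_min=tst, waso_min=waso, sol_min=sol, se_pct=se,
        light_pct=light, sws_pct=sws, rem_pct=rem,
        t_avg_min=average_sleep_cycle(h4), n1_pct=n1_pct,
    )


@dataclass(frozen=True)
class SubjectFactors:
    """Demographic and sleep-quality covariates for one participant."""

    subject_id: str
    age_years: int
    sex: str  # "female" | "male"
    psqi: int
    metrics: SleepMetrics

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not 0 <= self.psqi <= 21:
            raise ValueError("PSQI score must be in [0, 21]")
        if self.age_years <= 18:
            raise ValueError("participants are adults (age > 18)")


FACTOR_COLUMNS = ("subject_id", "age", "sex", "psqi", "tst", "waso", "sol",
                  "se", "light_pct", "sws_pct", "rem_pct", "t_avg")


def factors_table(subjects: Sequence[SubjectFactors]) -> pd.DataFrame:
    """One row per subject with the covariates used for stratification."""
    rows = []
    for s in subjects:
        m = s.metrics
        rows.append({
            "subject_id": s.subject_id, "age": s.age_years, "sex": s.sex,
            "psqi": s.psqi, "tst": m.tst_min, "waso": m.waso_min,
            "sol": m.sol_min, "se": m.se_pct, "light_pct": m.light_pct,
            "sws_pct": m.sws_pct, "rem_pct": m.rem_pct, "t_avg": m.t_avg_min,
        })
    return pd.DataFrame(rows, columns=list(FACTOR_COLUMNS))
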
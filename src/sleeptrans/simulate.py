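"""Synthetic cohorts of paired tracker/reference hypnograms.

Whole nights are generated as first-order 4-state Markov chains over
(W, L, D, R) at 30 s epochs.  The default generator matrices are the
cohort-mean transition probabilities reported for 23 healthy young adults
measured simultaneously with a clinical single-channel EEG (reference) and
a consumer wrist tracker; the printed rows carry rounding and are
renormalized to sum exactly to 1 before use.  Between-subject variation is
a per-row Dirichlet perturbation whose expectation is the cohort row.

The tracker channel is either an independent chain from the tracker-side
cohort matrix, or an epoch-wise misclassification (confusion) channel
applied to the reference night — the default confusion relabels wake and
deep-sleep epochs as light sleep with elevated probability, the error mode
consumer trackers are known for.  A first-order chain is sufficient here
because the estimator under test is itself first-order; real hypnograms
additionally carry stage-duration dependence and ultradian structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .hypnogram import (FOUR_STAGES, AlignedPair, Hypnogram, write_epoch_csv)
from .metrics import SleepMetrics, SubjectFactors, compute_metrics, factors_table
from .transitions import STAGE_INDEX

#: Cohort-mean transition probabilities (%) measured by the clinical EEG
#: reference in healthy young adults; rows ordered (W, L, D, R).
REFERENCE_COHORT_PERCENT = np.array([
    [53.7, 43.6, 0.2, 2.6],
    [2.6, 92.6, 3.9, 0.8],
    [2.5, 57.7, 35.5, 0.0],
    [2.0, 0.9, 0.0, 96.9],
])

#: Cohort-mean transition probabilities (%) measured by the consumer wrist
#: tracker in the same cohort; rows ordered (W, L, D, R).
TRACKER_COHORT_PERCENT = np.array([
    [89.8, 5.5, 0.2, 0.2],
    [0.5, 97.8, 1.1, 0.5],
    [0.2, 3.8, 94.9, 1.1],
    [0.1, 1.7, 1.2, 96.9],
])

#: Default epoch-wise misclassification: 30% of true wake and true deep
#: epochs are relabeled light sleep; light and REM are passed through.
DEFAULT_CONFUSION = np.array([
    [0.7, 0.3, 0.0, 0.0],
    [0.0, 1.0, 0.0, 0.0],
    [0.0, 0.3, 0.7, 0.0],
    [0.0, 0.0, 0.0, 1.0],
])

IDENTITY_CONFUSION = np.eye(4)


def renormalize_rows(matrix: np.ndarray) -> np.ndarray:
    """Scale each row to sum exactly to 1 (zeros are preserved)."""
    m = np.asarray(matrix, dtype=float)
    sums = m.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("every row needs positive mass")
    return m / sums


def reference_default_matrix() -> np.ndarray:
    """Row-stochastic reference (EEG) generator matrix."""
    return renormalize_rows(REFERENCE_COHORT_PERCENT)


def tracker_default_matrix() -> np.ndarray:
    """Row-stochastic tracker generator matrix."""
    return renormalize_rows(TRACKER_COHORT_PERCENT)


def _check_stochastic(matrix: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise ValueError("transition matrix must be 4x4")
    if (m < -tol).any() or (np.abs(m.sum(axis=1) - 1.0) > tol).any():
        raise ValueError("matrix is not row-stochastic")
    return np.clip(m, 0.0, 1.0)


def _as_rng(seed: Union[int, Sequence[int], np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_hypnogram(
    matrix: np.ndarray,
    n_epochs: int,
    initial_stage: str = "W",
    seed: Union[int, Sequence[int], np.random.Generator, None] = None,
    epoch_seconds: int = 30,
    subject_id: str = "",
    device: str = "reference",
    night_index: int = 1,
    start_time: Optional[datetime] = None,
) -> Hypnogram:
    """Simulate one night from a first-order stage-transition chain.

    The first epoch is ``initial_stage`` (wake, as nights begin in bed
    awake); each later epoch is drawn from the row of the previous stage.
    Deterministic under a fixed seed.
    """
    m = _check_stochastic(matrix)
    if n_epochs < 2:
        raise ValueError("a night needs at least 2 epochs")
    rng = _as_rng(seed)
    cum = np.cumsum(m, axis=1)
    cum[:, -1] = 1.0  # guard against rounding in the last column
    u = rng.random(n_epochs - 1)
    states = np.empty(n_epochs, dtype=np.int8)
    s = STAGE_INDEX[initial_stage]
    states[0] = s
    for t in range(1, n_epochs):
        s = int(np.searchsorted(cum[s], u[t - 1], side="right"))
        states[t] = s
    stages = tuple(FOUR_STAGES[i] for i in states)
    return Hypnogram(stages=stages, device=device, subject_id=subject_id,
                     night_index=night_index, start_time=start_time,
                     epoch_seconds=epoch_seconds)


def sample_subject_matrix(
    cohort_matrix: np.ndarray,
    jitter: float,
    seed: Union[int, Sequence[int], np.random.Generator, None] = None,
) -> np.ndarray:
    """Draw a subject-level matrix around the cohort matrix.

    Each row is a Dirichlet draw with concentration ``jitter`` centred on
    the cohort row (alpha = jitter * row over its nonzero cells), so the
    expectation equals the cohort row, structural zeros stay zero, and the
    jitter -> infinity limit recovers the cohort matrix.
    """
    if not jitter > 0:
        raise ValueError("jitter must be positive")
    m = _check_stochastic(cohort_matrix)
    rng = _as_rng(seed)
    out = np.zeros_like(m)
    for i in range(4):
        mask = m[i] > 0
        out[i, mask] = rng.dirichlet(jitter * m[i, mask])
    return out


def apply_confusion_channel(
    h: Hypnogram,
    confusion: np.ndarray,
    seed: Union[int, Sequence[int], np.random.Generator, None] = None,
) -> Hypnogram:
    """Relabel each epoch independently per the confusion row of its true stage."""
    if not h.is_four_stage:
        raise ValueError("confusion channel requires a 4-stage hypnogram")
    c = _check_stochastic(confusion)
    rng = _as_rng(seed)
    idx = np.array([STAGE_INDEX[s] for s in h.stages])
    cum = np.cumsum(c, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(len(idx))
    relabeled = (u[:, None] >= cum[idx]).sum(axis=1)
    stages = tuple(FOUR_STAGES[i] for i in relabeled)
    return replace(h, stages=stages, device="tracker")


@dataclass
class SimulationConfig:
    """Study conditions for a simulated validation cohort.

    Defaults mirror the validation study the analysis emulates: 23
    participants, whole nights of 960 thirty-second epochs (8 h), generator
    matrices equal to the cohort-mean reference/tracker transition
    probabilities, and moderate between-subject Dirichlet jitter
    (concentration 100 per row, giving cohort confidence-interval widths of
    the same order as those the study reports once within-night estimation
    noise is included).
    """

    n_subjects: int = 23
    n_epochs: int = 960
    epoch_seconds: int = 30
    reference_matrix: np.ndarray = field(default_factory=reference_default_matrix)
    tracker_mode: str = "confusion_channel"  # or "independent_chain"
    tracker_matrix: np.ndarray = field(default_factory=tracker_default_matrix)
    confusion: np.ndarray = field(default_factory=lambda: DEFAULT_CONFUSION.copy())
    subject_jitter: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.reference_matrix = _check_stochastic(self.reference_matrix)
        self.tracker_matrix = _check_stochastic(self.tracker_matrix)
        self.confusion = _check_stochastic(self.confusion)
        if self.tracker_mode not in ("independent_chain", "confusion_channel"):
            raise ValueError(f"unknown tracker_mode {self.tracker_mode!r}")
        if self.n_epochs < 2:
            raise ValueError("n_epochs must be >= 2")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_epochs": self.n_epochs,
            "epoch_seconds": self.epoch_seconds,
            "reference_matrix": self.reference_matrix.tolist(),
            "tracker_mode": self.tracker_mode,
            "tracker_matrix": self.tracker_matrix.tolist(),
            "confusion": self.confusion.tolist(),
            "subject_jitter": self.subject_jitter,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        for key in ("reference_matrix", "tracker_matrix", "confusion"):
            if key in data:
                data[key] = np.asarray(data[key], dtype=float)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: Union[str, Path]) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class SimulatedSubject:
    subject_id: str
    tracker: Hypnogram
    reference: Hypnogram
    factors: SubjectFactors

    @property
    def pair(self) -> AlignedPair:
        return AlignedPair(subject_id=self.subject_id, tracker=self.tracker,
                           reference=self.reference)


@dataclass(frozen=True)
class Cohort:
    subjects: Tuple[SimulatedSubject, ...]
    config: SimulationConfig

    @property
    def pairs(self) -> List[AlignedPair]:
        return [s.pair for s in self.subjects]

    @property
    def factors(self) -> pd.DataFrame:
        return factors_table([s.factors for s in self.subjects])


_NIGHT_START = datetime(2019, 1, 8, 23, 30)
_ANALYSIS_NIGHT = 2


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate one analysis night per subject plus the covariate table.

    Per-subject random streams are derived from the master seed and the
    subject index, so growing ``n_subjects`` extends the cohort without
    reshuffling existing subjects.  Covariates: age discrete uniform on
    21-30, sex Bernoulli matching the study's 14:9 men:women ratio, PSQI
    integer 0-10; sleep metrics are computed from the reference night.
    """
    subjects = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:02d}"
        rng_ref = np.random.default_rng((config.seed, i, 0))
        rng_trk = np.random.default_rng((config.seed, i, 1))
        rng_cov = np.random.default_rng((config.seed, i, 2))

        ref_matrix = sample_subject_matrix(config.reference_matrix,
                                           config.subject_jitter, rng_ref)
        reference = simulate_hypnogram(
            ref_matrix, config.n_epochs, seed=rng_ref,
            epoch_seconds=config.epoch_seconds, subject_id=sid,
            device="reference", night_index=_ANALYSIS_NIGHT,
            start_time=_NIGHT_START,
        )
        if config.tracker_mode == "independent_chain":
            trk_matrix = sample_subject_matrix(config.tracker_matrix,
                                               config.subject_jitter, rng_trk)
            tracker = simulate_hypnogram(
                trk_matrix, config.n_epochs, seed=rng_trk,
                epoch_seconds=config.epoch_seconds, subject_id=sid,
                device="tracker", night_index=_ANALYSIS_NIGHT,
                start_time=_NIGHT_START,
            )
        else:
            tracker = apply_confusion_channel(reference, config.confusion, rng_trk)
            tracker = replace(tracker, device="tracker")

        factors = SubjectFactors(
            subject_id=sid,
            age_years=int(rng_cov.integers(21, 31)),
            sex="male" if rng_cov.random() < 14 / 23 else "female",
            psqi=int(rng_cov.integers(0, 11)),
            metrics=compute_metrics(reference),
        )
        subjects.append(SimulatedSubject(subject_id=sid, tracker=tracker,
                                         reference=reference, factors=factors))
    return Cohort(subjects=tuple(subjects), config=config)


def write_cohort(cohort: Cohort, outdir: Union[str, Path]) -> Path:
    """Write a cohort as the on-disk formats the pipeline consumes.

    Emits per-subject epoch CSVs (reference) and tracker sleep JSON, a
    factors CSV and a YAML manifest; returns the manifest path.
    """
    from .hypnogram import write_fitbit_sleep_json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"factors": "factors.csv", "subjects": {}}
    for s in cohort.subjects:
        ref_path = f"{s.subject_id}_night{_ANALYSIS_NIGHT}_reference.csv"
        trk_path = f"{s.subject_id}_night{_ANALYSIS_NIGHT}_tracker.json"
        write_epoch_csv(s.reference, outdir / ref_path)
        write_fitbit_sleep_json(s.tracker, outdir / trk_path)
        manifest["subjects"][s.subject_id] = {
            "nights": {_ANALYSIS_NIGHT: {"tracker": trk_path, "reference": ref_path}}
        }
    cohort.factors.to_csv(outdir / "factors.csv", index=False)
    cohort.config.to_yaml(outdir / "simulation_config.yaml")
    manifest_path = outdir / "manifest.yaml"
    with manifest_path.open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path
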
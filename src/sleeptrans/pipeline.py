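"""End-to-end validation pipeline: load/align cohort, estimate transition
matrices, quantify tracker error and agreement, stratify by factors, and
write the report bundle.

Every stage is also usable in memory (``analyze_pairs``); the file-level
subcommands of the CLI and the monolithic ``run_pipeline`` share these code
paths, so staged and monolithic runs produce identical numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hypnogram import (AlignedPair, Hypnogram, NightSelection, align_pair,
                        map_five_to_four, read_epoch_csv,
                        read_fitbit_sleep_json, select_analysis_night,
                        MIN_VALID_EPOCHS, STAGE_LEVEL)
from .transitions import (TransitionCounts, TransitionMatrix, cohort_average,
                          cohort_summary_table, count_transitions,
                          transition_probabilities, transitions_long_table)
from .agreement import (ACCEPTABLE_BIAS_PCT, absolute_percent_error,
                        agreement_table, paired_t_matrix, plot_bland_altman)
from .stratify import stratification_report


@dataclass
class RunConfig:
    """Pipeline configuration; all randomness flows from ``seed``."""

    manifest: Optional[Union[str, Path]] = None
    outdir: Union[str, Path] = "results"
    alpha: float = 0.05
    acceptable_error_pct: float = ACCEPTABLE_BIAS_PCT
    ba_xaxis: str = "reference"  # or "mean" for the classical variant
    multiple_testing: str = "none"  # "bonferroni" | "bh"
    min_valid_epochs: int = MIN_VALID_EPOCHS
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.acceptable_error_pct > 0:
            raise ValueError("acceptable_error_pct must be positive")


# ---------------------------------------------------------------------------
# Manifest loading
# ---------------------------------------------------------------------------

def _read_device_file(path: Path, device: str) -> Hypnogram:
    if path.suffix.lower() == ".json":
        h = read_fitbit_sleep_json(path)
    else:
        h = read_epoch_csv(path, device=device)
    if h.granularity == STAGE_LEVEL and h.is_five_stage:
        h = map_five_to_four(h)
    return h


def load_manifest(path: Union[str, Path]) -> Tuple[List[AlignedPair], pd.DataFrame, List[NightSelection]]:
    """Resolve a cohort manifest into aligned pairs, factors and exclusions.

    The manifest maps subject ids to per-night device files (CSV or sleep
    JSON) plus a factors CSV.  Night selection follows the
    second/third/first rule; subjects without a valid night become
    exclusion records.
    """
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    base = path.parent
    factors = (pd.read_csv(base / doc["factors"], float_precision="round_trip")
               if "factors" in doc else pd.DataFrame())

    pairs: List[AlignedPair] = []
    exclusions: List[NightSelection] = []
    for sid, entry in doc.get("subjects", {}).items():
        nights = {}
        for night_idx, files in entry.get("nights", {}).items():
            trk = ref = None
            if files.get("tracker"):
                trk = _read_device_file(base / files["tracker"], "tracker")
            if files.get("reference"):
                ref = _read_device_file(base / files["reference"], "reference")
            nights[int(night_idx)] = (trk, ref)
        sel = select_analysis_night(nights, subject_id=str(sid))
        if sel.excluded:
            exclusions.append(sel)
        else:
            pairs.append(align_pair(sel.tracker, sel.reference))
    return pairs, factors, exclusions


# ---------------------------------------------------------------------------
# In-memory analysis
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """All tables the pipeline computes for one cohort."""

    subject_ids: List[str]
    tracker_counts: List[TransitionCounts]
    reference_counts: List[TransitionCounts]
    tracker_matrices: List[TransitionMatrix]
    reference_matrices: List[TransitionMatrix]
    transitions_long: pd.DataFrame
    cohort_summary: pd.DataFrame          # both devices, long format, percent
    paired_tests: pd.DataFrame
    agreement: pd.DataFrame
    agreement_results: dict = field(repr=False, default_factory=dict)
    errors_long: pd.DataFrame = None
    error_matrices: dict = field(repr=False, default_factory=dict)
    stratification: pd.DataFrame = None
    exclusions: List[NightSelection] = field(default_factory=list)


def analyze_pairs(
    pairs: Sequence[AlignedPair],
    factors: Optional[pd.DataFrame] = None,
    config: Optional[RunConfig] = None,
) -> PipelineResult:
    """Run estimation, error, agreement and stratification on aligned pairs."""
    config = config or RunConfig()
    if len(pairs) < 2:
        raise ValueError("need at least 2 analyzable subjects")
    subject_ids = [p.subject_id for p in pairs]

    trk_counts = [count_transitions(p.tracker) for p in pairs]
    ref_counts = [count_transitions(p.reference) for p in pairs]
    trk_mats = [transition_probabilities(c) for c in trk_counts]
    ref_mats = [transition_probabilities(c) for c in ref_counts]

    long = pd.concat([
        transitions_long_table(subject_ids, trk_counts, trk_mats, "tracker"),
        transitions_long_table(subject_ids, ref_counts, ref_mats, "reference"),
    ], ignore_index=True)
    summary = pd.concat([
        cohort_summary_table(cohort_average(trk_mats), "tracker"),
        cohort_summary_table(cohort_average(ref_mats), "reference"),
    ], ignore_index=True)

    tests = paired_t_matrix(trk_mats, ref_mats, alpha=config.alpha,
                            multiple_testing=config.multiple_testing)
    agreement, ba_results = agreement_table(
        trk_mats, ref_mats, xaxis=config.ba_xaxis,
        acceptable_threshold=config.acceptable_error_pct)

    error_mats = {
        sid: absolute_percent_error(f, m, subject_id=sid)
        for sid, f, m in zip(subject_ids, trk_mats, ref_mats)
    }
    errors_long = errors_long_table(error_mats)

    strat = None
    if factors is not None and len(factors):
        strat = stratification_report(error_mats, factors)

    return PipelineResult(
        subject_ids=subject_ids,
        tracker_counts=trk_counts, reference_counts=ref_counts,
        tracker_matrices=trk_mats, reference_matrices=ref_mats,
        transitions_long=long, cohort_summary=summary,
        paired_tests=tests, agreement=agreement, agreement_results=ba_results,
        errors_long=errors_long, error_matrices=error_mats,
        stratification=strat,
    )


def errors_long_table(error_mats: dict) -> pd.DataFrame:
    """Long-format per-subject absolute percent errors: subject_id,from,to,error_pct."""
    from .hypnogram import FOUR_STAGES

    records = []
    for sid, em in error_mats.items():
        for i, frm in enumerate(FOUR_STAGES):
            for j, to in enumerate(FOUR_STAGES):
                records.append({"subject_id": sid, "from": frm, "to": to,
                                "error_pct": em.errors[i, j]})
    return pd.DataFrame.from_records(records)


def error_matrices_from_long(table: pd.DataFrame) -> dict:
    """Rebuild per-subject :class:`ErrorMatrix` objects from the long table."""
    from .agreement import ErrorMatrix
    from .transitions import STAGE_INDEX

    out = {}
    for sid, grp in table.groupby("subject_id", sort=False):
        e = np.full((4, 4), np.nan)
        for _, row in grp.iterrows():
            e[STAGE_INDEX[row["from"]], STAGE_INDEX[row["to"]]] = row["error_pct"]
        out[str(sid)] = ErrorMatrix(subject_id=str(sid), errors=e)
    return out


# ---------------------------------------------------------------------------
# Monolithic run
# ---------------------------------------------------------------------------

def write_result(result: PipelineResult, config: RunConfig) -> Path:
    """Write the report bundle for an analyzed cohort; returns the outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.transitions_long.to_csv(outdir / "transitions_long.csv", index=False)
    result.cohort_summary.to_csv(outdir / "cohort_summary.csv", index=False)
    result.paired_tests.to_csv(outdir / "paired_tests.csv", index=False)
    result.agreement.to_csv(outdir / "agreement.csv", index=False)
    result.errors_long.to_csv(outdir / "errors_long.csv", index=False)
    if result.stratification is not None:
        result.stratification.to_csv(outdir / "stratification.csv", index=False)
    exclusions = pd.DataFrame(
        [{"subject_id": e.subject_id, "reason": e.reason} for e in result.exclusions],
        columns=["subject_id", "reason"],
    )
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    run_manifest = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "acceptable_error_pct": config.acceptable_error_pct,
        "ba_xaxis": config.ba_xaxis,
        "multiple_testing": config.multiple_testing,
        "min_valid_epochs": config.min_valid_epochs,
        "n_subjects": len(result.subject_ids),
        "n_excluded": len(result.exclusions),
    }
    with (outdir / "run_manifest.json").open("w") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if config.make_plots:
        plot_bland_altman(result.agreement_results, outdir / "figures")
    return outdir


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load the manifest, analyze the cohort, and write the report bundle.

    Raises ``ValueError`` (listing the exclusions) when fewer than 2
    subjects survive night selection.
    """
    if config.manifest is None:
        raise ValueError("RunConfig.manifest is required")
    pairs, factors, exclusions = load_manifest(config.manifest)
    if len(pairs) < 2:
        lines = "; ".join(f"{e.subject_id}: {e.reason}" for e in exclusions)
        raise ValueError(f"no analyzable cohort ({len(pairs)} subjects kept). Exclusions: {lines}")
    result = analyze_pairs(pairs, factors=factors, config=config)
    result.exclusions = exclusions
    write_result(result, config)
    return result
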
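"""Epoch-coded hypnograms: reading, validation, stage mapping and alignment.

A hypnogram is one device-night of sleep as an ordered sequence of staged
epochs (30 s by clinical convention).  Two alphabets are supported: the
4-stage consumer alphabet ``W, L, D, R`` (wake, light, deep, REM) and the
5-stage clinical alphabet ``W, N1, N2, N3, R``.  Consumer trackers may also
export *classic-level* records (``awake/restless/asleep`` at 60 s); these
carry no stage information and are flagged so the pipeline can exclude them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple, Union

FOUR_STAGES: Tuple[str, ...] = ("W", "L", "D", "R")
FIVE_STAGES: Tuple[str, ...] = ("W", "N1", "N2", "N3", "R")
CLASSIC_LEVELS: Tuple[str, ...] = ("awake", "restless", "asleep")

STAGE_LEVEL = "stage_level"
CLASSIC_LEVEL = "classic_level"

#: case-insensitive token -> canonical stage symbol
_TOKEN_MAP = {
    "w": "W", "wake": "W",
    "l": "L", "light": "L",
    "d": "D", "deep": "D",
    "r": "R", "rem": "R",
    "n1": "N1", "n2": "N2", "n3": "N3",
    # classic-level tokens kept verbatim (no stage information)
    "awake": "awake", "restless": "restless", "asleep": "asleep",
}


def map_stage_token(token: str) -> str:
    """Map a raw stage token to its canonical symbol (case-insensitive)."""
    key = token.strip().lower()
    try:
        return _TOKEN_MAP[key]
    except KeyError:
        raise ValueError(f"unknown stage token {token!r}") from None


@dataclass(frozen=True)
class Hypnogram:
    """One device-night as an ordered sequence of staged epochs.

    Parameters
    ----------
    stages
        Stage symbols, one per epoch, all from a single alphabet.
    device
        ``"tracker"`` (consumer wristband) or ``"reference"`` (medical EEG).
    epoch_seconds
        Epoch length; constant within a hypnogram (30 s clinical standard).
    granularity
        ``"stage_level"`` for staged data, ``"classic_level"`` for the
        coarse awake/restless/asleep export, which is unusable for staging.
    """

    stages: Tuple[str, ...]
    device: str = "reference"
    subject_id: str = ""
    night_index: int = 1
    start_time: Optional[datetime] = None
    epoch_seconds: int = 30
    granularity: str = STAGE_LEVEL

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("hypnogram has no epochs")
        object.__setattr__(self, "stages", tuple(self.stages))
        if self.device not in ("tracker", "reference"):
            raise ValueError(f"device must be 'tracker' or 'reference', got {self.device!r}")
        if self.night_index < 1:
            raise ValueError("night_index must be >= 1")
        if not (isinstance(self.epoch_seconds, int) and self.epoch_seconds > 0):
            raise ValueError("epoch_seconds must be a positive integer")
        if self.granularity not in (STAGE_LEVEL, CLASSIC_LEVEL):
            raise ValueError(f"unknown granularity {self.granularity!r}")
        symbols = set(self.stages)
        if self.granularity == CLASSIC_LEVEL:
            if not symbols <= set(CLASSIC_LEVELS):
                raise ValueError(f"classic-level hypnogram contains non-classic tokens: {sorted(symbols)}")
        elif not (symbols <= set(FOUR_STAGES) or symbols <= set(FIVE_STAGES)):
            raise ValueError(
                f"stages must come from one alphabet ({FOUR_STAGES} or {FIVE_STAGES}); got {sorted(symbols)}"
            )

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def is_four_stage(self) -> bool:
        return self.granularity == STAGE_LEVEL and set(self.stages) <= set(FOUR_STAGES)

    @property
    def is_five_stage(self) -> bool:
        return self.granularity == STAGE_LEVEL and not self.is_four_stage

    @property
    def duration_minutes(self) -> float:
        return self.n_epochs * self.epoch_seconds / 60.0

    @property
    def end_time(self) -> Optional[datetime]:
        if self.start_time is None:
            return None
        return self.start_time + timedelta(seconds=self.n_epochs * self.epoch_seconds)


@dataclass(frozen=True)
class AlignedPair:
    """Tracker and reference hypnograms trimmed to a common epoch grid."""

    subject_id: str
    tracker: Hypnogram
    reference: Hypnogram

    def __post_init__(self) -> None:
        if self.tracker.n_epochs != self.reference.n_epochs:
            raise ValueError("aligned hypnograms must have identical length")
        if self.tracker.epoch_seconds != self.reference.epoch_seconds:
            raise ValueError("aligned hypnograms must share epoch_seconds")

    @property
    def n_epochs(self) -> int:
        return self.tracker.n_epochs


# ---------------------------------------------------------------------------
# Epoch CSV  (header `epoch_index,stage`; metadata as `# key=value` lines)
# ---------------------------------------------------------------------------

def read_epoch_csv(path: Union[str, Path], device: str = "reference") -> Hypnogram:
    """Read an epoch CSV file (1-based contiguous ``epoch_index``, one stage per row).

    Metadata may precede the header as ``# key=value`` comment lines
    (``subject_id``, ``start_time`` ISO-8601, ``epoch_seconds``, ``night_index``).
    Unknown stage tokens and non-contiguous epoch indices are rejected with the
    offending row named.
    """
    path = Path(path)
    meta: dict = {}
    rows = []
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = []
    for ln in lines:
        if ln.startswith("#"):
            key, _, value = ln.lstrip("# ").partition("=")
            if _:
                meta[key.strip()] = value.strip()
        elif ln.strip():
            body.append(ln)
    if not body or body[0].split(",")[0].strip() != "epoch_index":
        raise ValueError(f"{path}: expected header 'epoch_index,stage'")
    for row_number, ln in enumerate(body[1:], start=1):
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed row {row_number}: {ln!r}")
        try:
            idx = int(parts[0])
        except ValueError:
            raise ValueError(f"{path}: non-integer epoch_index at row {row_number}") from None
        if idx != row_number:  # file is 1-based and contiguous
            raise ValueError(f"{path}: non-contiguous epoch_index {idx} at row {row_number}")
        try:
            stage = map_stage_token(parts[1])
        except ValueError:
            raise ValueError(f"{path}: unknown stage token {parts[1]!r} at row {row_number}") from None
        rows.append(stage)

    granularity = CLASSIC_LEVEL if set(rows) <= set(CLASSIC_LEVELS) and rows else STAGE_LEVEL
    start_time = None
    if "start_time" in meta:
        start_time = datetime.fromisoformat(meta["start_time"])
    return Hypnogram(
        stages=tuple(rows),
        device=meta.get("device", device),
        subject_id=meta.get("subject_id", ""),
        night_index=int(meta.get("night_index", 1)),
        start_time=start_time,
        epoch_seconds=int(meta.get("epoch_seconds", 30)),
        granularity=granularity,
    )


def write_epoch_csv(h: Hypnogram, path: Union[str, Path]) -> None:
    """Write a hypnogram in the epoch CSV dialect read by :func:`read_epoch_csv`."""
    path = Path(path)
    with path.open("w") as fh:
        if h.subject_id:
            fh.write(f"# subject_id={h.subject_id}\n")
        fh.write(f"# device={h.device}\n")
        fh.write(f"# night_index={h.night_index}\n")
        if h.start_time is not None:
            fh.write(f"# start_time={h.start_time.isoformat()}\n")
        fh.write(f"# epoch_seconds={h.epoch_seconds}\n")
        fh.write("epoch_index,stage\n")
        for i, stage in enumerate(h.stages, start=1):
            fh.write(f"{i},{stage}\n")


# ---------------------------------------------------------------------------
# Consumer-tracker sleep JSON dialect
# ---------------------------------------------------------------------------

_STAGE_LEVELS = {"wake": "W", "light": "L", "deep": "D", "rem": "R"}


def read_fitbit_sleep_json(path: Union[str, Path], record_index: int = 0) -> Hypnogram:
    """Read one night from a Fitbit-style sleep JSON document.

    The document holds ``{"sleep": [{"startTime": ..., "levels": {"data":
    [{"dateTime", "level", "seconds"}, ...]}}]}``.  Stage-level records
    (``wake/light/deep/rem``) are expanded to fixed 30 s epochs; classic-level
    documents (``awake/restless/asleep``, 60 s granularity) are returned
    flagged ``classic_level`` so downstream selection can exclude them.
    Records must tile the night contiguously; overlapping, retrograde or
    gapped ``dateTime`` sequences and durations not divisible by the epoch
    length are rejected.
    """
    path = Path(path)
    with path.open() as fh:
        doc = json.load(fh)
    try:
        rec = doc["sleep"][record_index]
        data = rec["levels"]["data"]
    except (KeyError, IndexError, TypeError):
        raise ValueError(f"{path}: not a recognisable sleep JSON document") from None
    if not data:
        raise ValueError(f"{path}: empty levels/data list")

    levels = {entry["level"] for entry in data}
    if levels <= set(_STAGE_LEVELS):
        epoch_seconds, granularity = 30, STAGE_LEVEL
    elif levels <= set(CLASSIC_LEVELS):
        epoch_seconds, granularity = 60, CLASSIC_LEVEL
    else:
        raise ValueError(f"{path}: mixed or unknown sleep levels {sorted(levels)}")

    stages = []
    prev_end: Optional[datetime] = None
    for entry in data:
        level, seconds = entry["level"], int(entry["seconds"])
        when = datetime.fromisoformat(entry["dateTime"])
        if prev_end is not None and when != prev_end:
            kind = "overlapping/retrograde" if when < prev_end else "gapped"
            raise ValueError(f"{path}: {kind} dateTime {entry['dateTime']}")
        if seconds <= 0 or seconds % epoch_seconds:
            raise ValueError(
                f"{path}: record duration {seconds}s is not a positive multiple of {epoch_seconds}s"
            )
        symbol = _STAGE_LEVELS.get(level, level)
        stages.extend([symbol] * (seconds // epoch_seconds))
        prev_end = when + timedelta(seconds=seconds)

    start = datetime.fromisoformat(rec["startTime"]) if "startTime" in rec else (
        datetime.fromisoformat(data[0]["dateTime"])
    )
    return Hypnogram(
        stages=tuple(stages),
        device="tracker",
        subject_id=str(rec.get("subject_id", "")),
        night_index=int(rec.get("night_index", 1)),
        start_time=start,
        epoch_seconds=epoch_seconds,
        granularity=granularity,
    )


_STAGE_SYMBOLS = {v: k for k, v in _STAGE_LEVELS.items()}


def write_fitbit_sleep_json(h: Hypnogram, path: Union[str, Path]) -> None:
    """Write a stage-level hypnogram in the sleep JSON dialect.

    Consecutive equal stages are merged into one ``{dateTime, level,
    seconds}`` record, matching how trackers export run-length data.
    Requires a start time so records can be timestamped.
    """
    if h.granularity != STAGE_LEVEL or not h.is_four_stage:
        raise ValueError("only 4-stage stage-level hypnograms can be written as sleep JSON")
    if h.start_time is None:
        raise ValueError("a start_time is required to timestamp sleep JSON records")
    data = []
    run_start = 0
    stages = list(h.stages) + [None]  # sentinel closes the last run
    for i in range(1, len(stages)):
        if stages[i] != stages[run_start]:
            when = h.start_time + timedelta(seconds=run_start * h.epoch_seconds)
            data.append({
                "dateTime": when.isoformat(),
                "level": _STAGE_SYMBOLS[stages[run_start]],
                "seconds": (i - run_start) * h.epoch_seconds,
            })
            run_start = i
    doc = {"sleep": [{
        "startTime": h.start_time.isoformat(),
        "subject_id": h.subject_id,
        "night_index": h.night_index,
        "levels": {"data": data},
    }]}
    with Path(path).open("w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Stage mapping and alignment
# ---------------------------------------------------------------------------

_FIVE_TO_FOUR = {"W": "W", "N1": "L", "N2": "L", "N3": "D", "R": "R",
                 "L": "L", "D": "D"}


def map_five_to_four(h: Hypnogram) -> Hypnogram:
    """Collapse clinical 5-stage scoring to the 4-stage consumer alphabet.

    N1 and N2 map to light sleep, N3 (slow-wave sleep) to deep sleep; W and R
    are unchanged.  Already-4-stage input is returned unchanged (idempotent).
    """
    if h.granularity != STAGE_LEVEL:
        raise ValueError("cannot stage-map a classic-level hypnogram")
    if h.is_four_stage:
        return h
    return replace(h, stages=tuple(_FIVE_TO_FOUR[s] for s in h.stages))


def align_pair(tracker: Hypnogram, reference: Hypnogram) -> AlignedPair:
    """Synchronise a tracker/reference pair onto a common epoch grid.

    The start is snapped to the later of the two start times (rounded to the
    nearest epoch boundary) and both records are trimmed to the overlapping
    interval.  Hypnograms without start times are assumed to start together.
    """
    for h, name in ((tracker, "tracker"), (reference, "reference")):
        if h.granularity != STAGE_LEVEL:
            raise ValueError(f"{name} hypnogram is classic-level; no stage information")
        if not h.is_four_stage:
            raise ValueError(f"{name} hypnogram must be 4-stage (map_five_to_four first)")
    if tracker.epoch_seconds != reference.epoch_seconds:
        raise ValueError("differing epoch_seconds between devices")

    es = tracker.epoch_seconds
    if tracker.start_time is not None and reference.start_time is not None:
        later = max(tracker.start_time, reference.start_time)
        skip_t = int(round((later - tracker.start_time).total_seconds() / es))
        skip_r = int(round((later - reference.start_time).total_seconds() / es))
    else:
        skip_t = skip_r = 0
    n = min(tracker.n_epochs - skip_t, reference.n_epochs - skip_r)
    if n <= 0:
        raise ValueError("hypnograms do not overlap in time")

    def _trim(h: Hypnogram, skip: int) -> Hypnogram:
        start = None
        if h.start_time is not None:
            start = h.start_time + timedelta(seconds=skip * es)
        return replace(h, stages=h.stages[skip:skip + n], start_time=start)

    subject = tracker.subject_id or reference.subject_id
    if tracker.subject_id and reference.subject_id and tracker.subject_id != reference.subject_id:
        raise ValueError(
            f"subject mismatch: tracker {tracker.subject_id!r} vs reference {reference.subject_id!r}"
        )
    return AlignedPair(subject_id=subject, tracker=_trim(tracker, skip_t),
                       reference=_trim(reference, skip_r))


# ---------------------------------------------------------------------------
# Analysis-night selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NightSelection:
    """Outcome of choosing the analysis night for one subject.

    ``night_index`` is ``None`` when the subject is excluded; ``reason``
    records why each candidate night was rejected.
    """

    subject_id: str
    night_index: Optional[int]
    tracker: Optional[Hypnogram] = None
    reference: Optional[Hypnogram] = None
    reason: str = ""

    @property
    def excluded(self) -> bool:
        return self.night_index is None


#: minimum usable night length: 240 epochs = 2 h of 30 s epochs
MIN_VALID_EPOCHS = 240


def select_analysis_night(
    nights: Mapping[int, Tuple[Optional[Hypnogram], Optional[Hypnogram]]],
    subject_id: str = "",
    min_epochs: int = MIN_VALID_EPOCHS,
) -> NightSelection:
    """Pick the analysis night: the second night, to avoid the first-night
    effect; the third as fallback; the first only when neither is valid.

    A night is valid when both hypnograms exist, the tracker export is
    stage-level, and both exceed ``min_epochs``.  Subjects with no valid
    night are returned as exclusion records, never raised.
    """
    problems = []

    def _valid(idx: int) -> bool:
        pair = nights.get(idx)
        if pair is None:
            problems.append(f"night {idx}: missing")
            return False
        trk, ref = pair
        if trk is None or ref is None:
            problems.append(f"night {idx}: missing {'tracker' if trk is None else 'reference'}")
            return False
        if trk.granularity != STAGE_LEVEL:
            problems.append(f"night {idx}: tracker data is classic-level")
            return False
        if trk.n_epochs < min_epochs or ref.n_epochs < min_epochs:
            problems.append(f"night {idx}: shorter than {min_epochs} epochs")
            return False
        return True

    for idx in (2, 3, 1):
        if _valid(idx):
            trk, ref = nights[idx]
            return NightSelection(subject_id=subject_id, night_index=idx,
                                  tracker=trk, reference=ref)
    reason = "; ".join(problems) if problems else "no nights supplied"
    return NightSelection(subject_id=subject_id, night_index=None, reason=reason)
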
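"""Summary motor features from 2-minute epoch score streams.

A wrist-worn logger emits one bradykinesia score (BKS) and one dyskinesia
score (DKS) every two minutes, together with a tremor flag and a worn flag.
This module reduces a multi-day stream to the recording-level summary used
for screening: daytime percentiles of BKS/DKS, percent time "off"
(bradykinetic, PTB), percent time dyskinetic (PTD), percent time immobile
(PTI), percent time with tremor (PTT) and the programmed levodopa dose
frequency.

Statistics other than PTI/PTT are computed over *valid* epochs: those
recorded between 09:00 and 18:00 while the device was worn, not flagged as
artifact, and not immobile (BKS <= 80).  PTI and PTT are computed over all
worn daytime epochs, immobile ones included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "EpochSeries",
    "DoseSchedule",
    "PKGSummary",
    "MODEL_FEATURES",
    "FEATURE_COLUMNS",
    "select_analysis_epochs",
    "summary_percentiles",
    "moving_majority",
    "percent_time_bradykinesia",
    "percent_time_dyskinesia",
    "percent_time_immobile",
    "percent_time_tremor",
    "doses_per_day",
    "extract_features",
    "PTBResult",
]

#: Epoch spacing of the logger.
EPOCH_SECONDS = 120
#: Daytime analysis window [09:00, 18:00), half-open.
DAY_START_S = 9 * 3600
DAY_END_S = 18 * 3600
#: BKS above this value marks an immobile epoch (excluded from most stats).
BKS_IMMOBILE = 80.0
#: Candidate "off" band for PTB.
OFF_BAND_LOW = 26.1
OFF_BAND_HIGH = 49.4
#: Epochs above this BKS still count as "off" candidates if tremor is present
#: (tremor corrupts the bradykinesia score upward).
TREMOR_RESCUE_BKS = 49.9
#: Recording-level gate for PTB: the 25th BKS percentile must exceed this ...
GATE_BKS25 = 18.5
#: ... and the 90th percentile must stay below this.
GATE_P90 = 80.0
#: DKS above this value is dyskinetic.
DKS_DYSKINETIC = 7.0
#: Moving-majority filter length: 15 two-minute epochs = 30 minutes.
DEFAULT_WINDOW_EPOCHS = 15

#: The eight classifier inputs, in the order they enter the model.
MODEL_FEATURES = (
    "doses_per_day",
    "dks75",
    "bks25",
    "bks75",
    "ptd",
    "pti",
    "ptt",
    "ptb",
)

#: All summary columns stored in a cohort table.
FEATURE_COLUMNS = (
    "median_bks",
    "bks25",
    "bks75",
    "median_dks",
    "dks75",
    "ptb",
    "ptd",
    "pti",
    "ptt",
    "doses_per_day",
)


def _as_bool(a, n: int, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=bool)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have length {n}")
    return arr


@dataclass
class EpochSeries:
    """One recording: per-2-minute-epoch scores for a single subject.

    Timestamps must be strictly increasing on a uniform 2-minute grid;
    gaps in wear are represented as epochs with ``worn=False``, not as
    missing rows.
    """

    subject_id: str
    timestamps: np.ndarray  # datetime64
    bks: np.ndarray
    dks: np.ndarray
    tremor: np.ndarray
    worn: np.ndarray
    artifact: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        n = self.timestamps.size
        if n == 0:
            raise ValueError("no epochs")
        self.bks = np.asarray(self.bks, dtype=float)
        self.dks = np.asarray(self.dks, dtype=float)
        if self.bks.shape != (n,) or self.dks.shape != (n,):
            raise ValueError("bks/dks must match timestamps in length")
        if not (np.isfinite(self.bks).all() and np.isfinite(self.dks).all()):
            raise ValueError("bks/dks must be finite")
        if (self.bks < 0).any() or (self.dks < 0).any():
            raise ValueError("bks/dks must be nonnegative")
        self.tremor = _as_bool(self.tremor, n, "tremor")
        self.worn = _as_bool(self.worn, n, "worn")
        if self.artifact is None:
            self.artifact = np.zeros(n, dtype=bool)
        else:
            self.artifact = _as_bool(self.artifact, n, "artifact")
        if n > 1:
            deltas = np.diff(self.timestamps).astype("timedelta64[s]").astype(int)
            if (deltas <= 0).any():
                raise ValueError("timestamps not increasing")
            if (deltas != EPOCH_SECONDS).any():
                raise ValueError("non-2-minute spacing between epochs")

    def __len__(self) -> int:
        return self.timestamps.size

    def time_of_day_seconds(self) -> np.ndarray:
        days = self.timestamps.astype("datetime64[D]")
        return (self.timestamps - days).astype("timedelta64[s]").astype(int)

    def daytime_mask(self) -> np.ndarray:
        tod = self.time_of_day_seconds()
        return (tod >= DAY_START_S) & (tod < DAY_END_S)


@dataclass
class DoseSchedule:
    """Medication reminders programmed into the logger for one recording."""

    reminder_times: np.ndarray
    acknowledged: np.ndarray
    recording_days: int

    def __post_init__(self) -> None:
        self.reminder_times = np.asarray(self.reminder_times, dtype="datetime64[s]")
        self.acknowledged = np.asarray(self.acknowledged, dtype=bool)
        if self.acknowledged.shape != self.reminder_times.shape:
            raise ValueError("acknowledged must parallel reminder_times")
        if self.reminder_times.size > 1 and (np.diff(self.reminder_times).astype(int) < 0).any():
            raise ValueError("reminder_times must be sorted")
        if self.recording_days < 1:
            raise ValueError("recording_days must be >= 1")


@dataclass
class PKGSummary:
    """Recording-level feature summary (the classifier's feature space)."""

    median_bks: float
    bks25: float
    bks75: float
    median_dks: float
    dks75: float
    ptb: float
    ptd: float
    pti: float
    ptt: float
    doses_per_day: float
    ptb_gate_failed: bool = field(default=False, compare=False)

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FEATURE_COLUMNS}


class Percentiles(NamedTuple):
    median_bks: float
    bks25: float
    bks75: float
    median_dks: float
    dks75: float


class PTBResult(NamedTuple):
    value: float
    gate_failed: bool


def select_analysis_epochs(series: EpochSeries) -> np.ndarray:
    """Boolean mask of epochs valid for summary statistics.

    Valid means: daytime ([09:00, 18:00)), worn, not artifact, and not
    immobile (BKS <= 80).
    """
    return (
        series.daytime_mask()
        & series.worn
        & ~series.artifact
        & (series.bks <= BKS_IMMOBILE)
    )


def _valid_or_raise(series: EpochSeries) -> np.ndarray:
    mask = select_analysis_epochs(series)
    if not mask.any():
        raise ValueError("no valid epochs")
    return mask


def summary_percentiles(series: EpochSeries) -> Percentiles:
    """Daytime BKS/DKS percentiles over valid epochs (linear interpolation)."""
    mask = _valid_or_raise(series)
    b = series.bks[mask]
    d = series.dks[mask]
    b25, b50, b75 = np.percentile(b, [25, 50, 75])
    d50, d75 = np.percentile(d, [50, 75])
    return Percentiles(float(b50), float(b25), float(b75), float(d50), float(d75))


def moving_majority(candidate: np.ndarray, valid: np.ndarray, window: int = DEFAULT_WINDOW_EPOCHS) -> np.ndarray:
    """Centered moving-majority filter on the epoch grid.

    An epoch is flagged iff it is valid and strictly more than half of the
    valid epochs inside the centered ``window``-epoch span are candidates.
    Invalid epochs are excluded from both counts (the window shrinks at the
    recording edges and across not-worn gaps rather than padding).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd number of epochs")
    candidate = np.asarray(candidate, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if candidate.shape != valid.shape:
        raise ValueError("candidate and valid must have the same length")
    n = valid.size
    half = window // 2
    lo = np.maximum(0, np.arange(n) - half)
    hi = np.minimum(n, np.arange(n) + half + 1)
    cum_valid = np.concatenate([[0], np.cumsum(valid)])
    cum_cand = np.concatenate([[0], np.cumsum(candidate & valid)])
    n_valid = cum_valid[hi] - cum_valid[lo]
    n_cand = cum_cand[hi] - cum_cand[lo]
    return valid & (n_cand > n_valid / 2.0)


def percent_time_bradykinesia(
    series: EpochSeries, window: int = DEFAULT_WINDOW_EPOCHS
) -> PTBResult:
    """Percent of valid daytime epochs classified "off" (PTB).

    Candidate epochs have BKS in [26.1, 49.4], or BKS > 49.9 with tremor
    present.  The recording must pass an eligibility gate (25th BKS
    percentile > 18.5 and 90th percentile < 80 over valid epochs); a gated
    recording has no measurable off time and returns 0 with the flag set.
    Candidates are smoothed by a 30-minute moving-majority filter before
    counting.
    """
    mask = _valid_or_raise(series)
    b = series.bks[mask]
    b25, b90 = np.percentile(b, [25, 90])
    if b25 <= GATE_BKS25 or b90 >= GATE_P90:
        return PTBResult(0.0, True)
    candidate = (
        (series.bks >= OFF_BAND_LOW) & (series.bks <= OFF_BAND_HIGH)
    ) | ((series.bks > TREMOR_RESCUE_BKS) & series.tremor)
    off = moving_majority(candidate, mask, window=window)
    return PTBResult(100.0 * off.sum() / mask.sum(), False)


def percent_time_dyskinesia(
    series: EpochSeries, window: int = DEFAULT_WINDOW_EPOCHS
) -> float:
    """Percent of valid daytime epochs classified dyskinetic (DKS > 7)."""
    mask = _valid_or_raise(series)
    candidate = series.dks > DKS_DYSKINETIC
    dysk = moving_majority(candidate, mask, window=window)
    return float(100.0 * dysk.sum() / mask.sum())


def _worn_daytime_or_raise(series: EpochSeries) -> np.ndarray:
    mask = series.daytime_mask() & series.worn
    if not mask.any():
        raise ValueError("no worn daytime epochs")
    return mask


def percent_time_immobile(series: EpochSeries) -> float:
    """Percent of worn daytime epochs with BKS > 80 (daytime-sleep proxy).

    Unlike the other statistics, immobile epochs stay in the denominator.
    """
    mask = _worn_daytime_or_raise(series)
    return float(100.0 * (series.bks[mask] > BKS_IMMOBILE).sum() / mask.sum())


def percent_time_tremor(series: EpochSeries) -> float:
    """Percent of worn daytime epochs that contained tremor."""
    mask = _worn_daytime_or_raise(series)
    return float(100.0 * series.tremor[mask].sum() / mask.sum())


def doses_per_day(schedule: DoseSchedule) -> float:
    """Programmed reminders per recording day (acknowledgements ignored)."""
    return float(schedule.reminder_times.size) / schedule.recording_days


def extract_features(
    series: EpochSeries,
    schedule: DoseSchedule,
    window: int = DEFAULT_WINDOW_EPOCHS,
) -> PKGSummary:
    """Full 10-feature summary of one recording."""
    pct = summary_percentiles(series)
    ptb = percent_time_bradykinesia(series, window=window)
    return PKGSummary(
        median_bks=pct.median_bks,
        bks25=pct.bks25,
        bks75=pct.bks75,
        median_dks=pct.median_dks,
        dks75=pct.dks75,
        ptb=ptb.value,
        ptd=percent_time_dyskinesia(series, window=window),
        pti=percent_time_immobile(series),
        ptt=percent_time_tremor(series),
        doses_per_day=doses_per_day(schedule),
        ptb_gate_failed=ptb.gate_failed,
    )
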
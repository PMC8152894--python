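"""Domain data model for fixed-interval timing sessions.

A session is one animal-day of behavior with simultaneously recorded single
units.  Trials are cued by a house light; the first lever press after the
interval (3 s or 12 s) elapses is rewarded.  All analysis-facing coordinates
are seconds relative to cue onset; the session clock appears only in raw
storage (spike timestamps and cue onsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

#: Interval durations (seconds) keyed by interval-type label.
INTERVAL_DURATIONS = {"FI3": 3.0, "FI12": 12.0}

#: Allowed intertrial intervals (seconds), drawn uniformly at random.
ITI_CHOICES = (6.0, 8.0, 10.0, 12.0)

AREAS = ("MFC", "DMS")

UNIT_CLASSES = (
    "putative_MSN",
    "putative_interneuron",
    "putative_pyramidal",
    "excluded",
    "unclassified",
)

TUNING_CLASSES = (
    "ramp_up",
    "ramp_down",
    "interval_modulated",
    "response_locked",
    "untuned",
)


@dataclass
class WaveformMetrics:
    """Waveform shape features used to separate striatal cell types.

    peak_to_trough_ratio : |max amplitude| / |min amplitude| (dimensionless)
    half_peak_width      : full width at half of the peak amplitude (ms)
    """

    peak_to_trough_ratio: float
    half_peak_width: float

    def validate(self) -> None:
        if not (np.isfinite(self.peak_to_trough_ratio) and self.peak_to_trough_ratio > 0):
            raise ValidationError("peak_to_trough_ratio must be finite and positive")
        if not (np.isfinite(self.half_peak_width) and self.half_peak_width > 0):
            raise ValidationError("half_peak_width must be finite and positive")


@dataclass
class TrialRecord:
    """One fixed-interval trial.

    ``press_times`` and ``reward_time`` are seconds relative to cue onset;
    ``cue_onset`` is on the session clock.  The reward is the first press
    after the interval elapses, so ``reward_time >= interval_duration``.
    """

    trial_id: int
    interval_type: str
    cue_onset: float
    interval_duration: float
    press_times: np.ndarray
    reward_time: float | None
    iti_before: float

    def __post_init__(self) -> None:
        self.press_times = np.asarray(self.press_times, dtype=float)

    def validate(self) -> None:
        if self.interval_type not in INTERVAL_DURATIONS:
            raise ValidationError(
                f"trial {self.trial_id}: unknown interval_type {self.interval_type!r}"
            )
        if self.interval_duration != INTERVAL_DURATIONS[self.interval_type]:
            raise ValidationError(
                f"trial {self.trial_id}: interval_duration {self.interval_duration} "
                f"does not match type {self.interval_type}"
            )
        if self.press_times.size and np.any(np.diff(self.press_times) <= 0):
            raise ValidationError(f"trial {self.trial_id}: press_times not strictly ascending")
        if self.reward_time is not None and self.reward_time < self.interval_duration:
            raise ValidationError(
                f"trial {self.trial_id}: reward_time {self.reward_time} precedes interval end"
            )

    @property
    def in_interval_presses(self) -> np.ndarray:
        """Presses within [0, interval_duration] (the anticipatory responses)."""
        T = self.interval_duration
        return self.press_times[(self.press_times >= 0.0) & (self.press_times <= T)]

    @property
    def span(self) -> float:
        """Trial span in seconds relative to cue: ends at the rewarded press."""
        if self.reward_time is not None:
            return float(self.reward_time)
        if self.press_times.size:
            return float(max(self.press_times[-1], self.interval_duration))
        return self.interval_duration


@dataclass
class UnitRecord:
    """A sorted single unit: spike timestamps plus waveform information."""

    unit_id: str
    area: str
    spike_times: np.ndarray
    waveform: np.ndarray | None = None
    waveform_dt: float | None = None  # sampling interval of the waveform, seconds
    metrics: WaveformMetrics | None = None
    unit_class: str = "unclassified"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.waveform is not None:
            self.waveform = np.asarray(self.waveform, dtype=float)

    def validate(self) -> None:
        if self.area not in AREAS:
            raise ValidationError(f"unit {self.unit_id}: unknown area {self.area!r}")
        if self.unit_class not in UNIT_CLASSES:
            raise ValidationError(f"unit {self.unit_id}: unknown class {self.unit_class!r}")
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not ascending")
        if self.metrics is not None:
            self.metrics.validate()

    def mean_rate(self, span: float) -> float:
        """Mean firing rate (Hz) over a recording span in seconds."""
        if span <= 0:
            raise ValidationError("session span must be positive")
        return self.spike_times.size / span


@dataclass
class SessionRecord:
    """One animal-day: all units and all trials."""

    animal_id: str
    day: int
    units: list[UnitRecord] = field(default_factory=list)
    trials: list[TrialRecord] = field(default_factory=list)

    def validate(self) -> None:
        if self.day not in (0, 1, 2, 3):
            raise ValidationError(f"session {self.animal_id}: day must be 0-3, got {self.day}")
        types = {t.interval_type for t in self.trials}
        if self.day == 0 and "FI3" in types:
            raise ValidationError("day-0 sessions contain only FI12 trials")
        for u in self.units:
            u.validate()
        prev_end = -np.inf
        for t in sorted(self.trials, key=lambda t: t.cue_onset):
            t.validate()
            if t.cue_onset < prev_end - 1e-9:
                raise ValidationError(
                    f"trial {t.trial_id}: cue onset overlaps the preceding trial"
                )
            prev_end = t.cue_onset + t.span + t.iti_before

    def trials_of(self, interval_type: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.interval_type == interval_type]

    @property
    def span(self) -> float:
        """Session span in seconds (end of the last trial's ITI)."""
        if not self.trials:
            return 0.0
        last = max(self.trials, key=lambda t: t.cue_onset)
        return last.cue_onset + last.span + last.iti_before


@dataclass
class PethMatrix:
    """Units x time-bins matrix of firing rates with bin metadata.

    ``normalization`` is ``"rate_hz"`` for raw kernel-density rates or
    ``"zscore"`` after per-row standardization.
    """

    unit_ids: list[str]
    bin_centers: np.ndarray
    values: np.ndarray
    normalization: str = "rate_hz"
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.unit_ids), self.bin_centers.size):
            raise ValidationError(
                f"PethMatrix shape {self.values.shape} inconsistent with "
                f"{len(self.unit_ids)} units x {self.bin_centers.size} bins"
            )


def trial_relative_spikes(
    unit: UnitRecord, trial: TrialRecord, window: tuple[float, float]
) -> np.ndarray:
    """Spike times shifted to cue-relative coordinates, filtered to ``window``.

    ``window`` is (start, end) in seconds relative to cue onset; the result is
    ascending and may be empty.  Negative window starts retrieve pre-cue
    spikes (used for decoder padding).
    """
    start, end = window
    if start >= end:
        raise ValidationError(f"window start {start} must precede end {end}")
    rel = unit.spike_times - trial.cue_onset
    lo = np.searchsorted(rel, start, side="left")
    hi = np.searchsorted(rel, end, side="right")
    return rel[lo:hi]
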
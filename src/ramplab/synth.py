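"""Synthetic session generator with ground truth.

Emulates the statistical structure the downstream analyses assume: seven
animals run daily fixed-interval sessions (FI12 only on Day 0, randomly
intermixed FI12/FI3 on Days 1-3).  Behavior follows a two-state model — a
low lever-press rate before a normally distributed start time, a high rate
after it, with the first press after the interval rewarded — whose constant
coefficient of variation across interval types gives approximately scalar
timing variability.  Units are inhomogeneous Poisson processes (exact
thinning, 2 ms dead time): ramping units add a signed linear trend over the
interval (steeper on FI3 by ``slope_scale_fi3``), interval-modulated units a
rate offset on one interval type, response-locked units a Gaussian bump
around each press, untuned units are homogeneous.  Waveforms come from a
biphasic difference-of-Gaussians template with class-separated width and
peak-to-trough ratio.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import DegenerateUnitError
from .model import (
    INTERVAL_DURATIONS,
    ITI_CHOICES,
    SessionRecord,
    TrialRecord,
    UnitRecord,
)

REFRACTORY_DEAD_TIME = 0.002  # seconds; enforced absolute refractory period

#: Waveform template parameters per putative class:
#: (half-peak width mean/sd in ms, peak-to-trough ratio mean/sd).
WAVEFORM_CLASS_PARAMS = {
    "putative_MSN": {"width": 0.30, "width_sd": 0.02, "ratio": 2.0, "ratio_sd": 0.15},
    "putative_interneuron": {"width": 0.12, "width_sd": 0.012, "ratio": 0.9, "ratio_sd": 0.08},
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Rates are Hz, times seconds.  ``ramp_slope_fi12`` is the unsigned ramp
    slope on FI12 trials; FI3 slopes are ``slope_scale_fi3`` times steeper
    (scalar rescaling of the drift toward the shorter interval).  The
    behavioral start time on a trial of duration T is drawn from
    Normal(mean_response_fraction*T, (response_cv*mean_response_fraction*T)^2)
    truncated to (0, T), so the start-time CV is interval-independent by
    construction.
    """

    n_animals: int = 7
    n_units_per_area: int = 8
    days: tuple[int, ...] = (0, 1, 2, 3)
    n_trials_per_interval: int = 40
    ramping_fraction: float = 1.0 / 3.0
    interval_mod_fraction: float = 0.25
    response_locked_fraction: float = 0.125
    baseline_rate: float = 5.0
    ramp_slope_fi12: float = 0.5
    slope_scale_fi3: float = 4.0
    interval_mod_rate: float = 3.0
    response_bump_rate: float = 8.0
    response_bump_sigma: float = 0.3
    response_cv: float = 0.15
    mean_response_fraction: float = 0.8
    press_rate_low: float = 0.05
    press_rate_high: float = 1.0
    interneuron_fraction: float = 0.25
    interval_mod_fraction_by_area: dict | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("ramping_fraction", "interval_mod_fraction", "response_locked_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("press_rate_low", "press_rate_high", "response_cv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be nonnegative")
        if self.slope_scale_fi3 <= 1:
            raise ValueError("slope_scale_fi3 must exceed 1 (steeper ramps on FI3)")
        if not 0.0 < self.mean_response_fraction < 1.0:
            raise ValueError("mean_response_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["days"] = list(self.days)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "days" in d:
            d["days"] = tuple(int(x) for x in d["days"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class UnitTruth:
    """Ground truth for one generated unit."""

    unit_id: str
    area: str
    tuning_class: str
    waveform_class: str
    #: signed true ramp slope (Hz/s) per interval type; 0 for non-ramping units
    slope: dict = field(default_factory=dict)
    #: true mean in-interval rate (Hz) per interval type, before rectification
    mean_rate: dict = field(default_factory=dict)
    modulated_interval: str | None = None


@dataclass
class GroundTruth:
    """Per-unit tuning truth and per-trial behavioral start times."""

    units: dict = field(default_factory=dict)  # unit_id -> UnitTruth
    start_times: dict = field(default_factory=dict)  # trial_id -> seconds


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic named substream: stage/animal/day keys do not collide."""
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()) & 0x7FFFFFFF)
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    # pathological parameterization; fall back to the clipped mean
    return float(np.clip(mean, lo + 1e-6, hi - 1e-6))


def _simulate_presses(
    rng: np.random.Generator, start: float, T: float, rate_low: float, rate_high: float
) -> np.ndarray:
    """Two-state Poisson press train; ends at the first press after T (reward)."""
    n_pre = rng.poisson(rate_low * start)
    pre = np.sort(rng.uniform(0.0, start, size=n_pre))
    post = []
    t = start
    while True:
        t += rng.exponential(1.0 / rate_high)
        post.append(t)
        if t > T:
            break
    presses = np.concatenate([pre, np.asarray(post)])
    # strict ascending (ties have probability zero but guard anyway)
    return np.unique(presses)


def generate_trials(
    config: GeneratorConfig, day: int, rng: np.random.Generator
) -> tuple[list[TrialRecord], dict]:
    """Generate one session's trial list plus true behavioral start times.

    Day 0 is FI12-only; Days 1-3 randomly interleave ``n_trials_per_interval``
    trials of each type.  ITIs are drawn uniformly from {6, 8, 10, 12} s.
    """
    if day not in config.days:
        raise ValueError(f"day {day} not in configured days {config.days}")
    n = config.n_trials_per_interval
    if day == 0:
        types = ["FI12"] * n
    else:
        types = ["FI12"] * n + ["FI3"] * n
        types = [types[i] for i in rng.permutation(len(types))]

    trials: list[TrialRecord] = []
    start_times: dict = {}
    clock = 10.0
    for trial_id, itype in enumerate(types):
        T = INTERVAL_DURATIONS[itype]
        mu = config.mean_response_fraction * T
        sd = config.response_cv * mu
        s = _truncated_normal(rng, mu, sd, 0.0, T)
        presses = _simulate_presses(rng, s, T, config.press_rate_low, config.press_rate_high)
        reward = float(presses[presses > T][0])
        iti = float(ITI_CHOICES[rng.integers(len(ITI_CHOICES))])
        trials.append(
            TrialRecord(
                trial_id=trial_id,
                interval_type=itype,
                cue_onset=clock,
                interval_duration=T,
                press_times=presses,
                reward_time=reward,
                iti_before=iti,
            )
        )
        start_times[trial_id] = s
        clock = (clock + reward) + iti
    return trials, start_times


# ---------------------------------------------------------------------------
# Spiking
# ---------------------------------------------------------------------------

@dataclass
class IntensitySpec:
    """Parameters of a unit's inhomogeneous Poisson intensity (session clock)."""

    baseline: float
    slopes: dict  # interval type -> signed Hz/s (empty for non-ramping)
    mod_rate: float = 0.0
    modulated_interval: str | None = None
    bump_amp: float = 0.0
    bump_sigma: float = 0.3


def evaluate_intensity(times: np.ndarray, trials: list[TrialRecord], spec: IntensitySpec) -> np.ndarray:
    """lambda(t) = max(0, baseline + class-specific term) at session-clock times."""
    times = np.asarray(times, dtype=float)
    lam = np.full(times.shape, spec.baseline, dtype=float)
    cues = np.array([t.cue_onset for t in trials])
    order = np.argsort(cues)
    for idx in order:
        tr = trials[idx]
        T = tr.interval_duration
        rel = times - tr.cue_onset
        in_int = (rel >= 0.0) & (rel <= T)
        if spec.slopes:
            lam[in_int] += spec.slopes.get(tr.interval_type, 0.0) * rel[in_int]
        if spec.modulated_interval == tr.interval_type:
            lam[in_int] += spec.mod_rate
        if spec.bump_amp > 0.0:
            sig = spec.bump_sigma
            for p in tr.press_times:
                d = rel - p
                near = np.abs(d) < 4.0 * sig
                if np.any(near):
                    lam[near] += spec.bump_amp * np.exp(-0.5 * (d[near] / sig) ** 2)
    return np.maximum(lam, 0.0)


def _intensity_bound(trials: list[TrialRecord], spec: IntensitySpec) -> float:
    bound = spec.baseline
    if spec.slopes:
        bound += max(
            (abs(s) * INTERVAL_DURATIONS[k] for k, s in spec.slopes.items()), default=0.0
        )
    bound += spec.mod_rate
    # up to a few press bumps may overlap; lambda is clipped to this bound
    bound += 3.0 * spec.bump_amp
    return bound


def simulate_spikes(
    trials: list[TrialRecord], spec: IntensitySpec, span: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact thinning over [0, span] followed by a 2 ms dead-time pass."""
    lam_max = _intensity_bound(trials, spec)
    if lam_max <= 0.0:
        raise DegenerateUnitError("intensity is zero everywhere")
    n = rng.poisson(lam_max * span)
    cand = np.sort(rng.uniform(0.0, span, size=n))
    lam = np.minimum(evaluate_intensity(cand, trials, spec), lam_max)
    keep = rng.uniform(0.0, lam_max, size=n) < lam
    spikes = cand[keep]
    if spikes.size == 0:
        return spikes
    # absolute refractory period: drop spikes within 2 ms of the previous kept spike
    kept = [spikes[0]]
    for s in spikes[1:]:
        if s - kept[-1] >= REFRACTORY_DEAD_TIME:
            kept.append(s)
    return np.asarray(kept)


def _make_intensity_spec(
    config: GeneratorConfig,
    tuning_class: str,
    direction: int = 1,
    modulated_interval: str | None = None,
) -> IntensitySpec:
    spec = IntensitySpec(baseline=config.baseline_rate, slopes={})
    if tuning_class in ("ramp_up", "ramp_down"):
        sgn = 1.0 if tuning_class == "ramp_up" else -1.0
        spec.slopes = {
            "FI12": sgn * direction * config.ramp_slope_fi12,
            "FI3": sgn * direction * config.ramp_slope_fi12 * config.slope_scale_fi3,
        }
    elif tuning_class == "interval_modulated":
        spec.mod_rate = config.interval_mod_rate
        spec.modulated_interval = modulated_interval or "FI3"
    elif tuning_class == "response_locked":
        spec.bump_amp = config.response_bump_rate
        spec.bump_sigma = config.response_bump_sigma
    elif tuning_class != "untuned":
        raise ValueError(f"unknown tuning class {tuning_class!r}")
    return spec


def waveform_template(
    width_ms: float, ratio: float, dt_ms: float = 0.025, total_ms: float = 2.5
) -> np.ndarray:
    """Biphasic difference-of-Gaussians waveform.

    The positive peak is a Gaussian whose FWHM equals ``width_ms``; the
    trough follows far enough behind that the analytic half-peak width of
    the template is ``width_ms`` to well under one sample.  Amplitudes are
    scaled so peak/|trough| equals ``ratio``.
    """
    t = np.arange(0.0, total_ms, dt_ms)
    sigma1 = width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma2 = 2.0 * sigma1
    t1 = 0.4
    t2 = t1 + 2.5 * (sigma1 + sigma2)
    return np.exp(-0.5 * ((t - t1) / sigma1) ** 2) - (1.0 / ratio) * np.exp(
        -0.5 * ((t - t2) / sigma2) ** 2
    )


def generate_waveform(
    unit_class: str, rng: np.random.Generator, dt_ms: float = 0.025
) -> tuple[np.ndarray, float]:
    """Draw a class-typical waveform; returns (samples, sampling interval in s).

    Additive noise SD is 2% of the peak amplitude.
    """
    if unit_class not in WAVEFORM_CLASS_PARAMS:
        raise ValueError(f"unit_class must be one of {sorted(WAVEFORM_CLASS_PARAMS)}")
    p = WAVEFORM_CLASS_PARAMS[unit_class]
    width = max(rng.normal(p["width"], p["width_sd"]), 0.02)
    ratio = max(rng.normal(p["ratio"], p["ratio_sd"]), 0.1)
    wf = waveform_template(width, ratio, dt_ms=dt_ms)
    wf = wf + rng.normal(0.0, 0.02 * wf.max(), size=wf.size)
    return wf, dt_ms * 1e-3


def generate_unit(
    config: GeneratorConfig,
    tuning_class: str,
    area: str,
    trials: list[TrialRecord],
    rng: np.random.Generator,
    unit_id: str = "u0",
    direction: int = 1,
    modulated_interval: str | None = None,
    waveform_class: str = "putative_MSN",
    span: float | None = None,
) -> tuple[UnitRecord, UnitTruth]:
    """Generate one unit's spikes (thinning) and waveform, with ground truth."""
    spec = _make_intensity_spec(config, tuning_class, direction, modulated_interval)
    if span is None:
        last = max(trials, key=lambda t: t.cue_onset)
        span = last.cue_onset + last.span + last.iti_before
    spikes = simulate_spikes(trials, spec, span, rng)
    wf, dt = generate_waveform(waveform_class, rng)
    unit = UnitRecord(
        unit_id=unit_id, area=area, spike_times=spikes, waveform=wf, waveform_dt=dt
    )
    mean_rate = {}
    for itype, T in INTERVAL_DURATIONS.items():
        mu = config.baseline_rate
        if spec.slopes:
            mu += spec.slopes.get(itype, 0.0) * T / 2.0
        if spec.modulated_interval == itype:
            mu += spec.mod_rate
        mean_rate[itype] = mu
    truth = UnitTruth(
        unit_id=unit_id,
        area=area,
        tuning_class=tuning_class,
        waveform_class=waveform_class,
        slope=dict(spec.slopes),
        mean_rate=mean_rate,
        modulated_interval=spec.modulated_interval,
    )
    return unit, truth


def _allocate_classes(config: GeneratorConfig, area: str) -> list[str]:
    """Deterministic tuning-class allocation for one area's units."""
    n = config.n_units_per_area
    mod_frac = config.interval_mod_fraction
    if config.interval_mod_fraction_by_area and area in config.interval_mod_fraction_by_area:
        mod_frac = config.interval_mod_fraction_by_area[area]
    n_ramp = round(config.ramping_fraction * n)
    n_mod = round(mod_frac * n)
    n_resp = round(config.response_locked_fraction * n)
    if n_ramp + n_mod + n_resp > n:
        raise ValueError("tuning-class fractions exceed the unit budget")
    classes = (
        ["ramp_up", "ramp_down"] * (n_ramp // 2 + 1)
    )[:n_ramp] + ["interval_modulated"] * n_mod + ["response_locked"] * n_resp
    classes += ["untuned"] * (n - len(classes))
    return classes


def generate_session(
    config: GeneratorConfig, animal_id: str, day: int, seed: int | None = None
) -> tuple[SessionRecord, GroundTruth]:
    """Compose trials and units for one animal-day, with full ground truth."""
    config.validate()
    base_seed = config.seed if seed is None else seed
    rng_trials = substream(base_seed, "trials", animal_id, day)
    trials, start_times = generate_trials(config, day, rng_trials)
    last = max(trials, key=lambda t: t.cue_onset)
    span = last.cue_onset + last.span + last.iti_before

    truth = GroundTruth(start_times=start_times)
    units: list[UnitRecord] = []
    for area in ("MFC", "DMS"):
        classes = _allocate_classes(config, area)
        rng_area = substream(base_seed, "units", animal_id, day, area)
        n_in = (
            round(config.interneuron_fraction * len(classes)) if area == "DMS" else 0
        )
        for i, tuning in enumerate(classes):
            uid = f"{animal_id}_d{day}_{area}_{i:02d}"
            wf_class = "putative_interneuron" if i < n_in else "putative_MSN"
            modulated = ("FI3", "FI12")[i % 2] if tuning == "interval_modulated" else None
            unit, ut = generate_unit(
                config,
                tuning,
                area,
                trials,
                rng_area,
                unit_id=uid,
                modulated_interval=modulated,
                waveform_class=wf_class,
                span=span,
            )
            units.append(unit)
            truth.units[uid] = ut

    session = SessionRecord(animal_id=animal_id, day=day, units=units, trials=trials)
    session.validate()
    return session, truth
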
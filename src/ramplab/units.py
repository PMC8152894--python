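"""Unit inclusion screening and waveform-based cell-type classification.

Units are analyzed only if they fire above 0.1 Hz and show a consistent
refractory period of at least 2 ms (at most 1% of interspike intervals may
violate it).  In the dorsomedial striatum, putative medium spiny neurons
(MSNs) are separated from interneurons by waveform shape: MSNs have broad
spikes (large half-peak width) with a high peak-to-trough ratio.  Medial
frontal cortex units are labeled putative pyramidal neurons; cortical
interneurons are assumed removed upstream at spike sorting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import MetricError, ValidationError
from .model import UnitRecord, WaveformMetrics


@dataclass
class ClassifierThresholds:
    """Screening and classification boundaries.

    min_rate       : inclusion rate threshold, Hz (unit must fire above it)
    min_refractory : refractory period, ms
    width_boundary : half-peak width boundary for MSN vs interneuron, ms
    ratio_boundary : peak-to-trough ratio boundary (dimensionless)

    The waveform feature pair is standard; the numeric boundaries are
    package defaults chosen to bisect the synthetic class templates and are
    fully configurable.
    """

    min_rate: float = 0.1
    min_refractory: float = 2.0
    width_boundary: float = 0.20
    ratio_boundary: float = 1.2
    max_refractory_violation_fraction: float = 0.01

    def validate(self) -> None:
        for name in ("min_rate", "min_refractory", "width_boundary", "ratio_boundary"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class ScreenResult:
    included: bool
    reason: str  # "ok", "rate", or "refractory"
    mean_rate: float
    refractory_violation_fraction: float


def compute_waveform_metrics(waveform: np.ndarray, sampling_interval: float) -> WaveformMetrics:
    """Peak-to-trough ratio and half-peak width of a biphasic waveform.

    ``sampling_interval`` is in seconds; the width is returned in ms.  The
    half-peak width is the time between the two crossings of half the peak
    amplitude on either side of the global peak, with linear interpolation
    between samples.
    """
    wf = np.asarray(waveform, dtype=float)
    if wf.size < 8:
        raise MetricError("waveform must have at least 8 samples")
    peak = wf.max()
    trough = wf.min()
    if peak <= 0 or trough >= 0:
        raise MetricError("waveform is monophasic: needs a positive peak and a negative trough")
    ratio = abs(peak) / abs(trough)

    i_peak = int(np.argmax(wf))
    half = peak / 2.0
    # left crossing
    left = None
    for i in range(i_peak, 0, -1):
        if wf[i - 1] < half <= wf[i]:
            frac = (half - wf[i - 1]) / (wf[i] - wf[i - 1])
            left = (i - 1) + frac
            break
    right = None
    for i in range(i_peak, wf.size - 1):
        if wf[i] >= half > wf[i + 1]:
            frac = (wf[i] - half) / (wf[i] - wf[i + 1])
            right = i + frac
            break
    if left is None or right is None:
        raise MetricError("peak does not fall to half amplitude within the waveform")
    width_ms = (right - left) * sampling_interval * 1e3
    return WaveformMetrics(peak_to_trough_ratio=ratio, half_peak_width=width_ms)


def screen_unit(
    unit: UnitRecord, session_span: float, thresholds: ClassifierThresholds | None = None
) -> ScreenResult:
    """Inclusion screen: mean rate above threshold, clean refractory period."""
    thr = thresholds or ClassifierThresholds()
    thr.validate()
    rate = unit.mean_rate(session_span)
    isis = np.diff(unit.spike_times)
    viol = (
        float(np.mean(isis < thr.min_refractory * 1e-3)) if isis.size else 0.0
    )
    if rate <= thr.min_rate:
        return ScreenResult(False, "rate", rate, viol)
    if viol > thr.max_refractory_violation_fraction:
        return ScreenResult(False, "refractory", rate, viol)
    return ScreenResult(True, "ok", rate, viol)


def classify_unit(
    metrics: WaveformMetrics, area: str, thresholds: ClassifierThresholds | None = None
) -> str:
    """Waveform classification: DMS MSN vs interneuron; MFC pyramidal."""
    thr = thresholds or ClassifierThresholds()
    if area == "MFC":
        return "putative_pyramidal"
    metrics.validate()
    if (
        metrics.half_peak_width >= thr.width_boundary
        and metrics.peak_to_trough_ratio >= thr.ratio_boundary
    ):
        return "putative_MSN"
    return "putative_interneuron"


def classify_session_units(
    units: list[UnitRecord], session_span: float, thresholds: ClassifierThresholds | None = None
) -> list[dict]:
    """Screen and classify every unit; annotates records in place.

    Returns one row per unit (unit_id, area, included, reason, mean_rate,
    metrics, assigned class).  Excluded units are labeled ``excluded``.
    """
    thr = thresholds or ClassifierThresholds()
    rows = []
    for u in units:
        screen = screen_unit(u, session_span, thr)
        metrics = u.metrics
        if metrics is None and u.waveform is not None and u.waveform_dt is not None:
            metrics = compute_waveform_metrics(u.waveform, u.waveform_dt)
            u.metrics = metrics
        if not screen.included:
            u.unit_class = "excluded"
        elif metrics is not None:
            u.unit_class = classify_unit(metrics, u.area, thr)
        rows.append(
            {
                "unit_id": u.unit_id,
                "area": u.area,
                "included": screen.included,
                "reason": screen.reason,
                "mean_rate": screen.mean_rate,
                "refractory_violation_fraction": screen.refractory_violation_fraction,
                "peak_to_trough_ratio": None if metrics is None else metrics.peak_to_trough_ratio,
                "half_peak_width": None if metrics is None else metrics.half_peak_width,
                "unit_class": u.unit_class,
            }
        )
    return rows
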
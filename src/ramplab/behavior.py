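"""Behavioral analyses: response times, single-trial start times, start-time CV.

The single-trial start time adapts the classic change-point analysis of
peak-interval timing to fixed-interval trials, where responding ends at
reward: only the low-to-high transition (the "start") is estimated.  For a
candidate change point s among the press times, the index

    index(s) = s * (r_overall - r_pre(s)) + (T - s) * (r_post(s) - r_overall)

contrasts the press rate before and after s against the whole-trial rate;
the press maximizing it is the start, with ties broken toward the earliest
press.  The start-time coefficient of variation (CV = SD / mean) across
trials is the scalar-timing summary: approximately constant across interval
durations when timing variability scales with the interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError
from .model import TrialRecord

#: Relative tolerance used to detect ties in the change-point index.
_TIE_RTOL = 1e-9


@dataclass
class StartTimeResult:
    trial_id: int
    start_time: float
    index_value: float
    n_presses: int


def response_times(trials: list[TrialRecord], scope: str = "all_presses") -> pd.DataFrame:
    """Long table of response times (seconds from cue), in-interval presses only.

    scope="all_presses": one row per press; scope="first_press": one row per
    trial with at least one in-interval press.
    """
    if not trials:
        raise ValueError("trials must be non-empty")
    if scope not in ("all_presses", "first_press"):
        raise ValueError(f"unknown scope {scope!r}")
    rows = []
    for t in trials:
        presses = t.in_interval_presses
        if presses.size == 0:
            continue
        selected = presses if scope == "all_presses" else presses[:1]
        for p in selected:
            rows.append(
                {"trial_id": t.trial_id, "interval_type": t.interval_type, "response_time": p}
            )
    return pd.DataFrame(rows, columns=["trial_id", "interval_type", "response_time"])


def start_time_index(press_times: np.ndarray, T: float, r_overall: float | None = None) -> np.ndarray:
    """Change-point index evaluated at every candidate press.

    A press at the candidate time counts toward the post-change rate (the
    transition begins with that press).  ``r_overall`` defaults to the
    trial's own press rate n/T but may be supplied from a wider context.
    """
    p = np.asarray(press_times, dtype=float)
    n = p.size
    if r_overall is None:
        r_overall = n / T
    idx = np.empty(n)
    for i, s in enumerate(p):
        r_pre = i / s if s > 0 else 0.0
        r_post = (n - i) / (T - s) if T > s else np.inf
        idx[i] = s * (r_overall - r_pre) + (T - s) * (r_post - r_overall)
    return idx


def start_time_single_trial(
    press_times: np.ndarray,
    T: float,
    r_overall: float | None = None,
    trial_id: int = -1,
    min_presses: int = 2,
) -> StartTimeResult | None:
    """Single-trial start time by exhaustive change-point search.

    Returns ``None`` (undefined marker) for trials with fewer than
    ``min_presses`` presses; such trials are excluded from CV summaries.
    """
    p = np.asarray(press_times, dtype=float)
    p = p[(p >= 0.0) & (p <= T)]
    if p.size < min_presses:
        return None
    idx = start_time_index(p, T, r_overall)
    best = idx.max()
    tol = _TIE_RTOL * max(1.0, abs(best))
    winner = int(np.flatnonzero(idx >= best - tol)[0])  # earliest tie
    return StartTimeResult(
        trial_id=trial_id,
        start_time=float(p[winner]),
        index_value=float(idx[winner]),
        n_presses=int(p.size),
    )


def start_times_table(trials: list[TrialRecord], min_presses: int = 2) -> pd.DataFrame:
    """Per-trial start times for a session (undefined trials omitted)."""
    rows = []
    for t in trials:
        res = start_time_single_trial(
            t.in_interval_presses, t.interval_duration, trial_id=t.trial_id, min_presses=min_presses
        )
        if res is None:
            continue
        rows.append(
            {
                "trial_id": t.trial_id,
                "interval_type": t.interval_type,
                "start_time": res.start_time,
                "index_value": res.index_value,
                "n_presses": res.n_presses,
            }
        )
    return pd.DataFrame(
        rows, columns=["trial_id", "interval_type", "start_time", "index_value", "n_presses"]
    )


def cv_of_start_times(start_times) -> tuple[float, float, float]:
    """(mean, SD, CV) of start times; SD uses the n-1 denominator."""
    x = np.asarray(start_times, dtype=float)
    if x.size < 2:
        raise DegenerateDataError("CV requires at least 2 defined start times")
    mean = float(x.mean())
    if mean == 0.0:
        raise DegenerateDataError("CV undefined: mean start time is zero")
    sd = float(x.std(ddof=1))
    return mean, sd, sd / mean
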
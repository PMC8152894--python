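"""Plain-text session storage.

One directory per session: a JSON manifest plus three RFC-4180 CSV tables
(trials, units, spikes).  All times are seconds; floats are written with
``%.17g`` so a write -> read round trip is exact and a second write is
byte-identical.  Press lists and waveform samples are semicolon-joined
floats inside a single CSV field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError
from .model import SessionRecord, TrialRecord, UnitRecord, WaveformMetrics

MANIFEST_NAME = "session.json"
FLOAT_FMT = "%.17g"

TRIAL_COLUMNS = [
    "trial_id",
    "interval_type",
    "cue_onset",
    "interval_duration",
    "press_times",
    "reward_time",
    "iti_before",
]
UNIT_COLUMNS = [
    "unit_id",
    "area",
    "unit_class",
    "waveform",
    "waveform_dt",
    "peak_to_trough_ratio",
    "half_peak_width",
]
SPIKE_COLUMNS = ["unit_id", "spike_time"]


def _fmt(x: float | None) -> str:
    return "" if x is None else FLOAT_FMT % x


def _join(values) -> str:
    return ";".join(FLOAT_FMT % v for v in np.asarray(values, dtype=float))


def parse_float_list(text: str) -> np.ndarray:
    """Parse a semicolon-joined float list; empty string -> empty array."""
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return np.array([], dtype=float)
    return np.array([float(tok) for tok in str(text).split(";")], dtype=float)


def write_session(session: SessionRecord, path: str | Path) -> None:
    """Write a session directory such that :func:`read_session` inverts it."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    trial_rows = [
        {
            "trial_id": t.trial_id,
            "interval_type": t.interval_type,
            "cue_onset": _fmt(t.cue_onset),
            "interval_duration": _fmt(t.interval_duration),
            "press_times": _join(t.press_times),
            "reward_time": _fmt(t.reward_time),
            "iti_before": _fmt(t.iti_before),
        }
        for t in session.trials
    ]
    pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS).to_csv(path / "trials.csv", index=False)

    unit_rows = []
    spike_frames = []
    for u in session.units:
        unit_rows.append(
            {
                "unit_id": u.unit_id,
                "area": u.area,
                "unit_class": u.unit_class,
                "waveform": "" if u.waveform is None else _join(u.waveform),
                "waveform_dt": _fmt(u.waveform_dt),
                "peak_to_trough_ratio": _fmt(
                    None if u.metrics is None else u.metrics.peak_to_trough_ratio
                ),
                "half_peak_width": _fmt(
                    None if u.metrics is None else u.metrics.half_peak_width
                ),
            }
        )
        spike_frames.append(
            pd.DataFrame(
                {
                    "unit_id": u.unit_id,
                    "spike_time": [FLOAT_FMT % s for s in u.spike_times],
                }
            )
        )
    pd.DataFrame(unit_rows, columns=UNIT_COLUMNS).to_csv(path / "units.csv", index=False)
    spikes = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=SPIKE_COLUMNS)
    )
    spikes.to_csv(path / "spikes.csv", index=False)

    manifest = {
        "animal_id": session.animal_id,
        "day": session.day,
        "files": {"trials": "trials.csv", "units": "units.csv", "spikes": "spikes.csv"},
    }
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table missing columns: {missing}")


def read_session(path: str | Path) -> SessionRecord:
    """Read and fully validate a session directory written by :func:`write_session`."""
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise SchemaError(f"no {MANIFEST_NAME} in {path}")
    manifest = json.loads(manifest_path.read_text())
    for key in ("animal_id", "day", "files"):
        if key not in manifest:
            raise SchemaError(f"manifest missing key {key!r}")

    trials_df = pd.read_csv(path / manifest["files"]["trials"], dtype=str, keep_default_na=False)
    units_df = pd.read_csv(path / manifest["files"]["units"], dtype=str, keep_default_na=False)
    spikes_df = pd.read_csv(path / manifest["files"]["spikes"], dtype=str, keep_default_na=False)
    _require_columns(trials_df, TRIAL_COLUMNS, "trials")
    _require_columns(units_df, UNIT_COLUMNS, "units")
    _require_columns(spikes_df, SPIKE_COLUMNS, "spikes")

    trials = []
    for row in trials_df.itertuples(index=False):
        trials.append(
            TrialRecord(
                trial_id=int(row.trial_id),
                interval_type=row.interval_type,
                cue_onset=float(row.cue_onset),
                interval_duration=float(row.interval_duration),
                press_times=parse_float_list(row.press_times),
                reward_time=None if row.reward_time == "" else float(row.reward_time),
                iti_before=float(row.iti_before),
            )
        )

    spikes_by_unit: dict[str, np.ndarray] = {}
    if len(spikes_df):
        times = spikes_df["spike_time"].astype(float).to_numpy()
        for uid, grp_idx in spikes_df.groupby("unit_id", sort=False).indices.items():
            spikes_by_unit[uid] = times[grp_idx]

    units = []
    for row in units_df.itertuples(index=False):
        spike_times = spikes_by_unit.get(row.unit_id, np.array([], dtype=float))
        if spike_times.size and np.any(np.diff(spike_times) < 0):
            raise ValidationError(f"unit {row.unit_id}: spike times not ascending")
        metrics = None
        if row.peak_to_trough_ratio != "" and row.half_peak_width != "":
            metrics = WaveformMetrics(
                peak_to_trough_ratio=float(row.peak_to_trough_ratio),
                half_peak_width=float(row.half_peak_width),
            )
        units.append(
            UnitRecord(
                unit_id=row.unit_id,
                area=row.area,
                spike_times=spike_times,
                waveform=None if row.waveform == "" else parse_float_list(row.waveform),
                waveform_dt=None if row.waveform_dt == "" else float(row.waveform_dt),
                metrics=metrics,
                unit_class=row.unit_class,
            )
        )

    session = SessionRecord(
        animal_id=str(manifest["animal_id"]), day=int(manifest["day"]), units=units, trials=trials
    )
    session.validate()
    return session
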
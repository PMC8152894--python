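"""End-to-end orchestration: simulate -> classify -> behavior -> ramping -> decode -> stats.

Every stochastic stage draws from a named substream of the master seed
(keyed by stage, animal, and day), so disabling one stage never shifts
another stage's randomness.  Stage outputs are written to stage-scoped
subdirectories as CSV/JSON; a JSON-lines log records warnings with entity
ids, and ``summary.json`` aggregates the headline numbers.  Identical
config + seed produces a byte-identical summary.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import decoding as dec
from . import ramping as rmp
from . import stats as st
from .io import write_session
from .model import SessionRecord
from .synth import GeneratorConfig, GroundTruth, generate_session, substream
from .units import ClassifierThresholds, classify_session_units


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    decoder: dec.DecoderConfig = field(default_factory=dec.DecoderConfig)
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "ramplab_out"
    stages: dict = field(
        default_factory=lambda: {
            "classify": True,
            "behavior": True,
            "ramping": True,
            "decode": True,
            "stats": True,
        }
    )
    n_shuffles: int = 1
    write_sessions: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "thresholds" in d:
            d["thresholds"] = ClassifierThresholds(**d["thresholds"])
        if "decoder" in d:
            d["decoder"] = dec.DecoderConfig(**d["decoder"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class _JsonlLog:
    def __init__(self, path: Path):
        self.path = path
        self.records: list[dict] = []

    def log(self, level: str, stage: str, message: str, **entities) -> None:
        self.records.append({"level": level, "stage": stage, "message": message, **entities})

    def flush(self) -> None:
        with self.path.open("w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages in dependency order; returns the summary dict."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _JsonlLog(out / "log.jsonl")
    gen = config.generator
    gen.validate()

    # --- simulate -----------------------------------------------------------
    sessions: list[SessionRecord] = []
    truths: dict[tuple[str, int], GroundTruth] = {}
    for a in range(gen.n_animals):
        animal = f"rat{a + 1:02d}"
        for day in gen.days:
            session, truth = generate_session(gen, animal, day, seed=config.seed)
            sessions.append(session)
            truths[(animal, day)] = truth
            if config.write_sessions:
                write_session(session, out / "sessions" / f"{animal}_d{day}")
    log.log("info", "simulate", f"generated {len(sessions)} sessions", seed=config.seed)

    summary: dict = {
        "seed": config.seed,
        "n_sessions": len(sessions),
        "n_units": int(sum(len(s.units) for s in sessions)),
        "stages": sorted(k for k, v in config.stages.items() if v),
    }

    # --- classify -----------------------------------------------------------
    unit_rows: list[dict] = []
    if config.stages.get("classify", True):
        for s in sessions:
            rows = classify_session_units(s.units, s.span, config.thresholds)
            for r in rows:
                r["animal_id"], r["day"] = s.animal_id, s.day
                if not r["included"]:
                    log.log("warning", "classify", "unit excluded", unit_id=r["unit_id"],
                            reason=r["reason"])
            unit_rows.extend(rows)
        units_df = pd.DataFrame(unit_rows)
        (out / "classify").mkdir(exist_ok=True)
        units_df.to_csv(out / "classify" / "units.csv", index=False)
        summary["classify"] = {
            "n_included": int(units_df["included"].sum()),
            "n_excluded": int((~units_df["included"]).sum()),
            "class_counts": {
                k: int(v) for k, v in units_df["unit_class"].value_counts().sort_index().items()
            },
        }

    # --- behavior -----------------------------------------------------------
    if config.stages.get("behavior", True):
        rt_frames, start_frames, cv_rows = [], [], []
        for s in sessions:
            rt = bhv.response_times(s.trials, scope="all_presses")
            rt["animal_id"], rt["day"] = s.animal_id, s.day
            rt_frames.append(rt)
            starts = bhv.start_times_table(s.trials)
            starts["animal_id"], starts["day"] = s.animal_id, s.day
            start_frames.append(starts)
            for itype, grp in starts.groupby("interval_type"):
                if len(grp) >= 2:
                    mean, sd, cv = bhv.cv_of_start_times(grp["start_time"])
                    cv_rows.append(
                        {"animal_id": s.animal_id, "day": s.day, "interval_type": itype,
                         "mean_start": mean, "sd_start": sd, "cv": cv}
                    )
        rt_df = pd.concat(rt_frames, ignore_index=True)
        starts_df = pd.concat(start_frames, ignore_index=True)
        cv_df = pd.DataFrame(cv_rows)
        (out / "behavior").mkdir(exist_ok=True)
        rt_df.to_csv(out / "behavior" / "response_times.csv", index=False)
        starts_df.to_csv(out / "behavior" / "start_times.csv", index=False)
        cv_df.to_csv(out / "behavior" / "cv.csv", index=False)
        summary["behavior"] = {
            "mean_response_time": {
                k: float(v) for k, v in
                rt_df.groupby("interval_type")["response_time"].mean().sort_index().items()
            },
            "mean_cv": {
                k: float(v) for k, v in cv_df.groupby("interval_type")["cv"].mean().sort_index().items()
            } if len(cv_df) else {},
        }

    # --- ramping ------------------------------------------------------------
    ramp_df = pd.DataFrame()
    if config.stages.get("ramping", True):
        (out / "ramping").mkdir(exist_ok=True)
        ramp_rows = []
        pca_summaries = {}
        for itype in ("FI12", "FI3"):
            peth_rows, meta = [], []
            for s in sessions:
                trials = s.trials_of(itype)
                if not trials:
                    continue
                for u in s.units:
                    if u.unit_class == "excluded":
                        continue
                    peth_rows.append(rmp.compute_peth(u, trials))
                    meta.append((s.animal_id, s.day, u))
            if len(peth_rows) < 2:
                continue
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                z = rmp.zscore_rows(rmp.stack_peths(peth_rows))
            for w in caught:
                log.log("warning", "ramping", str(w.message))
            pca = rmp.ensemble_pca(z)
            pca_summaries[itype] = [round(float(v), 4) for v in pca.explained_variance_fraction[:3]]
            pd.DataFrame(
                pca.components[:3], columns=[f"t{c:.2f}" for c in pca.bin_centers]
            ).to_csv(out / "ramping" / f"components_{itype}.csv", index=False)
            kept = set(pca.unit_ids)
            for animal, day, u in meta:
                if u.unit_id not in kept:
                    continue
                row = {
                    "unit_id": u.unit_id, "animal_id": animal, "day": day, "area": u.area,
                    "interval_type": itype, "abs_pc1_score": rmp.ramp_strength(pca, u.unit_id),
                }
                session = next(s for s in sessions if s.animal_id == animal and s.day == day)
                trials = session.trials_of(itype)
                try:
                    fit = rmp.fit_ramp_slope(u, trials)
                    row.update(slope=fit.slope, abs_slope=fit.abs_slope, slope_p=fit.p_value,
                               ramping=rmp.classify_ramping(fit, config.alpha))
                except Exception as exc:  # noqa: BLE001 - logged, unit simply unfit
                    log.log("warning", "ramping", f"slope fit failed: {exc}", unit_id=u.unit_id)
                ramp_rows.append(row)
        ramp_df = pd.DataFrame(ramp_rows)
        ramp_df.to_csv(out / "ramping" / "ramping.csv", index=False)

        mod_rows = []
        for s in sessions:
            fi3, fi12 = s.trials_of("FI3"), s.trials_of("FI12")
            if not fi3 or not fi12:
                continue
            for u in s.units:
                if u.unit_class == "excluded":
                    continue
                res = rmp.screen_interval_modulation(u, fi3, fi12, alpha=config.alpha)
                if res is None:
                    continue
                mod_rows.append(
                    {"unit_id": u.unit_id, "animal_id": s.animal_id, "day": s.day,
                     "area": u.area, "interval_effect_p": res.interval_effect_p,
                     "modulated": res.modulated, "also_ramping": res.also_ramping}
                )
        mod_df = pd.DataFrame(mod_rows)
        mod_df.to_csv(out / "ramping" / "interval_modulation.csv", index=False)
        summary["ramping"] = {
            "pc1_variance_fraction": pca_summaries,
            "fraction_ramping": (
                {k: round(float(v), 4) for k, v in
                 ramp_df.groupby("interval_type")["ramping"].mean().sort_index().items()}
                if len(ramp_df) and "ramping" in ramp_df else {}
            ),
            "n_modulated_by_area": (
                {k: int(v) for k, v in mod_df.groupby("area")["modulated"].sum().sort_index().items()}
                if len(mod_df) else {}
            ),
        }

    # --- decode -------------------------------------------------------------
    decode_df = pd.DataFrame()
    if config.stages.get("decode", True):
        decode_rows = []
        for s in sessions:
            for itype in ("FI12", "FI3"):
                trials = s.trials_of(itype)
                if len(trials) < 3:
                    continue
                for area in ("MFC", "DMS"):
                    units = [u for u in s.units if u.area == area and u.unit_class != "excluded"]
                    if len(units) < 2:
                        continue
                    F = dec.ensemble_features(units, trials, config.decoder)
                    real = dec.loocv_r2(F, config=config.decoder, interval_type=itype,
                                        trial_ids=[t.trial_id for t in trials])
                    decode_rows.append(
                        {"animal_id": s.animal_id, "day": s.day, "area": area,
                         "interval_type": itype, "shuffled": False, "r_squared": real.r_squared}
                    )
                    for k in range(config.n_shuffles):
                        shuf_seed = int(
                            substream(config.seed, "decode-shuffle", s.animal_id, s.day, area, k)
                            .integers(2**31)
                        )
                        shuf = dec.loocv_r2(F, config=config.decoder, interval_type=itype,
                                            shuffle=True, seed=shuf_seed)
                        decode_rows.append(
                            {"animal_id": s.animal_id, "day": s.day, "area": area,
                             "interval_type": itype, "shuffled": True, "r_squared": shuf.r_squared}
                        )
        decode_df = pd.DataFrame(decode_rows)
        (out / "decode").mkdir(exist_ok=True)
        decode_df.to_csv(out / "decode" / "r_squared.csv", index=False)
        if len(decode_df):
            summary["decode"] = {
                "mean_r2": {
                    f"{itype}_{'shuffled' if sh else 'real'}": round(float(v), 4)
                    for (itype, sh), v in
                    decode_df.groupby(["interval_type", "shuffled"])["r_squared"].mean().items()
                }
            }

    # --- stats --------------------------------------------------------------
    if config.stages.get("stats", True):
        stats_out: dict = {}
        if len(ramp_df) and "ramping" in ramp_df and config.stages.get("ramping", True):
            mod_path = out / "ramping" / "interval_modulation.csv"
            mod_df = pd.read_csv(mod_path) if mod_path.exists() else pd.DataFrame()
            if len(mod_df):
                counts = []
                for area in ("MFC", "DMS"):
                    sub = mod_df[mod_df["area"] == area]
                    counts.append([int(sub["modulated"].sum()), int((~sub["modulated"]).sum())])
                try:
                    stat, df_, p = st.chi_square_2x2(np.array(counts))
                    stats_out["interval_mod_chi2"] = {"statistic": stat, "df": df_, "p": p,
                                                      "counts": counts}
                except st.DegenerateDataError:
                    pass
        if len(decode_df):
            piv = decode_df.pivot_table(index=["animal_id", "day", "area", "interval_type"],
                                        columns="shuffled", values="r_squared", aggfunc="mean")
            if True in piv.columns and False in piv.columns and len(piv.dropna()) >= 5:
                piv = piv.dropna()
                res = st.signed_rank_and_d(piv[False].to_numpy(), piv[True].to_numpy(),
                                           alternative="greater")
                stats_out["decode_real_vs_shuffled"] = {
                    "W": res.statistic, "p": res.p_value, "cohens_d": res.cohens_d, "n": res.n,
                }
        if config.stages.get("behavior", True) and len(gen.days) > 1 and 0 in gen.days:
            rt_df = pd.read_csv(out / "behavior" / "response_times.csv")
            fi12 = rt_df[rt_df["interval_type"] == "FI12"].copy()
            fi12["context"] = np.where(fi12["day"] == 0, "one_interval", "two_interval")
            if fi12["context"].nunique() == 2 and fi12["animal_id"].nunique() >= 2:
                fit = st.fit_model(st.model_spec("response_context"), fi12)
                stats_out["response_context"] = {
                    "terms": fit.term_tests.to_dict(orient="records"),
                    "params": {k: float(v) for k, v in fit.params.items()},
                    "singular": fit.singular,
                }
        (out / "stats").mkdir(exist_ok=True)
        (out / "stats" / "stats.json").write_text(
            json.dumps(_round_floats(stats_out), indent=2, sort_keys=True) + "\n"
        )
        summary["stats"] = _round_floats(stats_out)

    log.log("info", "done", f"pipeline finished in {time.time() - t0:.1f} s")
    log.flush()
    summary = _round_floats(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def make_fixtures(seed: int, out_dir: str | Path) -> list[Path]:
    """Generate the miniature test dataset: 2 animals x 2 days, 8 units/area,
    30 trials per interval, every tuning class represented.

    Sessions are written as plain-text session directories; ground truth is
    stored alongside as JSON.  Returns the session directory paths.
    """
    config = GeneratorConfig(
        n_animals=2, n_units_per_area=8, days=(0, 1), n_trials_per_interval=30, seed=seed
    )
    out = Path(out_dir)
    paths = []
    for a in range(config.n_animals):
        animal = f"rat{a + 1:02d}"
        for day in config.days:
            session, truth = generate_session(config, animal, day, seed=seed)
            path = out / f"{animal}_d{day}"
            write_session(session, path)
            truth_json = {
                "start_times": {str(k): v for k, v in truth.start_times.items()},
                "units": {k: dataclasses.asdict(v) for k, v in truth.units.items()},
            }
            (path / "truth.json").write_text(json.dumps(truth_json, indent=2, sort_keys=True))
            paths.append(path)
    return paths
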
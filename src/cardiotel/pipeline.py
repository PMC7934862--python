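"""End-to-end drivers: simulate -> beats -> summarize -> variability ->
rhythm -> drug-response -> report.

Each stage function also works on its own; ``run_pipeline`` chains them,
writes every intermediate as CSV and records a JSON manifest with the
package version, seed and every analysis parameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beatproc import WaveformRecording, aggregate_epochs, detect_beats
from .circadian import sliding_cosinor
from .config import SimConfig
from .errors import AnalysisError, CardiotelError, ConfigError
from .groupstats import compare_groups, group_summary
from .pharm import quantify_drug_response
from .simgen import apply_drug_event, iter_study_animals
from .variability import SpectralParams, spectral_summary

__all__ = ["PipelineConfig", "run_pipeline", "telemetry_stage",
           "variability_stage", "drug_stage"]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    lights_on: float = 6.0
    nadir_window_s: tuple = (420.0, 720.0)
    rhythm_window_h: float = 27.0
    rhythm_step_h: float = 3.0
    injection_time_s: float = 3600.0
    variability_duration_s: float = 3600.0
    drug_duration_s: float = 7200.0
    run_rhythm: bool = True
    run_variability: bool = True
    run_drug: bool = True
    log_level: str = "INFO"

    def validate(self):
        self.sim.validate()
        self.spectral.validate()
        if not (0.0 <= self.lights_on < 24.0):
            raise ConfigError("lights_on must be a clock hour in [0, 24)")
        lo, hi = self.nadir_window_s
        if not (0 < lo < hi):
            raise ConfigError("invalid nadir window")
        if self.rhythm_window_h < 24.0:
            raise ConfigError("rhythm window must cover a full period")


def telemetry_stage(config: SimConfig, lights_on: float = 6.0,
                    rhythm_window_h: float = 27.0, rhythm_step_h: float = 3.0,
                    run_rhythm: bool = True, out_dir=None):
    """Baseline telemetry: simulate, detect beats, aggregate, fit rhythms.

    Streams one animal at a time.  Returns ``(animal_table, group_table,
    rhythm_table)``; the animal table has one row per animal with
    day/night/overall means of SBP, DBP, MAP, HR and activity.
    """
    rows = []
    rhythm_rows = []
    for animal in iter_study_animals(config):
        rec = WaveformRecording.from_simulated(animal)
        beats = detect_beats(rec)
        summ = aggregate_epochs(beats, animal.activity_counts,
                                lights_on=lights_on,
                                epoch_interval_s=config.epoch_interval_s)
        row = {"animal_id": animal.animal_id, "group": animal.group}
        for var in ("sbp", "dbp", "map", "hr", "activity"):
            for phase in ("day", "night", "overall"):
                row[f"{var}_{phase}"] = summ.phase_mean(var, phase)
        rows.append(row)
        if run_rhythm:
            pe = summ.per_epoch
            for var in ("map", "hr"):
                try:
                    fits = sliding_cosinor(pe["start_clock_h"].to_numpy(),
                                           pe[var].to_numpy(),
                                           window_h=rhythm_window_h,
                                           step_h=rhythm_step_h)
                except AnalysisError:
                    continue
                for _, r in fits.iterrows():
                    rhythm_rows.append({"animal_id": animal.animal_id,
                                        "group": animal.group,
                                        "variable": var, **r.to_dict()})
        if out_dir is not None:
            from .io import write_beats_csv
            write_beats_csv(beats, Path(out_dir) / f"beats_{animal.animal_id}.csv")
    animal_table = pd.DataFrame(rows)
    grp_rows = []
    for (g,), sub in animal_table.groupby(["group"]):
        for col in animal_table.columns:
            if col in ("animal_id", "group"):
                continue
            v = sub[col].to_numpy(dtype=float)
            grp_rows.append({"group": g, "measure": col, "n": len(v),
                             "mean": v.mean(),
                             "sem": v.std(ddof=1) / math.sqrt(len(v))
                             if len(v) > 1 else math.nan})
    group_table = pd.DataFrame(grp_rows)
    rhythm_table = pd.DataFrame(rhythm_rows)
    return animal_table, group_table, rhythm_table


def variability_stage(config: SimConfig, params: SpectralParams | None = None,
                      duration_s: float = 3600.0):
    """Continuous-mode spectral/BRS metrics, one row per animal."""
    params = params or SpectralParams()
    cfg = config.with_updates(sampling_mode="continuous",
                              duration_days=duration_s / 86400.0)
    rows = []
    for animal in iter_study_animals(cfg):
        rec = WaveformRecording.from_simulated(animal)
        beats = detect_beats(rec)
        s = spectral_summary(beats, params)
        rows.append({"animal_id": s.animal_id, "group": s.group,
                     "lf_pi": s.lf_pi, "hf_pi": s.hf_pi, "lf_hf": s.lf_hf_ratio,
                     "lf_sbp": s.lf_sbp, "rmssd": s.rmssd,
                     "brs_lf": s.brs_lf if s.brs_lf is not None else math.nan,
                     "coh_lf": s.mean_coherence_lf,
                     "brs_sequp": s.brs_sequp, "brs_seqdown": s.brs_seqdown,
                     "n_seq_up": s.n_seq_up, "n_seq_down": s.n_seq_down})
    return pd.DataFrame(rows)


def drug_stage(config: SimConfig, injection_time_s: float = 3600.0,
               duration_s: float = 7200.0,
               nadir_window_s: tuple = (420.0, 720.0)):
    """Blockade responses from continuous recordings around an injection."""
    from .simgen import render_waveform, simulate_beat_series, SimulatedAnimal

    cfg = config.with_updates(sampling_mode="continuous",
                              duration_days=duration_s / 86400.0)
    rows = []
    for group in sorted(cfg.groups):
        for a in range(cfg.n_animals_per_group):
            truth = simulate_beat_series(cfg, group, a, duration_s=duration_s)
            truth = apply_drug_event(truth, cfg, injection_time_s)
            samples = render_waveform(truth, 1000.0)
            rec = WaveformRecording(animal_id=f"{group}{a + 1:02d}",
                                    group=group, sampling_rate=1000.0,
                                    segments=[(float(truth.beat_times[0]),
                                               samples)],
                                    mode="continuous",
                                    start_clock_h=cfg.start_clock_h)
            beats = detect_beats(rec)
            r = quantify_drug_response(beats, injection_time_s,
                                       nadir_window_s=nadir_window_s)
            rows.append({"animal_id": r.animal_id, "group": r.group,
                         "baseline_map": r.baseline_map,
                         "baseline_hr": r.baseline_hr,
                         "delta_map": r.delta_map, "delta_hr": r.delta_hr,
                         "nadir_time_map_s": r.nadir_time_map_s,
                         "nadir_time_hr_s": r.nadir_time_hr_s})
    return pd.DataFrame(rows)


def _contrast(table: pd.DataFrame, col: str) -> dict:
    groups = sorted(table["group"].unique())
    out = {}
    for g in groups:
        v = table.loc[table["group"] == g, col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        out[g] = {"n": len(v), "mean": float(v.mean()) if len(v) else math.nan,
                  "sem": float(v.std(ddof=1) / math.sqrt(len(v)))
                  if len(v) > 1 else math.nan}
    return out


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage, write intermediates and a manifest; returns a dict
    of result tables."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    animal_table, group_table, rhythm_table = telemetry_stage(
        config.sim, lights_on=config.lights_on,
        rhythm_window_h=config.rhythm_window_h,
        rhythm_step_h=config.rhythm_step_h, run_rhythm=config.run_rhythm)
    animal_table.to_csv(out / "animal_summary.csv", index=False)
    group_table.to_csv(out / "group_summary.csv", index=False)
    if len(rhythm_table):
        rhythm_table.to_csv(out / "rhythm_fits.csv", index=False)
    results["animal_summary"] = animal_table
    results["group_summary"] = group_table
    results["rhythm_fits"] = rhythm_table

    if config.run_variability:
        metrics = variability_stage(config.sim, config.spectral,
                                    config.variability_duration_s)
        metrics.to_csv(out / "variability_metrics.csv", index=False)
        results["variability_metrics"] = metrics

    if config.run_drug:
        responses = drug_stage(config.sim, config.injection_time_s,
                               config.drug_duration_s, config.nadir_window_s)
        responses.to_csv(out / "drug_responses.csv", index=False)
        results["drug_responses"] = responses

    report = {}
    if len(animal_table["group"].unique()) == 2:
        for col, name in (("map_overall", "map"), ("hr_overall", "hr")):
            report[name] = _contrast(animal_table, col)
        if config.run_variability:
            for col in ("lf_sbp", "brs_sequp", "brs_seqdown", "brs_lf"):
                report[col] = _contrast(results["variability_metrics"], col)
        if config.run_drug:
            for col in ("delta_map", "delta_hr"):
                report[f"drug_{col}"] = _contrast(results["drug_responses"], col)
    manifest = {"cardiotel_version": __version__,
                "seed": config.sim.seed,
                "sim_config": config.sim.to_dict(),
                "spectral_params": vars(config.spectral).copy(),
                "lights_on": config.lights_on,
                "nadir_window_s": list(config.nadir_window_s),
                "rhythm_window_h": config.rhythm_window_h,
                "report": report}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    results["report"] = report
    return results
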
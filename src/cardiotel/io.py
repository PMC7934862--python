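"""CSV/TOML file formats: the package's documented plain-text dialects.

Waveforms: one CSV per animal, columns ``segment_id,t_s,pressure_mmHg``.
Epoch manifest: ``segment_id,start_clock_iso``.  Activity:
``minute_index,counts``.  Beat tables: ``beat_time_s,sbp,dbp,map,pi_ms,
flag,seg_id``.  Config: TOML mirroring the SimConfig field names.
"""

from __future__ import annotations

import datetime as _dt
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .beatproc import BeatSeries, WaveformRecording
from .config import GroupParams, SimConfig
from .errors import ConfigError, ParseError

WAVEFORM_COLUMNS = ["segment_id", "t_s", "pressure_mmHg"]
_EPOCH0 = _dt.datetime(2000, 1, 1)


def write_waveform_csv(rec: WaveformRecording, path) -> None:
    frames = []
    for seg_id, (t0, x) in enumerate(rec.segments):
        t = t0 + np.arange(len(x)) / rec.sampling_rate
        frames.append(pd.DataFrame({"segment_id": seg_id, "t_s": t,
                                    "pressure_mmHg": x}))
    pd.concat(frames).to_csv(path, index=False, float_format="%.17g")


def read_waveform_csv(path, animal_id: str | None = None, group: str = "",
                      mode: str | None = None,
                      start_clock_h: float = 6.0) -> WaveformRecording:
    """Read the waveform dialect back into a :class:`WaveformRecording`.

    The sampling rate is inferred from the median within-segment sample
    spacing.  Malformed rows are reported with their line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty input file") from None
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    missing = [c for c in WAVEFORM_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in WAVEFORM_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(f"{path}: malformed value in column {col!r} "
                             f"at line {row}")
        df[col] = coerced
    segments = []
    fs = None
    for seg_id, sub in df.groupby("segment_id", sort=True):
        t = sub["t_s"].to_numpy()
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                row = int(sub.index[np.argmax(dt <= 0) + 1]) + 2
                raise ParseError(f"{path}: non-monotone time in segment "
                                 f"{seg_id} at line {row}")
            fs = fs or 1.0 / float(np.median(dt))
        segments.append((float(t[0]), sub["pressure_mmHg"].to_numpy()))
    if fs is None:
        raise ParseError(f"{path}: cannot infer sampling rate")
    return WaveformRecording(animal_id=animal_id or path.stem, group=group,
                             sampling_rate=fs, segments=segments,
                             mode=mode or ("epochal" if len(segments) > 1
                                           else "continuous"),
                             start_clock_h=start_clock_h)


def write_epoch_manifest(rec: WaveformRecording, path) -> None:
    rows = []
    for seg_id, (t0, _) in enumerate(rec.segments):
        clock = _EPOCH0 + _dt.timedelta(hours=rec.start_clock_h, seconds=t0)
        rows.append({"segment_id": seg_id, "start_clock_iso": clock.isoformat()})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_activity_csv(counts, path) -> None:
    pd.DataFrame({"minute_index": np.arange(len(counts)),
                  "counts": np.asarray(counts)}).to_csv(path, index=False)


def read_activity_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "counts" not in df.columns:
        raise ParseError(f"{path}: missing 'counts' column")
    return df["counts"].to_numpy()


def write_beats_csv(beats: BeatSeries, path) -> None:
    beats.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_beats_csv(path, animal_id: str = "", group: str = "",
                   start_clock_h: float = 6.0) -> BeatSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    need = ["beat_time_s", "sbp", "dbp", "map", "pi_ms", "flag"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    t = df["beat_time_s"].to_numpy()
    pi = df["pi_ms"].to_numpy()
    # the table stores one row per cycle; the final peak is reconstructed
    last_valid = np.isfinite(pi[-1])
    bt = np.append(t, t[-1] + (pi[-1] / 1000.0 if last_valid else 1.0))
    sbp = np.append(df["sbp"].to_numpy(), df["sbp"].to_numpy()[-1])
    seg = (df["seg_id"].to_numpy() if "seg_id" in df.columns
           else np.zeros(len(df), dtype=int))
    seg = np.append(seg, seg[-1])
    return BeatSeries(animal_id=animal_id, group=group, beat_times=bt,
                      sbp=sbp, dbp=df["dbp"].to_numpy(),
                      map=df["map"].to_numpy(), pi_ms=pi,
                      flags=df["flag"].to_numpy(dtype=np.int64),
                      seg_id=seg, start_clock_h=start_clock_h)


def write_truth_csv(truth, path) -> None:
    n = truth.n_beats
    pd.DataFrame({"beat_time_s": truth.beat_times,
                  "true_sbp": truth.sbp, "true_dbp": truth.dbp,
                  "true_map": truth.map,
                  "true_pi_ms": np.append(truth.pi, np.nan)[:n],
                  }).to_csv(path, index=False, float_format="%.17g")


def load_sim_config(path) -> SimConfig:
    """Load a SimConfig from a TOML file mirroring the field names.

    Group sections live under ``[groups.<label>]``.
    """
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as err:
            raise ConfigError(f"{path}: {err}") from None
    groups = raw.pop("groups", None)
    if groups is not None:
        raw["groups"] = {k: GroupParams(**v) for k, v in groups.items()}
    try:
        return SimConfig(**raw)
    except TypeError as err:
        raise ConfigError(f"{path}: {err}") from None
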
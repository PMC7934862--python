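"""Beat detection and epoch aggregation for arterial-pressure waveforms.

``detect_beats`` finds systolic peaks with a refractory period and an
adaptive prominence threshold, then derives per-cycle diastolic pressure,
integral mean arterial pressure and pulse intervals.  The pulse-interval
fiducial is systolic peak to systolic peak.  Beats that fail physiological
screens are flagged, never silently dropped.

``aggregate_epochs`` rolls per-beat values up to 5-minute epochs and
day/night/overall phase summaries under a 12 h:12 h light schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from .errors import AnalysisError, NoBeatsError, SignalQualityError

__all__ = [
    "WaveformRecording", "BeatSeries", "EpochSummary",
    "detect_beats", "compute_map", "derive_hr", "aggregate_epochs",
    "FLAG_OK", "FLAG_CROSS_SEGMENT", "FLAG_PI_RANGE", "FLAG_NONPHYS",
]

FLAG_OK = 0
FLAG_CROSS_SEGMENT = 1   # interval spans a gap between acquisition segments
FLAG_PI_RANGE = 2        # pulse interval outside (50, 1000) ms
FLAG_NONPHYS = 4         # SBP <= DBP within the cycle

#: accepted murine pulse-interval range, ms
PI_RANGE_MS = (50.0, 1000.0)


@dataclass
class WaveformRecording:
    """Raw pressure samples with acquisition-scheme metadata."""

    animal_id: str
    group: str
    sampling_rate: float
    #: list of (start time in s, 1-D pressure array in mmHg)
    segments: list
    mode: str = "epochal"          # "epochal" or "continuous"
    start_clock_h: float = 6.0     # clock hour at recording time zero

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise AnalysisError("sampling_rate must be positive")
        if not self.segments:
            raise AnalysisError("recording has no segments")
        starts = [s for s, _ in self.segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise AnalysisError("segment start times must be strictly increasing")
        for _, x in self.segments:
            if len(x) == 0:
                raise AnalysisError("segment arrays must be non-empty")

    @classmethod
    def from_simulated(cls, animal) -> "WaveformRecording":
        return cls(animal_id=animal.animal_id, group=animal.group,
                   sampling_rate=animal.sampling_rate,
                   segments=animal.segments, mode=animal.mode,
                   start_clock_h=animal.start_clock_h)


@dataclass
class BeatSeries:
    """Per-beat series derived from a pressure waveform.

    ``beat_times`` (s) are systolic-peak times; ``sbp`` is per peak.  The
    cycle between peaks ``i`` and ``i+1`` carries ``dbp[i]`` (minimum of the
    cycle), ``map[i]`` (integral mean), ``pi_ms[i]`` and ``flags[i]``, so
    those arrays have one fewer element than ``beat_times``.
    """

    animal_id: str
    group: str
    beat_times: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    map: np.ndarray
    pi_ms: np.ndarray
    flags: np.ndarray
    seg_id: np.ndarray             # per peak
    start_clock_h: float = 6.0
    meta: dict = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    @property
    def accepted(self) -> np.ndarray:
        """Boolean mask of accepted (unflagged) cycles."""
        return self.flags == FLAG_OK

    def hr_bpm(self) -> np.ndarray:
        """Per-cycle heart rate, NaN where the cycle is rejected."""
        with np.errstate(divide="ignore", invalid="ignore"):
            hr = 60000.0 / self.pi_ms
        hr[~self.accepted] = np.nan
        return hr

    def to_frame(self) -> pd.DataFrame:
        n = self.n_beats - 1
        return pd.DataFrame({
            "beat_time_s": self.beat_times[:-1][:n],
            "sbp": self.sbp[:-1][:n],
            "dbp": self.dbp,
            "map": self.map,
            "pi_ms": self.pi_ms,
            "flag": self.flags,
            "seg_id": self.seg_id[:-1][:n],
        })


def _segment_peaks(x: np.ndarray, fs: float, refractory_ms: float,
                   prominence_frac: float) -> np.ndarray:
    if not np.all(np.isfinite(x)):
        raise NoBeatsError("segment contains non-finite samples")
    lo, hi = np.percentile(x, [2.0, 98.0])
    amp = hi - lo
    if amp < 1e-3:
        raise NoBeatsError("flat segment: no pulse pressure")
    rail = np.count_nonzero((x == x.max()) | (x == x.min()))
    if rail / len(x) > 0.05:
        raise SignalQualityError("saturated segment (>5% samples at rail)")
    distance = max(1, int(round(refractory_ms * fs / 1000.0)))
    peaks, _ = find_peaks(x, distance=distance, prominence=prominence_frac * amp)
    return peaks


def detect_beats(rec: WaveformRecording, refractory_ms: float = 50.0,
                 prominence_frac: float = 0.3,
                 map_method: str = "integral") -> BeatSeries:
    """Detect systolic peaks and derive the per-beat series.

    The prominence threshold adapts per segment to ``prominence_frac`` times
    the 2nd-98th percentile pressure range; the refractory period suppresses
    duplicate detections.  Intervals spanning segment gaps, or with pulse
    intervals outside the murine physiological range, are flagged.
    """
    fs = rec.sampling_rate
    if fs < 100.0:
        raise AnalysisError("sampling rate must be >= 100 Hz for beat detection")
    times, sbps, dbps, maps, pis, flags, seg_ids = [], [], [], [], [], [], []
    n_failed = 0
    last_err: Exception | None = None
    for seg_idx, (t0, x) in enumerate(rec.segments):
        x = np.asarray(x, dtype=float)
        try:
            peaks = _segment_peaks(x, fs, refractory_ms, prominence_frac)
        except (NoBeatsError, SignalQualityError) as err:
            if len(rec.segments) == 1:
                raise
            n_failed += 1
            last_err = err
            continue
        if len(peaks) < 2:
            n_failed += 1
            continue
        pk_t = t0 + peaks / fs
        pk_sbp = x[peaks]
        ct = cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0)
        for i in range(len(peaks) - 1):
            a, b = peaks[i], peaks[i + 1]
            cyc_dbp = float(x[a:b + 1].min())
            pi = (b - a) / fs * 1000.0
            if map_method == "integral":
                m = float((ct[b] - ct[a]) / ((b - a) / fs))
            elif map_method == "onethird":
                m = cyc_dbp + (pk_sbp[i] - cyc_dbp) / 3.0
            else:
                raise AnalysisError(f"unknown map_method {map_method!r}")
            fl = FLAG_OK
            if not (PI_RANGE_MS[0] < pi < PI_RANGE_MS[1]):
                fl |= FLAG_PI_RANGE
            if pk_sbp[i] <= cyc_dbp:
                fl |= FLAG_NONPHYS
            dbps.append(cyc_dbp)
            maps.append(m)
            pis.append(pi)
            flags.append(fl)
        # the last peak of the segment opens a cross-segment interval
        times.extend(pk_t)
        sbps.extend(pk_sbp)
        seg_ids.extend([seg_idx] * len(peaks))
        if seg_idx < len(rec.segments) - 1:
            dbps.append(math.nan)
            maps.append(math.nan)
            pis.append(math.nan)
            flags.append(FLAG_CROSS_SEGMENT)
    if not times:
        if last_err is not None:
            raise NoBeatsError(f"no segment yielded beats ({last_err})")
        raise NoBeatsError("no beats detected in any segment")
    n = len(times)
    # trailing cross-segment placeholders may overrun when final segments failed
    dbps, maps, pis, flags = (np.asarray(v, dtype=float)[:n - 1]
                              for v in (dbps, maps, pis, flags))
    return BeatSeries(animal_id=rec.animal_id, group=rec.group,
                      beat_times=np.asarray(times), sbp=np.asarray(sbps),
                      dbp=dbps, map=maps, pi_ms=pis,
                      flags=flags.astype(np.int64), seg_id=np.asarray(seg_ids),
                      start_clock_h=rec.start_clock_h,
                      meta={"n_failed_segments": n_failed,
                            "map_method": map_method})


def compute_map(rec: WaveformRecording, beats: BeatSeries,
                method: str = "integral") -> np.ndarray:
    """Recompute per-cycle MAP from the waveform.

    ``integral`` (default) is the trapezoidal time-average between
    consecutive systolic peaks; ``onethird`` is the classic
    DBP + pulse-pressure/3 formula, offered for cross-checks.
    """
    fs = rec.sampling_rate
    out = np.full(beats.n_beats - 1, np.nan)
    seg_lookup = {}
    for seg_idx, (t0, x) in enumerate(rec.segments):
        x = np.asarray(x, dtype=float)
        seg_lookup[seg_idx] = (t0, x, cumulative_trapezoid(x, dx=1.0 / fs, initial=0.0))
    for i in range(beats.n_beats - 1):
        if beats.flags[i] & FLAG_CROSS_SEGMENT:
            continue
        seg_idx = int(beats.seg_id[i])
        t0, x, ct = seg_lookup[seg_idx]
        a = int(round((beats.beat_times[i] - t0) * fs))
        b = int(round((beats.beat_times[i + 1] - t0) * fs))
        if a < 0 or b >= len(x) or b - a < 2:
            continue  # degenerate or out-of-segment window: MAP absent
        if method == "integral":
            out[i] = (ct[b] - ct[a]) / ((b - a) / fs)
        elif method == "onethird":
            out[i] = beats.dbp[i] + (beats.sbp[i] - beats.dbp[i]) / 3.0
        else:
            raise AnalysisError(f"unknown method {method!r}")
    return out


def derive_hr(beats: BeatSeries) -> np.ndarray:
    """Per-cycle heart rate HR = 60000 / PI (bpm); NaN where rejected."""
    if beats.n_beats < 2:
        raise AnalysisError("need at least one pulse interval")
    return beats.hr_bpm()


@dataclass
class EpochSummary:
    """Per-epoch and per-phase summaries for one animal."""

    animal_id: str
    group: str
    per_epoch: pd.DataFrame        # epoch, start_clock_h, phase, sbp..activity
    phase_stats: pd.DataFrame      # (variable, phase) -> mean, sem, n_epochs
    flags: dict

    def phase_mean(self, variable: str, phase: str) -> float:
        sel = self.phase_stats
        row = sel[(sel["variable"] == variable) & (sel["phase"] == phase)]
        return float(row["mean"].iloc[0]) if len(row) else math.nan


_VARS = ["sbp", "dbp", "map", "hr", "activity"]


def aggregate_epochs(beats: BeatSeries, activity_counts=None,
                     lights_on: float = 6.0,
                     epoch_interval_s: float = 300.0) -> EpochSummary:
    """Aggregate beats (and activity) into epoch and day/night summaries.

    Epochs are ``epoch_interval_s`` bins from recording time zero.  An epoch
    is day if its start clock hour falls in the 12 h after ``lights_on``.
    Phase values are means over usable epochs; the overall value is the
    phase means weighted by usable-epoch counts, so with an empty phase it
    reduces to the other phase's mean (flagged low-coverage).
    """
    if beats.n_beats < 2:
        raise AnalysisError("need at least one pulse interval to aggregate")
    t = beats.beat_times[:-1]
    ok = beats.accepted
    epoch = np.floor(t / epoch_interval_s).astype(int)
    hr = beats.hr_bpm()
    df = pd.DataFrame({"epoch": epoch, "sbp": beats.sbp[:-1],
                       "dbp": beats.dbp, "map": beats.map, "hr": hr,
                       "ok": ok})
    g = df[df["ok"]].groupby("epoch")
    per_epoch = g[["sbp", "dbp", "map", "hr"]].mean()
    per_epoch["n_beats"] = g.size()
    per_epoch = per_epoch.reset_index()
    start_h = beats.start_clock_h + per_epoch["epoch"] * epoch_interval_s / 3600.0
    clock = start_h % 24.0
    per_epoch["start_clock_h"] = start_h
    per_epoch["phase"] = np.where(((clock - lights_on) % 24.0) < 12.0,
                                  "day", "night")
    if activity_counts is not None:
        act = np.asarray(activity_counts, dtype=float)
        mins_per_epoch = epoch_interval_s / 60.0
        act_epoch = []
        for e in per_epoch["epoch"]:
            a = int(e * mins_per_epoch)
            b = int((e + 1) * mins_per_epoch)
            chunk = act[a:min(b, len(act))]
            act_epoch.append(chunk.mean() if len(chunk) else np.nan)
        per_epoch["activity"] = act_epoch
    else:
        per_epoch["activity"] = np.nan

    expected_per_phase = None
    span_s = beats.beat_times[-1] - beats.beat_times[0]
    if span_s >= 86400.0:
        expected_per_phase = (span_s / epoch_interval_s) / 2.0

    rows = []
    flags = {}
    phase_frames = {p: per_epoch[per_epoch["phase"] == p] for p in ("day", "night")}
    for p, sub in phase_frames.items():
        if expected_per_phase and len(sub) < 0.5 * expected_per_phase:
            flags[f"{p}_low_coverage"] = True
    if len(phase_frames["day"]) == 0:
        flags["day_low_coverage"] = True
    if len(phase_frames["night"]) == 0:
        flags["night_low_coverage"] = True
    for var in _VARS:
        stats = {}
        for p, sub in phase_frames.items():
            vals = sub[var].dropna().to_numpy()
            n = len(vals)
            mean = vals.mean() if n else math.nan
            sem = vals.std(ddof=1) / math.sqrt(n) if n > 1 else (0.0 if n == 1 else math.nan)
            stats[p] = (mean, sem, n)
            rows.append({"variable": var, "phase": p, "mean": mean,
                         "sem": sem, "n_epochs": n})
        (md, sd, nd), (mn, sn, nn) = stats["day"], stats["night"]
        if nd + nn > 0:
            wsum = (0.0 if nd == 0 else md * nd) + (0.0 if nn == 0 else mn * nn)
            overall = wsum / (nd + nn)
        else:
            overall = math.nan
        both = per_epoch[var].dropna().to_numpy()
        sem_o = both.std(ddof=1) / math.sqrt(len(both)) if len(both) > 1 else math.nan
        rows.append({"variable": var, "phase": "overall", "mean": overall,
                     "sem": sem_o, "n_epochs": nd + nn})
    phase_stats = pd.DataFrame(rows)
    return EpochSummary(animal_id=beats.animal_id, group=beats.group,
                        per_epoch=per_epoch, phase_stats=phase_stats,
                        flags=flags)
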
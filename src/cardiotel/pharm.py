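"""Quantification of BP/HR responses to autonomic blockade.

Baseline is the mean over a 1200 s frame ending at the injection; the
post-injection MAP and HR series are resampled to 1 Hz, smoothed with a
30 s moving average (so a single noisy beat cannot define the extremum),
and the nadir is the largest smoothed excursion from baseline inside the
7-12 minute post-injection window.  The same time ranges are used for both
variables.  Deltas are ``nadir - baseline`` exactly, so a depressor
response is negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beatproc import BeatSeries
from .errors import AnalysisError

__all__ = ["DrugResponse", "quantify_drug_response"]


@dataclass
class DrugResponse:
    animal_id: str
    group: str
    baseline_map: float
    baseline_hr: float
    nadir_map: float
    nadir_hr: float
    delta_map: float               # mmHg, nadir - baseline
    delta_hr: float                # bpm
    nadir_time_map_s: float        # relative to injection
    nadir_time_hr_s: float
    injection_time_s: float
    nadir_window_s: tuple
    #: per-variable deltas over the two disjoint 1200 s post frames
    frame_deltas: dict = field(default_factory=dict)


def _grid_series(times: np.ndarray, values: np.ndarray, t0: float,
                 t1: float, grid_hz: float, max_gap_s: float):
    """Beat series -> uniform grid by per-bin beat averaging.

    Every grid sample is the mean of the beats falling in its bin (so beat
    noise is reduced rather than sampled); empty bins are interpolated from
    their neighbours.
    """
    tg = np.arange(t0, t1, 1.0 / grid_hz)
    keep = np.isfinite(values)
    ts, vs = times[keep], values[keep]
    if len(ts) < 2:
        raise AnalysisError("not enough usable beats around the event")
    gaps = np.diff(ts)
    if np.any(gaps > max_gap_s):
        bad = ts[:-1][gaps > max_gap_s][0]
        raise AnalysisError(f"data gap of >{max_gap_s:.0f} s at t={bad:.0f} s")
    if ts[0] > t0 or ts[-1] < t1 - 1.0 / grid_hz:
        raise AnalysisError("beats do not cover the requested analysis span")
    bins = np.floor((ts - t0) * grid_hz).astype(int)
    inside = (bins >= 0) & (bins < len(tg))
    sums = np.bincount(bins[inside], weights=vs[inside], minlength=len(tg))
    counts = np.bincount(bins[inside], minlength=len(tg))
    vg = np.full(len(tg), np.nan)
    nz = counts > 0
    vg[nz] = sums[nz] / counts[nz]
    if not nz.all():
        vg[~nz] = np.interp(tg[~nz], tg[nz], vg[nz])
    return tg, vg


def quantify_drug_response(beats: BeatSeries, injection_time_s: float,
                           nadir_window_s: tuple = (420.0, 720.0),
                           baseline_s: float = 1200.0,
                           smooth_s: float = 30.0,
                           grid_hz: float = 1.0,
                           max_gap_s: float = 30.0) -> DrugResponse:
    """Quantify the MAP and HR response to an injection event.

    Requires continuous beat-by-beat data with at least 20 min before and
    15 min after the injection.  ``nadir_window_s`` is relative to the
    injection (default 7-12 min).
    """
    lo, hi = nadir_window_s
    if not (0 < lo < hi):
        raise AnalysisError("invalid nadir window")
    t = beats.beat_times[:-1]
    if injection_time_s < t[0] or injection_time_s > beats.beat_times[-1]:
        raise AnalysisError("injection time outside the recording")
    if injection_time_s - t[0] < 1200.0:
        raise AnalysisError("need >= 20 min of pre-injection data")
    if beats.beat_times[-1] - injection_time_s < 900.0:
        raise AnalysisError("need >= 15 min of post-injection data")
    base0 = injection_time_s - baseline_s
    if base0 < t[0]:
        raise AnalysisError("baseline frame starts before the recording")

    hr = beats.hr_bpm()
    mp = np.where(beats.accepted, beats.map, np.nan)
    end = min(float(beats.beat_times[-1]),
              injection_time_s + max(hi + smooth_s, 2400.0))
    results = {}
    k = max(1, int(round(smooth_s * grid_hz)))
    kern = np.ones(k) / k
    for name, vals in (("map", mp), ("hr", hr)):
        tg, vg = _grid_series(t, vals, base0, end, grid_hz, max_gap_s)
        baseline = float(vg[(tg >= base0) & (tg < injection_time_s)].mean())
        sm = np.convolve(vg, kern, mode="same")
        inwin = (tg >= injection_time_s + lo) & (tg <= injection_time_s + hi)
        if not inwin.any():
            raise AnalysisError("no samples inside the nadir window")
        dev = sm[inwin] - baseline
        i_ext = int(np.argmax(np.abs(dev)))
        nadir = float(sm[inwin][i_ext])
        t_nadir = float(tg[inwin][i_ext] - injection_time_s)
        frames = {}
        for fi in range(2):
            f0 = injection_time_s + fi * 1200.0
            f1 = f0 + 1200.0
            m = (tg >= f0) & (tg < f1)
            frames[f"frame{fi + 1}"] = (float(vg[m].mean()) - baseline
                                        if m.any() else math.nan)
        results[name] = (baseline, nadir, t_nadir, frames)

    b_map, n_map, tn_map, fr_map = results["map"]
    b_hr, n_hr, tn_hr, fr_hr = results["hr"]
    return DrugResponse(
        animal_id=beats.animal_id, group=beats.group,
        baseline_map=b_map, baseline_hr=b_hr,
        nadir_map=n_map, nadir_hr=n_hr,
        delta_map=n_map - b_map, delta_hr=n_hr - b_hr,
        nadir_time_map_s=tn_map, nadir_time_hr_s=tn_hr,
        injection_time_s=injection_time_s, nadir_window_s=(lo, hi),
        frame_deltas={"map": fr_map, "hr": fr_hr})
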
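"""Frequency- and time-domain cardiovascular variability and baroreflex
sensitivity.

The spectral chain mirrors the classical murine protocol: beat-indexed
systolic pressure and pulse-interval series are cubic-interpolated and
resampled at 12 Hz, linearly detrended, and analysed with Welch's method
(512-point Hanning-windowed FFT segments, 50% overlap, one-sided density
normalisation).  Up to five representative windows are selected per
recording under steady-state / no-jump / no-artifact criteria and their
spectra averaged.  Band powers integrate the PSD over the murine LF
(0.25-1.0 Hz) and HF (1.0-6.0 Hz) bands, half-open at the shared 1.0 Hz
edge.

Baroreflex sensitivity is estimated two ways:

* cross-spectral (BRS-LF): mean transfer gain ``|S_xy| / S_xx`` between
  SBP and PI over the LF band, pooled over the selected windows, accepted
  only when the mean LF magnitude-squared coherence reaches the threshold
  (default 0.8);
* sequence method: least-squares PI-vs-SBP slopes over spontaneous runs of
  >= 3 beats with concordant monotone SBP (>= 1 mmHg/beat) and lagged PI
  (>= 1 ms/beat) changes, kept when r >= 0.85; up- and down-ramps are
  averaged separately (sequp / seqdown).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import csd as _csd
from scipy.signal import welch as _welch

from .beatproc import BeatSeries
from .errors import AnalysisError, SegmentSelectionError

__all__ = [
    "SpectralParams", "UniformSeries", "SpectralSummary", "SequenceBRSResult",
    "select_segments", "resample_series", "welch_psd", "band_power", "rmssd",
    "cross_spectral_brs", "sequence_brs", "spectral_summary",
]


@dataclass(frozen=True)
class SpectralParams:
    """Tunable spectral/BRS analysis parameters (defaults per protocol)."""

    resample_hz: float = 12.0
    nfft: int = 512
    overlap: float = 0.5
    lf_band: tuple = (0.25, 1.0)
    hf_band: tuple = (1.0, 6.0)
    coherence_threshold: float = 0.8
    n_segments: int = 5
    window_s: float = 60.0          # selected-window length; 720 samples at 12 Hz
    max_trend_mmhg_per_beat: float = 0.05
    max_jump_mmhg: float = 15.0
    seq_min_beats: int = 3
    seq_delta_sbp: float = 1.0      # mmHg per beat
    seq_delta_pi: float = 1.0       # ms per beat
    seq_min_r: float = 0.85
    seq_lag: int = 1                # beats of PI delay relative to SBP

    def validate(self):
        if not (0 < self.coherence_threshold <= 1.0):
            raise AnalysisError("coherence_threshold must be in (0, 1]")
        if self.lf_band[0] >= self.lf_band[1] or self.hf_band[0] >= self.hf_band[1]:
            raise AnalysisError("band edges must be increasing")
        if self.window_s * self.resample_hz < self.nfft:
            raise AnalysisError("window_s too short for the FFT length")
        if self.seq_lag not in (0, 1):
            raise AnalysisError("seq_lag must be 0 or 1")


@dataclass
class UniformSeries:
    """Uniformly resampled, detrended series ready for spectral analysis."""

    values: np.ndarray
    rate: float
    t0: float
    variable: str = ""
    trend: tuple = (0.0, 0.0)      # removed linear trend (intercept, slope/s)

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise AnalysisError("uniform series must be finite")

    def __len__(self):
        return len(self.values)


@dataclass
class SpectralSummary:
    """Per-animal variability metrics."""

    animal_id: str
    group: str
    lf_pi: float                   # ms^2
    hf_pi: float                   # ms^2
    lf_hf_ratio: float
    lf_sbp: float                  # mmHg^2 (LFsys)
    rmssd: float                   # ms
    brs_lf: float | None           # ms/mmHg; None when coherence gate fails
    mean_coherence_lf: float
    n_segments_used: int
    lf_band: tuple
    hf_band: tuple
    brs_sequp: float = math.nan
    brs_seqdown: float = math.nan
    n_seq_up: int = 0
    n_seq_down: int = 0


@dataclass
class SequenceBRSResult:
    slope_up: float                # ms/mmHg, NaN when no up-sequences
    slope_down: float
    n_up: int
    n_down: int
    #: per-sequence records: (start beat index, length, direction, slope, r)
    sequences: list = field(default_factory=list)


def _valid_runs(beats: BeatSeries):
    """Contiguous runs of beats whose cycles are all accepted."""
    ok = beats.accepted
    runs = []
    start = None
    for i, v in enumerate(ok):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))      # cycles [start, i) valid
            start = None
    if start is not None:
        runs.append((start, len(ok)))
    return runs


def select_segments(beats: BeatSeries, params: SpectralParams | None = None,
                    n_target: int | None = None) -> list:
    """Choose up to ``n_target`` representative, non-overlapping windows.

    Candidate windows of ``window_s`` seconds must be steady-state (absolute
    SBP linear trend below ``max_trend_mmhg_per_beat``), free of sudden
    pressure changes (no beat-to-beat SBP jump above ``max_jump_mmhg``) and
    artifact-free (no flagged cycle).  Qualifying windows are ranked by how
    close their SBP variance lies to the median candidate variance, a
    representativeness proxy, and picked greedily without overlap.

    Returns a list of ``(i0, i1)`` beat-index windows (peaks ``i0..i1-1``).
    """
    params = params or SpectralParams()
    params.validate()
    if n_target is None:
        n_target = params.n_segments
    t = beats.beat_times
    counts = {"too_short": 0, "trend": 0, "jump": 0, "artifact": 0}
    candidates = []
    stride_s = params.window_s / 4.0
    # candidate start times on a fixed stride (quarter-window)
    start_times = np.arange(t[0], t[-1] - params.window_s + 1e-9, stride_s)
    for t0 in start_times:
        i0 = int(np.searchsorted(t, t0, side="left"))
        i1 = int(np.searchsorted(t, t0 + params.window_s, side="right"))
        if i1 - i0 < 4 or t[i1 - 1] - t[i0] < params.window_s * 0.95:
            counts["too_short"] += 1
            continue
        if i1 > beats.n_beats:
            continue
        sbp = beats.sbp[i0:i1]
        if np.any(beats.flags[i0:max(i0, min(i1 - 1, len(beats.flags)))] != 0):
            counts["artifact"] += 1
            continue
        if np.max(np.abs(np.diff(sbp))) > params.max_jump_mmhg:
            counts["jump"] += 1
            continue
        idx = np.arange(i1 - i0, dtype=float)
        slope = np.polyfit(idx, sbp, 1)[0]
        if abs(slope) > params.max_trend_mmhg_per_beat:
            counts["trend"] += 1
            continue
        candidates.append((i0, i1, float(np.var(sbp))))
    if not candidates:
        raise SegmentSelectionError(
            "no window satisfies the segment-selection criteria", counts)
    med = float(np.median([v for _, _, v in candidates]))
    order = sorted(candidates, key=lambda c: (abs(c[2] - med), c[0]))
    chosen: list[tuple[int, int]] = []
    for i0, i1, _ in order:
        if any(i0 < j1 and j0 < i1 for j0, j1 in chosen):
            continue
        chosen.append((i0, i1))
        if len(chosen) >= n_target:
            break
    chosen.sort()
    return chosen


def resample_series(beats: BeatSeries, variable: str, window: tuple,
                    rate: float = 12.0) -> UniformSeries:
    """Cubic-interpolate a beat-indexed variable onto a uniform grid and
    remove its least-squares linear trend.

    ``variable`` is ``"sbp"`` (value at each systolic peak) or ``"pi"``
    (interval opened by each peak, in ms).
    """
    i0, i1 = window
    t = beats.beat_times[i0:i1]
    if variable == "sbp":
        y = beats.sbp[i0:i1]
    elif variable == "pi":
        stop = min(i1, beats.n_beats - 1)
        t = beats.beat_times[i0:stop]
        y = beats.pi_ms[i0:stop]
    else:
        raise AnalysisError(f"unknown variable {variable!r}")
    if len(t) < 4:
        raise AnalysisError("window has fewer than 4 beats")
    if np.any(np.diff(t) <= 0):
        raise AnalysisError("non-monotone beat times")
    if np.any(~np.isfinite(y)):
        raise AnalysisError("window contains rejected beats")
    spline = CubicSpline(t, y)
    n = int(math.floor((t[-1] - t[0]) * rate)) + 1
    tu = t[0] + np.arange(n) / rate
    vals = spline(tu)
    a, b = np.polynomial.polynomial.polyfit(tu - tu[0], vals, 1)
    vals = vals - (a + b * (tu - tu[0]))
    return UniformSeries(values=vals, rate=rate, t0=float(t[0]),
                         variable=variable, trend=(float(a), float(b)))


def _welch_args(params: SpectralParams):
    nov = int(round(params.nfft * params.overlap))
    return dict(window="hann", nperseg=params.nfft, noverlap=nov,
                detrend="constant", scaling="density", return_onesided=True)


def welch_psd(series: UniformSeries, params: SpectralParams | None = None):
    """One-sided Welch PSD (Hanning, 512-point segments, 50% overlap).

    Density scaling compensates the window power, so the integral of the
    PSD over [0, Nyquist] recovers the series variance for broadband input.
    """
    params = params or SpectralParams()
    if len(series) < params.nfft:
        raise AnalysisError(
            f"series of {len(series)} samples shorter than the FFT length "
            f"{params.nfft}; use a longer window")
    f, p = _welch(series.values, fs=series.rate, **_welch_args(params))
    return f, p


def band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple) -> float:
    """Trapezoidal integral of the PSD over ``[f_lo, f_hi)``.

    Half-open on the right so the 1.0 Hz edge shared by the LF and HF bands
    is counted once (in LF).
    """
    lo, hi = band
    if hi <= lo:
        raise AnalysisError("inverted band")
    if lo < 0 or hi > freqs[-1] + 1e-12:
        raise AnalysisError("band outside the resolved frequency range")
    m = (freqs >= lo) & (freqs < hi)
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[m], freqs[m]))


def rmssd(pi_ms: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Root mean square of successive differences of accepted pulse
    intervals (ms), computed on the raw beat-indexed series.

    Pairs spanning a rejected interval are excluded.  Returns NaN when
    fewer than two usable adjacent intervals remain.
    """
    pi = np.asarray(pi_ms, dtype=float)
    if valid is None:
        valid = np.isfinite(pi)
    pair_ok = valid[:-1] & valid[1:]
    d = np.diff(pi)[pair_ok]
    if len(d) < 1:
        return math.nan
    return float(np.sqrt(np.mean(d ** 2)))


def cross_spectral_brs(sbp: UniformSeries, pi: UniformSeries,
                       params: SpectralParams | None = None):
    """Transfer gain and coherence between one SBP/PI window pair.

    Returns ``(freqs, gain, coherence, phase)`` with gain
    ``|S_xy(f)| / S_xx(f)`` (ms/mmHg) from Welch cross-spectra sharing the
    PSD segmentation.  For pooled multi-window estimates use
    :func:`spectral_summary`, which averages the auto- and cross-spectra
    before forming the ratio.
    """
    params = params or SpectralParams()
    if len(sbp) != len(pi) or sbp.rate != pi.rate:
        raise AnalysisError("SBP and PI windows must share grid and length")
    f, pxx, pyy, pxy = _window_spectra(sbp, pi, params)
    gain = np.abs(pxy) / pxx
    coh = np.abs(pxy) ** 2 / (pxx * pyy)
    phase = np.angle(pxy)
    return f, gain, coh, phase


def _window_spectra(sbp: UniformSeries, pi: UniformSeries,
                    params: SpectralParams):
    if len(sbp) < params.nfft:
        raise AnalysisError("window shorter than the FFT length")
    args = _welch_args(params)
    f, pxx = _welch(sbp.values, fs=sbp.rate, **args)
    _, pyy = _welch(pi.values, fs=pi.rate, **args)
    _, pxy = _csd(sbp.values, pi.values, fs=sbp.rate, **args)
    return f, pxx, pyy, pxy


def _mean_band(freqs, values, band):
    lo, hi = band
    m = (freqs >= lo) & (freqs < hi)
    return float(np.mean(values[m])) if m.any() else math.nan


def sequence_brs(beats: BeatSeries, params: SpectralParams | None = None
                 ) -> SequenceBRSResult:
    """Sequence-method spontaneous baroreflex sensitivity.

    Scans for maximal runs of >= ``seq_min_beats`` consecutive beats whose
    SBP rises (falls) by at least ``seq_delta_sbp`` every beat while the
    pulse interval, delayed by ``seq_lag`` beats, rises (falls) by at least
    ``seq_delta_pi``.  Each run's slope is the least-squares regression of
    the lagged PI on SBP; runs with correlation below ``seq_min_r`` are
    discarded.  Reported slopes are plain means over the kept up/down runs.
    """
    params = params or SpectralParams()
    params.validate()
    lag = params.seq_lag
    sbp = np.asarray(beats.sbp, dtype=float)
    pi = np.asarray(beats.pi_ms, dtype=float)
    n = beats.n_beats
    # The PI paired with beat i is pi[i + lag]: the interval opened by peak i
    # for lag 0, or by the following peak for lag 1 (a one-beat reflex delay,
    # the fast vagal convention).
    q = lambda i: i + lag

    def _step_ok(m, sign):
        """Condition on the step from beat m to beat m+1."""
        ka, kb = q(m), q(m + 1)
        if ka < 0 or kb >= len(pi):
            return False
        if not (np.isfinite(pi[ka]) and np.isfinite(pi[kb])):
            return False
        return (sign * (sbp[m + 1] - sbp[m]) >= params.seq_delta_sbp
                and sign * (pi[kb] - pi[ka]) >= params.seq_delta_pi)

    sequences = []
    for direction, sign in (("up", 1.0), ("down", -1.0)):
        steps = np.fromiter((_step_ok(m, sign) for m in range(n - 1)),
                            dtype=bool, count=n - 1)
        m = 0
        while m < n - 1:
            if not steps[m]:
                m += 1
                continue
            a = m
            while m < n - 1 and steps[m]:
                m += 1
            b = m  # maximal run covers beats a..b (b - a steps)
            run_len = b - a + 1
            if run_len >= params.seq_min_beats:
                xs = sbp[a:b + 1]
                ys = pi[[q(i) for i in range(a, b + 1)]]
                if xs.std() > 0 and ys.std() > 0:
                    r = float(np.corrcoef(xs, ys)[0, 1])
                else:
                    r = 0.0
                slope = float(np.polyfit(xs, ys, 1)[0])
                if r >= params.seq_min_r:
                    sequences.append((a, run_len, direction, slope, r))
    ups = [s[3] for s in sequences if s[2] == "up"]
    downs = [s[3] for s in sequences if s[2] == "down"]
    return SequenceBRSResult(
        slope_up=float(np.mean(ups)) if ups else math.nan,
        slope_down=float(np.mean(downs)) if downs else math.nan,
        n_up=len(ups), n_down=len(downs), sequences=sequences)


def spectral_summary(beats: BeatSeries, params: SpectralParams | None = None
                     ) -> SpectralSummary:
    """Full per-animal variability panel.

    Selects up to five representative windows, averages their Welch auto-
    and cross-spectra, integrates the LF/HF band powers, computes RMSSD on
    the raw pulse intervals of the selected windows, the coherence-gated
    cross-spectral BRS-LF, and the sequence-method slopes over the whole
    recording.
    """
    params = params or SpectralParams()
    params.validate()
    windows = select_segments(beats, params)
    pxx_l, pyy_l, pxy_l = [], [], []
    f = None
    rms_parts = []
    for w in windows:
        su = resample_series(beats, "sbp", w, params.resample_hz)
        pu = resample_series(beats, "pi", w, params.resample_hz)
        m = min(len(su), len(pu))
        su.values = su.values[:m]
        pu.values = pu.values[:m]
        f, pxx, pyy, pxy = _window_spectra(su, pu, params)
        pxx_l.append(pxx)
        pyy_l.append(pyy)
        pxy_l.append(pxy)
        stop = min(w[1], beats.n_beats - 1)
        rms_parts.append((beats.pi_ms[w[0]:stop],
                          beats.accepted[w[0]:stop]))
    pxx = np.mean(pxx_l, axis=0)
    pyy = np.mean(pyy_l, axis=0)
    pxy = np.mean(pxy_l, axis=0)
    gain = np.abs(pxy) / pxx
    coh = np.abs(pxy) ** 2 / (pxx * pyy)

    lf_pi = band_power(f, pyy, params.lf_band)
    hf_pi = band_power(f, pyy, params.hf_band)
    lf_sbp = band_power(f, pxx, params.lf_band)
    ratio = lf_pi / hf_pi if hf_pi > 0 else math.nan
    mean_coh = _mean_band(f, coh, params.lf_band)
    brs = _mean_band(f, gain, params.lf_band)
    brs_valid = mean_coh >= params.coherence_threshold

    pis = np.concatenate([p for p, _ in rms_parts])
    oks = np.concatenate([o for _, o in rms_parts])
    rms = rmssd(pis, oks)

    seq = sequence_brs(beats, params)
    return SpectralSummary(
        animal_id=beats.animal_id, group=beats.group,
        lf_pi=lf_pi, hf_pi=hf_pi, lf_hf_ratio=ratio, lf_sbp=lf_sbp,
        rmssd=rms, brs_lf=brs if brs_valid else None,
        mean_coherence_lf=mean_coh, n_segments_used=len(windows),
        lf_band=params.lf_band, hf_band=params.hf_band,
        brs_sequp=seq.slope_up, brs_seqdown=seq.slope_down,
        n_seq_up=seq.n_up, n_seq_down=seq.n_down)
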
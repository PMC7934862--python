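"""Synthetic arterial-pressure telemetry with known autonomic structure.

The generator produces beat-to-beat hemodynamics from a DeBoer-style
closed-loop recursion and renders them as 1000 Hz pressure waveforms under
either an epochal (10 s every 5 min) or continuous acquisition scheme.

Model
-----
At beat *n*, occurring at systolic-peak time ``t_n``:

.. math::

    SBP_n = M(t_n) + A_{LF} \\sin(2\\pi f_{LF} t_n)
            + A_{HF,s} \\sin(2\\pi f_{HF} t_n) + \\epsilon_n

    PI_n = PI_0(t_n) + G (SBP_{n-lag} - M(t_n))
           + A_{HF} \\sin(2\\pi f_{HF} t_n) + \\eta_n

where ``M(t)`` is the circadian systolic mesor track, ``PI_0(t)`` the
circadian pulse-interval track (``60000 / HR(t)``), ``G`` the ground-truth
baroreflex gain in ms/mmHg, and the next beat occurs ``PI_n`` ms later.
Diastolic pressure tracks systolic pressure at a fixed pulse pressure, so
the true per-beat MAP is ``DBP + MAP_FRACTION * PP`` (the time-average of
the rendered pulse shape).

The linear SBP->PI coupling makes the ground-truth gain well-defined for
both baroreflex-sensitivity estimators (sequence and cross-spectral), and
the oscillator centre frequencies sit mid-band (0.4 Hz Mayer wave,
2.5 Hz respiration) so their power lands inside the murine LF
(0.25-1.0 Hz) and HF (1.0-6.0 Hz) bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import (MAP_FRACTION, UPSTROKE_FRACTION, GroupParams, SimConfig,
                     decay_shape)
from .errors import ConfigError, RenderError

__all__ = [
    "GroundTruthBeats", "SimulatedAnimal", "TelemetryStudy",
    "simulate_beat_series", "render_waveform", "apply_drug_event",
    "simulate_telemetry_study", "iter_study_animals", "simulate_activity",
    "truth_to_beat_series", "brs_validation_config",
]

_TWO_PI = 2.0 * math.pi


@dataclass
class GroundTruthBeats:
    """Ground-truth per-beat series.

    ``beat_times`` are systolic-peak times in seconds; ``pi`` (ms) are the
    successive peak-to-peak differences, so ``len(pi) == len(beat_times) - 1``
    and ``pi == diff(beat_times) * 1000`` exactly.
    """

    beat_times: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    map: np.ndarray
    pi: np.ndarray
    group: str = ""
    animal_index: int = 0
    config: SimConfig | None = None

    def __post_init__(self):
        n = len(self.beat_times)
        if n < 1:
            raise ConfigError("a beat series needs at least one beat")
        if len(self.pi) != n - 1:
            raise ConfigError("pi must have one fewer element than beat_times")
        if n > 1:
            dt = np.diff(self.beat_times)
            if np.any(dt <= 0):
                raise ConfigError("beat_times must be strictly increasing")
            if not np.allclose(self.pi, dt * 1000.0, rtol=0, atol=1e-9):
                raise ConfigError("pi inconsistent with beat_times")
        if np.any(self.sbp <= self.dbp):
            raise ConfigError("sbp must exceed dbp elementwise")

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])


def _circadian_cos(cfg: SimConfig, t_s: np.ndarray | float):
    return np.cos(_TWO_PI * (cfg.clock_h(t_s) - cfg.acrophase) / 24.0)


def simulate_beat_series(config: SimConfig, group: str, animal_index: int,
                         *, t_start_s: float = 0.0,
                         duration_s: float | None = None,
                         rng: np.random.Generator | None = None
                         ) -> GroundTruthBeats:
    """Run the beat-to-beat recursion over ``[t_start, t_start + duration)``.

    The per-animal random stream is seeded from ``(config.seed, group index,
    animal_index)`` unless an explicit generator is passed, so identical
    configurations are bit-identical across runs.
    """
    if group not in config.groups:
        raise ConfigError(f"unknown group {group!r}")
    gp = config.groups[group]
    if duration_s is None:
        duration_s = config.duration_s
    if duration_s <= 0:
        raise ConfigError("duration must be positive")
    if rng is None:
        gi = sorted(config.groups).index(group)
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, gi, animal_index])

    hr_max = gp.mean_hr + abs(config.circadian_amp_hr) + 60.0
    n_max = int(duration_s * hr_max / 60.0) + 8
    eps = rng.normal(0.0, config.sbp_noise_sd, n_max) if config.sbp_noise_sd > 0 else np.zeros(n_max)
    eta = rng.normal(0.0, config.pi_noise_sd, n_max) if config.pi_noise_sd > 0 else np.zeros(n_max)

    lag = config.brs_lag
    w_lf = _TWO_PI * config.lf_freq
    w_hf = _TWO_PI * config.hf_freq
    amp_map = config.circadian_amp_map
    amp_hr = config.circadian_amp_hr
    acro = config.acrophase
    clock0 = config.start_clock_h
    cos = math.cos
    sin = math.sin

    times = np.empty(n_max)
    sbps = np.empty(n_max)
    pis = np.empty(n_max)
    t = t_start_s
    t_end = t_start_s + duration_s
    n = 0
    while t < t_end and n < n_max:
        circ = cos(_TWO_PI * ((clock0 + t / 3600.0) - acro) / 24.0)
        m = gp.mean_sbp + amp_map * circ
        s = (m + gp.lf_amp_sbp * sin(w_lf * t)
             + config.hf_amp_sbp * sin(w_hf * t) + eps[n])
        dev = (sbps[n - lag] - m) if n >= lag and lag > 0 else (s - m if lag == 0 else 0.0)
        hr_t = gp.mean_hr + amp_hr * circ
        p = (60000.0 / hr_t + gp.brs_gain * dev
             + config.hf_amp_pi * sin(w_hf * t) + eta[n])
        p = min(max(p, 50.0), 1000.0)  # physiological clamp, inert at defaults
        times[n] = t
        sbps[n] = s
        pis[n] = p
        t += p / 1000.0
        n += 1
    if n < 1:
        raise ConfigError("duration too short to place a single beat")

    times = times[:n]
    sbps = sbps[:n]
    # exact consistency: beat times already are cumulative sums of pi
    pi = np.diff(times) * 1000.0
    pp = gp.mean_sbp - gp.mean_dbp
    dbp = sbps - pp
    mean_map = dbp + MAP_FRACTION * pp
    return GroundTruthBeats(beat_times=times, sbp=sbps, dbp=dbp,
                            map=mean_map, pi=pi, group=group,
                            animal_index=animal_index, config=config)


def _drug_effect(t_s, injection_time_s: float, cfg: SimConfig):
    """Normalised effect profile: 0 before onset, ramp to 1 at the nadir
    time, plateau through the nadir window, linear recovery."""
    rel = (np.asarray(t_s, dtype=float) - injection_time_s) / 60.0
    onset, nadir = cfg.drug_onset_min, cfg.drug_nadir_min
    plateau_end, recovery = cfg.drug_plateau_end_min, cfg.drug_recovery_min
    e = np.zeros_like(rel)
    ramp = (rel > onset) & (rel < nadir)
    e[ramp] = (rel[ramp] - onset) / max(nadir - onset, 1e-12)
    e[(rel >= nadir) & (rel <= plateau_end)] = 1.0
    rec = (rel > plateau_end) & (rel < plateau_end + recovery)
    e[rec] = 1.0 - (rel[rec] - plateau_end) / recovery
    return e


def _drug_effect_scalar(t_s: float, injection_time_s: float,
                        cfg: SimConfig) -> float:
    rel = (t_s - injection_time_s) / 60.0
    if rel <= cfg.drug_onset_min:
        return 0.0
    if rel < cfg.drug_nadir_min:
        return (rel - cfg.drug_onset_min) / max(
            cfg.drug_nadir_min - cfg.drug_onset_min, 1e-12)
    if rel <= cfg.drug_plateau_end_min:
        return 1.0
    if rel < cfg.drug_plateau_end_min + cfg.drug_recovery_min:
        return 1.0 - (rel - cfg.drug_plateau_end_min) / cfg.drug_recovery_min
    return 0.0


def apply_drug_event(truth: GroundTruthBeats, config: SimConfig,
                     injection_time_s: float) -> GroundTruthBeats:
    """Superimpose a ganglionic-blockade-like depressor/bradycardic event.

    Pressures fall by ``drug_delta_map * e(t)``; heart rate falls by
    ``drug_delta_hr * e(t)`` (applied in the HR domain, then mapped back to
    pulse intervals), where ``e`` ramps from injection+onset to full effect
    at injection+``drug_nadir_min`` (inside the 7-12 min window), holds
    through the window and recovers linearly.  Beat times are rebuilt from
    the modified intervals.  With zero deltas the series is returned
    unchanged.
    """
    if truth.group not in config.groups:
        raise ConfigError(f"unknown group {truth.group!r}")
    gp = config.groups[truth.group]
    d_map, d_hr = gp.drug_delta_map, gp.drug_delta_hr
    if not (math.isfinite(d_map) and math.isfinite(d_hr)):
        raise ConfigError("drug deltas must be finite")
    t0, t_last = truth.beat_times[0], truth.beat_times[-1]
    if not (t0 <= injection_time_s <= t_last):
        raise ConfigError("injection time outside the recording")
    end_needed = injection_time_s + 60.0 * (config.drug_plateau_end_min
                                            + config.drug_recovery_min)
    if end_needed > t_last:
        raise ConfigError("drug window exceeds the recording")
    if d_map == 0.0 and d_hr == 0.0:
        return truth

    # Deterministic kinetics on the HR *track*, existing beat noise kept in
    # the PI domain: each interval is lengthened by the PI equivalent of the
    # drug-induced HR fall at that moment.  Bradycardia stretches the beat
    # grid, so the effect profile is evaluated on the output timeline via a
    # forward pass.
    n = truth.n_beats
    gp_cfg = truth.config if truth.config is not None else config
    amp_hr = gp_cfg.circadian_amp_hr
    acro = gp_cfg.acrophase
    clock0 = gp_cfg.start_clock_h
    times = np.empty(n)
    e_beat = np.empty(n)
    times[0] = truth.beat_times[0]
    for i in range(n - 1):
        e = _drug_effect_scalar(times[i], injection_time_s, config)
        e_beat[i] = e
        circ = math.cos(_TWO_PI * ((clock0 + times[i] / 3600.0) - acro) / 24.0)
        hr0 = gp.mean_hr + amp_hr * circ
        hr_drug = hr0 - d_hr * e
        if hr_drug <= 0:
            raise ConfigError("drug_delta_hr drives heart rate non-positive")
        pi_shift = 60000.0 / hr_drug - 60000.0 / hr0
        times[i + 1] = times[i] + (truth.pi[i] + pi_shift) / 1000.0
    e_beat[n - 1] = _drug_effect_scalar(times[n - 1], injection_time_s, config)
    sbp = truth.sbp - d_map * e_beat
    dbp = truth.dbp - d_map * e_beat
    map_ = truth.map - d_map * e_beat
    pi_new = np.diff(times) * 1000.0
    return GroundTruthBeats(beat_times=times, sbp=sbp, dbp=dbp, map=map_,
                            pi=pi_new, group=truth.group,
                            animal_index=truth.animal_index,
                            config=truth.config)


def render_waveform(truth: GroundTruthBeats, sampling_rate: float = 1000.0,
                    t_start: float | None = None,
                    t_end: float | None = None) -> np.ndarray:
    """Render the pressure waveform for ``[t_start, t_end)``.

    Each cycle between consecutive systolic peaks decays exponentially from
    the current peak to the next diastolic value over the first 2/3 of the
    interval, then rises to the next peak along a raised cosine.  The
    per-beat maxima/minima therefore equal the true SBP/DBP to within one
    sample of discretisation.  One virtual beat is padded at each end so
    requested windows slightly wider than the beat span stay covered.
    """
    if truth.n_beats < 2:
        raise RenderError("rendering needs at least two beats (one cycle)")
    if sampling_rate < 100.0:
        raise RenderError("sampling_rate must be >= 100 Hz")
    if np.any(truth.pi * sampling_rate / 1000.0 < 2.0):
        raise RenderError("pulse interval shorter than 2 samples")

    bt = truth.beat_times
    if t_start is None:
        t_start = float(bt[0])
    if t_end is None:
        t_end = float(bt[-1])
    if t_end <= t_start:
        raise RenderError("empty render window")
    pi_s = truth.pi / 1000.0
    bt_ext = np.concatenate([[bt[0] - pi_s[0]], bt, [bt[-1] + pi_s[-1]]])
    sbp_ext = np.concatenate([[truth.sbp[0]], truth.sbp, [truth.sbp[-1]]])
    dbp_ext = np.concatenate([[truth.dbp[0]], truth.dbp, [truth.dbp[-1]]])
    if t_start < bt_ext[0] or t_end > bt_ext[-1]:
        raise RenderError("render window extends beyond the padded beat span")

    n_samp = math.ceil((t_end - t_start) * sampling_rate)
    t = t_start + np.arange(n_samp) / sampling_rate
    idx = np.searchsorted(bt_ext, t, side="right") - 1
    idx = np.clip(idx, 0, len(bt_ext) - 2)
    cyc = bt_ext[idx + 1] - bt_ext[idx]
    u = (t - bt_ext[idx]) / cyc
    s_cur, s_nxt = sbp_ext[idx], sbp_ext[idx + 1]
    d_nxt = dbp_ext[idx + 1]
    decay_span = 1.0 - UPSTROKE_FRACTION
    out = np.empty(n_samp)
    dec = u < decay_span
    v = u[dec] / decay_span
    out[dec] = d_nxt[dec] + (s_cur[dec] - d_nxt[dec]) * decay_shape(v)
    up = ~dec
    w = (u[up] - decay_span) / UPSTROKE_FRACTION
    out[up] = d_nxt[up] + (s_nxt[up] - d_nxt[up]) * 0.5 * (1.0 - np.cos(math.pi * w))
    return out


def simulate_activity(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-minute Poisson activity counts with day/night rates."""
    n_min = int(round(config.duration_days * 1440))
    clock = (config.start_clock_h + np.arange(n_min) / 60.0) % 24.0
    day = ((clock - config.lights_on) % 24.0) < 12.0
    rates = np.where(day, config.activity_rate_day, config.activity_rate_night)
    return rng.poisson(rates).astype(np.int64)


@dataclass
class SimulatedAnimal:
    """One animal's simulated telemetry: waveform segments + truth + activity."""

    animal_id: str
    group: str
    sampling_rate: float
    mode: str
    #: list of (segment start time in s from study start, samples in mmHg)
    segments: list = field(default_factory=list)
    #: per-segment ground truth, aligned with ``segments``
    truth_segments: list = field(default_factory=list)
    activity_counts: np.ndarray | None = None
    start_clock_h: float = 6.0

    @property
    def segment_starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.segments])


def _simulate_animal(config: SimConfig, group: str, animal_index: int,
                     sampling_rate: float = 1000.0) -> SimulatedAnimal:
    gi = sorted(config.groups).index(group)
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, gi, animal_index])
    animal = SimulatedAnimal(animal_id=f"{group}{animal_index + 1:02d}",
                             group=group, sampling_rate=sampling_rate,
                             mode=config.sampling_mode,
                             start_clock_h=config.start_clock_h)
    if config.sampling_mode == "epochal":
        n_epochs = int(config.duration_s // config.epoch_interval_s)
        margin = 0.5  # s of extra beats so the window is fully covered
        for k in range(n_epochs):
            t0 = k * config.epoch_interval_s
            truth = simulate_beat_series(
                config, group, animal_index,
                t_start_s=t0 - margin,
                duration_s=config.epoch_duration_s + 2 * margin, rng=rng)
            samples = render_waveform(truth, sampling_rate, t_start=t0,
                                      t_end=t0 + config.epoch_duration_s)
            animal.segments.append((t0, samples))
            animal.truth_segments.append(truth)
    else:
        truth = simulate_beat_series(config, group, animal_index,
                                     t_start_s=0.0,
                                     duration_s=config.duration_s, rng=rng)
        samples = render_waveform(truth, sampling_rate)
        animal.segments.append((float(truth.beat_times[0]), samples))
        animal.truth_segments.append(truth)
    animal.activity_counts = simulate_activity(config, rng)
    return animal


def iter_study_animals(config: SimConfig, sampling_rate: float = 1000.0):
    """Yield ``SimulatedAnimal`` objects one at a time (memory-friendly)."""
    config.validate()
    for group in sorted(config.groups):
        for a in range(config.n_animals_per_group):
            yield _simulate_animal(config, group, a, sampling_rate)


@dataclass
class TelemetryStudy:
    config: SimConfig
    animals: list

    def by_group(self) -> dict[str, list]:
        out: dict[str, list] = {}
        for an in self.animals:
            out.setdefault(an.group, []).append(an)
        return out


def truth_to_beat_series(truth: GroundTruthBeats):
    """Repackage ground truth as a :class:`~cardiotel.beatproc.BeatSeries`.

    Skips rendering and detection — useful for validating the variability
    and baroreflex estimators directly against the generator.  The cycle
    opened by peak ``i`` carries the diastolic/MAP values of beat ``i + 1``,
    matching the detector's trough-before-next-peak convention.
    """
    from .beatproc import BeatSeries

    n = truth.n_beats
    return BeatSeries(
        animal_id=f"{truth.group}{truth.animal_index + 1:02d}",
        group=truth.group, beat_times=truth.beat_times, sbp=truth.sbp,
        dbp=truth.dbp[1:], map=truth.map[1:], pi_ms=truth.pi,
        flags=np.zeros(n - 1, dtype=np.int64),
        seg_id=np.zeros(n, dtype=np.int64),
        start_clock_h=truth.config.start_clock_h if truth.config else 6.0)


def brs_validation_config(gain: float, seed: int,
                          duration_s: float = 600.0) -> SimConfig:
    """Study conditions for baroreflex-estimator validation.

    A single-group continuous recording with strong Mayer-wave ramps
    (8 mmHg LF amplitude, so reflex pulse-interval changes comfortably
    exceed the 1 ms/beat sequence threshold at every gain in the validated
    range), small respiratory and measurement noise (0.5 ms HF amplitude,
    1 mmHg / 0.5 ms beat noise) and no circadian drift.  The sequence
    method is only defined in the regime where its thresholds do not bind;
    these conditions place every gain in that regime.
    """
    gp = GroupParams(brs_gain=gain, lf_amp_sbp=8.0)
    return SimConfig(seed=seed, groups={"G": gp}, sampling_mode="continuous",
                     duration_days=duration_s / 86400.0, hf_amp_pi=0.5,
                     sbp_noise_sd=1.0, pi_noise_sd=0.5,
                     circadian_amp_map=0.0, circadian_amp_hr=0.0,
                     n_animals_per_group=1)


def simulate_telemetry_study(config: SimConfig,
                             sampling_rate: float = 1000.0) -> TelemetryStudy:
    """Materialise the whole study in memory.

    For long studies prefer :func:`iter_study_animals`, which streams one
    animal at a time.
    """
    return TelemetryStudy(config=config,
                          animals=list(iter_study_animals(config, sampling_rate)))
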
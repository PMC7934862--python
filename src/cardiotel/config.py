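"""Simulation and pipeline configuration containers.

``SimConfig`` holds every ground-truth parameter of the synthetic telemetry
generator: per-group hemodynamic means and baroreflex gain, the LF
(Mayer-wave) and HF (respiratory) oscillator settings, the circadian
profile, drug-event kinetics, activity rates and the acquisition scheme.
Defaults emulate a two-genotype mouse radiotelemetry study: a 3-day
baseline under a 12 h:12 h light cycle (lights on 06:00), epochal
acquisition (10 s every 5 min at 1000 Hz), group mean arterial pressures
of 104 vs 96 mmHg and heart rates of 500 vs 463 bpm, LF systolic-pressure
power of 4.8 vs 2.4 mmHg^2, and a ganglionic-blocker event with nadir
7-12 min after injection.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

from .errors import ConfigError

# Pulse morphology constants shared by the renderer and the ground-truth MAP.
# A cycle runs systolic peak -> rounded shoulder + exponential decay to the
# next diastole over the first 2/3 of the pulse interval -> raised-cosine
# upstroke to the next peak over the final 1/3.  The cosine shoulder gives
# the peak zero slope on both sides, so sampled maxima stay within the
# rendering tolerance of the true SBP at any rate >= 100 Hz.
UPSTROKE_FRACTION = 1.0 / 3.0
DECAY_TAU = 0.22          # exponential time constant, normalised to decay span
DECAY_CAP_FRACTION = 0.25  # shoulder width as a fraction of the decay span
DECAY_CAP_DROP = 0.12      # pulse-height fraction lost across the shoulder


def decay_shape(v):
    """Normalised diastolic run-off: 1 at the systolic peak (v = 0), 0 at
    the next diastole (v = 1), cosine shoulder then exponential decay."""
    import numpy as np

    v = np.asarray(v, dtype=float)
    a = DECAY_CAP_FRACTION
    d0 = 1.0 - DECAY_CAP_DROP
    e_floor = math.exp(-(1.0 - a) / DECAY_TAU)
    cap = 1.0 - DECAY_CAP_DROP * 0.5 * (1.0 - np.cos(math.pi * np.minimum(v, a) / a))
    tail = d0 * (np.exp(-(np.maximum(v, a) - a) / DECAY_TAU) - e_floor) / (1.0 - e_floor)
    return np.where(v < a, cap, tail)


def _decay_mean() -> float:
    import numpy as np

    v = np.linspace(0.0, 1.0, 20001)
    return float(np.trapezoid(decay_shape(v), v))


DECAY_MEAN = _decay_mean()

#: Time-average of the normalised pulse shape: MAP = DBP + MAP_FRACTION * PP.
MAP_FRACTION = (1.0 - UPSTROKE_FRACTION) * DECAY_MEAN + UPSTROKE_FRACTION * 0.5


def sbp_dbp_for_map(mean_map: float, pulse_pressure: float = 35.0) -> tuple[float, float]:
    """Systolic/diastolic means that give ``mean_map`` under the pulse shape.

    The rendered pulse has time-average DBP + MAP_FRACTION * (SBP - DBP), so
    for a target MAP and pulse pressure the diastolic mean is
    ``MAP - MAP_FRACTION * PP``.
    """
    if pulse_pressure <= 0:
        raise ConfigError("pulse_pressure must be positive")
    dbp = mean_map - MAP_FRACTION * pulse_pressure
    return dbp + pulse_pressure, dbp


@dataclass(frozen=True)
class GroupParams:
    """Ground-truth hemodynamics for one experimental group.

    Parameters
    ----------
    mean_sbp, mean_dbp : float
        Group mean systolic/diastolic pressure, mmHg.
    mean_hr : float
        Group mean heart rate, bpm.
    brs_gain : float
        True baroreflex gain G, ms/mmHg: the pulse-interval response to a
        1 mmHg systolic deviation one (``brs_lag``) beat earlier.
    lf_amp_sbp : float
        Amplitude of the low-frequency (Mayer-wave) SBP oscillation, mmHg.
        True LF-band SBP power is ``lf_amp_sbp**2 / 2``.
    drug_delta_map, drug_delta_hr : float
        Full depressor/bradycardic effect of the blockade event (positive
        values mean a fall), mmHg and bpm.
    """

    mean_sbp: float = 125.9
    mean_dbp: float = 90.9
    mean_hr: float = 500.0
    brs_gain: float = 2.6
    lf_amp_sbp: float = 3.10
    drug_delta_map: float = 28.0
    drug_delta_hr: float = 266.0

    @property
    def mean_map(self) -> float:
        """Implied ground-truth mean arterial pressure, mmHg."""
        return self.mean_dbp + MAP_FRACTION * (self.mean_sbp - self.mean_dbp)


def _default_groups() -> dict[str, GroupParams]:
    wt_sbp, wt_dbp = sbp_dbp_for_map(104.0)
    ko_sbp, ko_dbp = sbp_dbp_for_map(96.0)
    return {
        "WT": GroupParams(mean_sbp=wt_sbp, mean_dbp=wt_dbp, mean_hr=500.0,
                          brs_gain=2.6, lf_amp_sbp=math.sqrt(2 * 4.8),
                          drug_delta_map=28.0, drug_delta_hr=266.0),
        "KO": GroupParams(mean_sbp=ko_sbp, mean_dbp=ko_dbp, mean_hr=463.0,
                          brs_gain=3.8, lf_amp_sbp=math.sqrt(2 * 2.4),
                          drug_delta_map=20.0, drug_delta_hr=206.0),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full ground-truth configuration of a simulated telemetry study."""

    seed: int = 0
    n_animals_per_group: int = 6
    groups: dict[str, GroupParams] = field(default_factory=_default_groups)
    duration_days: float = 3.0
    brs_lag: int = 1              # beats
    lf_freq: float = 0.4          # Hz, Mayer-wave centre
    hf_freq: float = 2.5          # Hz, respiratory centre
    hf_amp_pi: float = 4.0        # ms, respiratory sinus arrhythmia amplitude
    hf_amp_sbp: float = 0.0       # mmHg, respiratory SBP modulation (off by default)
    sbp_noise_sd: float = 1.5     # mmHg, beat-to-beat SBP noise
    pi_noise_sd: float = 2.0      # ms, beat-to-beat PI noise
    circadian_amp_map: float = 6.3  # mmHg cosine amplitude of the MAP mesor
    circadian_amp_hr: float = 40.0  # bpm cosine amplitude of the HR track
    acrophase: float = 0.0        # clock-hour of the circadian peak (night-active)
    lights_on: float = 6.0        # clock-hour; lights off 12 h later
    start_clock_h: float = 6.0    # clock-hour at recording time zero
    drug_onset_min: float = 2.0
    drug_nadir_min: float = 8.0   # full effect reached here; inside [7, 12]
    drug_plateau_end_min: float = 12.0
    drug_recovery_min: float = 30.0
    activity_rate_day: float = 5.0    # counts/min
    activity_rate_night: float = 16.0
    sampling_mode: str = "epochal"    # "epochal" (10 s / 5 min) or "continuous"
    epoch_interval_s: float = 300.0
    epoch_duration_s: float = 10.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.groups:
            raise ConfigError("at least one group required")
        for label, g in self.groups.items():
            vals = [g.mean_sbp, g.mean_dbp, g.mean_hr, g.brs_gain,
                    g.lf_amp_sbp, g.drug_delta_map, g.drug_delta_hr]
            if not all(math.isfinite(v) for v in vals):
                raise ConfigError(f"non-finite parameter in group {label!r}")
            if g.mean_sbp <= 0 or g.mean_dbp <= 0:
                raise ConfigError(f"pressures must be positive in group {label!r}")
            if g.mean_sbp <= g.mean_dbp:
                raise ConfigError(f"mean_sbp must exceed mean_dbp in group {label!r}")
            if g.brs_gain < 0:
                raise ConfigError(f"brs_gain must be >= 0 in group {label!r}")
            if g.mean_hr <= 0:
                raise ConfigError(f"mean_hr must be positive in group {label!r}")
        scalars = [self.duration_days, self.lf_freq, self.hf_freq,
                   self.hf_amp_pi, self.hf_amp_sbp, self.sbp_noise_sd,
                   self.pi_noise_sd, self.circadian_amp_map,
                   self.circadian_amp_hr, self.acrophase, self.lights_on,
                   self.drug_onset_min, self.drug_nadir_min,
                   self.drug_plateau_end_min, self.drug_recovery_min,
                   self.activity_rate_day, self.activity_rate_night]
        if not all(math.isfinite(v) for v in scalars):
            raise ConfigError("non-finite scalar parameter")
        if self.n_animals_per_group < 1:
            raise ConfigError("n_animals_per_group must be >= 1")
        if self.duration_days <= 0:
            raise ConfigError("duration_days must be positive")
        if not (0.25 <= self.lf_freq <= 1.0):
            raise ConfigError("lf_freq must lie in the LF band [0.25, 1.0] Hz")
        if not (1.0 < self.hf_freq <= 6.0):
            raise ConfigError("hf_freq must lie in the HF band (1.0, 6.0] Hz")
        if not (0.0 <= self.acrophase < 24.0):
            raise ConfigError("acrophase must lie in [0, 24)")
        if self.brs_lag < 0:
            raise ConfigError("brs_lag must be >= 0")
        if min(self.sbp_noise_sd, self.pi_noise_sd, self.hf_amp_pi,
               self.hf_amp_sbp, self.activity_rate_day,
               self.activity_rate_night) < 0:
            raise ConfigError("noise SDs, amplitudes and rates must be >= 0")
        if self.sampling_mode not in ("epochal", "continuous"):
            raise ConfigError("sampling_mode must be 'epochal' or 'continuous'")
        if self.sampling_mode == "epochal":
            if self.duration_days * 86400.0 < self.epoch_interval_s:
                raise ConfigError("epochal mode needs at least one epoch")
        if not (0 < self.drug_onset_min <= self.drug_nadir_min
                <= self.drug_plateau_end_min):
            raise ConfigError("drug kinetics must satisfy 0 < onset <= nadir <= plateau end")
        if self.drug_recovery_min <= 0:
            raise ConfigError("drug_recovery_min must be positive")

    @property
    def duration_s(self) -> float:
        return self.duration_days * 86400.0

    def clock_h(self, t_s: float) -> float:
        """Clock hour (0-24, unwrapped allowed) at recording time ``t_s``."""
        return self.start_clock_h + t_s / 3600.0

    def with_updates(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = {k: asdict(v) for k, v in self.groups.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        groups = d.pop("groups", None)
        if groups is not None:
            d["groups"] = {k: GroupParams(**v) if isinstance(v, dict) else v
                           for k, v in groups.items()}
        return cls(**d)
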
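import numpy as np
import pytest

from cardiotel import (GroupParams, SimConfig, WaveformRecording,
                       detect_beats, render_waveform, simulate_beat_series)


@pytest.fixture
def quiet_config():
    """No oscillators, no noise, no circadian: constant SBP/PI."""
    gp = GroupParams(mean_sbp=120.0, mean_dbp=80.0, mean_hr=500.0,
                     brs_gain=0.0, lf_amp_sbp=0.0)
    return SimConfig(seed=0, groups={"WT": gp}, sampling_mode="continuous",
                     duration_days=60.0 / 86400.0, hf_amp_pi=0.0,
                     sbp_noise_sd=0.0, pi_noise_sd=0.0,
                     circadian_amp_map=0.0, circadian_amp_hr=0.0,
                     n_animals_per_group=1)


@pytest.fixture
def noise_free_config():
    """Oscillators and coupling on, stochastic terms off."""
    gp = GroupParams(mean_sbp=120.0, mean_dbp=85.0, mean_hr=500.0,
                     brs_gain=3.0, lf_amp_sbp=4.0)
    return SimConfig(seed=0, groups={"WT": gp}, sampling_mode="continuous",
                     duration_days=120.0 / 86400.0, hf_amp_pi=3.0,
                     sbp_noise_sd=0.0, pi_noise_sd=0.0,
                     circadian_amp_map=0.0, circadian_amp_hr=0.0,
                     n_animals_per_group=1)


def simulate_detect(config, group="WT", animal=0, duration_s=None, pad=True):
    """simulate -> render -> detect round trip helper."""
    truth = simulate_beat_series(config, group, animal, duration_s=duration_s)
    pi_s = truth.pi / 1000.0
    t0 = truth.beat_times[0] - (pi_s[0] if pad else 0.0)
    t1 = truth.beat_times[-1] + (pi_s[-1] if pad else 0.0)
    wave = render_waveform(truth, 1000.0, t_start=t0, t_end=t1)
    rec = WaveformRecording(animal_id="t", group=group, sampling_rate=1000.0,
                            segments=[(t0, wave)], mode="continuous")
    return truth, detect_beats(rec)


def match_beats(truth, beats, tol_s=0.01):
    """Indices (i_truth, i_detected) of peaks matched within ``tol_s``."""
    pairs = []
    j = 0
    for i, t in enumerate(truth.beat_times):
        while (j < beats.n_beats - 1
               and abs(beats.beat_times[j + 1] - t) < abs(beats.beat_times[j] - t)):
            j += 1
        if abs(beats.beat_times[j] - t) <= tol_s:
            pairs.append((i, j))
    return pairs
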
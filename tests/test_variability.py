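"""Spectral estimators, band powers, RMSSD and both BRS techniques."""

import math

import numpy as np
import pytest

from cardiotel import (AnalysisError, SegmentSelectionError, SimConfig,
                       SpectralParams, band_power, cross_spectral_brs,
                       resample_series, rmssd, select_segments, sequence_brs,
                       simulate_beat_series, spectral_summary, welch_psd)
from cardiotel.beatproc import BeatSeries
from cardiotel.simgen import brs_validation_config, truth_to_beat_series
from cardiotel.variability import UniformSeries


def make_beats(pi_ms=None, sbp=None, rate_hz=8.0, n=None, flags=None):
    """Construct a BeatSeries with explicit per-beat values."""
    if pi_ms is not None:
        n = len(pi_ms) + 1
    elif sbp is not None:
        n = len(sbp)
    t = np.arange(n) / rate_hz
    if pi_ms is None:
        pi_ms = np.full(n - 1, 1000.0 / rate_hz)
    if sbp is None:
        sbp = np.full(n, 120.0)
    if flags is None:
        flags = np.zeros(n - 1, dtype=np.int64)
    return BeatSeries(animal_id="a", group="g", beat_times=t,
                      sbp=np.asarray(sbp, dtype=float),
                      dbp=np.full(n - 1, 80.0), map=np.full(n - 1, 95.0),
                      pi_ms=np.asarray(pi_ms, dtype=float),
                      flags=np.asarray(flags, dtype=np.int64),
                      seg_id=np.zeros(n, dtype=int))


class TestSelectSegments:
    def test_stationary_simulation_yields_five_windows(self,
                                                       noise_free_config):
        cfg = noise_free_config.with_updates(duration_days=600.0 / 86400.0)
        beats = truth_to_beat_series(simulate_beat_series(cfg, "WT", 0))
        wins = select_segments(beats)
        assert len(wins) == 5
        for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
            assert a1 <= b0      # non-overlapping, ordered

    def test_windows_avoid_pressure_step(self, noise_free_config):
        cfg = noise_free_config.with_updates(duration_days=600.0 / 86400.0)
        truth = simulate_beat_series(cfg, "WT", 0)
        beats = truth_to_beat_series(truth)
        mid = beats.n_beats // 2
        beats.sbp[mid:] += 40.0   # injected sudden BP change
        wins = select_segments(beats)
        assert all(not (a <= mid - 1 and mid <= b) for a, b in wins)

    def test_selection_is_deterministic(self):
        cfg = brs_validation_config(3.0, seed=21)
        beats = truth_to_beat_series(simulate_beat_series(cfg, "G", 0))
        assert select_segments(beats) == select_segments(beats)

    def test_no_qualifying_window_raises_with_diagnostics(self):
        beats = make_beats(sbp=120 + np.repeat([0.0, 20.0], 300))
        with pytest.raises(SegmentSelectionError) as err:
            select_segments(beats)
        assert err.value.diagnostics   # counts of rejection reasons


class TestResample:
    def test_constant_series_detrends_to_zero(self):
        beats = make_beats(pi_ms=np.full(700, 120.0))
        s = resample_series(beats, "pi", (0, 700))
        assert np.allclose(s.values, 0.0, atol=1e-9)

    def test_linear_ramp_detrends_to_zero(self):
        beats = make_beats(pi_ms=120.0 + 0.01 * np.arange(700))
        s = resample_series(beats, "pi", (0, 700))
        assert np.allclose(s.values, 0.0, atol=1e-6)

    def test_sinusoid_preserved_against_dense_analytic_oracle(self):
        t = np.arange(701) / 8.0
        pi = 120.0 + 5.0 * np.sin(2 * np.pi * 0.4 * t[:-1])
        beats = make_beats(pi_ms=pi)
        s = resample_series(beats, "pi", (0, 701))
        assert s.rate == 12.0
        tu = s.t0 + np.arange(len(s.values)) / s.rate
        analytic = 5.0 * np.sin(2 * np.pi * 0.4 * tu)
        # the protocol removes a least-squares line; apply it to the oracle
        coef = np.polynomial.polynomial.polyfit(tu - tu[0], analytic, 1)
        analytic = analytic - (coef[0] + coef[1] * (tu - tu[0]))
        # interior comparison (spline edges are one-sided)
        sl = slice(10, -10)
        assert np.max(np.abs(s.values[sl] - analytic[sl])) < 0.1
        amp = 2 * np.abs(np.exp(-2j * np.pi * 0.4 * tu) @ s.values) / len(tu)
        assert amp == pytest.approx(5.0, abs=0.1)

    def test_nonmonotone_times_rejected(self):
        beats = make_beats(pi_ms=np.full(20, 120.0))
        beats.beat_times[5] = beats.beat_times[7]
        with pytest.raises(AnalysisError):
            resample_series(beats, "sbp", (0, 20))


class TestWelch:
    def test_white_noise_parseval(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 2.0, 4096)
        s = UniformSeries(values=x - x.mean(), rate=12.0, t0=0.0)
        f, p = welch_psd(s)
        total = np.trapezoid(p, f)
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_sinusoid_power_is_half_amplitude_squared(self):
        t = np.arange(4096) / 12.0
        x = 2.0 * np.sin(2 * np.pi * 0.5 * t)
        f, p = welch_psd(UniformSeries(values=x, rate=12.0, t0=0.0))
        assert np.trapezoid(p, f) == pytest.approx(2.0, rel=0.05)

    def test_zero_series_zero_psd(self):
        f, p = welch_psd(UniformSeries(values=np.zeros(512), rate=12.0,
                                       t0=0.0))
        assert np.allclose(p, 0.0)

    def test_short_series_rejected(self):
        with pytest.raises(AnalysisError, match="longer"):
            welch_psd(UniformSeries(values=np.zeros(100), rate=12.0, t0=0.0))


class TestBandPower:
    @pytest.mark.parametrize("freq,band_with_power,band_without", [
        (0.5, (0.25, 1.0), (1.0, 6.0)),
        (3.0, (1.0, 6.0), (0.25, 1.0)),
    ])
    def test_sinusoid_lands_in_its_band(self, freq, band_with_power,
                                        band_without):
        t = np.arange(4096) / 12.0
        x = 2.0 * np.sin(2 * np.pi * freq * t)
        f, p = welch_psd(UniformSeries(values=x, rate=12.0, t0=0.0))
        inside = band_power(f, p, band_with_power)
        outside = band_power(f, p, band_without)
        assert inside == pytest.approx(2.0, rel=0.05)
        assert outside < 0.05 * inside

    def test_equal_tones_give_unit_lf_hf_ratio(self):
        t = np.arange(8192) / 12.0
        x = (3.0 * np.sin(2 * np.pi * 0.4 * t)
             + 3.0 * np.sin(2 * np.pi * 2.5 * t))
        f, p = welch_psd(UniformSeries(values=x, rate=12.0, t0=0.0))
        lf = band_power(f, p, (0.25, 1.0))
        hf = band_power(f, p, (1.0, 6.0))
        assert lf / hf == pytest.approx(1.0, rel=0.10)

    def test_inverted_band_rejected(self):
        f = np.linspace(0, 6, 257)
        with pytest.raises(AnalysisError):
            band_power(f, np.ones_like(f), (1.0, 0.25))


class TestRMSSD:
    def test_alternating_pair_differences(self):
        assert rmssd(np.array([800.0, 810.0, 800.0, 810.0])) == pytest.approx(10.0)

    def test_constant_is_zero(self):
        assert rmssd(np.full(10, 120.0)) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(12)
        pi = 120 + rng.normal(0, 5, 50)
        d = [pi[i + 1] - pi[i] for i in range(49)]
        oracle = math.sqrt(sum(x * x for x in d) / len(d))
        assert rmssd(pi) == pytest.approx(oracle, rel=1e-12)

    def test_pairs_spanning_flagged_beat_excluded(self):
        pi = np.array([100.0, 110.0, np.nan, 100.0, 110.0])
        valid = np.isfinite(pi)
        assert rmssd(pi, valid) == pytest.approx(10.0)

    def test_too_few_intervals_nan(self):
        assert math.isnan(rmssd(np.array([120.0])))


class TestCrossSpectralBRS:
    def test_exact_linear_coupling_gain_and_unit_coherence(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 2, 1024)
        sbp = UniformSeries(values=x, rate=12.0, t0=0.0)
        pi = UniformSeries(values=3.0 * x, rate=12.0, t0=0.0)
        f, gain, coh, _ = cross_spectral_brs(sbp, pi)
        m = (f >= 0.25) & (f < 1.0)
        assert np.allclose(gain[m], 3.0, atol=1e-9)
        assert np.allclose(coh[m], 1.0, atol=1e-9)

    def test_independent_noise_fails_coherence_gate(self):
        fails = 0
        trials = 20
        for k in range(trials):
            cfg = brs_validation_config(3.0, seed=500 + k)
            beats = truth_to_beat_series(simulate_beat_series(cfg, "G", 0))
            rng = np.random.default_rng(900 + k)
            beats.pi_ms = 120.0 + rng.normal(0, 3, beats.n_beats - 1)
            s = spectral_summary(beats)
            if s.brs_lf is None:
                fails += 1
        assert fails >= 0.95 * trials

    def test_closed_loop_gain_recovered(self):
        """G = 3.8 ms/mmHg with moderate noise, 5 averaged segments."""
        vals = []
        for k in range(5):
            cfg = brs_validation_config(3.8, seed=300 + k)
            beats = truth_to_beat_series(simulate_beat_series(cfg, "G", 0))
            s = spectral_summary(beats)
            assert s.n_segments_used == 5
            if s.brs_lf is not None:
                vals.append(s.brs_lf)
        assert len(vals) >= 4
        assert np.mean(vals) == pytest.approx(3.8, rel=0.15)

    def test_mismatched_windows_rejected(self):
        a = UniformSeries(values=np.zeros(512), rate=12.0, t0=0.0)
        b = UniformSeries(values=np.zeros(600), rate=12.0, t0=0.0)
        with pytest.raises(AnalysisError):
            cross_spectral_brs(a, b)


def brute_force_sequences(sbp, pi, params):
    """Independent exhaustive enumerator of maximal concordant runs."""
    n = len(sbp)
    lag = params.seq_lag
    out = []
    for direction, sign in (("up", 1.0), ("down", -1.0)):
        def step_ok(m):
            ka, kb = m + lag, m + 1 + lag
            if ka < 0 or kb >= len(pi):
                return False
            if not (np.isfinite(pi[ka]) and np.isfinite(pi[kb])):
                return False
            return (sign * (sbp[m + 1] - sbp[m]) >= params.seq_delta_sbp
                    and sign * (pi[kb] - pi[ka]) >= params.seq_delta_pi)

        for a in range(n - 1):
            for b in range(a + params.seq_min_beats - 1, n):
                if not all(step_ok(m) for m in range(a, b)):
                    continue
                maximal = ((a == 0 or not step_ok(a - 1))
                           and (b == n - 1 or not step_ok(b)))
                if not maximal:
                    continue
                xs = np.array([sbp[i] for i in range(a, b + 1)])
                ys = np.array([pi[i + lag] for i in range(a, b + 1)])
                if xs.std() > 0 and ys.std() > 0:
                    r = float(np.corrcoef(xs, ys)[0, 1])
                else:
                    r = 0.0
                den = ((xs - xs.mean()) ** 2).sum()
                slope = float((((xs - xs.mean()) * (ys - ys.mean())).sum())
                              / den)
                if r >= params.seq_min_r:
                    out.append((a, b - a + 1, direction, slope, r))
    return out


class TestSequenceBRS:
    def test_constructed_up_ramp(self):
        sbp = np.array([120.0, 120.0, 122.0, 124.0, 126.0, 128.0, 126.0,
                        124.5, 123.5, 123.0, 122.8, 122.7])
        pi = np.full(11, 120.0)
        # lag-1: pi[i+1] responds to sbp[i]; slope 2.5 ms/mmHg over the ramp
        for i in range(1, 5):
            pi[i + 1] = pi[i] + 2.5 * (sbp[i + 1] - sbp[i])
        beats = make_beats(pi_ms=pi, sbp=sbp)
        res = sequence_brs(beats)
        assert res.n_up == 1
        assert res.n_down == 0
        assert res.slope_up == pytest.approx(2.5, abs=1e-9)

    def test_alternating_sbp_has_no_sequences(self):
        sbp = 120.0 + np.tile([0.0, 3.0], 50)
        pi = 120.0 + np.tile([0.0, 3.0], 50)[:-1]
        res = sequence_brs(make_beats(pi_ms=pi, sbp=sbp))
        assert res.n_up == 0 and res.n_down == 0

    def test_matches_brute_force_enumerator(self):
        params = SpectralParams()
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = 80
            sbp = 120 + np.cumsum(rng.normal(0, 1.5, n))
            pi = np.empty(n - 1)
            pi[0] = 120.0
            pi[1:] = 120 + 3.0 * (sbp[:n - 2] - 120) + rng.normal(0, 1, n - 2)
            beats = make_beats(pi_ms=pi, sbp=sbp)
            mine = [(s[0], s[1], s[2]) for s in sequence_brs(beats, params).sequences]
            oracle = [(s[0], s[1], s[2]) for s in
                      brute_force_sequences(sbp, pi, params)]
            assert sorted(mine) == sorted(oracle)
            my_slopes = sorted(s[3] for s in sequence_brs(beats, params).sequences)
            or_slopes = sorted(s[3] for s in brute_force_sequences(sbp, pi, params))
            assert np.allclose(my_slopes, or_slopes, rtol=0, atol=1e-9)


class TestParsevalBound:
    def test_band_sum_below_total_power_below_variance(self):
        cfg = brs_validation_config(3.0, seed=50)
        beats = truth_to_beat_series(simulate_beat_series(cfg, "G", 0))
        for w in select_segments(beats):
            s = resample_series(beats, "sbp", w)
            f, p = welch_psd(s)
            lf = band_power(f, p, (0.25, 1.0))
            hf = band_power(f, p, (1.0, 6.0))
            total = np.trapezoid(p, f)
            assert lf + hf <= total * (1 + 1e-9)
            assert total <= np.var(s.values) * 1.05


class TestLFMonotonicity:
    def test_lf_sbp_increases_with_oscillator_amplitude(self):
        measured = []
        for amp in (1.5, 3.0, 6.0):
            cfg = brs_validation_config(3.0, seed=60)
            gp = cfg.groups["G"]
            from dataclasses import replace
            cfg = cfg.with_updates(groups={"G": replace(gp, lf_amp_sbp=amp)})
            beats = truth_to_beat_series(simulate_beat_series(cfg, "G", 0))
            measured.append(spectral_summary(beats).lf_sbp)
        assert measured[0] < measured[1] < measured[2]
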
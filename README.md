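# cardiotel

Cardiovascular autonomic phenotyping from arterial-pressure telemetry.

`cardiotel` is a tested Python pipeline for the analysis protocol used in
murine radiotelemetry studies of autonomic blood-pressure control: systolic
beat detection from 1000 Hz pressure waveforms, day/night epoch
aggregation, blood-pressure and heart-rate variability spectra, spontaneous
baroreflex sensitivity (BRS) by two independent techniques, cosinor
circadian rhythm fits, and quantification of the depressor/bradycardic
response to ganglionic blockade. Because raw animal telemetry is rarely
shared, the package includes a first-class synthetic telemetry generator
with fully known ground truth — a closed-loop beat-to-beat model that
drives every downstream estimator and makes the whole chain verifiable.

## Who it is for

Cardiovascular physiologists and methods developers who need a
reproducible, scriptable implementation of the classical telemetry
analysis stack (as found in commercial acquisition suites and legacy
in-house spectral code), or a calibrated test bed for validating beat
detectors and BRS estimators.

## The model and the estimators

**Generator.** Beat *n* at systolic-peak time *t<sub>n</sub>* follows a
DeBoer-style linear baroreflex recursion:

```
SBP_n = M(t_n) + A_LF sin(2π f_LF t_n) + ε_n
PI_n  = PI_0(t_n) + G (SBP_{n−lag} − M(t_n)) + A_HF sin(2π f_HF t_n) + η_n
```

with `M(t)` a circadian mesor track (12 h:12 h light cycle, lights on
06:00), `PI_0(t) = 60000 / HR(t)`, `G` the true baroreflex gain in
ms/mmHg, a 0.4 Hz Mayer-wave SBP oscillation, 2.5 Hz respiratory
modulation of the pulse interval, and Gaussian beat noise. The next beat
occurs `PI_n` ms later, and pressure waveforms are rendered at 1000 Hz in
either epochal (10 s every 5 min) or continuous beat-by-beat mode.

**Estimators.**

* Beat detection: refractory-gated peak finding with adaptive prominence;
  pulse interval = peak-to-peak; MAP = waveform integral mean per cycle.
* Spectra: beat series cubic-resampled at 12 Hz, linearly detrended, Welch
  PSD with 512-point Hanning segments; five representative windows chosen
  under steady-state / no-jump / no-artifact criteria and averaged. LF
  band 0.25–1.0 Hz, HF band 1.0–6.0 Hz; LFsys is the LF power of systolic
  pressure; RMSSD is computed on raw pulse intervals.
* Cross-spectral BRS: `|S_xy(f)| / S_xx(f)` between SBP and PI averaged
  over LF bins, accepted only when mean LF coherence ≥ 0.8.
* Sequence BRS: least-squares PI-on-SBP slopes over spontaneous runs of
  ≥ 3 beats with concordant monotone SBP (≥ 1 mmHg/beat) and lagged PI
  (≥ 1 ms/beat) changes, kept at r ≥ 0.85 (sequp / seqdown).
* Cosinor: fixed 24 h single-harmonic least-squares fits over sliding 27 h
  windows → mesor, amplitude, acrophase.
* Blockade response: baseline over a 1200 s pre-injection frame; nadir of
  the 30 s-smoothed post-injection series inside the 7–12 min window.
* Group statistics: two-tailed t tests, two-way genotype × phase ANOVA
  (type II), two-sided Grubbs outlier screening, and the assay
  normalisations (urinary analyte/osmolality, specific uptake, per-cell
  content).

## Worked example

```python
from cardiotel import SimConfig, spectral_summary
from cardiotel.simgen import simulate_beat_series, truth_to_beat_series

cfg = SimConfig(seed=42, n_animals_per_group=1, sampling_mode="continuous",
                duration_days=3600 / 86400)          # one hour
truth = simulate_beat_series(cfg, "KO", 0)           # true gain 3.8 ms/mmHg
s = spectral_summary(truth_to_beat_series(truth))
print(f"animal {s.animal_id}: LFsys = {s.lf_sbp:.2f} mmHg^2, "
      f"RMSSD = {s.rmssd:.2f} ms")
print(f"BRS-LF = {s.brs_lf:.2f} ms/mmHg (mean LF coherence "
      f"{s.mean_coherence_lf:.2f}, {s.n_segments_used} segments)")
```

prints

```
animal KO01: LFsys = 2.93 mmHg^2, RMSSD = 9.85 ms
BRS-LF = 3.70 ms/mmHg (mean LF coherence 0.89, 5 segments)
```

The KO group's configured LF oscillator carries 2.4 mmHg² of true LF
power; the measured 2.93 mmHg² includes the beat-noise floor of the
default configuration. The cross-spectral gain 3.70 ms/mmHg estimates the
configured baroreflex gain of 3.8 within its sampling error, and the
coherence of 0.89 clears the 0.8 acceptance gate.

The command line mirrors the library:

```
cardiotel simulate --config study.toml --out-dir data/
cardiotel beats data/waveform_WT01.csv --out beats_WT01.csv
cardiotel summarize beats_WT01.csv --lights-on 6 --out summary_WT01.csv
cardiotel run-all --config study.toml --out-dir results/
```

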
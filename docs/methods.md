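# Methods

This note documents the models, estimators, parameter choices and known
limitations of `cardiotel`, in the spirit of a statistical software
methods appendix. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## 1. The synthetic telemetry generator (`simgen`)

### Beat-to-beat model

The generator produces per-beat systolic pressure and pulse interval from
a closed-loop recursion chosen so that the ground-truth baroreflex gain is
well defined for both estimators the package implements (both assume a
linear SBP→PI transfer):

    SBP_n = M(t_n) + A_LF · sin(2π f_LF t_n) + A_HF,s · sin(2π f_HF t_n) + ε_n
    PI_n  = PI_0(t_n) + G · (SBP_{n−lag} − M(t_n)) + A_HF · sin(2π f_HF t_n) + η_n

* `M(t)` — circadian systolic mesor: group mean plus a 24 h cosine of
  amplitude `circadian_amp_map` peaking at `acrophase` (default midnight,
  i.e. night-active animals). `PI_0(t) = 60000 / HR(t)` with the HR track
  built the same way.
* `G` (`brs_gain`, ms/mmHg) — the true reflex gain; the interval *opened*
  by peak `n` responds to the systolic value `lag` beats earlier
  (default lag 1, the fast-vagal convention).
* The next beat occurs `PI_n` ms later, so beat times, intervals and the
  sinusoid phases are mutually consistent by construction
  (`pi == diff(beat_times) · 1000` exactly).

Index bookkeeping that matters downstream: `pi[k]`, the interval from
peak `k` to peak `k+1`, is generated from `sbp[k−1]` under lag 1. The
sequence-method estimator therefore pairs `(sbp[i], pi[i+lag])`; pairing
one beat off attenuates recovered slopes by the LF autocorrelation ratio
(about −10% at the default settings), which the estimator-validation grid
would detect.

### Parameters, units, defaults

| parameter | unit | default | why |
|---|---|---|---|
| mean MAP (WT/KO) | mmHg | 104 / 96 | published overall group means |
| mean HR (WT/KO) | bpm | 500 / 463 | published overall group means |
| pulse pressure | mmHg | 35 | mid-range murine arterial pulse |
| `brs_gain` (WT/KO) | ms/mmHg | 2.6 / 3.8 | published sequence-method group values |
| `lf_freq` | Hz | 0.4 | mid-LF-band placement; no murine Mayer-wave centre frequency is established, so this is a package choice |
| `lf_amp_sbp` (WT/KO) | mmHg | √(2·4.8) / √(2·2.4) | encodes the published LF SBP powers (a sinusoid of amplitude A carries A²/2) |
| `hf_freq` / `hf_amp_pi` | Hz / ms | 2.5 / 4 | mid-HF respiratory rate; RSA amplitude giving RMSSD ≈ 10 ms |
| `sbp_noise_sd`, `pi_noise_sd` | mmHg, ms | 1.5, 2.0 | moderate beat-level measurement/physiological noise |
| `circadian_amp_map`, `circadian_amp_hr` | mmHg, bpm | 6.3, 40 | derived from published day/night phase means: the mean of a unit cosine over its better half-day is 2/π ≈ 0.637, so amplitude = (night − day)/2 ÷ 0.637 |
| `drug_delta_map`, `drug_delta_hr` (WT/KO) | mmHg, bpm | 28/266, 20/206 | published blockade responses |
| drug kinetics | min | onset 2, full effect 8, plateau to 12, recovery 30 | piecewise-linear profile whose extreme value falls inside the 7–12 min nadir window |
| activity day/night | counts/min | 5 / 16 | published phase means |
| acquisition | — | 10 s per 5 min at 1000 Hz, 3 days | the epochal telemetry schedule |

Animals within a group share all parameters; only their noise
realisations differ (each animal draws from an independent stream seeded
by `(seed, group, animal)`, making studies bit-reproducible). There is
deliberately no between-animal variance component, so group means are
recovered with very small standard errors relative to a real cohort —
passing group-contrast checks shows estimator correctness and
calibration, not statistical power under biological heterogeneity.

### Waveform rendering

Each cycle between systolic peaks is rendered as: a cosine "shoulder"
(25% of the decay span, 12% of pulse height, zero slope at the peak),
an exponential run-off (τ = 0.22 of the decay span) reaching the next
diastolic value at 2/3 of the interval, then a raised-cosine upstroke to
the next peak. The shoulder exists so that sampled maxima equal true SBP
within 0.1 mmHg at 1000 Hz (a shape with nonzero slope at the peak loses
up to 0.65 mmHg to discretisation). Only the extrema and their timing are
contractual; the shape itself carries no physiological claim. The
time-average of the normalised shape (`MAP_FRACTION` ≈ 0.437) defines
ground-truth MAP = DBP + 0.437 · PP, and diastolic pressure tracks
systolic at a fixed pulse pressure.

### Drug events

`apply_drug_event` applies deterministic kinetics on the *tracks* while
keeping the existing beat noise: pressures shift by `Δ_MAP · e(t)` and
each interval is lengthened by the PI equivalent of an HR-track fall of
`Δ_HR · e(t)`. Two implementation details matter:

* the effect profile is evaluated on the **output** timeline by a forward
  pass, because bradycardia stretches the beat grid (evaluating on the
  input grid smears the profile and the full effect is never reached in
  real time);
* applying the HR delta to the deterministic track (rather than the noisy
  per-beat HR) keeps beat noise in the PI domain, so HR-domain noise
  shrinks as intervals lengthen — the physiological behaviour — instead
  of staying at its baseline magnitude.

## 2. Beat processing (`beatproc`)

Systolic peaks: `scipy.signal.find_peaks` per segment with a 50 ms
refractory distance and prominence 0.3 × (2nd–98th percentile range).
Flat and non-finite segments raise; a segment with more than 5% of
samples pinned at its extreme values is rejected as saturated. The pulse
interval is peak-to-peak (the most robust pressure landmark); the cycle
opened by peak *i* carries the trough before peak *i+1* as its DBP and
the trapezoidal integral mean as its MAP (the DBP + PP/3 formula is
available as a cross-check option). Cycles with intervals outside
(50, 1000) ms, non-physiological extrema, or spanning acquisition gaps
are flagged, never dropped. Mean HR is the arithmetic mean of per-beat
60000/PI (the alternative 60000/mean-PI differs by a Jensen term of
≈ +0.6% at murine noise levels; both conventions shift the two groups
almost identically, so group contrasts are insensitive to the choice).

Epoch aggregation assigns each 5-min epoch to day or night by its start
clock hour relative to lights-on (06:00); the overall value is the
phase means weighted by usable-epoch counts, which reduces to the
available phase (with a low-coverage flag) when one phase is empty.
Missing epochs are excluded, not imputed.

## 3. Variability and baroreflex estimation (`variability`)

Window selection implements the three published criteria concretely:
steady state = |least-squares SBP trend| < 0.05 mmHg/beat; no sudden
changes = no beat-to-beat SBP jump > 15 mmHg; no artifacts = no flagged
cycle. Candidate 60 s windows on a quarter-window stride are ranked by
closeness of their SBP variance to the median candidate variance (a
representativeness proxy) and up to five non-overlapping windows are
kept. Each window is cubic-spline resampled at 12 Hz (720 samples ≥ the
512-point FFT), linearly detrended, and analysed with Welch's method
(Hanning, 50% overlap, one-sided density normalisation, so the PSD
integral recovers the variance). Auto- and cross-spectra are averaged
across the five windows *before* forming the transfer gain
`|S_xy|/S_xx` and magnitude-squared coherence — with a single window the
coherence would be identically 1. Band powers integrate over
[0.25, 1.0) and [1.0, 6.0) Hz (half-open at the shared edge). RMSSD is
computed on the raw beat-indexed pulse intervals of the selected
windows, excluding pairs that span a flagged beat.

The sequence method uses the field's common convention (the protocol
itself states none): ΔSBP ≥ 1 mmHg/beat, ΔPI ≥ 1 ms/beat, runs ≥ 3
beats, r ≥ 0.85, lag 1; all are configuration keys. Runs are maximal
stretches of consecutive qualifying steps, so the sequence set is
well-defined and is verified bit-identically against an exhaustive
brute-force enumerator in the tests.

### Estimator validation conditions

`simgen.brs_validation_config` defines the conditions under which the
package certifies both estimators (|bias| < 15%, perfect rank ordering
over G ∈ {1, 2, 3, 4, 6} ms/mmHg): 600 s continuous recordings, LF
amplitude 8 mmHg, HF amplitude 0.5 ms, beat noise 1.0 mmHg / 0.5 ms,
circadian off. The LF amplitude is deliberately strong so that reflex
pulse-interval ramps exceed the 1 ms/beat sequence threshold at *every*
gain in the grid: the sequence method is only defined in the regime where
its thresholds do not bind, and near the threshold it exhibits the
well-known positive selection bias (concordant noise excursions are
preferentially selected — at G = 1 with weak ramps the bias exceeds
+40%). The cross-spectral estimator is insensitive to this but needs the
LF-band coherence to clear the 0.8 gate, which the same conditions
provide. Under the default (study-emulation) settings the sequence
estimates carry a residual positive bias of ~10–20% at low gain; the
package reports them regardless, as the original technique does.

## 4. Cosinor rhythms (`circadian`)

Single-harmonic least-squares cosinor with the period fixed at 24 h,
fitted in the linear `β_c cos + β_s sin` parameterisation over sliding
27 h windows advancing in 3 h steps. Amplitude is `√(β_c² + β_s²)`;
acrophase `atan2(β_s, β_c) · 24/2π` wrapped to [0, 24). A constant
series yields amplitude 0 with the phase flagged undefined. Why 27 h
windows rather than 24 is a protocol convention adopted as-is. Acrophase
is a circular quantity: consumers averaging across windows should use a
circular mean (per-window values cluster tightly at the true phase; a
naive arithmetic mean across the 0/24 wrap is meaningless).

## 5. Blockade responses (`pharm`)

Baseline = mean over the 1200 s frame ending at injection. The per-beat
MAP and HR series are averaged into 1 s bins (bin-averaging reduces beat
noise, where point interpolation would sample it), smoothed with a 30 s
moving average, and the nadir is the largest smoothed excursion from
baseline inside the 7–12 min window; the same windows are used for both
variables, and deltas are nadir − baseline exactly. Two disjoint 1200 s
post-injection frames are also reported. Min-picking over a smoothed
noisy series biases the recovered delta by ≈ −1 to −3 units at default
noise; recovery experiments in the acceptance suite run without
circadian drift (blockade testing is a steady-state protocol), since a
40 bpm circadian swing contributes several bpm of drift between the
baseline and nadir windows that is not part of the drug effect.

## 6. Group statistics and normalisations (`groupstats`)

Classical equal-variance two-tailed t by default (Welch by flag), the
two-way genotype × phase ANOVA with interaction via statsmodels using
type II sums of squares (main-effects focus; robust to mild imbalance),
and two-sided Grubbs at α = 0.05 — single-pass by default, iterative
optional and logged; points are flagged, never removed. The Grubbs
critical value uses the standard t-quantile formula. Normalisations are
exact arithmetic with validation (positive osmolality and cell counts;
negative specific uptake returned but flagged).

## 7. What the synthetic data does and does not show

The generator emulates the study conditions — group means calibrated to
the published values, the acquisition schedule, circadian structure,
band-limited LF/HF oscillations with known power, a linear baroreflex
with known gain, Poisson activity, and blockade kinetics with a
prescribed nadir window. It does **not** emulate: between-animal
heterogeneity; broadband (1/f) cardiovascular variability — the
oscillators are pure tones, so real spectra are messier and coherence
gates are harder to clear in practice; nonstationarity, movement
artifacts or transmitter dropout beyond what the selection criteria
screen; respiratory–cardiac mechanical coupling; or pharmacokinetics
(the drug profile is piecewise-linear kinetics, not a PK model).
Passing tests therefore certify that the estimators recover known
structure at realistic murine scales and noise levels — not that every
choice is optimal for arbitrary real recordings.

Numerical conventions worth knowing: band integrals are trapezoidal on
the Welch grid (Δf = 12/512 Hz); the 1.0 Hz edge belongs to LF; the
coherence criterion "about 0.8" is read as ≥ 0.80; spline resampling can
overshoot between beats by ~2% of a sinusoid's amplitude; and all
randomness flows from `numpy.random.default_rng` seeded per
(seed, group, animal), so identical configurations are bit-identical
across runs and platforms.

## 8. Problem sizes used in the verification suite

The calibrated group-contrast studies use 6 animals per group for 3 days
(epochal mode) and 5 per group for one hour (continuous mode) — the
published cohort sizes — and the estimator-validation grid uses 20
replicates of 600 s recordings per gain. These sizes give standard
errors comfortably inside every stated tolerance while keeping the full
suite fast to re-run.
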
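# Methods

This note documents the models and estimators in `mousehrv`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Pipeline overview

Raw single-lead ECG (default 4 kHz; analog acquisition assumed band-limited
to roughly 0.3 Hz – 1 kHz) → Pan–Tompkins R-peak detection → RR tachogram
(ms) with optional ectopy screening → two analysis domains: the beat-domain
NN series for time-domain and nonlinear metrics, and a uniform 10 Hz
interval signal (Berger resampling) for spectral analysis.  Group-level
inference operates on a tidy subjects × metrics table.

## R-peak detection

Classic Pan–Tompkins stages with constants rescaled for murine timing: the
mouse QRS is ~10 ms wide and heart rates run 250–400 bpm, so the defaults
are band-pass 10–100 Hz (2nd-order Butterworth, zero-phase), five-point
derivative, squaring, 15 ms moving-window integration, 50 ms refractory
period, searchback factor 1.66.  Signal/noise peak levels are tracked on
both the integrated and band-passed signals with the classic 1/8 learning
rate (quartered during searchback); the acceptance threshold is
`noise + 0.25 (signal − noise)`.  Accepted fiducials are refined to the
extremum of the *raw* trace within ± one integration window, avoiding any
residual filter delay; with `polarity_agnostic` (default) the refinement
uses the absolute deviation from the baseline median, which also handles
inverted leads.  All constants are configurable because vendor detectors
tuned for human ECG (5–15 Hz pass-band) are inappropriate at murine time
scales.

On clean synthetic ECG the detector achieves 100 % sensitivity and positive
predictivity with worst-case timing error under 1 ms across 250–380 bpm
(the acceptance script measures this).

## Tachogram, NN screening, Berger resampling

`rr_from_peaks` gives intervals in ms with the closing beat time attached.
The ectopy screen flags an interval deviating from the running median (11
beats) by more than 20 % of that median; it is **off by default** because
the screening criterion applied to the original recordings is not
specified beyond "normal = no ectopic beats", and synthetic data contain
no ectopy.  Downstream metrics use the flagged-in (NN) subset; successive
differences are taken only between adjacent normal intervals.

Berger resampling: for each 10 Hz output sample a window of width
2/f<sub>s</sub> = 200 ms counts the fractional number of beat intervals it
covers; local rate = f<sub>s</sub>/2 × count, stored as the equivalent
interval in ms (ms² spectral units are the HRV convention).  Edge samples
whose window would leave the record are dropped, not padded.  A flagged
interval is merged with its neighbor (the shared beat is removed) so the
windowed count never sees the artifactual rate spike.  The windowed count
is a boxcar filter with amplitude response sinc(f·0.2 s): ~0.64 at 2.5 Hz.
This attenuation is deliberate in Berger's scheme (it suppresses
beat-quantization noise) and is compensated in the *generator*, not in the
analyzer (see below).

## Time domain

- SDNN: sample SD (denominator N−1) — convention for short segments.
- RMSSD: mean over the number of successive differences.
- Mean HR: 60000 / mean NN, not the mean of instantaneous rates; the two
  differ for variable series and the interval-based definition is the
  unambiguous one.
- TINN: histogram at 1 ms bins (the human-standard 1/128 s bin is too
  coarse for murine NN spreads of a few ms), apex fixed at the mode, and
  an exhaustive search over bin-aligned feet (N, M) minimizing the squared
  error between histogram and triangle; the result is M − N.  Feet may
  extend beyond the occupied support (a uniform histogram is best fit by a
  wider triangle).  Histograms are small, so exactness beats speed.
  Single-bin histograms return 0.
- A helper splits long records into the standard 5-minute segments; the
  default analysis segment is the full provided series.

## Frequency domain

Welch-averaged periodograms: 60 s Hann segments, 50 % overlap, per-segment
linear detrend, one-sided density in ms²/Hz.  The estimator itself is a
package choice (the acquisition software behind the published group tables
offers several and does not disclose one); window and overlap are
configurable.  Murine bands: VLF 0–0.15, LF 0.15–1.5, HF 1.5–5 Hz.  Band
integration is trapezoidal with interpolated band edges; the 0 Hz (mean)
bin is excluded from VLF; total power is defined as VLF+LF+HF so the three
relative powers always sum to 100 % (published group triples sum to ~100,
implying VLF is in the denominator).  Parseval: the integrated density and
the band total match the mean variance of the linearly detrended Welch
segments to within 5 % (the global-detrend variance is larger, since
per-segment detrending removes sub-1/60 Hz drift by construction — this is
the correct time-domain counterpart of the estimate).

## Nonlinear metrics

**DFA.**  Integrate y(k) = Σ<sub>i≤k</sub>(RR<sub>i</sub> − mean RR); for
each integer box size n, partition y from the start into ⌊N/n⌋ boxes (tail
discarded, no reversed second pass — the simplest faithful reading of
non-overlapping equal boxes), fit a least-squares line per box, and take
F(n) as the RMS residual over the covered length.  α1 and α2 are natural-
log slopes of F(n) vs n over the inclusive integer ranges [4, 11] and
[12, 64]; the strict-inequality reading ([5, 10], [13, 63]) is available
via the range arguments.  Inclusive ranges follow the usual short-/long-
term convention of starting the short-term window at 4 beats.

A calibration caveat documented here because it is easy to misread:
first-order DFA has an exactly known small-box bias for uncorrelated
input, E[F²(n)] = σ²(n² − 4)/(15 n), so the *expected* α1 of white noise
measured over boxes 4–11 is ≈ 0.62, not 0.5 (the asymptotic value).  The
long-range exponent is unbiased in practice: white noise gives α2 ≈ 0.5
and an integrated random walk α2 ≈ 1.5.  The implementation reproduces the
canonical estimator faithfully rather than correcting the small-box bias,
because reported α1 values in the rodent literature carry the same bias.

**Poincaré.**  With pairs x = RR<sub>n</sub>, y = RR<sub>n+1</sub>:
SD1 = SD of (x − y)/√2 and SD2 = SD of (x + y)/√2, both about their means
with the **pair count** as denominator.  Under that convention
SD1 = RMSSD/√2 holds exactly whenever the mean successive difference is
zero, and SD1² + SD2² ≈ 2·SDNN² (up to end effects, within 2 % for ≥ 500
beats).  SD2/SD1 is reported as NaN when SD1 = 0 rather than raising.

**Entropies.**  Chebyshev (max-norm) template distance, m = 2,
r = 0.2 × sample SD — the common HRV convention (r between 10 % and 25 %
of SD).  ApEn includes self-matches (Φ<sup>m</sup> − Φ<sup>m+1</sup> with
counts over N − m + 1 templates); SampEn excludes them and counts ordered
pairs over the same N − m templates for both lengths, −ln(A/B).  An
undefined SampEn (A = 0) is reported as NaN, never infinity, keeping group
tables numeric with explicit missingness.  A constant series returns 0 for
both by convention.  Both implementations agree with a direct O(N²)
pair-counting oracle to machine precision (tested).

## Group statistics

Shapiro–Wilk normality screen per group, one-way ANOVA across the three
groups, and pairwise two-sided t-tests.  Pairwise tests default to Welch
(unequal variances): the published group SDs differ up to four-fold and the
test variant is not disclosed.  No multiplicity correction by default,
matching the apparent original practice; Holm is available behind a flag.
Exact p values are reported together with the conventional grades
(*/**/***).  `welch_t_from_summary` runs the identical Welch test from
(mean, SD, n) triples and matches the raw-data path to 10⁻¹⁰; it makes the
published group tables directly auditable — e.g. the KX vs P heart-rate
summaries give |t| = 7.74, p ≈ 1.1 × 10⁻⁵.

## Synthetic data: what it emulates, and what it does not

The generator uses integral pulse frequency modulation: beats fire at
integer crossings of ∫(1 + m(t))/T dt with T the target mean interval.
IPFM guarantees positive intervals and is the standard beat-generation
model for HRV validation; direct RR-noise addition was rejected because it
can produce non-physical interval sequences.  The modulation m(t) is a sum
of

- a VLF drift: Gaussian noise low-passed at 0.15 Hz (4th-order
  Butterworth, zero-phase), unit-normalized — a mechanism choice, since no
  VLF structure is reported for these recordings;
- LF and HF sinusoidal carriers at 0.4 and 2.5 Hz — the band midpoints,
  chosen because the bands are defined but no carrier frequencies are
  measured (no respiration co-signal is recorded for anesthetized mice);
- a fractal 1/f<sup>β</sup> Gaussian component carrying the remainder of
  the power budget (β = 1 in the presets).

Component amplitudes follow the requested band fractions; the sinusoid
amplitudes are pre-emphasized by the inverse Berger window gain
1/|sinc(f·0.2 s)| so the requested fractions refer to the *analyzed*
(resampled) spectrum; a one-pass pilot calibration (generate → measure
interval SD → rescale linearly → regenerate) brings the emitted SD to the
requested `total_sd`.  Exact fraction matching is not promised — the
one-pass scheme targets the stated tolerances only.  The integrand is
evaluated on a 250 Hz grid with trapezoidal integration and linear
interpolation of the integer crossings; a modulation that would drive
1 + m(t) near or below zero is rejected.

Presets (mean_rr = 60000/HR, total_sd = group SDNN):

| group | mean HR (bpm) | SDNN (ms) | VLF / LF / HF / fractal fractions |
|---|---|---|---|
| KX | 253.81 | 8.57  | 0.35 / 0.10 / 0.45 / 0.10 |
| P  | 376.39 | 4.58  | 0.35 / 0.22 / 0.08 / 0.35 |
| PF | 377.99 | 2.498 | 0.28 / 0.34 / 0.08 / 0.30 |

The mixtures are statistical mimics chosen once to reproduce each group's
variability *structure* — KX pairs deep bradycardia with strong
beat-to-beat (HF) variability and a large slow drift (high RMSSD and SD1,
SD2/SD1 near 1.5), while P and PF are slow-component-dominated (SD2/SD1
near 2.5–3) — not pharmacokinetic models of the anesthetics.  At the KX
beat rate (~4.2 Hz) the 2.5 Hz carrier lies above the beat-sampling
Nyquist frequency and aliases to ~1.7 Hz; that alias is still inside the
murine HF band, which is why the preset remains usable, but printed
relative-power triples for KX should be read with that in mind.  Passing
tests on these signals demonstrate correctness of the estimators and of
the pipeline plumbing, not that any particular animal's spectrum looks
like the presets; real recordings additionally contain movement artifact,
electrode noise and nonstationarity that the generator does not model.

The ECG renderer places five Gaussian bumps (P, Q, R, S, T) at each beat
time — murine defaults: R 1.0 mV with σ = 2 ms (QRS span ≈ 10 ms), T wave
22 ms after R reflecting the short murine ST segment — plus a 0.3 Hz
baseline wander (0.05 mV) and white noise (0.01 mV).  Morphology is fully
configurable since no waveform numerics accompany the published group
tables.  Ground-truth R times are returned with the record, enabling exact
detector scoring.

## Determinism and problem sizes

All randomness flows through `numpy.random.default_rng` seeds; identical
(spec, duration, seed) triples are bit-reproducible, and the study runner
derives per-subject seeds from one master seed via `SeedSequence`.  The
shipped study scale mirrors the original design at desk scale: 3 groups ×
7 subjects × 300 s records (≈ 1300–1900 beats per subject), which runs in
well under a minute; detector validation uses 50 × 60 s records at 4 kHz.

## Known limitations

- Whether time-domain and nonlinear metrics should be computed on the
  beat-domain tachogram or on the 10 Hz interpolated signal is ambiguous
  in the original description; the default is the conventional beat-domain
  NN input, and `interpolated_domain = True` applies the literal
  same-series reading (all metrics on the 10 Hz signal).
- Published total-power units are not stated; absolute powers here are ms²
  by construction.  The published relative-power triples are internally
  inconsistent with their own narrative in places; this package reports
  computed values and takes no side.
- No multi-lead fusion, arrhythmia classification, autoregressive/
  Lomb–Scargle spectra, multiscale entropy, or real-time streaming.
- TINN's exhaustive search is O(bins³) and intended for the narrow murine
  NN histograms it was designed for; very broad histograms (hundreds of
  ms spread at 1 ms bins) will be slow and should use a coarser bin.
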
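# Methods

## Scope

`abrkit` implements the analysis chain used to quantify auditory brainstem
responses (ABRs) in rodent hearing studies: averaging raw evoked-potential
sweeps into per-condition traces, measuring wave I–IV peaks, estimating
hearing thresholds across frequency (audiograms), extracting the binaural
interaction component (BIC/DN1) across interaural time differences (ITDs),
and comparing groups (sex × genotype) with linear mixed-effects models and
estimated marginal means.  Because no public ABR recordings accompany the
study design this package targets, it ships a first-class synthetic
generator whose ground truth drives every test.

## Acquisition conventions

All traces cover a 12 ms window starting at stimulus onset, sampled at
97656.25 Hz.  `ceil(12 ms × fs) = 1172` samples, `t[n] = n/fs` — fixed so
sample-index assertions are exact.  Voltages are arbitrary units (aV): only
ratios between conditions and groups are meaningful, so the generator's
absolute scale is a free convention (wave amplitudes ~1 aV at 90 dB SPL).

## The synthetic response model

The generator is a forward model of the measured quantities, not of cochlear
mechanics.  Its conventions:

- **Wave shape.** Each wave I–IV is a Gaussian-windowed biphasic deflection:
  a positive lobe at latency *L* followed by a trough at *L + 1.5 w*
  (unit-normalized on the sample grid), with per-wave width *w* ≈ 0.16–0.22 ms.
  This yields unambiguous peak/trough pairs matching the peak-to-trough
  quantification rule.  Default latencies 1.3/2.2/3.1/4.3 ms and peak
  amplitudes 1.2/1.0/0.8/1.0 aV are configurable conventions chosen to look
  like a healthy mouse click ABR at 90 dB SPL.
- **Level growth.** Amplitude grows linearly above a per-stimulus threshold:
  `gain = max(0, (level − T₀)/60 dB)`, exactly zero at and below `T₀`.
  Linear growth keeps threshold recovery well-posed.  Click `T₀` = 30 dB SPL;
  tone `T₀` follows a typical mouse audiogram (best 8–16 kHz):
  60/45/35/30/35/40/45/55 dB at 1/2/4/8/16/24/32/46 kHz.
  The *hearing threshold* recorded in truth tables is the lowest **tested**
  level with strictly positive amplitude (the lowest level at which a
  response exists), one grid step above `T₀` when `T₀` lies on the grid.
- **Binaural condition.** `binaural = left + right − DN1`, with each ear's
  wave complex delayed by ∓ itd/2 (positive ITD = left leads) and DN1 a
  negative Gaussian (width 0.25 ms) near wave IV (4.55 ms).  DN1 amplitude
  decays as `exp(−|itd|/2 ms)` and latency grows as `0.25 ms per ms |itd|`,
  the simplest smooth monotone forms consistent with the qualitative
  behaviour of the rodent BIC.  The monaural members of an ITD triplet carry
  the same per-ear delays, so the subtraction identity holds exactly at zero
  noise.
- **Baseline convention.** Every noiseless condition waveform is emitted
  with its 12 ms mean subtracted, and truth metrics are measured on that
  zero-mean waveform.  The analysis zeroes traces the same way, so truth and
  measurement share one baseline; without this the full-window zeroing would
  bias DN1 amplitude by the kernel's mean (~5%).
- **Group effects.** Configurable per (sex, genotype): a multiplicative wave
  IV amplitude factor, a DN1 latency shift applied **only at 0 ITD**, and a
  high-frequency (32/46 kHz) threshold shift in dB.  The "study" preset uses
  ×0.7 wave IV in homozygous mutant females, +0.2 ms DN1 latency and +15 dB
  high-frequency shift in mutant males.  Defaults are null.
- **Animal heterogeneity.** Each animal draws an amplitude intercept
  (SD 0.1 aV, added to every wave's base amplitude) and small per-wave
  latency offsets (SD 0.02 ms).  Litter labels are assigned round-robin
  within group and carry no generative effect.  Morphometrics: pinna length
  9.8 ± 0.4 mm, width 6.6 ± 0.3 mm, interpinna 15.5 ± 0.6 mm, nose-to-pinna
  23 ± 0.8 mm; weight 23 ± 1.5 g (females) vs 28 ± 1.5 g (males) — the only
  morphological group effect is sex on weight.
- **Noise.** Per-sweep white Gaussian background (default SD 0.3 aV) plus,
  with probability 0.05, a heartbeat-like transient (Gaussian bump,
  0.4 ms wide, 15 aV) at a random latency.  Averaging N accepted sweeps
  reduces background by √N; the defaults give an averaged-trace SNR of
  ~25–60 for 100–500 sweeps, comparable to a clean recording session.

What the generator does **not** emulate: realistic 1/f or EMG-coloured
noise, wave-shape variability across animals beyond latency/amplitude
offsets, adaptation across sweeps, electrode drift, or any cochlear
nonlinearity (growth is piecewise-linear, not sigmoid).  Passing tests
therefore demonstrate the correctness and calibration of the *analysis* under
a known truthful signal model — not robustness to every pathology of real
recordings.

## Preprocessing

Fixed order: reject → average → filter → zero-baseline, all settings recorded
in trace provenance.

- **Artifact rejection** thresholds each sweep's peak |voltage|; rejection is
  strict (`>`), a sweep exactly at threshold is kept.  The default threshold
  is `median(p) + 5·MAD(p)` over the per-sweep peaks *p* — a robust outlier
  rule on the statistic being thresholded; an absolute aV threshold can be
  given instead.  If every sweep is rejected the condition fails loudly.
- **Averaging** is the pointwise arithmetic mean of accepted sweeps.
- **Filtering** is a second-order Butterworth 50–3000 Hz bandpass applied
  forward–backward (`sosfiltfilt`), i.e. zero-phase, so peak latencies — the
  core metric — are unbiased.  The effective magnitude response is the
  squared design response.  Note that steady-state probes (sines, DC) need
  test windows much longer than 12 ms: the 50 Hz corner's time constant makes
  a 12 ms window edge-dominated for tones, while the compact mid-window ABR
  deflections are essentially unaffected (≤1 sample latency shift, 1–4%
  amplitude attenuation).
- **Baselining** subtracts the full-window mean (there is no pre-stimulus
  segment; the window starts at onset).

## Wave I–IV quantification

Per-wave search windows default to the response model's latencies ±0.6 ms
(overlaps split at the midpoint); for real data they come from
configuration.  Within its window, a wave is the most prominent local
maximum (`scipy.signal.find_peaks` prominence), ties broken toward the
earliest latency; candidates below `min_prominence` leave the wave *missing*
— never zero-filled, so the statistics layer sees missingness explicitly.
The trough is the minimum between the peak and the next detected wave's
peak; wave IV's trough search extends 1.5 ms past its peak (no wave V bounds
it in this scheme).  Amplitude = peak − trough, latency = time of peak.
Manual overrides can move or clear any wave; edited entries are re-measured
with the same trough rule and marked `source='manual'`, and edits that break
the I→IV latency order are rejected.

Monaural summaries average the two ears' metrics per wave ("measure then
average").  Averaging the two ears' *traces* before measuring is the other
reading of the procedure; metric averaging was chosen because it is robust
to small inter-ear latency differences that would smear an averaged trace,
and a wave missing in one ear falls back to the other ear's value, flagged.

## Threshold estimation

The reference procedure is a human rater watching traces as level descends
in 5–10 dB steps.  The declared algorithmic surrogate: a response is present
when the RMS of the 0.5–9 ms response window strictly exceeds
`criterion_multiple` (default 2.0) × a noise floor estimated from the
lowest-level (subthreshold) trace of the same series.  The threshold is the
lowest tested level at which detection holds *and* persists at every higher
level (monotone enforcement, standing in for the rater's smoothing of
isolated flickers); failure at the top level reports "no response".
Thresholds are reported as tested levels, never interpolated.  A
template-projection detector (normalized cross-correlation against a
suprathreshold template) is available behind the same interface and is more
selective at equal criterion because off-template noise does not count.
Raising the criterion can only raise the estimate.

## BIC / DN1

`BIC = binaural − (left + right)`, pointwise, after identical preprocessing.
DN1 is the minimum of the BIC within ±1.5 ms (widened by |itd|/2) of the
wave IV peak detected on the *summed* ABR.  The measurement is absent when
wave IV gives no anchor, when the extremum is non-negative, or when its
magnitude is below 3× the RMS of the BIC outside the search window (the
declared absence floor — the reference procedure has none).  Amplitude is
reported as the non-negative magnitude relative to the zero baseline; the
signed value is retained.  Series across the ±2 ms ITD grid keep absent
entries as explicit gaps.

## Statistics

Responses in long format (animal, sex, genotype, litter, condition, value)
are fitted by REML with `statsmodels` MixedLM: fixed effects
`sex * genotype * condition + litter`, random intercept per animal.
Rank-deficient designs raise an error naming the aliased columns.  A
variance component whose SD falls below 1% of the residual SD is flagged
singular (the optimizer stops slightly off an exact zero boundary), never
hidden.

Group comparisons use estimated marginal means: model predictions on the
full factor grid, averaged with equal weights over nuisance factors, with
contrast variance from the fixed-effects covariance.  Degrees of freedom are
between–within style: `df = n_animals − rank(animal-averaged design)`,
which is exact for between-animal contrasts in the balanced designs
generated here (a Satterthwaite approximation is not available in the
underlying fitter; for these balanced designs the two coincide).  Pairwise
contrasts within a family of k levels use the studentized-range (Tukey)
adjustment; raw and adjusted p-values are both reported, with significance
tiers * p<0.05, ** p<0.01, *** p<0.0001.  Marginal means make the contrasts
invariant to factor reference-level recoding.

Morphological measures use two-way ANOVA (sex × genotype, type II) with
Tukey HSD post hocs; empty or single-observation cells raise explicit
errors.  Missing waves are dropped rows, never imputed.

## Problem sizes

Simulation-based checks are scaled to routine hardware: detection fidelity
uses 500 traces built as 100-sweep averages at the default noise; threshold
recovery uses 200 series at single-sweep SNR 5 averaged over 50 sweeps;
statistical power and type-I calibration use 100 replicate cohorts of 8
animals per sex × genotype cell with 60 sweeps per condition.  The shipped
demo pipeline configuration uses 2 animals per cell with 50 sweeps and a
10 dB audiogram grid; at that size mixed-model REML can fail to converge
for near-constant responses (latencies), in which case the affected
contrast family is skipped and recorded in provenance rather than aborting
the run.

## Known limitations

- The RMS detector's noise floor comes from the lowest-level trace; if the
  series bottoms out above threshold the floor is inflated and thresholds
  biased upward (the tested grids reach 20 dB SPL, below every default
  threshold).
- DN1 anchoring requires a detectable wave IV on the summed trace; at large
  |ITD| the summed wave IV is bimodal and the anchor follows the more
  prominent mode, which the widened search window absorbs.
- Mixed-model inference uses between–within df, exact only for balanced
  between-animal contrasts; strongly unbalanced real designs would warrant
  Satterthwaite/Kenward–Roger machinery not implemented here.
- Generator realism limits listed above apply to every simulation result.
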
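# abrkit

Analysis toolkit for **auditory brainstem responses (ABRs)** in rodent
hearing studies: epoch preprocessing and averaging, wave I–IV peak
quantification, audiogram (hearing-threshold) estimation, **binaural
interaction component (BIC/DN1)** extraction across interaural time
differences (ITDs), morphometrics, and mixed-model group comparisons —
validated end-to-end against a built-in synthetic ABR generator with known
ground truth.

## Who this is for

Auditory electrophysiology labs measuring click/tone ABRs in mice (or other
small rodents) who want the quantification steps that are usually buried in
rig-specific scripts — artifact rejection, zero-phase filtering, peak/trough
measurement, threshold calls, BIC subtraction, and the factorial statistics —
as tested, reproducible library code.

## The measurements

An ABR epoch is a 12 ms voltage sweep sampled at 97656.25 Hz, time-locked to
a click or tone burst.  After rejecting high-amplitude (heartbeat) sweeps,
averaging hundreds of repetitions, applying a second-order 50–3000 Hz
zero-phase bandpass and zeroing the baseline:

- **Wave I–IV metrics** — for each wave, amplitude is the voltage from peak
  to the following trough ("the lowest point for that wave") and latency the
  time to peak.  Detection picks the most prominent local maximum inside a
  per-wave latency window; manual corrections are supported.
- **Thresholds** — the lowest level (dB SPL) at which a response is
  detected, as level descends in 5–10 dB steps; across the 1–46 kHz tone
  grid this gives the audiogram.  The rater's visual call is replaced by a
  declared RMS-versus-noise-floor criterion.
- **BIC / DN1** — the binaural ABR minus the sum of the two monaural ABRs;
  its prominent negative wave DN1 (aligned with wave IV) indexes binaural
  brainstem interaction.  Measured across ITDs of ±2 ms in 0.5 ms steps,
  DN1 amplitude decays and latency grows with |ITD|.
- **Group statistics** — linear mixed-effects models (sex, genotype, litter
  and condition as fixed effects; animal as random intercept) with
  estimated-marginal-mean pairwise contrasts (Tukey-adjusted), plus two-way
  ANOVA for morphological measures such as the effective pinna diameter
  √(length × width).

The synthetic generator produces all of this with configurable group-effect
structure (wave IV amplitude deficits, DN1 latency shifts at 0 ITD,
high-frequency threshold elevations) and emits truth tables, so every stage
is testable without any recordings.  See `docs/methods.md` for the model and
its conventions.

## Worked example

Measure waves on an averaged click response (`examples/01_preprocess_and_peaks.py`):

```python
import numpy as np
from abrkit import StimulusSpec, detect_peaks, preprocess, synth_epochs
from abrkit.simulate import NoiseModel

spec = StimulusSpec("click", "left", level_db=90.0)
epochs, truth = synth_epochs(spec, n_epochs=200,
                             noise=NoiseModel(background_sd_av=0.3, artifact_rate=0.05),
                             rng=np.random.default_rng(0))
trace = preprocess(epochs)                    # reject -> average -> filter -> zero
peaks = detect_peaks(trace, min_prominence=0.1)
```

prints

```
sweeps accepted: 190, rejected: 10 (generator injected 9 artifacts)
wave  latency ms  amplitude aV  truth lat  truth amp
   I       1.239         2.321      1.239      2.396
  II       2.130         1.935      2.140      1.981
 III       3.031         1.558      3.031      1.589
  IV       4.219         1.979      4.219      2.000
```

Latencies agree with generator truth to about one sample (0.0102 ms);
amplitudes sit a few percent below truth because the bandpass mildly
attenuates each wave.  The other examples cover audiograms
(`02_audiogram.py` — a mutant male's +15 dB shift appears only at 32/46 kHz),
the DN1-versus-ITD series (`03_bic_itd_series.py`), group statistics
(`04_group_statistics.py` — a 30% female wave IV deficit is recovered as a
−0.50 ± 0.09 aV Tukey-significant contrast, with the sexes' 5 g weight
difference showing up in the morphometrics ANOVA), and the full pipeline
(`05_full_pipeline.py`).

## Command line

```bash
abrkit run --seed 17 --out demo_out/          # full pipeline, demo cohort
abrkit synth --config cohort.yaml --seed 17 --out epochs/
abrkit preprocess --epochs epochs/ --out traces/
abrkit peaks | audiogram | bic | stats ...    # single stages
```

All subcommands take `--config` (YAML, see `abrkit.config.RunConfig`),
`--seed`, `--out` and `--log-level`.  Identical config + seed reproduces
every output file byte-for-byte.

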
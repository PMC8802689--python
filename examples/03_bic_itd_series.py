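"""Extract the binaural interaction component (DN1) across ITDs.

For each interaural time difference on the +/-2 ms grid, synthesizes the
(left, right, binaural) sweep triplet, preprocesses each, subtracts the
summed monaural ABR from the binaural ABR, and measures the DN1 deflection
near the summed-trace wave IV.  Amplitude decays and latency grows with
|ITD|, the signature of binaural brainstem interaction.
"""
import numpy as np

from abrkit import bic_itd_series, preprocess, synth_bic_triplet
from abrkit.core import ITD_GRID_MS
from abrkit.simulate import NoiseModel

rng = np.random.default_rng(2)
noise = NoiseModel(background_sd_av=0.3, artifact_rate=0.02)

triplets = {}
for itd in ITD_GRID_MS:
    left, right, binaural, _truth = synth_bic_triplet(
        90.0, itd, n_epochs=150, noise=noise, rng=rng)
    triplets[itd] = (preprocess(left), preprocess(right), preprocess(binaural))

series = bic_itd_series(triplets, min_prominence=0.1)
print(f"{'ITD ms':>7} {'DN1 latency ms':>15} {'DN1 amplitude aV':>17}")
for itd in series.itds():
    m = series.measurements[itd]
    if m is None:
        print(f"{itd:+7.1f} {'absent':>15}")
    else:
        print(f"{itd:+7.1f} {m.latency_ms:15.3f} {m.amplitude_av:17.3f}")
print("Amplitude peaks at 0 ITD and decays symmetrically; latency is shortest")
print("at 0 ITD and grows ~0.25 ms per ms of |ITD|.")
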
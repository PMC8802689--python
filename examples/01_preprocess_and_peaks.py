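"""Average raw ABR sweeps and quantify waves I-IV.

Synthesizes 200 click sweeps at 90 dB SPL for one ear (with background noise
and occasional heartbeat artifacts), runs the preprocessing chain
(reject -> average -> 50-3000 Hz zero-phase bandpass -> zero baseline), and
measures each wave's peak-to-trough amplitude and time-to-peak latency.
"""
import numpy as np

from abrkit import StimulusSpec, detect_peaks, preprocess, synth_epochs
from abrkit.simulate import NoiseModel

spec = StimulusSpec("click", "left", level_db=90.0)
epochs, truth = synth_epochs(
    spec, n_epochs=200, noise=NoiseModel(background_sd_av=0.3, artifact_rate=0.05),
    rng=np.random.default_rng(0),
)
trace = preprocess(epochs)
print(f"sweeps accepted: {trace.n_accepted}, rejected: {trace.n_rejected} "
      f"(generator injected {len(truth.artifact_epochs)} artifacts)")

peaks = detect_peaks(trace, min_prominence=0.1)
print(f"{'wave':>4} {'latency ms':>11} {'amplitude aV':>13} {'truth lat':>10} {'truth amp':>10}")
for wave, wt in zip(("I", "II", "III", "IV"), truth.waves):
    p = peaks[wave]
    print(f"{wave:>4} {p.peak_latency_ms:11.3f} {p.amplitude_av:13.3f} "
          f"{wt.peak_latency_ms:10.3f} {wt.amplitude_av:10.3f}")
print("Latencies match generator truth to ~one sample (0.0102 ms); amplitudes")
print("sit a few percent low because the bandpass slightly attenuates each wave.")
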
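"""Estimate an audiogram: hearing threshold across tone frequencies.

For each of the 8 tone frequencies, synthesizes averaged traces down a
descending 5 dB level series and finds the lowest level at which the RMS
response detector fires (and keeps firing at all higher levels).  The animal
is a mutant male carrying a +15 dB high-frequency threshold shift, visible
at 32 and 46 kHz.
"""
import numpy as np

from abrkit import StimulusSpec, build_audiogram
from abrkit.core import FS_HZ, TONE_FREQS_KHZ, AveragedTrace
from abrkit.simulate import AnimalModel, condition_waveform, study_effects

rng = np.random.default_rng(1)
animal = AnimalModel("M-Fmr1-00", "male", "Fmr1")
effects = study_effects()
levels = [float(v) for v in range(90, 15, -5)]

series_by_freq = {}
for f in TONE_FREQS_KHZ:
    series = []
    for level in levels:
        spec = StimulusSpec("tone", "left", level, frequency_khz=f)
        signal, _ = condition_waveform(spec, effects=effects, animal=animal)
        noisy = signal + rng.normal(0.0, 0.01, signal.size)  # ~100-sweep average
        series.append((level, AveragedTrace(noisy, FS_HZ, spec, animal.animal)))
    series_by_freq[f] = series

audiogram = build_audiogram(series_by_freq)
print("frequency (kHz) : threshold (dB SPL)")
for f in TONE_FREQS_KHZ:
    print(f"{f:15g} : {audiogram.threshold(f):g}")
print("Best hearing sits at 8-16 kHz; the +15 dB mutant-male shift raises only")
print("the 32 and 46 kHz thresholds relative to a wild-type audiogram.")
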
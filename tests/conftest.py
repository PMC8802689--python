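"""Shared fixtures: noiseless models, quick trace builders, measurement tables."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from abrkit import simulate as sim
from abrkit.core import FS_HZ, WAVES, AveragedTrace, StimulusSpec


@pytest.fixture
def noise_free() -> sim.NoiseModel:
    return sim.NoiseModel(background_sd_av=0.0, artifact_rate=0.0)


@pytest.fixture
def kernels() -> sim.WaveKernelParams:
    return sim.WaveKernelParams()


@pytest.fixture
def click90() -> StimulusSpec:
    return StimulusSpec("click", "left", 90.0)


def make_trace(samples, spec=None, animal="A0", **kw) -> AveragedTrace:
    return AveragedTrace(np.asarray(samples, dtype=float), FS_HZ, spec, animal, **kw)


@pytest.fixture
def trace_factory():
    return make_trace


def noisy_condition_trace(spec, sd, rng, kernels=None, effects=None, animal=None):
    """Averaged-trace-level synthesis: noiseless waveform + trace noise."""
    sig, truth = sim.condition_waveform(spec, kernels, effects, animal)
    tr = AveragedTrace(sig + rng.normal(0.0, sd, sig.size), FS_HZ, spec,
                       animal.animal if animal else "A0")
    return tr, truth


@pytest.fixture
def noisy_trace_factory():
    return noisy_condition_trace


def truth_measurement_table(cohort: sim.Cohort, rng: np.random.Generator,
                            meas_sd: float = 0.05) -> pd.DataFrame:
    """Fast per-animal wave-amplitude table: generator truth + measurement noise.

    Bypasses the epoch/detection path; used where only the statistics layer is
    under test.
    """
    rows = []
    for a in cohort.animals:
        t = cohort.truth.animals[a.animal]
        for i, w in enumerate(WAVES):
            amp = 0.5 * (t.wave_amplitude_av["left"][i] + t.wave_amplitude_av["right"][i])
            rows.append({
                "animal": a.animal, "sex": a.sex, "genotype": a.genotype,
                "litter": a.litter, "condition": w,
                "amplitude_av": amp + rng.normal(0.0, meas_sd),
            })
    return pd.DataFrame(rows)


@pytest.fixture
def measurement_table_factory():
    return truth_measurement_table
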
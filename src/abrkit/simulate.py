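"""Synthetic ABR generator with known ground truth.

Emulates the acquisition used for mouse click/tone ABRs: 12 ms sweeps at
97656.25 Hz, four-wave morphology, level-dependent amplitudes above a
per-frequency hearing threshold, a binaural interaction component (the DN1
deflection) whose amplitude decays and latency grows with the interaural time
difference (ITD), Gaussian background noise, and sporadic heartbeat-like
high-amplitude artifacts.  Group effects (genotype x sex) can scale wave IV,
shift the DN1 latency at 0 ITD, and raise high-frequency thresholds, so that
the full analysis chain - preprocessing, peak metrics, audiometry, binaural
series, statistics - can be validated against generator truth.

Conventions (the response model, not a measured fact):

* a wave is a Gaussian-windowed biphasic deflection (positive lobe followed
  by a trough), peak-normalized on the sample grid;
* amplitude grows linearly with level above threshold,
  ``gain = max(0, (level - threshold) * slope)``, zero at and below threshold;
* every noiseless condition waveform is emitted baseline-zeroed (window mean
  subtracted), and all truth metrics are measured on that zero-mean waveform,
  matching the pipeline's baseline convention;
* binaural waveform = left + right (each ear delayed by -/+ itd/2)
  minus a Gaussian DN1 kernel with ``amp ~ exp(-|itd|/tau)`` and
  ``latency = L0 + c*|itd|`` (+ any group shift, applied at itd = 0 only).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    FS_HZ,
    GENOTYPES,
    ITD_GRID_MS,
    N_SAMPLES,
    SEXES,
    TONE_FREQS_KHZ,
    WAVES,
    EpochSet,
    StimulusSpec,
    time_axis_ms,
)

GroupKey = Tuple[str, str]  # (sex, genotype)

#: Default per-frequency zero-amplitude levels (dB SPL): a typical mouse
#: audiogram, best hearing 8-16 kHz, rising toward both edges.
DEFAULT_TONE_THRESHOLDS_DB: Mapping[float, float] = {
    1.0: 60.0,
    2.0: 45.0,
    4.0: 35.0,
    8.0: 30.0,
    16.0: 35.0,
    24.0: 40.0,
    32.0: 45.0,
    46.0: 55.0,
}

#: Frequencies counted as "high frequency" for threshold-shift effects (kHz).
HIGH_FREQS_KHZ = (32.0, 46.0)


@dataclass(frozen=True)
class WaveKernelParams:
    """Shape parameters of the four-wave ABR response model.

    Latencies must be strictly increasing and inside the 12 ms window.
    ``base_amplitude_av`` is the peak value at unit level gain; the
    peak-to-trough amplitude of the biphasic kernel is proportionally larger.
    """

    base_latency_ms: Tuple[float, ...] = (1.3, 2.2, 3.1, 4.3)
    base_amplitude_av: Tuple[float, ...] = (1.2, 1.0, 0.8, 1.0)
    width_ms: Tuple[float, ...] = (0.16, 0.18, 0.20, 0.22)
    latency_jitter_sd_ms: float = 0.02
    #: trough center sits ``trough_separation * width`` after the peak lobe
    trough_separation: float = 1.5

    # DN1 (binaural interaction) kernel
    dn1_latency_ms: float = 4.55
    dn1_width_ms: float = 0.25
    dn1_amplitude_av: float = 0.8
    dn1_itd_tau_ms: float = 2.0
    dn1_itd_latency_slope: float = 0.25  # ms per ms of |itd|

    # level growth
    level_slope_per_db: float = 1.0 / 60.0
    click_threshold_db: float = 30.0
    tone_thresholds_db: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_TONE_THRESHOLDS_DB)
    )

    def __post_init__(self) -> None:
        lats = self.base_latency_ms
        if len(lats) != 4 or len(self.base_amplitude_av) != 4 or len(self.width_ms) != 4:
            raise ValueError("exactly four waves (I-IV) are modelled")
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise ValueError("wave latencies must be strictly increasing")
        if max(lats) >= 12.0:
            raise ValueError("wave latencies must fall inside the 12 ms window")
        if any(w <= 0 for w in self.width_ms):
            raise ValueError("wave widths must be positive")


@dataclass(frozen=True)
class GroupEffects:
    """Genotype x sex effect structure injected by the generator.

    Defaults are the null model (all multipliers 1, all shifts 0).  Keys are
    ``(sex, genotype)`` tuples; unlisted groups get the null value.
    """

    wave4_amp_multiplier: Mapping[GroupKey, float] = field(default_factory=dict)
    dn1_latency_shift_at_zero_itd_ms: Mapping[GroupKey, float] = field(default_factory=dict)
    highfreq_threshold_shift_db: Mapping[GroupKey, float] = field(default_factory=dict)
    animal_intercept_sd_av: float = 0.1

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.wave4_amp_multiplier.values()):
            raise ValueError("wave IV multipliers must be positive")
        for mapping in (
            self.dn1_latency_shift_at_zero_itd_ms,
            self.highfreq_threshold_shift_db,
        ):
            if any(not np.isfinite(v) for v in mapping.values()):
                raise ValueError("group shifts must be finite")
        if self.animal_intercept_sd_av < 0:
            raise ValueError("random-intercept SD must be >= 0")

    def wave4_mult(self, sex: str, genotype: str) -> float:
        return float(self.wave4_amp_multiplier.get((sex, genotype), 1.0))

    def dn1_shift(self, sex: str, genotype: str) -> float:
        return float(self.dn1_latency_shift_at_zero_itd_ms.get((sex, genotype), 0.0))

    def threshold_shift(self, sex: str, genotype: str, frequency_khz: float) -> float:
        if any(np.isclose(frequency_khz, f) for f in HIGH_FREQS_KHZ):
            return float(self.highfreq_threshold_shift_db.get((sex, genotype), 0.0))
        return 0.0


def study_effects() -> GroupEffects:
    """The group-effect structure the cohort study design assumes.

    Homozygous Fmr1 females carry a 30% wave IV amplitude deficit, Fmr1
    males a +0.2 ms DN1 latency shift at 0 ITD and a +15 dB high-frequency
    threshold elevation.
    """
    return GroupEffects(
        wave4_amp_multiplier={("female", "Fmr1"): 0.7},
        dn1_latency_shift_at_zero_itd_ms={("male", "Fmr1"): 0.2},
        highfreq_threshold_shift_db={("male", "Fmr1"): 15.0},
    )


@dataclass(frozen=True)
class NoiseModel:
    """Background and artifact model for raw sweeps.

    ``background_sd_av`` is per-epoch white Gaussian noise; averaging N
    accepted sweeps reduces it by sqrt(N).  With probability
    ``artifact_rate`` an epoch additionally receives a heartbeat-like
    transient of peak ``artifact_amplitude_av`` (much larger than the
    background so threshold rejection is well defined).
    """

    background_sd_av: float = 0.3
    artifact_rate: float = 0.05
    artifact_amplitude_av: float = 15.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be a probability")
        if self.background_sd_av < 0 or self.artifact_amplitude_av < 0:
            raise ValueError("noise amplitudes must be >= 0")


@dataclass
class AnimalModel:
    """Per-animal latent parameters drawn once per synthetic animal."""

    animal: str
    sex: str
    genotype: str
    litter: str = "L1"
    amp_offset_av: float = 0.0
    latency_offsets_ms: Tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    pinna_length_mm: float = 9.8
    pinna_width_mm: float = 6.6
    interpinna_mm: float = 15.5
    nose_to_pinna_mm: float = 23.0
    weight_g: float = 25.0


@dataclass
class WaveTruth:
    """True peak/trough metrics of one wave on the noiseless waveform."""

    wave: str
    present: bool
    peak_latency_ms: float = float("nan")
    peak_value_av: float = float("nan")
    trough_latency_ms: float = float("nan")
    trough_value_av: float = float("nan")
    amplitude_av: float = float("nan")


@dataclass
class ConditionTruth:
    """Ground truth attached to one synthesized condition."""

    spec_key: str
    noiseless: np.ndarray
    waves: List[WaveTruth] = field(default_factory=list)
    dn1_latency_ms: Optional[float] = None
    dn1_amplitude_av: Optional[float] = None
    artifact_epochs: Tuple[int, ...] = ()


def _biphasic_kernel(t_ms: np.ndarray, latency_ms: float, width_ms: float,
                     separation: float) -> np.ndarray:
    """Peak-normalized positive-lobe-then-trough deflection."""
    g1 = np.exp(-0.5 * ((t_ms - latency_ms) / width_ms) ** 2)
    g2 = np.exp(-0.5 * ((t_ms - latency_ms - separation * width_ms) / width_ms) ** 2)
    k = g1 - g2
    peak = k.max()
    return k / peak if peak > 0 else k


def _gauss_kernel(t_ms: np.ndarray, latency_ms: float, width_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - latency_ms) / width_ms) ** 2)


def level_gain(level_db: float, threshold_db: float, slope_per_db: float) -> float:
    """Linear suprathreshold growth, clipped at zero at/below threshold."""
    return max(0.0, (level_db - threshold_db) * slope_per_db)


def threshold_for(spec: StimulusSpec, kernels: WaveKernelParams,
                  effects: GroupEffects, sex: str = "female",
                  genotype: str = "B6") -> float:
    """Generative zero-amplitude level for this stimulus and group (dB SPL)."""
    if spec.modality == "click":
        return kernels.click_threshold_db
    base = None
    for f, thr in kernels.tone_thresholds_db.items():
        if np.isclose(f, spec.frequency_khz):
            base = thr
            break
    if base is None:
        raise ValueError(f"no threshold defined for {spec.frequency_khz} kHz")
    return base + effects.threshold_shift(sex, genotype, spec.frequency_khz)


def _wave_components(spec: StimulusSpec, kernels: WaveKernelParams,
                     effects: GroupEffects, animal: AnimalModel,
                     delay_ms: float = 0.0):
    """(latency, amplitude, width) per wave for one ear's contribution."""
    gain = level_gain(
        spec.level_db,
        threshold_for(spec, kernels, effects, animal.sex, animal.genotype),
        kernels.level_slope_per_db,
    )
    comps = []
    w4 = effects.wave4_mult(animal.sex, animal.genotype)
    for i in range(4):
        lat = kernels.base_latency_ms[i] + animal.latency_offsets_ms[i] + delay_ms
        amp = max(0.0, kernels.base_amplitude_av[i] + animal.amp_offset_av) * gain
        if i == 3:
            amp *= w4
        comps.append((lat, amp, kernels.width_ms[i]))
    return comps, gain


def _render(comps, t_ms: np.ndarray, kernels: WaveKernelParams) -> np.ndarray:
    out = np.zeros_like(t_ms)
    for lat, amp, width in comps:
        if amp > 0:
            out += amp * _biphasic_kernel(t_ms, lat, width, kernels.trough_separation)
    return out


def _dn1_params(spec: StimulusSpec, kernels: WaveKernelParams,
                effects: GroupEffects, animal: AnimalModel, gain: float):
    itd = abs(spec.itd_ms)
    amp = kernels.dn1_amplitude_av * gain * np.exp(-itd / kernels.dn1_itd_tau_ms)
    lat = (
        kernels.dn1_latency_ms
        + animal.latency_offsets_ms[3]
        + kernels.dn1_itd_latency_slope * itd
    )
    if spec.itd_ms == 0.0:
        lat += effects.dn1_shift(animal.sex, animal.genotype)
    return lat, amp


def _measure_wave_truth(signal: np.ndarray, comps, fs: float,
                        post_window_ms: float = 1.5) -> List[WaveTruth]:
    """Measure true peak/trough metrics on the zero-mean noiseless waveform.

    Peak: maximum within +/-0.5 ms of the wave's component latency.  Trough:
    minimum between that peak and the next wave's peak (wave IV: a 1.5 ms
    post-window), i.e. the same quantification rule the analysis applies.
    """
    t = time_axis_ms(signal.size, fs)
    n = signal.size
    peaks = []
    for lat, amp, _w in comps:
        if amp <= 0:
            peaks.append(None)
            continue
        lo = int(np.searchsorted(t, lat - 0.5))
        hi = int(np.searchsorted(t, lat + 0.5))
        seg = signal[lo:hi]
        peaks.append(lo + int(np.argmax(seg)) if seg.size else None)
    out: List[WaveTruth] = []
    for i, name in enumerate(WAVES):
        p = peaks[i]
        if p is None:
            out.append(WaveTruth(wave=name, present=False))
            continue
        nxt = next((peaks[j] for j in range(i + 1, 4) if peaks[j] is not None), None)
        if nxt is None:
            nxt = min(n, p + int(round(post_window_ms / 1000.0 * fs)) + 1)
        seg = signal[p:nxt]
        tr = p + int(np.argmin(seg))
        out.append(
            WaveTruth(
                wave=name,
                present=True,
                peak_latency_ms=t[p],
                peak_value_av=float(signal[p]),
                trough_latency_ms=t[tr],
                trough_value_av=float(signal[tr]),
                amplitude_av=float(signal[p] - signal[tr]),
            )
        )
    return out


def condition_waveform(spec: StimulusSpec,
                       kernels: Optional[WaveKernelParams] = None,
                       effects: Optional[GroupEffects] = None,
                       animal: Optional[AnimalModel] = None,
                       ) -> Tuple[np.ndarray, ConditionTruth]:
    """Noiseless, baseline-zeroed waveform for one condition, plus its truth."""
    kernels = kernels or WaveKernelParams()
    effects = effects or GroupEffects()
    animal = animal or AnimalModel(animal="A0", sex="female", genotype="B6")
    t = time_axis_ms()

    if spec.ear in ("left", "right"):
        comps, _gain = _wave_components(spec, kernels, effects, animal,
                                        delay_ms=spec.onset_delay_ms)
        raw = _render(comps, t, kernels)
        signal = raw - raw.mean()
        truth = ConditionTruth(spec_key=spec.key, noiseless=signal,
                               waves=_measure_wave_truth(signal, comps, FS_HZ))
        return signal, truth

    # binaural: left + right (each delayed by -/+ itd/2) minus the DN1 kernel
    if spec.modality != "click":
        raise ValueError("binaural synthesis is defined for clicks only")
    half = spec.itd_ms / 2.0
    left_spec = StimulusSpec("click", "left", spec.level_db, onset_delay_ms=-half)
    right_spec = StimulusSpec("click", "right", spec.level_db, onset_delay_ms=+half)
    lcomps, gain = _wave_components(left_spec, kernels, effects, animal, delay_ms=-half)
    rcomps, _ = _wave_components(right_spec, kernels, effects, animal, delay_ms=+half)
    raw = _render(lcomps, t, kernels) + _render(rcomps, t, kernels)
    dn1_lat, dn1_amp = _dn1_params(spec, kernels, effects, animal, gain)
    dn1_raw = dn1_amp * _gauss_kernel(t, dn1_lat, kernels.dn1_width_ms)
    raw = raw - dn1_raw
    signal = raw - raw.mean()

    # DN1 truth measured exactly as the analysis sees it: on the zero-mean
    # BIC residual -(dn1_raw - mean(dn1_raw))
    bic = -(dn1_raw - dn1_raw.mean())
    truth = ConditionTruth(spec_key=spec.key, noiseless=signal)
    if dn1_amp > 0:
        imin = int(np.argmin(bic))
        truth.dn1_latency_ms = float(t[imin])
        truth.dn1_amplitude_av = float(-bic[imin])
    return signal, truth


def synth_epochs(spec: StimulusSpec, n_epochs: int,
                 kernels: Optional[WaveKernelParams] = None,
                 effects: Optional[GroupEffects] = None,
                 noise: Optional[NoiseModel] = None,
                 animal: Optional[AnimalModel] = None,
                 rng: Optional[np.random.Generator] = None,
                 ) -> Tuple[EpochSet, ConditionTruth]:
    """Synthesize raw sweeps for one condition.

    Returns the epoch stack and the condition's ground truth, including which
    repetitions carry an injected artifact.  Deterministic given ``rng`` (or
    ``noise.seed``).
    """
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    kernels = kernels or WaveKernelParams()
    effects = effects or GroupEffects()
    noise = noise or NoiseModel()
    animal = animal or AnimalModel(animal="A0", sex="female", genotype="B6")
    rng = rng if rng is not None else np.random.default_rng(noise.seed)

    signal, truth = condition_waveform(spec, kernels, effects, animal)
    data = np.tile(signal, (n_epochs, 1))
    if noise.background_sd_av > 0:
        data = data + rng.normal(0.0, noise.background_sd_av, data.shape)
    artifact_mask = rng.random(n_epochs) < noise.artifact_rate
    t = time_axis_ms()
    for i in np.flatnonzero(artifact_mask):
        center = rng.uniform(1.0, 11.0)
        data[i] += noise.artifact_amplitude_av * _gauss_kernel(t, center, 0.4)
    truth.artifact_epochs = tuple(int(i) for i in np.flatnonzero(artifact_mask))
    eset = EpochSet(data, FS_HZ, spec, animal.animal,
                    artifact_epochs=truth.artifact_epochs)
    return eset, truth


def synth_binaural_epochs(spec: StimulusSpec, n_epochs: int, **kwargs):
    """Binaural sweeps; ``spec.ear`` must be 'both' with ``itd_ms`` set."""
    if spec.ear != "both":
        raise ValueError("binaural synthesis requires ear='both'")
    return synth_epochs(spec, n_epochs, **kwargs)


def synth_bic_triplet(level_db: float, itd_ms: float, n_epochs: int,
                      kernels: Optional[WaveKernelParams] = None,
                      effects: Optional[GroupEffects] = None,
                      noise: Optional[NoiseModel] = None,
                      animal: Optional[AnimalModel] = None,
                      rng: Optional[np.random.Generator] = None):
    """Left / right / binaural epoch sets for one ITD condition.

    The monaural members carry the same per-ear onset delays as the binaural
    stimulus, so at zero noise ``binaural = left + right - DN1`` holds
    sample-for-sample and the BIC subtraction recovers the injected DN1.
    Returns ``(left, right, binaural)`` EpochSets and the binaural truth.
    """
    rng = rng if rng is not None else np.random.default_rng(
        (noise.seed if noise is not None else None))
    half = itd_ms / 2.0
    lspec = StimulusSpec("click", "left", level_db, onset_delay_ms=-half)
    rspec = StimulusSpec("click", "right", level_db, onset_delay_ms=+half)
    bspec = StimulusSpec("click", "both", level_db, itd_ms=itd_ms)
    left, _ = synth_epochs(lspec, n_epochs, kernels, effects, noise, animal, rng)
    right, _ = synth_epochs(rspec, n_epochs, kernels, effects, noise, animal, rng)
    binaural, truth = synth_epochs(bspec, n_epochs, kernels, effects, noise,
                                   animal, rng)
    return left, right, binaural, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class AnimalTruth:
    """Per-animal generative truth (analytic; no noise involved)."""

    wave_amplitude_av: Dict[str, List[float]] = field(default_factory=dict)  # ear -> 4
    wave_latency_ms: Dict[str, List[float]] = field(default_factory=dict)
    thresholds_db: Dict[float, Optional[float]] = field(default_factory=dict)
    click_threshold_db: Optional[float] = None
    dn1_latency_ms: Dict[float, float] = field(default_factory=dict)  # itd -> ms
    dn1_amplitude_av: Dict[float, float] = field(default_factory=dict)


@dataclass
class GenerativeTruth:
    """Cohort-level truth table, JSON-serializable."""

    animals: Dict[str, AnimalTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, AnimalTruth):
                d = asdict(o)
                d["thresholds_db"] = {f"{k:g}": v for k, v in o.thresholds_db.items()}
                d["dn1_latency_ms"] = {f"{k:+.1f}": v for k, v in o.dn1_latency_ms.items()}
                d["dn1_amplitude_av"] = {f"{k:+.1f}": v for k, v in o.dn1_amplitude_av.items()}
                return d
            raise TypeError(o)
        return json.dumps({"animals": {k: enc(v) for k, v in self.animals.items()}},
                          indent=1, sort_keys=True)


def default_design(genotypes: Sequence[str] = GENOTYPES) -> List[GroupKey]:
    """Full sex x genotype factorial."""
    return [(s, g) for s in SEXES for g in genotypes]


#: Morphometric sampling distributions: mean, SD (mm or g).  Only weight has
#: a sex effect (females lighter), matching the study's morphology findings.
MORPHOMETRY = {
    "pinna_length_mm": (9.8, 0.4),
    "pinna_width_mm": (6.6, 0.3),
    "interpinna_mm": (15.5, 0.6),
    "nose_to_pinna_mm": (23.0, 0.8),
    "weight_g": {"female": (23.0, 1.5), "male": (28.0, 1.5)},
}


@dataclass
class Cohort:
    """A synthetic cohort: animals, metadata table, truth, and lazy epochs.

    Epoch data are generated on demand per animal (deterministically, from
    per-animal child seeds) so large cohorts never hold all raw sweeps in
    memory at once.
    """

    animals: List[AnimalModel]
    metadata: "object"  # pandas.DataFrame
    truth: GenerativeTruth
    kernels: WaveKernelParams
    effects: GroupEffects
    noise: NoiseModel
    n_epochs: int
    level_db: float
    itds_ms: Tuple[float, ...]
    audiogram_levels_db: Tuple[float, ...]
    include: Tuple[str, ...]
    _animal_seeds: Dict[str, np.random.SeedSequence] = field(default_factory=dict)

    def monaural_click_sets(self, animal_id: str):
        """(left, right) EpochSets and truths at the reference click level."""
        a = self._animal(animal_id)
        rng = np.random.default_rng(self._animal_seeds[animal_id].spawn(1)[0])
        out = {}
        for ear in ("left", "right"):
            spec = StimulusSpec("click", ear, self.level_db)
            out[ear] = synth_epochs(spec, self.n_epochs, self.kernels,
                                    self.effects, self.noise, a, rng)
        return out

    def binaural_triplets(self, animal_id: str):
        """dict itd -> (left, right, binaural, truth)."""
        a = self._animal(animal_id)
        rng = np.random.default_rng(self._animal_seeds[animal_id].spawn(2)[1])
        return {
            itd: synth_bic_triplet(self.level_db, itd, self.n_epochs,
                                   self.kernels, self.effects, self.noise, a, rng)
            for itd in self.itds_ms
        }

    def tone_series(self, animal_id: str):
        """dict frequency -> list of (level, EpochSet, truth), descending."""
        a = self._animal(animal_id)
        rng = np.random.default_rng(self._animal_seeds[animal_id].spawn(3)[2])
        out = {}
        for f in TONE_FREQS_KHZ:
            series = []
            for lvl in self.audiogram_levels_db:
                spec = StimulusSpec("tone", "left", lvl, frequency_khz=f)
                eset, truth = synth_epochs(spec, self.n_epochs, self.kernels,
                                           self.effects, self.noise, a, rng)
                series.append((lvl, eset, truth))
            out[f] = series
        return out

    def _animal(self, animal_id: str) -> AnimalModel:
        for a in self.animals:
            if a.animal == animal_id:
                return a
        raise KeyError(animal_id)


def synth_cohort(n_per_group: int = 8,
                 design: Optional[Sequence[GroupKey]] = None,
                 kernels: Optional[WaveKernelParams] = None,
                 effects: Optional[GroupEffects] = None,
                 noise: Optional[NoiseModel] = None,
                 seed: int = 0,
                 n_epochs: int = 100,
                 level_db: float = 90.0,
                 itds_ms: Sequence[float] = ITD_GRID_MS,
                 audiogram_levels_db: Sequence[float] = tuple(range(90, 15, -5)),
                 n_litters: int = 4,
                 include: Sequence[str] = ("monaural", "binaural", "audiogram"),
                 ) -> Cohort:
    """Draw a synthetic cohort with the study's factorial structure.

    Each animal gets a random amplitude intercept (shared across waves), small
    per-wave latency offsets, morphometrics, and a litter label assigned
    round-robin (no generative litter effect).  Reproducible given ``seed``.
    """
    if n_per_group < 2:
        raise ValueError("need at least two animals per group")
    design = list(design) if design is not None else default_design()
    if not design:
        raise ValueError("empty design")
    kernels = kernels or WaveKernelParams()
    effects = effects or GroupEffects()
    noise = noise or NoiseModel()
    levels = tuple(float(v) for v in audiogram_levels_db)
    if any(b >= a for a, b in zip(levels, levels[1:])):
        raise ValueError("audiogram levels must be strictly descending")

    import pandas as pd

    root = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    animals: List[AnimalModel] = []
    rows = []
    counter = 0
    for sex, genotype in design:
        for k in range(n_per_group):
            aid = f"{'F' if sex == 'female' else 'M'}-{genotype.replace(' ', '')}-{k:02d}"
            wmean, wsd = MORPHOMETRY["weight_g"][sex]
            a = AnimalModel(
                animal=aid,
                sex=sex,
                genotype=genotype,
                litter=f"L{k % n_litters + 1}",  # crossed with group cells
                amp_offset_av=float(param_rng.normal(0.0, effects.animal_intercept_sd_av)),
                latency_offsets_ms=tuple(
                    param_rng.normal(0.0, kernels.latency_jitter_sd_ms, 4)
                ),
                pinna_length_mm=round(float(param_rng.normal(*MORPHOMETRY["pinna_length_mm"])), 2),
                pinna_width_mm=round(float(param_rng.normal(*MORPHOMETRY["pinna_width_mm"])), 2),
                interpinna_mm=round(float(param_rng.normal(*MORPHOMETRY["interpinna_mm"])), 2),
                nose_to_pinna_mm=round(float(param_rng.normal(*MORPHOMETRY["nose_to_pinna_mm"])), 2),
                weight_g=round(float(param_rng.normal(wmean, wsd)), 1),
            )
            animals.append(a)
            rows.append({
                "animal": aid, "sex": sex, "genotype": genotype, "litter": a.litter,
                "pinna_length_mm": a.pinna_length_mm, "pinna_width_mm": a.pinna_width_mm,
                "interpinna_mm": a.interpinna_mm, "nose_to_pinna_mm": a.nose_to_pinna_mm,
                "weight_g": a.weight_g,
            })
            counter += 1
    metadata = pd.DataFrame(rows)

    truth = GenerativeTruth()
    for a in animals:
        at = AnimalTruth()
        spec90 = StimulusSpec("click", "left", level_db)
        for ear in ("left", "right"):
            spec = StimulusSpec("click", ear, level_db)
            _, ct = condition_waveform(spec, kernels, effects, a)
            at.wave_amplitude_av[ear] = [w.amplitude_av for w in ct.waves]
            at.wave_latency_ms[ear] = [w.peak_latency_ms for w in ct.waves]
        for f in TONE_FREQS_KHZ:
            t0 = threshold_for(StimulusSpec("tone", "left", 90.0, frequency_khz=f),
                               kernels, effects, a.sex, a.genotype)
            above = [lvl for lvl in levels if lvl > t0]
            at.thresholds_db[f] = min(above) if above else None
        c0 = threshold_for(spec90, kernels, effects, a.sex, a.genotype)
        above = [lvl for lvl in levels if lvl > c0]
        at.click_threshold_db = min(above) if above else None
        for itd in itds_ms:
            bspec = StimulusSpec("click", "both", level_db, itd_ms=itd)
            _, ct = condition_waveform(bspec, kernels, effects, a)
            at.dn1_latency_ms[itd] = ct.dn1_latency_ms
            at.dn1_amplitude_av[itd] = ct.dn1_amplitude_av
        truth.animals[a.animal] = at

    epoch_seeds = root.spawn(len(animals) + 1)[1:]
    return Cohort(
        animals=animals,
        metadata=metadata,
        truth=truth,
        kernels=kernels,
        effects=effects,
        noise=noise,
        n_epochs=n_epochs,
        level_db=level_db,
        itds_ms=tuple(itds_ms),
        audiogram_levels_db=levels,
        include=tuple(include),
        _animal_seeds={a.animal: s for a, s in zip(animals, epoch_seeds)},
    )
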
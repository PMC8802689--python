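"""Core containers and acquisition conventions for ABR analysis.

An auditory brainstem response (ABR) is recorded as a short evoked-potential
sweep time-locked to a click or tone burst.  Throughout the package a sweep
("epoch") covers a 12 ms window sampled at 97656.25 Hz, i.e. 1172 samples with
``t[n] = n / fs`` starting at stimulus onset.  Voltages are in arbitrary
voltage units (aV); only ratios between conditions are meaningful.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional

import numpy as np

#: Acquisition sampling rate (Hz).
FS_HZ = 97656.25
#: Epoch window length (ms), starting at stimulus onset.
WINDOW_MS = 12.0
#: Samples per epoch: ceil(12 ms * fs) so the full window is covered.
N_SAMPLES = 1172

#: Interaural time differences tested, ms (positive = left ear leads).
ITD_GRID_MS = tuple(round(-2.0 + 0.5 * i, 1) for i in range(9))
#: Tone-burst frequencies tested for the audiogram (kHz).
TONE_FREQS_KHZ = (1.0, 2.0, 4.0, 8.0, 16.0, 24.0, 32.0, 46.0)

SEXES = ("female", "male")
GENOTYPES = ("B6", "Fmr1", "Fmr1 het")
WAVES = ("I", "II", "III", "IV")


def time_axis_ms(n_samples: int = N_SAMPLES, fs: float = FS_HZ) -> np.ndarray:
    """Time axis in ms for an epoch of ``n_samples`` at ``fs``."""
    return np.arange(n_samples) / fs * 1000.0


@dataclass(frozen=True)
class StimulusSpec:
    """Description of one acoustic stimulus condition.

    Parameters
    ----------
    modality : {'click', 'tone'}
        Broadband click (0.1 ms transient) or tone burst.
    ear : {'left', 'right', 'both'}
        Presentation side; ``'both'`` is the binaural condition.
    level_db : float
        Sound level in dB SPL (>= 0).
    frequency_khz : float, optional
        Tone frequency; required for tones, disallowed for clicks.  Must lie
        on the 8-frequency audiogram grid (1-46 kHz).
    itd_ms : float, optional
        Interaural time difference; required for (and restricted to)
        ``ear='both'``.  Must lie on the +/-2 ms grid in 0.5 ms steps.
    onset_delay_ms : float
        Stimulus-onset delay for a monaural member of a lateralized binaural
        triplet (each ear's click in an ITD condition is shifted by
        ``+/- itd/2``); 0 for ordinary monaural stimuli.
    isi_mean_ms, isi_sd_ms : float
        Inter-stimulus interval statistics (30 +/- 5 ms).  Metadata only:
        epochs are generated and analysed as already-segmented windows.
    """

    modality: str
    ear: str
    level_db: float
    frequency_khz: Optional[float] = None
    itd_ms: Optional[float] = None
    onset_delay_ms: float = 0.0
    isi_mean_ms: float = 30.0
    isi_sd_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.modality not in ("click", "tone"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.ear not in ("left", "right", "both"):
            raise ValueError(f"unknown ear {self.ear!r}")
        if not np.isfinite(self.level_db) or self.level_db < 0:
            raise ValueError(f"level must be >= 0 dB SPL, got {self.level_db}")
        if self.modality == "tone":
            if self.frequency_khz is None:
                raise ValueError("tone stimulus requires frequency_khz")
            if not any(np.isclose(self.frequency_khz, f) for f in TONE_FREQS_KHZ):
                raise ValueError(
                    f"frequency {self.frequency_khz} kHz not on the grid "
                    f"{TONE_FREQS_KHZ}"
                )
        elif self.frequency_khz is not None:
            raise ValueError("click stimulus takes no frequency")
        if self.ear == "both":
            if self.itd_ms is None:
                raise ValueError("binaural stimulus requires itd_ms")
            if not any(np.isclose(self.itd_ms, g) for g in ITD_GRID_MS):
                raise ValueError(
                    f"itd {self.itd_ms} ms not on the +/-2 ms / 0.5 ms grid"
                )
        elif self.itd_ms is not None:
            raise ValueError("itd_ms is only valid for ear='both'")

    @property
    def key(self) -> str:
        """Stable string key identifying this condition."""
        parts = [self.modality, self.ear, f"{self.level_db:g}dB"]
        if self.frequency_khz is not None:
            parts.append(f"{self.frequency_khz:g}kHz")
        if self.itd_ms is not None:
            parts.append(f"itd{self.itd_ms:+.1f}")
        if self.onset_delay_ms:
            parts.append(f"delay{self.onset_delay_ms:+.3f}")
        return "|".join(parts)


@dataclass(frozen=True)
class Epoch:
    """A single raw sweep: one stimulus repetition."""

    samples: np.ndarray
    fs: float
    spec: StimulusSpec
    animal: str
    index: int

    def __post_init__(self) -> None:
        if self.samples.ndim != 1:
            raise ValueError("epoch samples must be 1-D")


@dataclass
class EpochSet:
    """A stack of repeated sweeps for one animal x stimulus condition.

    ``samples`` has shape ``(n_epochs, n_samples)``.  ``artifact_epochs``
    carries the generator's bookkeeping of which repetitions received an
    injected high-amplitude artifact (empty for real recordings).
    """

    samples: np.ndarray
    fs: float
    spec: StimulusSpec
    animal: str
    artifact_epochs: tuple = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("EpochSet samples must be 2-D (epochs x samples)")

    def __len__(self) -> int:
        return self.samples.shape[0]

    def __iter__(self) -> Iterator[Epoch]:
        for i in range(len(self)):
            yield Epoch(self.samples[i], self.fs, self.spec, self.animal, i)

    def subset(self, indices) -> "EpochSet":
        indices = np.asarray(indices, dtype=int)
        kept = frozenset(int(i) for i in indices)
        return EpochSet(
            self.samples[indices],
            self.fs,
            self.spec,
            self.animal,
            tuple(i for i in self.artifact_epochs if i in kept),
        )


@dataclass
class AveragedTrace:
    """One processed evoked-potential waveform for a stimulus condition."""

    samples: np.ndarray
    fs: float
    spec: Optional[StimulusSpec]
    animal: str
    n_accepted: int = 1
    n_rejected: int = 0
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be 1-D")
        if self.n_accepted < 1:
            raise ValueError("an averaged trace needs at least one epoch")

    @property
    def time_ms(self) -> np.ndarray:
        return time_axis_ms(self.samples.size, self.fs)

    @property
    def duration_ms(self) -> float:
        return self.samples.size / self.fs * 1000.0

    def with_samples(self, samples: np.ndarray, **extra_provenance) -> "AveragedTrace":
        prov = dict(self.provenance)
        prov.update(extra_provenance)
        return replace(self, samples=np.asarray(samples, dtype=float), provenance=prov)

    def sample_at(self, latency_ms: float) -> int:
        """Index of the sample closest to ``latency_ms``."""
        idx = int(round(latency_ms / 1000.0 * self.fs))
        return min(max(idx, 0), self.samples.size - 1)
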
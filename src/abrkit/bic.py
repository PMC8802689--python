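"""Binaural interaction component (BIC) and DN1 extraction.

The BIC is the binaural ABR minus the sum of the two monaural ABRs; a
nonzero BIC reflects binaural neural interaction.  Its prominent negative
deflection, DN1, is temporally aligned with wave IV of the summed/binaural
ABR.  DN1 amplitude is reported as the non-negative magnitude of the
deflection relative to the zero baseline; latency as time of the minimum.
Repeating the measurement across interaural time differences (ITDs) of
+/-2 ms in 0.5 ms steps yields an amplitude/latency-vs-ITD series.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .core import ITD_GRID_MS, AveragedTrace, time_axis_ms
from .peaks import WavePeakSet, detect_peaks

DEFAULT_HALF_WINDOW_MS = 1.5
#: DN1 presence floor: |minimum| must exceed this multiple of the BIC RMS
#: outside the search window.
DEFAULT_FLOOR_MULTIPLE = 3.0


@dataclass
class BicTrace:
    """BIC residual trace with references to its parent traces."""

    samples: np.ndarray
    fs: float
    itd_ms: Optional[float]
    animal: str
    left: AveragedTrace
    right: AveragedTrace
    binaural: AveragedTrace

    @property
    def time_ms(self) -> np.ndarray:
        return time_axis_ms(self.samples.size, self.fs)


@dataclass(frozen=True)
class Dn1Measurement:
    """DN1 latency/amplitude at one ITD; amplitude is a magnitude (>= 0)."""

    latency_ms: float
    amplitude_av: float
    value_av: float  # signed voltage at the minimum (retained internally)
    itd_ms: Optional[float]
    window_ms: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.amplitude_av < 0:
            raise ValueError("DN1 amplitude is a magnitude")


def compute_bic(left: AveragedTrace, right: AveragedTrace,
                binaural: AveragedTrace) -> BicTrace:
    """``binaural - (left + right)``, pointwise.

    All three traces must share length, sampling rate and animal, and should
    have been preprocessed identically.
    """
    for name, tr in (("left", left), ("right", right)):
        if tr.samples.size != binaural.samples.size:
            raise ValueError(f"{name} trace length differs from binaural")
        if tr.fs != binaural.fs:
            raise ValueError(f"{name} trace sampling rate differs from binaural")
        if tr.animal != binaural.animal:
            raise ValueError(f"{name} trace comes from a different animal")
    itd = binaural.spec.itd_ms if binaural.spec is not None else None
    return BicTrace(
        samples=binaural.samples - (left.samples + right.samples),
        fs=binaural.fs,
        itd_ms=itd,
        animal=binaural.animal,
        left=left,
        right=right,
        binaural=binaural,
    )


def summed_trace(left: AveragedTrace, right: AveragedTrace) -> AveragedTrace:
    """The summed ABR (left + right), used to anchor the DN1 search."""
    return left.with_samples(left.samples + right.samples, stage="summed")


def find_dn1(bic: BicTrace, anchor_latency_ms: float,
             half_window_ms: float = DEFAULT_HALF_WINDOW_MS,
             floor_multiple: float = DEFAULT_FLOOR_MULTIPLE,
             widen_by_itd: bool = True) -> Optional[Dn1Measurement]:
    """Locate DN1 within a window around the wave IV anchor latency.

    The window is ``anchor +/- half_window``, widened by ``|itd|/2`` when the
    ITD is known, to track lateralized shifts.  DN1 is the minimum of the BIC
    inside the window; it must be negative and its magnitude must exceed
    ``floor_multiple`` x the RMS of the BIC outside the window, otherwise the
    measurement is absent (returns None).
    """
    if not np.isfinite(anchor_latency_ms):
        raise ValueError("anchor latency must be finite")
    hw = half_window_ms
    if widen_by_itd and bic.itd_ms is not None:
        hw += abs(bic.itd_ms) / 2.0
    t = bic.time_ms
    mask = (t >= anchor_latency_ms - hw) & (t <= anchor_latency_ms + hw)
    if not mask.any():
        raise ValueError("DN1 search window contains no samples")
    seg = bic.samples[mask]
    idx = np.flatnonzero(mask)
    imin = idx[int(np.argmin(seg))]
    value = float(bic.samples[imin])
    outside = bic.samples[~mask]
    floor = floor_multiple * float(np.sqrt(np.mean(outside ** 2))) if outside.size else 0.0
    if value >= 0 or abs(value) <= floor:
        return None
    return Dn1Measurement(
        latency_ms=float(t[imin]),
        amplitude_av=abs(value),
        value_av=value,
        itd_ms=bic.itd_ms,
        window_ms=(anchor_latency_ms - hw, anchor_latency_ms + hw),
    )


def measure_bic(left: AveragedTrace, right: AveragedTrace,
                binaural: AveragedTrace,
                windows: Optional[Mapping[str, Tuple[float, float]]] = None,
                min_prominence: float = 0.0,
                half_window_ms: float = DEFAULT_HALF_WINDOW_MS,
                floor_multiple: float = DEFAULT_FLOOR_MULTIPLE,
                ) -> Tuple[BicTrace, Optional[Dn1Measurement]]:
    """BIC computation plus DN1 search anchored at the summed-trace wave IV.

    Returns ``(bic, dn1)``; ``dn1`` is None when wave IV cannot be detected
    on the summed ABR (no anchor) or the deflection is below the floor.
    """
    bic = compute_bic(left, right, binaural)
    if bic.itd_ms is not None and windows is None:
        # widen the default wave IV window by |itd|/2 so the lateralized
        # summed-trace wave IV still falls inside it
        from .peaks import DEFAULT_WINDOWS_MS
        windows = dict(DEFAULT_WINDOWS_MS)
        lo, hi = windows["IV"]
        d = abs(bic.itd_ms) / 2.0
        windows["IV"] = (lo - d, hi + d)
    summed = summed_trace(left, right)
    peaks: WavePeakSet = detect_peaks(summed, windows=windows,
                                      min_prominence=min_prominence)
    w4 = peaks["IV"]
    if w4 is None:
        return bic, None
    return bic, find_dn1(bic, w4.peak_latency_ms, half_window_ms,
                         floor_multiple)


@dataclass
class BicSeries:
    """Per-animal DN1 measurements across the ITD grid."""

    animal: str
    measurements: Dict[float, Optional[Dn1Measurement]] = field(default_factory=dict)

    def itds(self):
        return sorted(self.measurements)

    def amplitudes(self) -> Dict[float, Optional[float]]:
        return {i: (m.amplitude_av if m else None)
                for i, m in self.measurements.items()}

    def latencies(self) -> Dict[float, Optional[float]]:
        return {i: (m.latency_ms if m else None)
                for i, m in self.measurements.items()}


def bic_itd_series(triplets: Mapping[float, Tuple[AveragedTrace, AveragedTrace, AveragedTrace]],
                   animal: Optional[str] = None,
                   **measure_kwargs) -> BicSeries:
    """Measure DN1 across ITDs from per-ITD (left, right, binaural) triplets.

    ITDs must be unique values on the +/-2 ms grid; absent DN1s are carried
    as None entries, never silently dropped.
    """
    series = BicSeries(animal=animal or "")
    seen = []
    for itd, (l, r, b) in triplets.items():
        if not any(np.isclose(itd, g) for g in ITD_GRID_MS):
            raise ValueError(f"itd {itd} ms not on the grid")
        if any(np.isclose(itd, s) for s in seen):
            raise ValueError(f"duplicate ITD {itd} ms")
        seen.append(itd)
        _, dn1 = measure_bic(l, r, b, **measure_kwargs)
        series.measurements[float(itd)] = dn1
        if not series.animal:
            series.animal = b.animal
    return series
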
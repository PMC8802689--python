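"""Hearing-threshold estimation: per-frequency audiograms and click thresholds.

The reference procedure is a human rater judging "the lowest level (dB SPL)
at which a response could be detected" while the level descends in 5-10 dB
steps.  That judgement is replaced here by a declared algorithmic criterion:
a response is present when the RMS of the post-stimulus response window
exceeds ``criterion_multiple`` x the noise floor (estimated from the
lowest-level, subthreshold trace of the same series).  A template
cross-correlation detector is available behind the same interface.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import TONE_FREQS_KHZ, AveragedTrace

#: Post-stimulus window (ms) over which response energy is measured; spans
#: the wave I-IV complex and its troughs.
DEFAULT_RESPONSE_WINDOW_MS = (0.5, 9.0)
DEFAULT_CRITERION_MULTIPLE = 2.0

#: Sentinel for frequencies with no detectable response at any tested level.
NO_RESPONSE = None

Detector = Callable[[AveragedTrace], bool]


def _window_slice(trace: AveragedTrace,
                  window_ms: Tuple[float, float]) -> np.ndarray:
    lo, hi = window_ms
    if not hi > lo:
        raise ValueError("degenerate response window")
    t = trace.time_ms
    seg = trace.samples[(t >= lo) & (t <= hi)]
    if seg.size == 0:
        raise ValueError("response window contains no samples")
    return seg


def response_rms(trace: AveragedTrace,
                 window_ms: Tuple[float, float] = DEFAULT_RESPONSE_WINDOW_MS,
                 ) -> float:
    """RMS voltage inside the response window."""
    seg = _window_slice(trace, window_ms)
    return float(np.sqrt(np.mean(seg ** 2)))


def detect_response(trace: AveragedTrace, noise_floor: float,
                    criterion_multiple: float = DEFAULT_CRITERION_MULTIPLE,
                    window_ms: Tuple[float, float] = DEFAULT_RESPONSE_WINDOW_MS,
                    ) -> bool:
    """RMS detection: response present iff RMS > criterion x noise floor.

    The comparison is strictly greater, so a trace exactly at the criterion
    boundary (including a zero trace against a zero floor) is 'no response'.
    """
    if not noise_floor > 0:
        raise ValueError("noise_floor must be positive")
    return response_rms(trace, window_ms) > criterion_multiple * noise_floor


def detect_response_template(trace: AveragedTrace, template: AveragedTrace,
                             noise_floor: float,
                             criterion_multiple: float = DEFAULT_CRITERION_MULTIPLE,
                             window_ms: Tuple[float, float] = DEFAULT_RESPONSE_WINDOW_MS,
                             ) -> bool:
    """Template detector: normalized cross-correlation against a
    suprathreshold template exceeding the criterion.

    The statistic is the template-projected RMS
    ``|<x, u>| / sqrt(len)`` with ``u`` the unit-norm template restricted to
    the response window, compared against ``criterion_multiple x noise_floor``
    like the RMS rule.  More selective than plain RMS because noise orthogonal
    to the template shape does not count.
    """
    if not noise_floor > 0:
        raise ValueError("noise_floor must be positive")
    x = _window_slice(trace, window_ms)
    u = _window_slice(template, window_ms)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("template is identically zero in the window")
    stat = abs(float(np.dot(x, u / norm))) / np.sqrt(x.size)
    return stat > criterion_multiple * noise_floor


def estimate_noise_floor(series: Sequence[Tuple[float, AveragedTrace]],
                         window_ms: Tuple[float, float] = DEFAULT_RESPONSE_WINDOW_MS,
                         ) -> float:
    """Noise floor: RMS of the lowest-level trace of the series."""
    lowest = min(series, key=lambda lt: lt[0])[1]
    return response_rms(lowest, window_ms)


def estimate_threshold(series: Sequence[Tuple[float, AveragedTrace]],
                       noise_floor: Optional[float] = None,
                       criterion_multiple: float = DEFAULT_CRITERION_MULTIPLE,
                       window_ms: Tuple[float, float] = DEFAULT_RESPONSE_WINDOW_MS,
                       detector: Optional[Detector] = None,
                       ) -> Optional[float]:
    """Threshold from a descending level series of averaged traces.

    ``series`` is a list of ``(level_db, trace)`` with strictly descending
    levels in 5-10 dB steps.  The threshold is the lowest tested level at
    which a response is detected *and* detection holds at every higher tested
    level (monotone enforcement, standing in for the rater's smoothing of
    isolated flickers).  Returns ``None`` ('no response') when detection
    fails at the highest level.
    """
    levels = [lv for lv, _ in series]
    if len(levels) < 2:
        raise ValueError("need at least two levels")
    steps = [a - b for a, b in zip(levels, levels[1:])]
    if any(s <= 0 for s in steps):
        raise ValueError("levels must be strictly descending")
    if any(not 5.0 <= s <= 10.0 for s in steps):
        raise ValueError("level steps must be between 5 and 10 dB SPL")
    if detector is None:
        if noise_floor is None:
            noise_floor = estimate_noise_floor(series, window_ms)
        def detector(tr: AveragedTrace) -> bool:
            return detect_response(tr, noise_floor, criterion_multiple, window_ms)

    threshold: Optional[float] = None
    for level, trace in series:  # descending
        if detector(trace):
            threshold = level
        else:
            break
    return threshold


@dataclass
class Audiogram:
    """Per-frequency hearing thresholds for one animal.

    ``thresholds_db[f]`` is a tested level in dB SPL, or None for
    'no response at any tested level'.
    """

    thresholds_db: Dict[float, Optional[float]]
    levels_tested_db: Tuple[float, ...]
    settings: Mapping = field(default_factory=dict)

    def threshold(self, frequency_khz: float) -> Optional[float]:
        for f, thr in self.thresholds_db.items():
            if np.isclose(f, frequency_khz):
                return thr
        raise KeyError(frequency_khz)


def build_audiogram(series_by_freq: Mapping[float, Sequence[Tuple[float, AveragedTrace]]],
                    skip: Sequence[float] = (),
                    criterion_multiple: float = DEFAULT_CRITERION_MULTIPLE,
                    window_ms: Tuple[float, float] = DEFAULT_RESPONSE_WINDOW_MS,
                    ) -> Audiogram:
    """Assemble an audiogram across the 8-frequency grid.

    Every grid frequency must appear either in ``series_by_freq`` or in
    ``skip`` (explicitly untested); duplicates are rejected.
    """
    seen: List[float] = []
    for f in series_by_freq:
        if any(np.isclose(f, g) for g in seen):
            raise ValueError(f"duplicate frequency entry {f} kHz")
        seen.append(f)
    covered = list(seen) + list(skip)
    for f in TONE_FREQS_KHZ:
        if not any(np.isclose(f, g) for g in covered):
            raise ValueError(
                f"frequency {f:g} kHz neither measured nor explicitly skipped"
            )
    thresholds: Dict[float, Optional[float]] = {}
    levels: Tuple[float, ...] = ()
    for f, series in series_by_freq.items():
        thresholds[float(f)] = estimate_threshold(
            series, criterion_multiple=criterion_multiple, window_ms=window_ms
        )
        levels = tuple(lv for lv, _ in series)
    return Audiogram(
        thresholds_db=thresholds,
        levels_tested_db=levels,
        settings={"criterion_multiple": criterion_multiple,
                  "response_window_ms": list(window_ms),
                  "detector": "rms",
                  "skipped_khz": list(skip)},
    )
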
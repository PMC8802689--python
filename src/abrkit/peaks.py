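"""Wave I-IV quantification on averaged ABR traces.

Each ABR wave is a positive deflection; its amplitude is measured peak to
following trough and its latency as time to peak.  Detection searches a
per-wave latency window for the most prominent local maximum; the trough is
the lowest point between that peak and the next wave's peak (for wave IV,
within a post-window, since no wave V bounds it here).  Detected entries can
be manually corrected or cleared, mirroring rater review.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .core import WAVES, AveragedTrace
from .simulate import WaveKernelParams

#: Default per-wave search windows: the response model's wave latencies
#: +/- 0.6 ms.  For real recordings these come from configuration.
_KP = WaveKernelParams()
DEFAULT_WINDOWS_MS: Dict[str, Tuple[float, float]] = {
    w: (_KP.base_latency_ms[i] - 0.6, _KP.base_latency_ms[i] + 0.6)
    for i, w in enumerate(WAVES)
}
#: Wave IV trough search extends this far past its peak.
DEFAULT_POST_WINDOW_MS = 1.5


@dataclass(frozen=True)
class WavePeak:
    """One wave's peak/trough annotation."""

    wave: str
    peak_latency_ms: float
    peak_value_av: float
    trough_latency_ms: float
    trough_value_av: float
    amplitude_av: float
    source: str = "auto"  # auto | manual
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.amplitude_av < 0:
            raise ValueError("peak-to-trough amplitude cannot be negative")
        if self.trough_latency_ms <= self.peak_latency_ms:
            raise ValueError("trough must follow the peak")


@dataclass
class WavePeakSet:
    """Wave annotations for one trace, with the settings that produced them."""

    trace: AveragedTrace
    peaks: Dict[str, Optional[WavePeak]]
    settings: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        lats = [p.peak_latency_ms for p in self.present()]
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise ValueError("wave peak latencies must be strictly increasing")

    def present(self) -> List[WavePeak]:
        return [self.peaks[w] for w in WAVES if self.peaks.get(w) is not None]

    def __getitem__(self, wave: str) -> Optional[WavePeak]:
        return self.peaks.get(wave)


def _resolve_windows(windows: Mapping[str, Tuple[float, float]],
                     duration_ms: float) -> Dict[str, Tuple[float, float]]:
    """Order windows by wave and split any overlap at its midpoint."""
    named = [(w, tuple(windows[w])) for w in WAVES if w in windows]
    if not named:
        raise ValueError("no search windows given")
    centers = [0.5 * (lo + hi) for _, (lo, hi) in named]
    if any(b <= a for a, b in zip(centers, centers[1:])):
        raise ValueError("windows must be ordered by wave latency")
    bounds = [list(win) for _, win in named]
    for i in range(len(bounds) - 1):
        if bounds[i][1] > bounds[i + 1][0]:
            mid = 0.5 * (bounds[i][1] + bounds[i + 1][0])
            bounds[i][1] = mid
            bounds[i + 1][0] = mid
    out = {}
    for (w, _), (lo, hi) in zip(named, bounds):
        if hi > duration_ms:
            raise ValueError(f"window for wave {w} extends past the trace")
        out[w] = (max(lo, 0.0), hi)
    return out


def _trough_after(x: np.ndarray, fs: float, peak_idx: int,
                  next_peak_idx: Optional[int],
                  post_window_ms: float) -> int:
    if next_peak_idx is None:
        next_peak_idx = min(x.size,
                            peak_idx + int(round(post_window_ms / 1000.0 * fs)) + 1)
    seg = x[peak_idx:next_peak_idx]
    if seg.size == 0:
        seg = x[peak_idx:peak_idx + 1]
    return peak_idx + int(np.argmin(seg))


def detect_peaks(trace: AveragedTrace,
                 windows: Optional[Mapping[str, Tuple[float, float]]] = None,
                 min_prominence: float = 0.0,
                 post_window_ms: float = DEFAULT_POST_WINDOW_MS,
                 ) -> WavePeakSet:
    """Automatic wave I-IV detection.

    For each wave the most prominent local maximum inside its window is taken
    (ties broken toward the earliest latency, favouring physiological order);
    a wave with no candidate of at least ``min_prominence`` is reported as
    missing, never fabricated.
    """
    if min_prominence < 0:
        raise ValueError("min_prominence must be >= 0")
    windows = _resolve_windows(windows or DEFAULT_WINDOWS_MS, trace.duration_ms)
    x = trace.samples
    t = trace.time_ms
    candidates: Dict[str, Optional[int]] = {}
    # prominence=min_prominence also makes find_peaks return the prominences
    idx_all, props = find_peaks(x, prominence=min_prominence)
    prom_all = props["prominences"] if idx_all.size else np.array([])
    for wave, (lo, hi) in windows.items():
        in_win = (t[idx_all] >= lo) & (t[idx_all] <= hi)
        cand = idx_all[in_win]
        if cand.size == 0:
            candidates[wave] = None
            continue
        prom = prom_all[in_win]
        best = np.flatnonzero(prom == prom.max())
        candidates[wave] = int(cand[best[0]])  # earliest among ties

    wave_names = list(windows.keys())
    peaks: Dict[str, Optional[WavePeak]] = {w: None for w in WAVES}
    for i, wave in enumerate(wave_names):
        p = candidates[wave]
        if p is None:
            continue
        nxt = next((candidates[w2] for w2 in wave_names[i + 1:]
                    if candidates[w2] is not None), None)
        tr = _trough_after(x, trace.fs, p, nxt, post_window_ms)
        peaks[wave] = WavePeak(
            wave=wave,
            peak_latency_ms=float(t[p]),
            peak_value_av=float(x[p]),
            trough_latency_ms=float(t[tr]),
            trough_value_av=float(x[tr]),
            amplitude_av=float(x[p] - x[tr]),
        )
    return WavePeakSet(
        trace=trace,
        peaks=peaks,
        settings={"windows_ms": {w: list(v) for w, v in windows.items()},
                  "min_prominence_av": min_prominence,
                  "post_window_ms": post_window_ms},
    )


def apply_manual_override(peakset: WavePeakSet,
                          edits: Mapping[str, Optional[float]],
                          post_window_ms: float = DEFAULT_POST_WINDOW_MS,
                          ) -> WavePeakSet:
    """Apply rater corrections: set a wave's peak latency (ms) or clear it.

    ``edits`` maps wave name -> new peak latency in ms, or None to deselect
    the wave.  Amplitude and trough are recomputed from the overridden peak
    with the same trough rule; edited entries are marked ``source='manual'``.
    An edit that breaks the wave latency ordering is rejected.
    """
    trace = peakset.trace
    x = trace.samples
    t = trace.time_ms
    new: Dict[str, Optional[int]] = {}
    sources: Dict[str, str] = {}
    for w in WAVES:
        cur = peakset.peaks.get(w)
        new[w] = trace.sample_at(cur.peak_latency_ms) if cur is not None else None
        sources[w] = cur.source if cur is not None else "auto"
    for w, lat in edits.items():
        if w not in WAVES:
            raise ValueError(f"unknown wave {w!r}")
        if lat is None:
            new[w] = None
        else:
            if not 0.0 <= lat <= trace.duration_ms:
                raise ValueError(f"latency {lat} ms outside the trace")
            new[w] = trace.sample_at(lat)
        sources[w] = "manual"

    order = [new[w] for w in WAVES if new[w] is not None]
    if any(b <= a for a, b in zip(order, order[1:])):
        bad = ", ".join(w for w in edits)
        raise ValueError(
            f"edit ({bad}) would break the wave I-IV latency ordering"
        )

    peaks: Dict[str, Optional[WavePeak]] = {w: None for w in WAVES}
    names = [w for w in WAVES]
    for i, w in enumerate(names):
        p = new[w]
        if p is None:
            continue
        nxt = next((new[w2] for w2 in names[i + 1:] if new[w2] is not None), None)
        tr = _trough_after(x, trace.fs, p, nxt, post_window_ms)
        peaks[w] = WavePeak(
            wave=w,
            peak_latency_ms=float(t[p]),
            peak_value_av=float(x[p]),
            trough_latency_ms=float(t[tr]),
            trough_value_av=float(x[tr]),
            amplitude_av=float(x[p] - x[tr]),
            source=sources[w],
        )
    return WavePeakSet(trace=trace, peaks=peaks, settings=dict(peakset.settings))


@dataclass(frozen=True)
class WaveSummary:
    """Across-ear summary of one wave's metrics."""

    wave: str
    amplitude_av: float
    latency_ms: float
    n_ears: int
    flagged: bool  # True when only one ear contributed


def monaural_summary(left: WavePeakSet, right: WavePeakSet,
                     ) -> Dict[str, Optional[WaveSummary]]:
    """Average the two ears' wave metrics into one monaural summary.

    Per wave: the arithmetic mean of the two ears' amplitudes and latencies.
    A wave present in only one ear contributes that ear's value, flagged; a
    wave missing in both ears is missing in the summary.
    """
    lvl = left.trace.spec.level_db if left.trace.spec else None
    rvl = right.trace.spec.level_db if right.trace.spec else None
    if lvl is not None and rvl is not None and lvl != rvl:
        raise ValueError("both ears must be measured at the same level")
    out: Dict[str, Optional[WaveSummary]] = {}
    for w in WAVES:
        lp, rp = left[w], right[w]
        if lp is None and rp is None:
            out[w] = None
        elif lp is not None and rp is not None:
            out[w] = WaveSummary(
                wave=w,
                amplitude_av=0.5 * (lp.amplitude_av + rp.amplitude_av),
                latency_ms=0.5 * (lp.peak_latency_ms + rp.peak_latency_ms),
                n_ears=2,
                flagged=False,
            )
        else:
            p = lp if lp is not None else rp
            out[w] = WaveSummary(
                wave=w,
                amplitude_av=p.amplitude_av,
                latency_ms=p.peak_latency_ms,
                n_ears=1,
                flagged=True,
            )
    return out
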
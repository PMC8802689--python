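"""Wave I-IV detection, manual overrides, and across-ear summaries."""
from __future__ import annotations

import numpy as np
import pytest

from abrkit import simulate as sim
from abrkit.core import FS_HZ, WAVES, StimulusSpec
from abrkit.peaks import (
    DEFAULT_WINDOWS_MS,
    apply_manual_override,
    detect_peaks,
    monaural_summary,
)
from abrkit.preprocess import bandpass_filter, zero_baseline
from conftest import make_trace

ONE_SAMPLE_MS = 1000.0 / FS_HZ


@pytest.fixture
def noiseless_trace(click90, noise_free):
    sig, truth = sim.condition_waveform(click90)
    return make_trace(sig, spec=click90), truth


class TestDetectPeaks:
    def test_recovers_truth_on_noiseless_trace(self, noiseless_trace):
        trace, truth = noiseless_trace
        ps = detect_peaks(trace, min_prominence=0.05)
        for w, wt in zip((ps[k] for k in WAVES), truth.waves):
            assert w is not None
            assert abs(w.peak_latency_ms - wt.peak_latency_ms) <= ONE_SAMPLE_MS
            assert w.amplitude_av == pytest.approx(wt.amplitude_av, rel=1e-9)

    def test_recovers_filtered_truth_within_one_percent(self, noiseless_trace):
        """After filtering, metrics match truth measured through the same
        filter (filter compensation) to 1%."""
        trace, _ = noiseless_trace
        filtered = zero_baseline(bandpass_filter(trace))
        ps = detect_peaks(filtered, min_prominence=0.05)
        # oracle: quantify the filtered noiseless trace directly
        for w in ps.present():
            lo, hi = DEFAULT_WINDOWS_MS[w.wave]
            t = filtered.time_ms
            seg = (t >= lo) & (t <= hi)
            peak_idx = np.flatnonzero(seg)[np.argmax(filtered.samples[seg])]
            assert abs(w.peak_latency_ms - t[peak_idx]) <= ONE_SAMPLE_MS

    def test_single_bump_yields_one_wave(self):
        t = np.arange(1172) / FS_HZ * 1000
        x = np.exp(-0.5 * ((t - 1.3) / 0.15) ** 2)
        ps = detect_peaks(make_trace(x), min_prominence=0.1)
        assert ps["I"] is not None
        assert all(ps[w] is None for w in ("II", "III", "IV"))

    def test_flat_trace_all_missing(self):
        ps = detect_peaks(make_trace(np.zeros(1172)), min_prominence=0.0)
        assert ps.present() == []

    def test_noise_only_rarely_triggers_at_6_sigma(self):
        """Pure bandpassed noise with a 6-sigma prominence floor yields zero
        detected waves in at least 95% of 200 seeded runs."""
        rng = np.random.default_rng(12)
        n_clean = 0
        for _ in range(200):
            raw = make_trace(rng.normal(0.0, 1.0, 1172))
            tr = zero_baseline(bandpass_filter(raw))
            sd = float(tr.samples.std())
            if not detect_peaks(tr, min_prominence=6 * sd).present():
                n_clean += 1
        assert n_clean >= 190

    def test_translation_equivariance(self, noiseless_trace):
        trace, _ = noiseless_trace
        k = 30  # samples
        shifted = make_trace(np.roll(trace.samples, k), spec=trace.spec)
        shift_ms = k * ONE_SAMPLE_MS
        windows = {w: (lo + shift_ms, hi + shift_ms)
                   for w, (lo, hi) in DEFAULT_WINDOWS_MS.items()}
        base = detect_peaks(trace, min_prominence=0.05)
        moved = detect_peaks(shifted, windows=windows, min_prominence=0.05)
        for w in WAVES:
            assert moved[w].peak_latency_ms - base[w].peak_latency_ms == \
                pytest.approx(shift_ms, abs=1e-9)

    def test_amplitude_scaling(self, noiseless_trace):
        trace, _ = noiseless_trace
        c = 3.7
        base = detect_peaks(trace, min_prominence=0.05)
        scaled = detect_peaks(make_trace(c * trace.samples, spec=trace.spec),
                              min_prominence=0.05 * c)
        for w in WAVES:
            assert scaled[w].amplitude_av == pytest.approx(
                c * base[w].amplitude_av, rel=1e-12)
            assert scaled[w].peak_latency_ms == base[w].peak_latency_ms

    def test_outputs_satisfy_invariants_on_random_traces(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            tr = zero_baseline(bandpass_filter(make_trace(rng.normal(0, 1, 1172))))
            ps = detect_peaks(tr, min_prominence=1.0 * tr.samples.std())
            present = ps.present()
            assert all(p.amplitude_av >= 0 for p in present)
            lats = [p.peak_latency_ms for p in present]
            assert lats == sorted(lats)

    def test_window_past_trace_end_rejected(self, noiseless_trace):
        trace, _ = noiseless_trace
        with pytest.raises(ValueError, match="past the trace"):
            detect_peaks(trace, windows={"I": (1.0, 20.0)})


class TestManualOverride:
    def test_clear_wave(self, noiseless_trace):
        trace, _ = noiseless_trace
        ps = detect_peaks(trace, min_prominence=0.05)
        edited = apply_manual_override(ps, {"III": None})
        assert edited["III"] is None
        assert len(edited.present()) == 3

    def test_set_to_auto_position_is_idempotent(self, noiseless_trace):
        trace, _ = noiseless_trace
        ps = detect_peaks(trace, min_prominence=0.05)
        edited = apply_manual_override(ps, {"I": ps["I"].peak_latency_ms})
        assert edited["I"].source == "manual"
        for f in ("peak_latency_ms", "peak_value_av", "trough_latency_ms",
                  "amplitude_av"):
            assert getattr(edited["I"], f) == getattr(ps["I"], f)

    def test_moving_peak_changes_amplitude_by_value_difference(self, noiseless_trace):
        trace, _ = noiseless_trace
        ps = detect_peaks(trace, min_prominence=0.05)
        w4 = ps["IV"]
        i = trace.sample_at(w4.peak_latency_ms)
        new_lat = trace.time_ms[i + 2]
        edited = apply_manual_override(ps, {"IV": new_lat})
        expected_delta = trace.samples[i + 2] - trace.samples[i]
        assert edited["IV"].trough_latency_ms == w4.trough_latency_ms
        assert edited["IV"].amplitude_av - w4.amplitude_av == \
            pytest.approx(expected_delta, abs=1e-12)

    def test_out_of_order_edit_rejected(self, noiseless_trace):
        trace, _ = noiseless_trace
        ps = detect_peaks(trace, min_prominence=0.05)
        with pytest.raises(ValueError, match="ordering"):
            apply_manual_override(ps, {"II": 0.9})  # before wave I's peak


class TestMonauralSummary:
    def _peaksets(self, effects=None):
        spec_l = StimulusSpec("click", "left", 90.0)
        spec_r = StimulusSpec("click", "right", 90.0)
        out = {}
        for spec in (spec_l, spec_r):
            sig, _ = sim.condition_waveform(spec, effects=effects)
            out[spec.ear] = detect_peaks(make_trace(sig, spec=spec),
                                         min_prominence=0.05)
        return out

    def test_identical_ears_equal_summary(self):
        ps = self._peaksets()
        summary = monaural_summary(ps["left"], ps["right"])
        for w in WAVES:
            assert summary[w].amplitude_av == ps["left"][w].amplitude_av
            assert summary[w].n_ears == 2 and not summary[w].flagged

    def test_mean_of_two_amplitudes(self, noiseless_trace):
        trace, _ = noiseless_trace
        base = detect_peaks(trace, min_prominence=0.05)
        doubled = detect_peaks(make_trace(2 * trace.samples, spec=trace.spec),
                               min_prominence=0.05)
        s = monaural_summary(base, doubled)
        for w in WAVES:
            assert s[w].amplitude_av == pytest.approx(
                1.5 * base[w].amplitude_av, rel=1e-12)

    def test_single_ear_fallback_is_flagged(self, noiseless_trace):
        trace, _ = noiseless_trace
        ps = detect_peaks(trace, min_prominence=0.05)
        left = apply_manual_override(ps, {"II": None})
        s = monaural_summary(left, ps)
        assert s["II"].n_ears == 1 and s["II"].flagged
        assert s["II"].amplitude_av == ps["II"].amplitude_av

    def test_missing_in_both_ears_missing_in_summary(self, noiseless_trace):
        trace, _ = noiseless_trace
        ps = apply_manual_override(detect_peaks(trace, min_prominence=0.05),
                                   {"II": None})
        s = monaural_summary(ps, ps)
        assert s["II"] is None

    def test_level_mismatch_rejected(self, noiseless_trace):
        trace, _ = noiseless_trace
        ps = detect_peaks(trace, min_prominence=0.05)
        spec70 = StimulusSpec("click", "right", 70.0)
        sig, _ = sim.condition_waveform(spec70)
        ps70 = detect_peaks(make_trace(sig, spec=spec70), min_prominence=0.02)
        with pytest.raises(ValueError, match="same level"):
            monaural_summary(ps, ps70)
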
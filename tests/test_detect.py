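import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfpkit.detect import (
    DetectionSettings,
    band_bins,
    compute_threshold,
    detect_amplitude,
    detect_spectral,
    filter_by_duration,
    find_peaks_above,
    group_peaks_to_bursts,
    merge_bursts,
    preprocess,
    sliding_band_power,
)
from lfpkit.errors import ParameterError
from lfpkit.synth import SeizureSchedule, SimulationSpec, generate_signals

FS = 2000.0


def amp_settings(**kw):
    kw.setdefault("threshold_n_sd", 5.0)
    kw.setdefault("min_duration_s", 3.0)
    return DetectionSettings(**kw)


# ---------------------------------------------------------------- oracles


def oracle_group(peaks, min_freq):
    """Connected components over the 'gap <= 1/f' relation (O(n^2))."""
    peaks = sorted(peaks)
    if not peaks:
        return []
    max_gap = 1.0 / min_freq
    adj = {
        (i, j)
        for i in range(len(peaks))
        for j in range(len(peaks))
        if i != j and abs(peaks[i] - peaks[j]) <= max_gap
    }
    groups = [{i} for i in range(len(peaks))]
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(groups)), 2):
            if any((i, j) in adj for i in groups[a] for j in groups[b]):
                groups[a] |= groups[b]
                del groups[b]
                changed = True
                break
    groups.sort(key=min)
    return [[peaks[i] for i in sorted(g)] for g in groups]


def oracle_merge(bursts, window):
    """Repeatedly merge any mergeable adjacent pair until fixed point."""
    bursts = [list(b) for b in bursts]
    changed = True
    while changed:
        changed = False
        for i in range(len(bursts) - 1):
            if bursts[i + 1][0] - bursts[i][-1] <= window:
                bursts[i] = bursts[i] + bursts[i + 1]
                del bursts[i + 1]
                changed = True
                break
    return bursts


def oracle_band_power(x, w, band, fs):
    """Direct per-window DFT."""
    lo, hi = band
    bins = [k for k in range(w // 2 + 1) if lo <= k * fs / w <= hi]
    out = []
    for start in range(len(x) - w + 1):
        spectrum = np.fft.fft(x[start : start + w])
        out.append(np.mean(np.abs(spectrum[bins]) ** 2))
    return np.array(out)


# ---------------------------------------------------------------- preprocess


class TestPreprocess:
    def test_stopband_attenuation(self):
        t = np.arange(0, 10, 1 / FS)
        s = amp_settings()
        out_pass = preprocess(np.sin(2 * np.pi * 10 * t), s, FS)
        out_stop = preprocess(np.sin(2 * np.pi * 100 * t), s, FS)
        mid = slice(1000, -1000)  # away from filter edges
        ratio = np.abs(out_stop[mid]).max() / np.abs(out_pass[mid]).max()
        assert 20 * np.log10(ratio) <= -20

    def test_zero_in_zero_out(self):
        out = preprocess(np.zeros(4000), amp_settings(), FS)
        assert out.shape == (1000,)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_sign_multiplier_negates(self, rng):
        x = rng.standard_normal(4000)
        a = preprocess(x, amp_settings(), FS)
        b = preprocess(x, amp_settings(sign_multiplier=-1), FS)
        np.testing.assert_allclose(a, -b)

    def test_output_length_floor(self, rng):
        x = rng.standard_normal(4003)
        assert preprocess(x, amp_settings(), FS).size == 1000

    def test_downsample_above_rate_rejected(self):
        with pytest.raises(ParameterError):
            preprocess(np.zeros(4000), amp_settings(), sample_rate_hz=400.0)

    def test_bad_band_edges_rejected(self):
        with pytest.raises(ParameterError):
            amp_settings(band_low_hz=60.0, band_high_hz=50.0)
        with pytest.raises(ParameterError):
            amp_settings(band_high_hz=300.0)  # above Nyquist of 250


class TestThreshold:
    def test_mean0_sd1(self):
        trace = np.tile([-1.0, 1.0], 500)
        assert compute_threshold(trace, 5.0) == pytest.approx(5.0)

    def test_constant_trace_warns(self):
        with pytest.warns(UserWarning, match="SD is zero"):
            assert compute_threshold(np.full(100, 3.0), 7.0) == 3.0

    @given(c=st.floats(0.01, 100), n=st.floats(0.5, 10))
    def test_homogeneity(self, c, n):
        trace = np.sin(np.arange(200) / 7.0)
        base = compute_threshold(trace, n) - trace.mean()
        scaled = compute_threshold(c * trace, n) - c * trace.mean()
        assert scaled == pytest.approx(c * base, rel=1e-9)


class TestFindPeaks:
    def test_triangular_pulse(self):
        x = np.zeros(100)
        x[40:51] = np.linspace(0, 10, 11)
        x[50:61] = np.linspace(10, 0, 11)
        times = find_peaks_above(x, 5.0, 500.0)
        np.testing.assert_allclose(times, [50 / 500.0])

    def test_all_below_threshold(self):
        assert find_peaks_above(np.sin(np.arange(1000) / 10), 2.0, 500.0).size == 0

    def test_comb_10hz(self):
        fs = 500.0
        x = np.zeros(int(fs))
        apices = (np.arange(10) * fs / 10 + 10).astype(int)
        for a in apices:
            x[a - 2 : a + 3] += [1, 5, 10, 5, 1]
        times = find_peaks_above(x, 5.0, fs)
        assert times.size == 10
        np.testing.assert_allclose(np.diff(times), 0.1)

    def test_plateau_reports_first_sample(self):
        x = np.zeros(20)
        x[8:12] = 7.0
        times = find_peaks_above(x, 5.0, 1.0)
        np.testing.assert_allclose(times, [8.0])

    def test_strictly_above(self):
        x = np.zeros(9)
        x[4] = 5.0
        assert find_peaks_above(x, 5.0, 1.0).size == 0


GRID = [0.0, 0.25, 0.3, 0.6, 1.0, 1.35, 3.0, 6.0]


class TestBursts:
    def test_group_three_at_3hz(self):
        bursts = group_peaks_to_bursts(np.array([0.0, 0.3, 0.6]), 3.0)
        assert len(bursts) == 1
        np.testing.assert_allclose(bursts[0], [0.0, 0.3, 0.6])

    def test_gap_above_period_splits(self):
        bursts = group_peaks_to_bursts(np.array([0.0, 0.4]), 3.0)
        assert len(bursts) == 2

    def test_empty(self):
        assert group_peaks_to_bursts(np.array([]), 3.0) == []

    def test_group_oracle_exhaustive_grid(self):
        # every subset (<= 8 peaks) of an 8-point time grid
        for r in range(len(GRID) + 1):
            for subset in itertools.combinations(GRID, r):
                got = group_peaks_to_bursts(np.array(subset), 3.0)
                expected = oracle_group(list(subset), 3.0)
                assert [list(b) for b in got] == expected, subset

    def test_merge_within_window(self):
        merged = merge_bursts([np.array([0.0, 0.5]), np.array([2.5, 3.0])], 2.5)
        assert len(merged) == 1
        np.testing.assert_allclose(merged[0], [0.0, 0.5, 2.5, 3.0])

    def test_no_merge_beyond_window(self):
        merged = merge_bursts([np.array([0.0, 0.5]), np.array([3.5, 4.0])], 2.5)
        assert len(merged) == 2

    def test_merge_idempotent_and_oracle_exhaustive(self):
        for r in range(1, len(GRID) + 1):
            for subset in itertools.combinations(GRID, r):
                bursts = group_peaks_to_bursts(np.array(subset), 3.0)
                merged = merge_bursts(bursts, 2.5)
                again = merge_bursts(merged, 2.5)
                assert [list(b) for b in merged] == [list(b) for b in again]
                assert [list(b) for b in merged] == oracle_merge(bursts, 2.5)

    def test_filter_by_duration(self):
        kept = filter_by_duration([np.array([0.0, 2.0, 5.0])], 3.0)
        assert len(kept) == 1
        assert kept[0].onset_s == 0.0
        assert kept[0].offset_s == 5.0
        assert kept[0].duration_s == 5.0
        assert kept[0].n_peaks == 3

    def test_filter_drops_short(self):
        assert filter_by_duration([np.array([0.0, 1.0])], 3.0) == []

    def test_zero_min_duration_keeps_all(self):
        bursts = [np.array([0.0]), np.array([5.0, 6.0])]
        assert len(filter_by_duration(bursts, 0.0)) == 2


class TestSlidingBandPower:
    def test_pure_sine_stationary(self):
        # 10 Hz is not bin-centered at 500 Hz / 128 points, so rectangular
        # window scalloping leaves a small periodic ripple
        fs = 500.0
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        power = sliding_band_power(x, 128, (4.0, 40.0), fs)
        inner = power[64:-64]
        assert inner.max() / inner.min() == pytest.approx(1.0, rel=0.15)

    def test_bin_centered_sine_exactly_stationary(self):
        fs = 500.0
        f0 = 3 * fs / 128  # exactly bin 3
        t = np.arange(int(2 * fs)) / fs
        power = sliding_band_power(np.sin(2 * np.pi * f0 * t), 128, (4.0, 40.0), fs)
        inner = power[64:-64]
        assert inner.max() / inner.min() == pytest.approx(1.0, rel=1e-6)

    def test_dc_trace_zero_power(self):
        power = sliding_band_power(np.full(300, 4.2), 128, (4.0, 40.0), 500.0)
        np.testing.assert_allclose(power, 0.0, atol=1e-18)

    def test_bin_selection_500hz_128pt(self):
        np.testing.assert_array_equal(
            band_bins(128, (4.0, 40.0), 500.0), np.arange(2, 11)
        )

    def test_direct_dft_oracle(self, rng):
        x = rng.standard_normal(1000)
        power = sliding_band_power(x, 128, (4.0, 40.0), 500.0)
        expected = oracle_band_power(x, 128, (4.0, 40.0), 500.0)
        positions = rng.choice(power.size, size=25, replace=False)
        np.testing.assert_allclose(
            power[positions], expected[positions], rtol=1e-9, atol=1e-12
        )

    def test_too_short_raises(self):
        with pytest.raises(ParameterError):
            sliding_band_power(np.zeros(100), 128, (4.0, 40.0), 500.0)


def seizure_session(seed, duration_s=120.0, starts=(30.0,), seizure_s=6.0):
    spec = SimulationSpec(
        seed=seed,
        duration_s=duration_s,
        n_animals=1,
        seizures=[
            SeizureSchedule(
                animal=0, start_s=s, duration_s=seizure_s, amplitude_uv=600.0,
                spike_rate_hz=8.0,
            )
            for s in starts
        ],
    )
    signals, truth = generate_signals(spec)
    return signals[0], truth


class TestDetectAmplitude:
    def test_injected_seizure_recovered(self):
        trace, _ = seizure_session(seed=11, starts=(50.0,), seizure_s=5.0)
        events = detect_amplitude(trace, amp_settings(), FS)
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(50.0, abs=0.2)
        assert events[0].offset_s == pytest.approx(55.0, abs=0.2)
        assert events[0].method == "amplitude"

    def test_zero_trace_no_events(self):
        with pytest.warns(UserWarning):
            assert detect_amplitude(np.zeros(40000), amp_settings(), FS) == []

    def test_two_trains_merge(self):
        # two 2-s trains separated by 2.0 s -> one event spanning >= 6 s
        trace, _ = seizure_session(seed=12, starts=(40.0, 44.0), seizure_s=2.0)
        events = detect_amplitude(trace, amp_settings(min_duration_s=3.0), FS)
        assert len(events) == 1
        assert events[0].duration_s >= 5.5

    def test_pipeline_equals_stage_composition(self):
        trace, _ = seizure_session(seed=13)
        s = amp_settings()
        det = preprocess(trace, s, FS)
        threshold = compute_threshold(det, s.threshold_n_sd)
        peaks = find_peaks_above(det, threshold, s.downsample_hz)
        bursts = group_peaks_to_bursts(peaks, s.min_burst_freq_hz)
        merged = merge_bursts(bursts, s.merge_window_s)
        manual = filter_by_duration(
            merged, s.min_duration_s, method="amplitude", threshold_used=threshold
        )
        auto = detect_amplitude(trace, s, FS)
        assert len(auto) == len(manual)
        for a, m in zip(auto, manual):
            assert a.onset_s == m.onset_s
            assert a.offset_s == m.offset_s
            np.testing.assert_array_equal(a.peak_times_s, m.peak_times_s)

    def test_monotone_in_n_and_duration(self):
        trace, _ = seizure_session(seed=14, starts=(20.0, 60.0, 100.0))
        s_lo = amp_settings(threshold_n_sd=3.0, min_duration_s=0.0)
        s_hi = amp_settings(threshold_n_sd=8.0, min_duration_s=0.0)
        det = preprocess(trace, s_lo, FS)
        peaks_lo = find_peaks_above(det, compute_threshold(det, 3.0), 500.0)
        peaks_hi = find_peaks_above(det, compute_threshold(det, 8.0), 500.0)
        assert peaks_hi.size <= peaks_lo.size
        n_events = [
            len(detect_amplitude(trace, amp_settings(min_duration_s=d), FS))
            for d in (0.0, 3.0, 30.0)
        ]
        assert n_events[0] >= n_events[1] >= n_events[2]


class TestDetectSpectral:
    def test_injected_seizure_recovered(self):
        trace, truth = seizure_session(seed=21, starts=(50.0,), seizure_s=6.0)
        events = detect_spectral(
            trace, amp_settings(method="spectral"), FS
        )
        assert len(events) == 1
        lo, hi = truth.seizure_intervals[0][0]
        assert events[0].onset_s < hi and events[0].offset_s > lo
        assert events[0].method == "spectral"

    @pytest.mark.parametrize("seed", range(5))
    def test_noise_only_no_events_high_n(self, seed):
        spec = SimulationSpec(seed=seed, duration_s=60.0, n_animals=1)
        signals, _ = generate_signals(spec)
        s = amp_settings(method="spectral", threshold_n_sd=10.0)
        assert detect_spectral(signals[0], s, FS) == []


class TestScaleInvariance:
    @pytest.mark.parametrize("c", [0.1, 10.0])
    @pytest.mark.parametrize("method", ["amplitude", "spectral"])
    def test_events_unchanged_under_scaling(self, c, method):
        trace, _ = seizure_session(seed=31, starts=(30.0, 70.0))
        s = amp_settings(method=method)
        fn = detect_amplitude if method == "amplitude" else detect_spectral
        base = fn(trace, s, FS)
        scaled = fn(c * trace, s, FS)
        assert len(base) == len(scaled) == 2
        for a, b in zip(base, scaled):
            assert a.onset_s == b.onset_s
            assert a.offset_s == b.offset_s
            assert a.n_peaks == b.n_peaks


class TestSettingsIO:
    def test_json_roundtrip(self, tmp_path):
        s = amp_settings(threshold_n_sd=4.5, min_duration_s=2.0, method="spectral")
        path = tmp_path / "settings.json"
        s.to_json(path)
        back = DetectionSettings.from_json(path)
        assert back == s
        assert back.settings_hash() == s.settings_hash()
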
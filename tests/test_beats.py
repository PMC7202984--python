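"""Beat extraction: baseline removal, peak detection, HR, outliers, splines."""

import numpy as np
import pytest

from circosc import (
    BeatSeries,
    compute_hr,
    detect_r_peaks,
    detect_systolic_peaks,
    downsample_ldf,
    extract_ppg_amplitude,
    extract_variables,
    interpolate_to_uniform,
    remove_baseline_wander,
    remove_outliers,
    select_segment,
)


class TestBaselineWander:
    def test_dc_offset_removed(self, clean_short):
        _, rec, _ = clean_short
        ecg = rec.channels["ecg"] + 0.5
        out = remove_baseline_wander(ecg, rec.fs)
        assert abs(np.median(out)) < 0.01

    def test_sinusoidal_wander_suppressed(self, clean_short):
        # Project the residual onto the injected wander to measure leftover
        # amplitude: must be < 10% of the 0.3 mV injected.
        _, rec, _ = clean_short
        fs = rec.fs
        t = np.arange(rec.n_samples) / fs
        wander = 0.3 * np.sin(2 * np.pi * t / 5.0)
        out = remove_baseline_wander(rec.channels["ecg"] + wander, fs)
        basis = np.sin(2 * np.pi * t / 5.0)
        residual_amp = 2 * np.abs(out @ basis) / len(t)
        assert residual_amp < 0.03

    def test_zero_signal_maps_to_zero(self):
        out = remove_baseline_wander(np.zeros(4000), fs=400.0)
        assert np.allclose(out, 0.0)

    def test_window_longer_than_signal_raises(self):
        with pytest.raises(ValueError, match="window"):
            remove_baseline_wander(np.zeros(100), fs=400.0, window=1.0)


class TestPeakDetection:
    def test_r_peaks_match_ledger(self, clean_short):
        _, rec, ledger = clean_short
        ecg = remove_baseline_wander(rec.channels["ecg"], rec.fs)
        r = detect_r_peaks(ecg, rec.fs)
        assert len(r) == len(ledger.beat_times)
        assert np.abs(r.times - ledger.beat_times).max() <= 0.005

    def test_amplitude_modulation_recovered(self, clean_short):
        _, rec, ledger = clean_short
        ecg = remove_baseline_wander(rec.channels["ecg"], rec.fs)
        r = detect_r_peaks(ecg, rec.fs)
        assert np.corrcoef(r.values, ledger.true_r_amp)[0, 1] > 0.99

    def test_white_noise_yields_no_beats(self, rng):
        noise = rng.normal(0.0, 0.05, size=int(60 * 400))
        with pytest.warns(UserWarning, match="no R peaks"):
            r = detect_r_peaks(noise, 400.0)
        assert len(r) == 0

    def test_systolic_peaks_match_ledger(self, clean_short):
        _, rec, ledger = clean_short
        s = detect_systolic_peaks(rec.channels["bp"], rec.fs)
        assert len(s) == len(ledger.beat_times)
        assert np.allclose(s.values, ledger.true_sbp, rtol=0.01)
        assert np.corrcoef(s.values, ledger.true_sbp)[0, 1] > 0.99

    def test_flat_line_bp_yields_no_beats(self):
        with pytest.warns(UserWarning, match="flat"):
            s = detect_systolic_peaks(np.full(4000, 80.0), 400.0)
        assert len(s) == 0


class TestComputeHr:
    @pytest.mark.parametrize(
        "times, expected",
        [
            ([0.0, 1.0, 2.0], [60.0, 60.0]),
            ([0.0, 0.75], [80.0]),
            ([0.0, 1.0, 1.5, 2.5], [60.0, 120.0, 60.0]),
        ],
    )
    def test_hr_values(self, times, expected):
        hr = compute_hr(np.array(times))
        assert np.allclose(hr.values, expected)

    def test_timestamp_conventions(self):
        hr_mid = compute_hr(np.array([0.0, 1.0, 2.0]), timestamp="mid")
        hr_start = compute_hr(np.array([0.0, 1.0, 2.0]), timestamp="start")
        assert np.allclose(hr_mid.times, [0.5, 1.5])
        assert np.allclose(hr_start.times, [0.0, 1.0])

    def test_non_increasing_times_raise(self):
        with pytest.raises(ValueError):
            compute_hr(np.array([0.0, 1.0, 0.5]))

    def test_ledger_closure_machine_precision(self, clean_short):
        _, _, ledger = clean_short
        hr = compute_hr(ledger.beat_times)
        assert np.array_equal(hr.values, 60.0 / np.diff(ledger.beat_times))


class TestOutlierRemoval:
    @staticmethod
    def _series(values):
        return BeatSeries(times=np.arange(len(values), dtype=float),
                          values=np.asarray(values, dtype=float), role="SBP")

    def test_clean_series_unchanged(self, rng):
        s = self._series(120 + rng.normal(0, 2, size=200))
        out = remove_outliers(s, k=4.0)
        assert len(out) == len(s)

    def test_single_spike_removed(self, rng):
        # Brute-force oracle: compute every point's robust z-score and check
        # exactly the planted spike exceeds k.
        base = 120 + rng.normal(0, 2, size=200)
        base[77] += 10 * 2 * 1.4826  # ~10 robust scale units
        s = self._series(base)
        out = remove_outliers(s, k=4.0, window=60)
        removed = sorted(set(range(200)) - set(out.times.astype(int)))
        z = np.empty(200)
        for i in range(200):
            lo, hi = max(0, i - 30), min(200, i + 31)
            seg = base[lo:hi]
            med = np.median(seg)
            z[i] = abs(base[i] - med) / (1.4826 * np.median(np.abs(seg - med)))
        assert removed == sorted(np.flatnonzero(z > 4.0))
        assert 77 in removed

    def test_constant_series_kept_by_zero_scale_guard(self):
        out = remove_outliers(self._series(np.full(50, 120.0)), k=4.0)
        assert len(out) == 50

    def test_idempotent(self, rng):
        base = 120 + rng.normal(0, 2, size=300)
        base[50] += 40
        base[200] -= 35
        once = remove_outliers(self._series(base), k=4.0)
        twice = remove_outliers(once, k=4.0)
        assert np.array_equal(once.values, twice.values)

    def test_too_few_events_raise(self):
        with pytest.raises(ValueError):
            remove_outliers(self._series([1.0, 2.0, 3.0]), k=4.0)


class TestInterpolation:
    def test_sinusoid_interpolation_error_below_1pct(self, rng):
        # Beat-like (~1 Hz, jittered) samples of a 100-s sinusoid.
        t = np.arange(0.0, 100.0, 1.0) + rng.uniform(0.0, 0.3, size=100)
        values = 5 * np.sin(2 * np.pi * t / 100.0)
        s = BeatSeries(times=t, values=values, role="SBP")
        out = interpolate_to_uniform(s, fs=10.0)
        truth = 5 * np.sin(2 * np.pi * out.times / 100.0)
        inner = (out.times > t[2]) & (out.times < t[-3])
        assert np.abs(out.values - truth)[inner].max() < 0.05

    def test_grid_points_reproduced_exactly(self):
        t = np.arange(0.0, 10.0, 0.5)
        s = BeatSeries(times=t, values=np.sin(t), role="SBP")
        out = interpolate_to_uniform(s, fs=10.0)
        shared = np.isin(np.round(out.times, 6), np.round(t, 6))
        assert np.allclose(out.values[shared], np.sin(t), atol=1e-12)

    def test_too_few_events_raise(self):
        s = BeatSeries(times=np.array([0.0, 1.0, 2.0]), values=np.zeros(3), role="SBP")
        with pytest.raises(ValueError):
            interpolate_to_uniform(s)

    def test_no_extrapolation_beyond_events(self):
        t = np.linspace(0.33, 9.61, 20)
        s = BeatSeries(times=t, values=np.ones(20), role="SBP")
        out = interpolate_to_uniform(s, fs=10.0)
        assert out.times[0] >= t[0] - 1e-9
        assert out.times[-1] <= t[-1] + 1e-9


class TestAuxChannels:
    def test_ppg_same_algorithm_as_bp(self, clean_short):
        # Feeding the BP waveform through the PPG path must reproduce the
        # iSBP path output exactly (shared code path).
        _, rec, _ = clean_short
        via_ppg = extract_ppg_amplitude(rec.channels["bp"], rec.fs)
        s = detect_systolic_peaks(rec.channels["bp"], rec.fs)
        via_bp = interpolate_to_uniform(remove_outliers(s), fs=10.0)
        assert np.array_equal(via_ppg.values, via_bp.values)

    def test_ldf_constant_preserved(self):
        out = downsample_ldf(np.full(40000, 200.0), fs_in=400.0)
        assert np.allclose(out.values, 200.0, rtol=1e-6)
        assert out.fs == 10.0

    def test_ldf_passband_amplitude_preserved(self):
        t = np.arange(0, 100, 1 / 400)
        out = downsample_ldf(np.sin(2 * np.pi * t / 50.0), fs_in=400.0)
        inner = out.values[50:-50]
        assert np.max(np.abs(inner)) == pytest.approx(1.0, rel=0.01)

    def test_ldf_filter_response(self):
        t = np.arange(0, 60, 1 / 400)
        low = downsample_ldf(np.sin(2 * np.pi * 1.0 * t), fs_in=400.0)
        high = downsample_ldf(np.sin(2 * np.pi * 6.0 * t), fs_in=400.0)
        assert np.abs(low.values[100:-100]).max() > 0.95
        assert np.abs(high.values[100:-100]).max() < 0.1

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            downsample_ldf(np.zeros(100), fs_in=5.0, fs_out=10.0)


class TestSegments:
    def test_full_segment_is_identity(self, clean_short):
        _, rec, _ = clean_short
        seg = select_segment(rec, 0.0, rec.duration)
        assert np.array_equal(seg.channels["ecg"], rec.channels["ecg"])

    def test_sample_counts(self, clean_short):
        _, rec, _ = clean_short
        seg = select_segment(rec, 60.0, 100.0)
        assert seg.n_samples == int(100.0 * rec.fs)
        assert seg.start_time == pytest.approx(60.0)

    def test_out_of_range_raises(self, clean_short):
        _, rec, _ = clean_short
        with pytest.raises(ValueError):
            select_segment(rec, -1.0, 10.0)
        with pytest.raises(ValueError):
            select_segment(rec, 0.0, rec.duration + 1.0)


class TestEndToEnd:
    def test_recovery_of_injected_modulations(self, clean_short):
        _, rec, ledger = clean_short
        res = extract_variables(rec)
        targets = {"iSBP": "SBP", "iHR": "HR", "iAmp": "R-amplitude"}
        for name, target in targets.items():
            s = res.series[name]
            injected = ledger.modulations[0].waveform(s.times, target)
            r = np.corrcoef(s.values - s.values.mean(), injected)[0, 1]
            assert r > 0.99, name

    def test_counts_account_for_outliers(self, noisy_short):
        _, rec, _ = noisy_short
        res = extract_variables(rec)
        for name, c in res.counts.items():
            kept = len(res.beats[name]) if name in res.beats else None
            if kept is not None:
                assert c["detected"] == kept + c["removed"]

    def test_series_aligned_on_common_grid(self, noisy_short):
        _, rec, _ = noisy_short
        res = extract_variables(rec)
        lengths = {len(s) for s in res.series.values()}
        starts = {s.start_time for s in res.series.values()}
        assert len(lengths) == 1
        assert len(starts) == 1
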
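"""Filtering, referencing, masking, and channel-QC tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spindec import preprocess as pp
from spindec.synthetic import RawRecording, SimConfig, simulate_session

FS = 20_000.0


def sine(freq, fs=FS, dur=2.0, amp=1.0, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestChannelQC:
    def test_only_in_window_channels_kept(self):
        qc = pp.channel_qc(np.array([50e3, 500e3, 3e6]))
        np.testing.assert_array_equal(qc.functional, [False, True, False])

    def test_window_boundaries_are_closed(self):
        qc = pp.channel_qc(np.array([1e5, 2e6, 1e5 - 1, 2e6 + 1]))
        np.testing.assert_array_equal(qc.functional, [True, True, False, False])

    def test_drop_disconnected_preserves_order_and_geometry(self):
        rec, _, _ = simulate_session(SimConfig(seed=1, duration_s=3.0, n_channels=6, n_units=3))
        qc = pp.channel_qc(np.array([5e5, 5e4, 5e5, 5e5, 3e6, 5e5]))
        out = pp.drop_disconnected(rec, qc)
        np.testing.assert_array_equal(out.samples, rec.samples[[0, 2, 3, 5]])
        np.testing.assert_array_equal(out.channel_positions_um,
                                      rec.channel_positions_um[[0, 2, 3, 5]])

    def test_all_in_range_is_identity(self):
        rec, _, _ = simulate_session(SimConfig(seed=1, duration_s=3.0, n_channels=4, n_units=2))
        out = pp.drop_disconnected(rec, pp.channel_qc(np.full(4, 5e5)))
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_zero_functional_channels_is_an_error(self):
        rec, _, _ = simulate_session(SimConfig(seed=1, duration_s=3.0, n_channels=4, n_units=2))
        with pytest.raises(ValueError, match="no functional"):
            pp.drop_disconnected(rec, pp.channel_qc(np.full(4, 1e3)))


class TestArtifactMask:
    def test_constant_trace_all_valid(self):
        mask = pp.reject_artifacts(np.full((2, 4000), 7.0), FS)
        assert mask.all()

    def test_alternating_burst_flags_exactly_its_window(self):
        x = np.zeros(20_000)  # 1 s -> 20 windows of 50 ms
        w = 1000
        x[5 * w : 6 * w] = 100.0 * (-1) ** np.arange(w)  # sample std ~ 100 µV
        mask = pp.reject_artifacts(x, FS)
        assert not mask[5 * w : 6 * w].any()
        keep = np.ones(len(x), dtype=bool)
        keep[5 * w : 6 * w] = False
        assert mask[keep].all()

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="longer than"):
            pp.reject_artifacts(np.zeros(100), FS, window_ms=50.0)

    def test_white_noise_tail_matches_chi_square(self, rng):
        # sample std of a 1000-sample window: (n-1)s^2/sigma^2 ~ chi2(n-1)
        sigma, thresh, n = 10.0, 10.5, 1000
        n_windows = 2400
        x = sigma * rng.standard_normal((2, n_windows // 2 * n))
        mask = pp.reject_artifacts(x, FS, std_thresh_uv=thresh)
        flagged = (~mask).sum() / n
        p = stats.chi2.sf((n - 1) * thresh**2 / sigma**2, n - 1)
        expect = p * n_windows
        assert abs(flagged - expect) <= 4 * np.sqrt(expect * (1 - p))

    def test_rle_round_trip(self, rng):
        mask = rng.random((3, 500)) > 0.2
        np.testing.assert_array_equal(pp.rle_to_mask(pp.mask_to_rle(mask)), mask)


class TestCommonMedianReference:
    def test_three_channel_example(self):
        out = pp.common_median_reference(np.array([[3.0], [5.0], [9.0]]))
        np.testing.assert_allclose(out[:, 0], [-2.0, 0.0, 4.0])

    @given(st.integers(2, 9), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_common_mode_rejection(self, n_ch, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal((n_ch, 200))
        c = r.standard_normal(200)  # arbitrary waveform added to every channel
        np.testing.assert_allclose(
            pp.common_median_reference(x + c), pp.common_median_reference(x), atol=1e-12
        )

    def test_even_channel_median_is_mean_of_central_pair(self, rng):
        x = rng.standard_normal((6, 50))
        manual = np.sort(x, axis=0)[2:4].mean(axis=0)  # sorted-list oracle
        np.testing.assert_allclose(pp.common_median_reference(x), x - manual)

    def test_single_channel_passes_through_with_warning(self):
        x = np.arange(10.0)[None, :]
        with pytest.warns(UserWarning):
            out = pp.common_median_reference(x)
        np.testing.assert_array_equal(out, x)


class TestFilters:
    def test_spike_band_passes_1khz_with_zero_phase(self):
        x = sine(1000.0)
        y = pp.bandpass(x, FS, 300.0, 6000.0)
        mid = slice(4000, -4000)
        amp = y[mid].std() / x[mid].std()
        assert abs(amp - 1.0) < 0.01
        lags = np.arange(-5, 6)
        xc = [np.dot(x[mid], np.roll(y, L)[mid]) for L in lags]
        assert abs(lags[int(np.argmax(xc))]) <= 1

    def test_spike_band_rejects_10hz(self):
        x = sine(10.0)
        y = pp.bandpass(x, FS, 300.0, 6000.0)
        assert np.abs(y[4000:-4000]).max() <= 0.01

    def test_dc_removed_by_any_bandpass(self):
        y = pp.bandpass(np.full(40_000, 3.3), FS, 1.0, 300.0)
        assert abs(y.mean()) < 1e-6

    def test_unstable_design_rejected(self):
        with pytest.raises(ValueError):
            pp.bandpass(np.zeros(1000), FS, 300.0, 10_001.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=10, deadline=None)
    def test_linearity_superposition(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal((2, 4000))
        alpha = float(r.uniform(-3, 3))
        lhs = pp.bandpass(alpha * a + b, FS, 300.0, 6000.0)
        rhs = alpha * pp.bandpass(a, FS, 300.0, 6000.0) + pp.bandpass(b, FS, 300.0, 6000.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_notch_kills_50hz(self):
        x = sine(50.0)
        y = pp.notch(x, FS)
        assert y[4000:-4000].std() <= 0.1 * x.std()  # >= 20 dB

    def test_notch_spares_neighbors_and_10hz(self):
        for f in (10.0, 45.0, 55.0):
            x = sine(f, dur=4.0)
            y = pp.notch(x, FS)
            mid = slice(8000, -8000)
            assert y[mid].std() >= 0.95 * x[mid].std(), f
        np.testing.assert_array_equal(pp.notch(np.zeros(1000), FS), np.zeros(1000))


class TestBandSplit:
    def test_3hz_lands_only_in_lowest_band(self):
        fs = 2000.0
        x = sine(3.0, fs=fs, dur=10.0)
        bands = pp.split_lfp_bands(x, fs)
        mid = slice(int(2 * fs), -int(2 * fs))
        amps = {name: b[mid].std() * np.sqrt(2) for name, b in bands.items()}
        assert amps["1-4"] > 0.9
        for name, a in amps.items():
            if name != "1-4":
                assert a < 0.3, name

    def test_60hz_lands_only_in_30_90(self):
        fs = 2000.0
        bands = pp.split_lfp_bands(sine(60.0, fs=fs, dur=6.0), fs)
        mid = slice(int(fs), -int(fs))
        amps = {name: b[mid].std() * np.sqrt(2) for name, b in bands.items()}
        assert amps["30-90"] > 0.9
        assert all(a < 0.1 for n, a in amps.items() if n != "30-90")

    def test_band_energies_bounded_by_broadband(self, rng):
        fs = 2000.0
        x = rng.standard_normal(int(10 * fs))
        broadband = pp.bandpass(x, fs, 1.0, 300.0)
        bands = pp.split_lfp_bands(x, fs)
        assert sum(b.var() for b in bands.values()) <= 1.02 * broadband.var()

    def test_canonical_band_set(self):
        names = [b.name for b in pp.BANDS]
        assert names == ["1-4", "4-8", "8-12", "12-30", "30-90", "90-200", "200-300"]
        assert (pp.SPIKE_BAND.low_hz, pp.SPIKE_BAND.high_hz) == (300.0, 6000.0)


class TestDownsample:
    def test_inband_sine_survives(self):
        x = sine(100.0)
        y = pp.downsample(x, FS, 1000.0)
        assert abs(y[500:-500].std() * np.sqrt(2) - 1.0) < 0.02

    def test_dc_survives_exactly(self):
        y = pp.downsample(np.full(20_000, 2.5), FS, 1000.0)
        np.testing.assert_allclose(y, 2.5)

    def test_high_frequency_suppressed(self):
        y = pp.downsample(sine(9000.0), FS, 1000.0)
        assert np.abs(y[100:-100]).max() <= 0.01

    def test_non_divisor_rate_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            pp.downsample(np.zeros(1000), FS, 900.0)

    def test_sample_count(self):
        assert pp.downsample(np.zeros(20_000), FS, 1000.0).shape == (1000,)
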
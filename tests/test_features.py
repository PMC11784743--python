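import numpy as np
import pytest
from scipy import signal as sps

from hatl.data import get_profile
from hatl.features import (RawRecording, WindowSpec, differential_entropy,
                           extract_dataset, head_movement_features,
                           peripheral_features, sliding_windows,
                           welch_band_power)
from hatl.simulate import simulate_raw_recording


def _recording(n_samples, fs=128.0, n_ch=1, kind="eeg"):
    return RawRecording(np.zeros((n_ch, n_samples)), fs,
                        tuple(f"CH{i+1}" for i in range(n_ch)), kind)


class TestSlidingWindows:
    def test_worked_example_60s_at_128hz(self):
        # 3-s windows, 2-s overlap: L=384, hop=128, floor((7680-384)/128)+1
        wins = sliding_windows(_recording(60 * 128), WindowSpec(3.0, 2.0))
        assert len(wins) == 58
        assert wins[0] == (0, 384)
        assert wins[1][0] - wins[0][0] == 128

    def test_exactly_one_window(self):
        wins = sliding_windows(_recording(384), WindowSpec(3.0, 2.0))
        assert wins == [(0, 384)]

    def test_zero_overlap_tiles(self):
        wins = sliding_windows(_recording(1000), WindowSpec(3.0, 0.0))
        assert len(wins) == 1000 // 384
        for (a, b) in wins:
            assert b - a == 384 and b <= 1000

    def test_hop_and_bounds_invariant(self):
        rec = _recording(5000, fs=100.0)
        spec = WindowSpec(2.5, 1.0)
        wins = sliding_windows(rec, spec)
        L = round(2.5 * 100)
        hop = L - round(1.0 * 100)
        starts = [a for a, _ in wins]
        assert all(s2 - s1 == hop for s1, s2 in zip(starts, starts[1:]))
        assert all(b <= rec.n_samples for _, b in wins)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            sliding_windows(_recording(100), WindowSpec(3.0, 2.0))

    def test_bad_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(2.0, 2.0)


class TestDifferentialEntropy:
    def test_inband_sinusoid_with_reference_variance(self):
        # a 10 Hz sinusoid passes the alpha filter nearly untouched; with
        # amplitude giving variance 1/(2*pi*e) the Gaussian DE is 0
        fs, t = 256.0, np.arange(0, 8, 1 / 256.0)
        target = 1.0 / (2.0 * np.pi * np.e)
        x = np.sqrt(2 * target) * np.sin(2 * np.pi * 10 * t)
        de = differential_entropy(x, (8.0, 12.0), fs)
        assert abs(de) < 0.05

    def test_unit_variance_closed_form(self):
        fs, t = 256.0, np.arange(0, 8, 1 / 256.0)
        x = np.sqrt(2) * np.sin(2 * np.pi * 10 * t)  # variance 1
        de = differential_entropy(x, (8.0, 12.0), fs)
        assert de == pytest.approx(0.5 * np.log(2 * np.pi * np.e), abs=0.03)

    def test_zero_variance_sentinel(self):
        de = differential_entropy(np.zeros(512), (8.0, 12.0), 128.0)
        assert de == -np.inf

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            differential_entropy(np.ones(100), (60.0, 70.0), 128.0)

    def test_monotone_in_band_variance(self, rng):
        rec = simulate_raw_recording({(8.0, 12.0): 1.0}, 128.0, 8.0, seed=1)
        x = rec.signals[0]
        des = [differential_entropy(a * x, (8.0, 12.0), 128.0)
               for a in (0.5, 1.0, 2.0, 4.0)]
        assert all(d1 < d2 for d1, d2 in zip(des, des[1:]))

    def test_independent_filter_oracle(self):
        # FIR band-pass as the independent implementation; the test signal's
        # energy lies inside the band so filter-skirt differences between the
        # two designs cannot dominate the comparison
        fs, band = 128.0, (8.0, 12.0)
        rec = simulate_raw_recording({(9.0, 11.0): 1.0}, fs, 16.0, seed=3)
        x = rec.signals[0]
        de_iir = differential_entropy(x, band, fs)
        taps = sps.firwin(257, band, fs=fs, pass_zero=False)
        var_fir = sps.filtfilt(taps, [1.0], x).var()
        de_fir = 0.5 * np.log(2 * np.pi * np.e * var_fir)
        assert de_iir == pytest.approx(de_fir, abs=0.05 * abs(de_fir) + 0.02)


class TestWelchBandPower:
    BANDS = [(4.0, 8.0), (8.0, 12.0), (12.0, 30.0), (30.0, 45.0)]

    def test_zero_signal(self):
        out = welch_band_power(np.zeros(512), self.BANDS, 128.0)
        assert np.all(out == 0.0)

    def test_sinusoid_power_concentrated_in_alpha(self):
        fs, t = 128.0, np.arange(0, 16, 1 / 128.0)
        x = np.sin(2 * np.pi * 10 * t)  # power a^2/2 = 0.5
        out = welch_band_power(x, self.BANDS, fs)
        alpha = out[1]
        assert alpha == pytest.approx(0.5, rel=0.10)
        others = np.delete(out, 1)
        assert np.all(others < 0.05 * alpha)

    def test_white_noise_power_proportional_to_bandwidth(self):
        fs = 128.0
        bands = [(4.0, 8.0), (8.0, 16.0)]  # 2x bandwidth
        ratios = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            out = welch_band_power(rng.normal(size=1024), bands, fs)
            ratios.append(out[1] / out[0])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)

    def test_adjacent_band_additivity(self):
        # fs/nperseg chosen so each band spans an even number of PSD bins,
        # making composite Simpson integration exactly additive
        fs = 128.0
        rng = np.random.default_rng(7)
        x = rng.normal(size=1024)
        parts = welch_band_power(x, [(4.0, 8.0), (8.0, 12.0)], fs, nperseg=256)
        union = welch_band_power(x, [(4.0, 12.0)], fs, nperseg=256)
        assert parts.sum() == pytest.approx(union[0], rel=1e-6)

    def test_band_outside_nyquist(self):
        with pytest.raises(ValueError):
            welch_band_power(np.ones(512), [(30.0, 70.0)], 128.0)


class TestPeripheralFeatures:
    def test_constant_signal(self):
        out = peripheral_features(np.full(100, 3.0))
        # mean, std, min, max, |d1|, |d2|, power (DC excluded), gradient
        assert np.allclose(out, [3.0, 0, 3.0, 3.0, 0, 0, 0, 0])

    def test_linear_ramp(self):
        m, n = 0.5, 50
        x = m * np.arange(n)
        out = peripheral_features(x)
        assert out[4] == pytest.approx(m)   # mean |first difference|
        assert out[7] == pytest.approx(m)   # average gradient

    def test_matches_naive_loops(self, rng):
        x = rng.normal(size=64)
        out = peripheral_features(x)
        d1 = [x[i + 1] - x[i] for i in range(63)]
        d2 = [x[i + 2] - 2 * x[i + 1] + x[i] for i in range(62)]
        spec = np.abs(np.fft.rfft(x)) ** 2 / x.size
        grad = np.gradient(x)
        naive = [np.mean(x), np.std(x), np.min(x), np.max(x),
                 np.mean(np.abs(d1)), np.mean(np.abs(d2)),
                 spec[1:].sum(), np.mean(grad)]
        assert np.allclose(out, naive)

    def test_too_short(self):
        with pytest.raises(ValueError):
            peripheral_features(np.array([1.0, 2.0]))


class TestHeadMovementFeatures:
    def _angles(self, arr):
        return RawRecording(arr, 30.0, ("yaw", "pitch", "roll"), "head-angles")

    def test_constant_angles_all_zero(self):
        out = head_movement_features(self._angles(np.ones((3, 50))))
        assert np.allclose(out, 0.0)

    def test_steady_yaw_rotation(self):
        arr = np.zeros((3, 50))
        arr[0] = np.arange(50)  # 1 degree per frame
        out = head_movement_features(self._angles(arr))
        assert np.allclose(out[:5], [1, 1, 1, 1, 0])
        assert np.allclose(out[5:], 0.0)

    def test_matches_naive_recomputation(self, rng):
        arr = np.cumsum(rng.normal(size=(3, 100)), axis=1)
        out = head_movement_features(self._angles(arr))
        naive = []
        for ax in arr:
            d = np.diff(ax)
            naive += [d.min(), d.max(), d.mean(), np.median(d), d.std()]
        assert np.allclose(out, naive)

    def test_wrong_channel_count(self):
        with pytest.raises(ValueError):
            RawRecording(np.zeros((2, 10)), 30.0, ("yaw", "pitch"), "head-angles")


class TestExtractDataset:
    def test_deap_profile_feature_counts(self):
        schema = get_profile("deap")
        fs, dur = 128.0, 9.0
        bands = {(4.0, 45.0): 1.0}
        eeg = simulate_raw_recording(bands, fs, dur, seed=0, n_channels=32,
                                     channel_names=schema.eeg_channels)
        periph = simulate_raw_recording({(0.5, 10.0): 1.0}, fs, dur, seed=1,
                                        n_channels=8,
                                        channel_names=tuple("P%d" % i for i in range(8)),
                                        kind="peripheral")
        ds = extract_dataset(eeg, periph, schema, WindowSpec(3.0, 2.0),
                             label=2, subject="s01")
        assert ds.X_eeg.shape[1] == 128 and ds.S_noneeg.shape[1] == 64
        assert ds.X_eeg.shape[0] == 7  # floor((1152-384)/128)+1
        assert np.all(ds.y == 2) and np.all(ds.subject == "s01")

    def test_seedv_profile_eeg_width(self):
        schema = get_profile("seedv")
        eeg = simulate_raw_recording({(1.0, 50.0): 1.0}, 200.0, 3.0, seed=0,
                                     n_channels=62,
                                     channel_names=schema.eeg_channels)
        # eye-movement features arrive precomputed from the tracker software
        eye_features = np.random.default_rng(1).random(33)
        ds = extract_dataset(eeg, eye_features, schema, WindowSpec(3.0, 0.0),
                             label=0, subject=1)
        assert ds.X_eeg.shape == (1, 310)
        assert ds.S_noneeg.shape == (1, 33)

    def test_graffitivr_profile_with_composites(self):
        schema = get_profile("graffitivr")
        fs, dur = 500.0, 4.0
        eeg = simulate_raw_recording({(1.0, 45.0): 1.0}, fs, dur, seed=0,
                                     n_channels=6,
                                     channel_names=schema.eeg_channels)
        head = simulate_raw_recording({(0.1, 5.0): 1.0}, fs, dur, seed=1,
                                      n_channels=3,
                                      channel_names=("yaw", "pitch", "roll"),
                                      kind="head-angles")
        ds = extract_dataset(eeg, head, schema, WindowSpec(2.0, 1.0),
                             label=1, subject=5,
                             eeg_extra=np.zeros(5))
        assert ds.X_eeg.shape[1] == 35 and ds.S_noneeg.shape[1] == 15

    def test_missing_channel_raises(self):
        schema = get_profile("mini")
        eeg = simulate_raw_recording({(4.0, 45.0): 1.0}, 128.0, 4.0, seed=0,
                                     n_channels=1, channel_names=("C1",))
        periph = simulate_raw_recording({(0.5, 5.0): 1.0}, 128.0, 4.0, seed=1,
                                        n_channels=4,
                                        channel_names=("a", "b", "c", "d"),
                                        kind="peripheral")
        with pytest.raises(ValueError, match="missing"):
            extract_dataset(eeg, periph, schema, WindowSpec(3.0, 0.0), 0, 0)
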
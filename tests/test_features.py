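import dataclasses

import numpy as np
import pytest
from scipy.signal.windows import hann

from pulseaf.records import PPGRecord
from pulseaf.decompose import EmdConfig, EnsembleConfig
from pulseaf.features import (
    FeatureConfig,
    MissingFeatureError,
    power_spectrum,
    spectrum_bin_freqs,
    build_filterbank,
    apply_filterbank,
    power_normalize,
    power_law,
    time_domain_features,
    extract_cepncc,
    write_feature_csv,
    read_feature_csv,
    _gammatone_weights,
)
from pulseaf.synth import AF_PRESET, NSR_PRESET, generate_record
from pulseaf.preprocess import preprocess_record, SegmentConfig
from conftest import noiseless

FS = 125.0


def tone(freq, n=2000, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestPowerSpectrum:
    def test_tone_peaks_at_its_bin(self):
        spec = power_spectrum(tone(5.0), FS, 4.0, 2.0)
        freqs = spectrum_bin_freqs(FS, 4.0)
        assert np.all(np.abs(freqs[np.argmax(spec, axis=1)] - 5.0) < 0.3)

    def test_zero_vector_gives_zero_matrix(self):
        spec = power_spectrum(np.zeros(2000), FS, 4.0, 2.0)
        assert spec.shape[0] == 7
        assert np.all(spec == 0)

    def test_nonnegative(self, nsr_segment):
        spec = power_spectrum(nsr_segment.samples, FS, 4.0, 2.0)
        assert np.all(spec >= 0)
        assert spec.shape == (59, 251)

    def test_parseval_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        spec = power_spectrum(x, FS, 4.0, 2.0)
        w = hann(500, sym=False)
        for k in range(spec.shape[0]):
            frame = x[250 * k : 250 * k + 500] * w
            energy = float(np.sum(frame**2))
            assert abs(spec[k].sum() - energy) / energy < 1e-6

    def test_short_signal_zero_padded_to_one_frame(self):
        spec = power_spectrum(np.ones(100), FS, 4.0, 2.0)
        assert spec.shape[0] == 1


class TestFilterbank:
    def test_single_filter_peaks_at_center(self):
        cfg = FeatureConfig(n_filters=1, f_lo_hz=2.0, f_hi_hz=2.5)
        bank = build_filterbank(cfg, FS, 251)
        freqs = spectrum_bin_freqs(FS, 4.0)
        assert abs(freqs[np.argmax(bank[0].weights)] - 2.0) <= freqs[1]

    def test_weights_nonnegative_peak_one(self):
        bank = build_filterbank(FeatureConfig(), FS, 251)
        assert len(bank) == 32
        for f in bank:
            assert np.all(f.weights >= 0)
            assert f.weights.max() == pytest.approx(1.0)

    def test_centers_log_spaced(self):
        bank = build_filterbank(FeatureConfig(), FS, 251)
        centers = np.array([f.center_freq_hz for f in bank])
        ratios = centers[1:] / centers[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_bandwidth_grows_with_w(self):
        """-3 dB width of the order-4 Gammatone grows monotonically in w."""
        widths = []
        for w in (0.2, 0.4, 0.8, 1.6):
            weights = _gammatone_weights(5.0, w, 4, FS, 4097)
            widths.append(int(np.sum(weights >= 1 / np.sqrt(2))))
        assert widths == sorted(widths)
        assert widths[0] < widths[-1]

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            build_filterbank(FeatureConfig(f_hi_hz=100.0), FS, 251)


class TestApplyFilterbank:
    def test_indicator_filter_selects_bin(self):
        from pulseaf.features import GammatoneFilter

        w = np.zeros(251)
        w[20] = 1.0
        bank = [GammatoneFilter(5.0, 1.0, 4, w)]
        spec = power_spectrum(tone(5.0), FS, 4.0, 2.0)
        out = apply_filterbank(spec, bank)
        np.testing.assert_allclose(out[:, 0], spec[:, 20])

    def test_power_scaling_is_quadratic(self):
        bank = build_filterbank(FeatureConfig(), FS, 251)
        s1 = apply_filterbank(power_spectrum(tone(3.0), FS, 4.0, 2.0), bank)
        s2 = apply_filterbank(power_spectrum(tone(3.0, amp=2.0), FS, 4.0, 2.0), bank)
        np.testing.assert_allclose(s2, 4 * s1, rtol=1e-9)

    def test_tone_at_filter_center_maximizes_that_band(self):
        cfg = FeatureConfig()
        bank = build_filterbank(cfg, FS, 251)
        k = 20
        spec = power_spectrum(tone(bank[k].center_freq_hz, n=4000), FS, 4.0, 2.0)
        bands = apply_filterbank(spec, bank)
        assert np.all(np.argmax(bands, axis=1) == k)

    def test_bin_mismatch_rejected(self):
        bank = build_filterbank(FeatureConfig(), FS, 251)
        with pytest.raises(ValueError):
            apply_filterbank(np.zeros((3, 100)), bank)


class TestPowerNormalize:
    def test_constant_matrix_becomes_ones(self):
        np.testing.assert_allclose(power_normalize(np.full((4, 3), 7.0)), np.ones((4, 3)))

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        U = rng.random((5, 4))
        np.testing.assert_allclose(power_normalize(137.0 * U), power_normalize(U))

    def test_global_mean_is_one(self):
        rng = np.random.default_rng(2)
        out = power_normalize(rng.random((6, 8)))
        assert np.mean(out) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_passthrough(self):
        np.testing.assert_array_equal(power_normalize(np.zeros((2, 2))), np.zeros((2, 2)))


class TestPowerLaw:
    def test_examples(self):
        assert power_law(np.array([1.0]), 0.3)[0] == 1.0
        assert power_law(np.array([4.0]), 0.5)[0] == pytest.approx(2.0)
        assert power_law(np.array([0.0]), 0.5)[0] == 0.0

    def test_compression(self):
        theta = 1 / 15
        assert power_law(np.array([3.0]), theta)[0] < 3.0
        assert power_law(np.array([0.2]), theta)[0] > 0.2

    @pytest.mark.parametrize("theta", [0.0, 1.0, -0.5, 2.0])
    def test_theta_outside_unit_interval_rejected(self, theta):
        with pytest.raises(ValueError):
            power_law(np.ones((2, 2)), theta)


class TestTimeDomainFeatures:
    def periodic_record(self, ibi=0.8, n_beats=40, amp=1.0):
        fs = 125.0
        n = int(n_beats * ibi * fs)
        t = np.arange(n) / fs
        x = np.zeros(n)
        for k in range(n_beats):
            x += amp * np.exp(-0.5 * ((t - k * ibi) / 0.05) ** 2)
        return PPGRecord(x, fs_hz=fs)

    def test_perfectly_periodic_train_has_zero_variability(self):
        f = time_domain_features(self.periodic_record())
        ibi_mean, ibi_sd, rmssd, frac50, entropy, amp_cv = f
        assert ibi_mean == pytest.approx(0.8, abs=0.02)
        assert ibi_sd < 0.005
        assert rmssd < 0.01
        assert frac50 == 0.0
        assert entropy == 0.0
        assert amp_cv < 0.01

    def test_af_rmssd_at_least_3x_nsr_at_matched_mean_ibi(self):
        """The interval-irregularity signature: AF's RMSSD dwarfs NSR's
        when mean heart rate is matched (noiseless, >= 200 beats)."""
        af = noiseless(AF_PRESET, mean_ibi_s=0.8, amp_cv=0.0)
        nsr = noiseless(NSR_PRESET, amp_cv=0.0)
        r_af = time_domain_features(generate_record(af, 180, 125, seed=1))[2]
        r_nsr = time_domain_features(generate_record(nsr, 180, 125, seed=2))[2]
        assert r_af >= 3 * r_nsr

    def test_too_few_peaks_is_missing_feature_error(self):
        with pytest.raises(MissingFeatureError):
            time_domain_features(PPGRecord(np.ones(1000), fs_hz=125))


@pytest.fixture(scope="module")
def small_cfgs():
    return (
        EmdConfig(),
        EnsembleConfig(n_realizations=2, seed=7),
        FeatureConfig(),
    )


@pytest.fixture(scope="module")
def segment():
    rec = generate_record(NSR_PRESET, 70, 125, seed=21)
    return preprocess_record(rec, SegmentConfig(n_points=7500))


class TestExtractCepncc:

    def test_scale_invariance(self, segment, small_cfgs):
        emd_cfg, ens_cfg, feat_cfg = small_cfgs
        a = extract_cepncc(segment, emd_cfg, ens_cfg, feat_cfg)
        scaled = segment.with_samples(3.7 * segment.samples)
        b = extract_cepncc(scaled, emd_cfg, ens_cfg, feat_cfg)
        np.testing.assert_allclose(b.values, a.values, rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(b.time_features, a.time_features, rtol=1e-6)

    def test_deterministic_given_seed(self, segment, small_cfgs):
        a = extract_cepncc(segment, *small_cfgs)
        b = extract_cepncc(segment, *small_cfgs)
        np.testing.assert_array_equal(a.values, b.values)

    def test_dimensions_depend_only_on_config(self, small_cfgs):
        emd_cfg, ens_cfg, feat_cfg = small_cfgs
        shapes = set()
        for preset, seed in ((AF_PRESET, 1), (NSR_PRESET, 2)):
            rec = generate_record(preset, 70, 125, seed=seed)
            seg = preprocess_record(rec, SegmentConfig(n_points=7500))
            fm = extract_cepncc(seg, emd_cfg, ens_cfg, feat_cfg)
            shapes.add(fm.values.shape)
        assert shapes == {(29, 32)}

    def test_af_nsr_separability(self, small_cfgs):
        """Between-class distance of feature matrices exceeds within-class
        distance for the two rhythm presets."""
        emd_cfg, ens_cfg, feat_cfg = small_cfgs
        mats = {"AF": [], "NSR": []}
        for label, preset in (("AF", AF_PRESET), ("NSR", NSR_PRESET)):
            for seed in range(4):
                rec = generate_record(preset, 70, 125, seed=100 + seed)
                seg = preprocess_record(rec, SegmentConfig(n_points=7500))
                ens = dataclasses.replace(ens_cfg, seed=seed)
                fm = extract_cepncc(seg, emd_cfg, ens, feat_cfg)
                mats[label].append(
                    np.concatenate([fm.values.ravel(), fm.time_features])
                )
        within, between = [], []
        for la, xs in mats.items():
            for i in range(len(xs)):
                for j in range(i + 1, len(xs)):
                    within.append(np.linalg.norm(xs[i] - xs[j]))
        for xa in mats["AF"]:
            for xn in mats["NSR"]:
                between.append(np.linalg.norm(xa - xn))
        assert np.mean(between) > np.mean(within)

    def test_csv_round_trip(self, segment, small_cfgs, tmp_path):
        fm = extract_cepncc(segment, *small_cfgs)
        path = tmp_path / "fm.csv"
        write_feature_csv(fm, str(path))
        back = read_feature_csv(str(path))
        np.testing.assert_array_equal(back.values, fm.values)
        np.testing.assert_array_equal(back.time_features, fm.time_features)
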
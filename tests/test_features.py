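import numpy as np
import pytest

from eegaffect.features import (
    EstimationError,
    FeatureConfig,
    FeatureMatrix,
    WaveletFilterPair,
    extract_matrix,
    extract_trial,
    feature_names,
    hurst_many,
    hurst_rs,
    statistical_features,
    wpd_decompose,
    wpd_features,
)
from eegaffect.synthetic import FBMSpec, generate_fbm


class TestStatisticalFeatures:
    def test_hand_worked_example(self):
        # x=(1..5): mean 3, V = (4+1+0+1+4)/6 with the n+1 denominator
        sf = statistical_features([1, 2, 3, 4, 5])
        assert sf.mean == pytest.approx(3.0)
        assert sf.variance == pytest.approx(10.0 / 6.0)
        assert sf.std == pytest.approx(np.sqrt(10.0 / 6.0))
        assert sf.minimum == 1 and sf.maximum == 5 and sf.median == 3

    def test_conventional_denominator_switch(self):
        sf = statistical_features([1, 2, 3, 4, 5], variance_denominator="n-1")
        assert sf.variance == pytest.approx(2.5)

    def test_symmetric_series_has_zero_skewness(self):
        x = np.concatenate([np.arange(10), -np.arange(10)])
        assert statistical_features(x).skewness == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_degenerate_rule(self):
        sf = statistical_features(np.full(16, 3.3))
        assert sf.variance == 0 and sf.skewness == 0 and sf.kurtosis == 0
        assert sf.degenerate
        assert sf.minimum == sf.maximum == sf.median == pytest.approx(3.3)

    @pytest.mark.parametrize("a,b", [(2.5, -1.0), (-3.0, 4.0)])
    def test_affine_equivariance(self, a, b):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(257)
        s0 = statistical_features(x)
        s1 = statistical_features(a * x + b)
        assert s1.mean == pytest.approx(a * s0.mean + b)
        assert s1.std == pytest.approx(abs(a) * s0.std)
        assert s1.skewness == pytest.approx(np.sign(a) * s0.skewness)
        assert s1.kurtosis == pytest.approx(s0.kurtosis)


def oracle_wpd(x, lo, hi, level):
    """Independent direct convolution + decimate cascade (periodic).

    y[m] = sum_k filt[k] x[(2m + L/2 - k) mod n]: circular convolution,
    downsampled by two, phase-aligned to half the filter length.
    """
    def analyze(data, filt):
        n = data.size
        L = len(filt)
        return np.array([
            sum(filt[k] * data[(2 * m + L // 2 - k) % n] for k in range(L))
            for m in range(n // 2)
        ])

    nodes = {"": np.asarray(x, float)}
    frontier = [""]
    for _ in range(level):
        nxt = []
        for path in frontier:
            nodes[path + "0"] = analyze(nodes[path], lo)
            nodes[path + "1"] = analyze(nodes[path], hi)
            nxt += [path + "0", path + "1"]
        frontier = nxt
    return nodes


class TestWPD:
    def test_haar_annihilates_constants(self):
        tree = wpd_decompose(np.full(64, 2.0), "haar", 2)
        for path in ("1", "01", "11"):
            assert np.allclose(tree.nodes[path], 0.0)

    def test_haar_level1_is_average_difference_cascade(self):
        x = np.array([1.0, 3.0, 2.0, 6.0])
        tree = wpd_decompose(x, "haar", 1)
        np.testing.assert_allclose(tree.nodes["0"], [4 / np.sqrt(2), 8 / np.sqrt(2)])
        np.testing.assert_allclose(tree.nodes["1"], [-2 / np.sqrt(2), -4 / np.sqrt(2)])

    def test_parseval_energy_conservation(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(512)
        tree = wpd_decompose(x, "db4", 2)
        energy = sum(float(np.sum(c**2)) for c in tree.terminal_nodes())
        assert energy == pytest.approx(float(np.sum(x**2)), rel=1e-8)

    def test_matches_direct_convolution_oracle(self):
        import pywt

        rng = np.random.default_rng(7)
        x = rng.standard_normal(64)
        w = pywt.Wavelet("db4")
        tree = wpd_decompose(x, "db4", 2)
        oracle = oracle_wpd(x, np.asarray(w.dec_lo), np.asarray(w.dec_hi), 2)
        for path in ("00", "01", "10", "11"):
            np.testing.assert_allclose(tree.nodes[path], oracle[path], atol=1e-10)

    def test_twenty_values_with_stable_names(self):
        tree = wpd_decompose(np.random.default_rng(0).standard_normal(256), "db4", 2)
        vals = wpd_features(tree)
        assert vals.shape == (20,)
        names = [n for n in feature_names(4) if n.startswith("wpd")]
        assert len(names) == 20 and names[2] == "wpd_n0_power"

    def test_all_zero_input_gives_all_zero_features(self):
        tree = wpd_decompose(np.zeros(128), "db4", 2)
        np.testing.assert_array_equal(wpd_features(tree), np.zeros(20))

    def test_sinusoid_lands_in_matching_subband(self):
        # 20 Hz at 128 Hz sampling: second frequency-ordered node (16-32 Hz)
        t = np.arange(2048) / 128.0
        tree = wpd_decompose(np.sin(2 * np.pi * 20 * t), "db4", 2)
        powers = wpd_features(tree)[2::5]
        assert powers.argmax() == 1

    def test_too_short_series_raises(self):
        with pytest.raises(EstimationError, match="level"):
            wpd_decompose(np.ones(4), "db4", 3)

    def test_quadrature_mirror_relation_of_family_filters(self):
        # g(k) = +-(-1)^k h(L-1-k): the QMF relation holds up to the usual
        # global sign ambiguity of the detail filter
        pair = WaveletFilterPair.from_family("db4")
        L = pair.lowpass.size
        expected = np.array([(-1) ** k * pair.lowpass[L - 1 - k] for k in range(L)])
        err_plus = np.abs(pair.highpass - expected).max()
        err_minus = np.abs(pair.highpass + expected).max()
        assert min(err_plus, err_minus) < 1e-12


class TestHurst:
    def test_white_noise_near_half(self):
        ests = [hurst_rs(np.random.default_rng(s).standard_normal(8192)).H
                for s in range(20)]
        assert 0.45 <= np.median(ests) <= 0.60

    def test_fbm_increments_recover_h(self):
        for h in (0.3, 0.8):
            ests = []
            for s in range(10):
                inc = np.diff(generate_fbm(FBMSpec(h, 8193, seed=s)))
                ests.append(hurst_rs(inc).H)
            assert np.median(ests) == pytest.approx(h, abs=0.1)

    def test_persistent_series_scores_higher_than_noise(self):
        from scipy.signal import lfilter

        diffs = []
        for s in range(30):
            rng = np.random.default_rng(s)
            e = rng.standard_normal(4096)
            ar = lfilter([1.0], [1.0, -0.9], e)
            diffs.append(hurst_rs(ar).H - hurst_rs(e).H)
        assert np.mean(diffs) > 0.05

    def test_short_series_raises(self):
        with pytest.raises(EstimationError):
            hurst_rs(np.arange(12.0), min_window=8)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(4)
        rows = rng.standard_normal((3, 1024))
        hv = hurst_many(rows)
        for i in range(3):
            assert hv[i] == pytest.approx(hurst_rs(rows[i]).H, abs=1e-12)


class TestAssembly:
    def test_sixty_eight_named_columns(self, small_dataset):
        vec = extract_trial(small_dataset[0].signals[0],
                            FeatureConfig())
        names = feature_names(small_dataset[0].n_channels)
        assert names[:8] == [f"stat_{s}" for s in
                             ("mean", "variance", "std", "skewness", "kurtosis",
                              "minimum", "maximum", "median")]
        assert vec.size == 8 + 20 + small_dataset[0].n_channels
        assert len(feature_names(40)) == 68
        assert len([n for n in feature_names(40) if n.startswith("hurst")]) == 40

    def test_all_zero_trial_degenerate_fill(self):
        vec = extract_trial(np.zeros((4, 256)))
        np.testing.assert_array_equal(vec[:28], np.zeros(28))
        np.testing.assert_array_equal(vec[28:], np.full(4, 0.5))

    def test_matrix_shape_and_determinism(self, small_dataset):
        fm = extract_matrix(small_dataset[:1])
        assert fm.values.shape == (20, 8 + 20 + 8)
        fm2 = extract_matrix(small_dataset[:1])
        np.testing.assert_array_equal(fm.values, fm2.values)

    def test_matrix_round_trips_through_csv(self, small_dataset, tmp_path):
        fm = extract_matrix(small_dataset[:1])
        fm.to_csv(tmp_path / "f.csv")
        back = FeatureMatrix.from_csv(tmp_path / "f.csv")
        np.testing.assert_allclose(back.values, fm.values)
        assert back.column_names == fm.column_names

    def test_eeg_only_switch_limits_hurst_block(self, canonical_subject):
        cfg = FeatureConfig(eeg_only=True)
        vec = extract_trial(canonical_subject.signals[0], cfg)
        assert vec.size == 8 + 20 + 32
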
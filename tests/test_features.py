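"""Filter banks, cepstral front-ends, activation features, deltas."""

import numpy as np
import pytest
import scipy.fft

import birdnmf as b
from birdnmf import features as ft


def _spec_from_matrix(V, sample_rate=22050):
    F = V.shape[0]
    freqs = np.linspace(0, sample_rate / 2, F)
    return b.Spectrogram(V, freqs, 0.01, 0.02, sample_rate)


@pytest.fixture(scope="module")
def bump_dictionary_specs():
    """Spectrograms synthesized from 8 planted Gaussian spectral bumps."""
    V, W0, H0 = b.planted_factorization(64, 8, 600, noise_level=0.02, seed=21)
    specs = [_spec_from_matrix(V[:, i : i + 200]) for i in range(0, 600, 200)]
    return specs, W0


class TestMelFilterbank:
    def test_shape_and_positivity(self):
        bank = b.mel_filterbank(40, 512, 22050)
        assert bank.filters.shape == (40, 257)
        assert np.all(bank.filters.sum(axis=1) > 0)

    def test_filters_unimodal(self):
        bank = b.mel_filterbank(40, 512, 22050)
        for f in bank.filters:
            active = np.flatnonzero(f)
            segment = f[active[0] : active[-1] + 1]
            peak = int(np.argmax(segment))
            assert np.all(np.diff(segment[: peak + 1]) >= 0)
            assert np.all(np.diff(segment[peak:]) <= 0)

    def test_center_frequencies_increasing(self):
        bank = b.mel_filterbank(40, 512, 22050)
        centers = bank.freqs[bank.filters.argmax(axis=1)]
        assert np.all(np.diff(centers) > 0)

    def test_too_many_filters_for_resolution(self):
        with pytest.raises(ValueError, match="filter"):
            b.mel_filterbank(300, 128, 22050)


class TestLearnNmfFilterbank:
    def test_recovers_planted_bumps(self, bump_dictionary_specs):
        specs, W0 = bump_dictionary_specs
        bank = b.learn_nmf_filterbank(specs, K=8, seed=3)
        learned_peaks = np.sort(bank.filters.argmax(axis=1))
        true_peaks = np.sort(W0.argmax(axis=0))
        assert np.mean(np.abs(learned_peaks - true_peaks)) <= 2

    def test_row_count_normalization_and_ordering(self, bump_dictionary_specs):
        specs, _ = bump_dictionary_specs
        bank = b.learn_nmf_filterbank(specs, K=8, seed=3)
        assert bank.filters.shape[0] == 8
        assert np.allclose(bank.filters.sum(axis=1), 1.0)
        assert np.all(np.diff(bank.filters.argmax(axis=1)) >= 0)

    def test_deterministic(self, bump_dictionary_specs):
        specs, _ = bump_dictionary_specs
        b1 = b.learn_nmf_filterbank(specs, K=4, seed=9)
        b2 = b.learn_nmf_filterbank(specs, K=4, seed=9)
        assert np.array_equal(b1.filters, b2.filters)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            b.learn_nmf_filterbank([], K=4, seed=0)

    def test_filters_concentrate_in_active_band(self, small_recordings):
        """The learned bank allocates filters where vocal energy lives:
        at least 80% of filters peak inside the 1-10.5 kHz band."""
        specs = [r.spec for r in small_recordings[:8]]
        bank = b.learn_nmf_filterbank(specs, K=10, max_iter=100, seed=4)
        peak_freqs = bank.freqs[bank.filters.argmax(axis=1)]
        in_band = (peak_freqs > 1000.0) & (peak_freqs < 10500.0)
        assert in_band.mean() >= 0.8


class TestCepstralFeatures:
    def test_thirteen_columns(self, small_recordings):
        bank = b.mel_filterbank(40, 512, 22050)
        feats = b.cepstral_features(small_recordings[0].spec, bank)
        assert feats.n_dims == 13
        assert feats.layout[-1] == "logE"

    def test_identical_frames_identical_rows(self):
        col = np.linspace(0.1, 1.0, 40)
        spec = _spec_from_matrix(np.tile(col[:, None], (1, 5)))
        bank = b.mel_filterbank(10, 78, 22050)
        feats = b.cepstral_features(spec, bank, n_ceps=6)
        assert np.allclose(feats.X, feats.X[0][None, :])

    def test_amplitude_scaling_moves_only_log_energy(self):
        rng = np.random.default_rng(2)
        V = rng.random((257, 7)) + 0.05
        bank = b.mel_filterbank(40, 512, 22050)
        f1 = b.cepstral_features(_spec_from_matrix(V), bank)
        f2 = b.cepstral_features(_spec_from_matrix(2.0 * V), bank)
        # log-DCT pushes a global gain into the discarded C0 coefficient
        assert np.allclose(f2.X[:, :12], f1.X[:, :12], atol=1e-9)
        assert np.allclose(f2.X[:, 12] - f1.X[:, 12], np.log(4.0), atol=1e-9)

    def test_silent_frames_stay_finite(self):
        spec = _spec_from_matrix(np.zeros((257, 4)))
        bank = b.mel_filterbank(40, 512, 22050)
        feats = b.cepstral_features(spec, bank)
        assert np.all(np.isfinite(feats.X))

    def test_dct_is_orthonormal(self):
        rng = np.random.default_rng(3)
        x = rng.random(40)
        coeffs = scipy.fft.dct(x, type=2, norm="ortho")
        assert np.allclose(
            scipy.fft.idct(coeffs, type=2, norm="ortho"), x, atol=1e-9
        )


class TestLearnClassSbvs:
    def test_column_count_for_twelve_classes(self):
        rng = np.random.default_rng(5)
        per_class = {
            f"sp{i}": [_spec_from_matrix(rng.random((30, 20)) + 0.01)]
            for i in range(12)
        }
        model = b.learn_class_sbvs(per_class, K=4, n_restarts=2, max_iter=20, seed=1)
        assert model.W_bs.shape == (30, 48)
        assert model.class_block("sp3") == slice(12, 16)

    def test_disjoint_supports_recovered(self):
        rng = np.random.default_rng(6)
        F, T = 40, 300
        lowV = np.zeros((F, T))
        lowV[2:14] = rng.random((12, T)) * (rng.random(T) + 0.1)
        highV = np.zeros((F, T))
        highV[26:38] = rng.random((12, T)) * (rng.random(T) + 0.1)
        model = b.learn_class_sbvs(
            {"low": [_spec_from_matrix(lowV)], "high": [_spec_from_matrix(highV)]},
            K=4, seed=2,
        )
        for label, band in (("low", slice(2, 14)), ("high", slice(26, 38))):
            block = model.W_bs[:, model.class_block(label)]
            mass = block[band].sum(axis=0) / np.maximum(block.sum(axis=0), 1e-12)
            assert np.all(mass >= 0.9)

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        per_class = {
            "a": [_spec_from_matrix(rng.random((20, 30)))],
            "z": [_spec_from_matrix(rng.random((20, 30)))],
        }
        m1 = b.learn_class_sbvs(per_class, K=3, n_restarts=2, max_iter=30, seed=4)
        m2 = b.learn_class_sbvs(per_class, K=3, n_restarts=2, max_iter=30, seed=4)
        assert np.array_equal(m1.W_bs, m2.W_bs)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no training frames"):
            b.learn_class_sbvs({"empty": []}, K=2, seed=0)


class TestHccFeatures:
    def test_fourteen_columns_default(self):
        feats = ft.hcc_from_activations(np.random.default_rng(8).random((16, 9)))
        assert feats.n_dims == 14
        assert feats.layout[-1] == "gnmf"

    def test_gnmf_is_one_based_argmax(self):
        H = np.array([[0.1, 0.0], [3.2, 0.0], [0.5, 0.0]])
        feats = ft.hcc_from_activations(H, n_ceps=2, with_gnmf=True)
        assert feats.X[0, -1] == 2.0  # unique max at 1-based position 2
        assert feats.X[1, -1] == 1.0  # all-zero column: first-index tie-break

    def test_gnmf_points_into_generating_class_block(self):
        rng = np.random.default_rng(9)
        F, K = 40, 4
        per_class = {}
        bases = {}
        for i, lo in enumerate((2, 22)):
            W = np.zeros((F, K))
            for k in range(K):
                W[lo + 4 * k : lo + 4 * k + 4, k] = rng.random(4) + 0.5
            bases[f"c{i}"] = W
            per_class[f"c{i}"] = [_spec_from_matrix(W @ (rng.random((K, 150)) + 0.1))]
        model = b.learn_class_sbvs(per_class, K=K, seed=3)
        # fresh spectrogram drawn from class c1's basis only
        V_test = bases["c1"] @ (rng.random((K, 60)) + 0.1)
        feats = b.hcc_features(_spec_from_matrix(V_test), model, n_ceps=7, seed=11)
        blk = model.class_block("c1")
        gnmf = feats.X[:, -1].astype(int) - 1
        frac_in_block = np.mean((gnmf >= blk.start) & (gnmf < blk.stop))
        assert frac_in_block > 0.5

    def test_gnmf_values_integral_in_range(self):
        rng = np.random.default_rng(10)
        H = rng.random((16, 25))
        feats = ft.hcc_from_activations(H)
        g = feats.X[:, -1]
        assert np.array_equal(g, np.round(g))
        assert g.min() >= 1 and g.max() <= 16


class TestDeltasAndConcat:
    def test_delta_doubles_columns(self):
        feats = b.ShortTimeFeatures(np.random.default_rng(0).random((10, 13)),
                                    [f"c{i}" for i in range(13)])
        out = b.append_deltas(feats)
        assert out.n_dims == 26
        assert out.layout[13] == "d_c0"

    def test_constant_features_zero_delta(self):
        feats = b.ShortTimeFeatures(np.ones((8, 3)), ["a", "b", "c"])
        assert np.allclose(b.append_deltas(feats).X[:, 3:], 0.0)

    def test_linear_ramp_delta_equals_slope(self):
        a = 0.7
        t = np.arange(12, dtype=float)
        feats = b.ShortTimeFeatures((a * t)[:, None], ["ramp"])
        deltas = b.append_deltas(feats, window=2).X[:, 1]
        assert np.allclose(deltas[2:-2], a, atol=1e-12)

    def test_concat_dimensions_and_order(self):
        rng = np.random.default_rng(1)
        mfcc = b.ShortTimeFeatures(rng.random((6, 13)),
                                   [f"c{i}" for i in range(13)])
        hcc = b.ShortTimeFeatures(rng.random((6, 14)),
                                  [f"h{i}" for i in range(14)])
        out = b.concat_features(mfcc, hcc)
        assert out.n_dims == 27
        assert out.layout[:13] == mfcc.layout
        assert np.array_equal(out.X[:, :13], mfcc.X)

    def test_concat_with_empty_is_identity(self):
        rng = np.random.default_rng(2)
        feats = b.ShortTimeFeatures(rng.random((4, 5)), list("abcde"))
        empty = b.ShortTimeFeatures(np.zeros((4, 0)), [])
        out = b.concat_features(feats, empty)
        assert np.array_equal(out.X, feats.X)
        assert out.layout == feats.layout

    def test_concat_frame_mismatch_rejected(self):
        f1 = b.ShortTimeFeatures(np.zeros((3, 2)), ["a", "b"])
        f2 = b.ShortTimeFeatures(np.zeros((4, 2)), ["c", "d"])
        with pytest.raises(ValueError, match="frame counts"):
            b.concat_features(f1, f2)
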
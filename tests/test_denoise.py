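"""Thresholding, noise-scale estimation, depth selection and the pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import wpdenoise as w
from wpdenoise.denoise import _grow_to_best_level, effective_level_cap
from wpdenoise.errors import DegenerateInputError, ParameterError


def exhaustive_best_level(signal, wavelet, config):
    """Oracle: decompose to the cap, scan all level max-entropies."""
    cap = effective_level_cap(len(signal), wavelet.filter_length, config.level_cap)
    if cap == 1:
        return 1
    tree = w.wp_decompose(signal, wavelet, cap, config.boundary_mode)
    maxent = {L: tree.max_entropy(L) for L in range(1, cap + 1)}
    for L in range(1, cap):
        if maxent[L] < maxent[L + 1]:
            return L
    return cap


class TestSoftThreshold:
    @pytest.mark.parametrize("x,thr,expected", [(5, 2, 3), (-1, 2, 0), (-5, 2, -3),
                                                (0.5, 0.5, 0), (2, 0, 2)])
    def test_shrinkage(self, x, thr, expected):
        assert w.soft_threshold([x], thr)[0] == pytest.approx(expected)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ParameterError):
            w.soft_threshold([1.0], -0.1)
        with pytest.raises(ParameterError):
            w.hard_threshold([1.0], -0.1)

    @given(x=st.floats(-1e6, 1e6), y=st.floats(-1e6, 1e6), t=st.floats(0, 1e3))
    def test_nonexpansive(self, x, y, t):
        sx, sy = w.soft_threshold([x], t)[0], w.soft_threshold([y], t)[0]
        assert abs(sx) <= abs(x) + 1e-12
        assert abs(sx - sy) <= abs(x - y) + 1e-9

    def test_hard_keeps_or_kills(self):
        np.testing.assert_allclose(w.hard_threshold([5, -1, -5], 2), [5, 0, -5])


class TestThresholdTree:
    def test_zero_threshold_is_identity(self, random_signal):
        tree = w.wp_decompose(random_signal, w.wavelet_filters("db4"), 3)
        out = w.threshold_tree(tree, 0.0)
        for a, b in zip(tree.leaves(), out.leaves()):
            np.testing.assert_array_equal(a.coeffs, b.coeffs)

    def test_huge_threshold_zeroes_reconstruction(self, random_signal):
        tree = w.wp_decompose(random_signal, w.wavelet_filters("db4"), 3)
        big = 1 + max(np.max(np.abs(n.coeffs)) for n in tree.leaves())
        out = w.wp_reconstruct(w.threshold_tree(tree, big))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_matches_elementwise_oracle(self, random_signal):
        tree = w.wp_decompose(random_signal, w.wavelet_filters("db4"), 3)
        out = w.threshold_tree(tree, 1.0)
        for node in tree.leaves():
            expect = np.array(
                [np.sign(c) * max(abs(c) - 1.0, 0.0) for c in node.coeffs]
            )
            np.testing.assert_allclose(out.node(3, node.index).coeffs, expect,
                                       atol=1e-14)

    def test_exempt_approximation_leaf(self, random_signal):
        tree = w.wp_decompose(random_signal, w.wavelet_filters("db4"), 3)
        cfg = w.DenoiseConfig(exempt_approximation=True)
        out = w.threshold_tree(tree, 1e9, cfg)
        np.testing.assert_array_equal(out.node(3, 0).coeffs, tree.node(3, 0).coeffs)
        np.testing.assert_allclose(out.node(3, 1).coeffs, 0.0)


class TestNoiseSigma:
    def test_zero_signal_gives_zero(self):
        sig = w.AudioSignal(np.zeros(1024), 8000)
        tree = w.wp_decompose(sig, w.wavelet_filters("db4"), 1)
        assert w.estimate_noise_sigma(tree) == 0.0

    def test_scales_linearly_with_signal(self, random_signal):
        spec = w.wavelet_filters("db4")
        t1 = w.wp_decompose(random_signal, spec, 2)
        t2 = w.wp_decompose(random_signal.replace_samples(2 * random_signal.samples),
                            spec, 2)
        assert w.estimate_noise_sigma(t2) == pytest.approx(
            2 * w.estimate_noise_sigma(t1), rel=1e-12)

    def test_recovers_unit_variance_white_noise(self):
        # orthonormal filtering preserves white-noise variance
        spec = w.wavelet_filters("dmey")
        est = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(32768)
            tree = w.wp_decompose(w.AudioSignal(x, 8000), spec, 1)
            est.append(w.estimate_noise_sigma(tree))
        assert np.mean(est) == pytest.approx(1.0, rel=0.05)


class TestBestLevel:
    def test_cap_binds(self, white_fixture):
        sig = white_fixture.annotated.audio
        cfg = w.DenoiseConfig(level_cap=1)
        assert w.best_level(sig, w.wavelet_filters("db4"), cfg) == 1

    @pytest.mark.parametrize("strength,color,seed", [
        (50.0, "white", 0), (100.0, "white", 5), (200.0, "pink", 2),
        (25.0, "brown", 3),
    ])
    def test_matches_exhaustive_oracle_on_tone_fixtures(self, strength, color, seed):
        fx = w.noisy_tone_fixture(strength, seed, color)
        cfg = w.DenoiseConfig()
        spec = w.wavelet_filters("dmey")
        assert w.best_level(fx.annotated.audio, spec, cfg) == \
            exhaustive_best_level(fx.annotated.audio, spec, cfg)

    def test_matches_oracle_on_pure_gaussian(self):
        spec = w.wavelet_filters("db8")
        cfg = w.DenoiseConfig(level_cap=6)
        for seed in range(5):
            x = 0.2 * np.random.default_rng(seed).standard_normal(4096)
            sig = w.AudioSignal(x, 8000)
            assert w.best_level(sig, spec, cfg) == exhaustive_best_level(sig, spec, cfg)

    def test_signal_shorter_than_filter_rejected(self):
        sig = w.AudioSignal(np.ones(32), 8000)
        with pytest.raises(DegenerateInputError):
            w.best_level(sig, w.wavelet_filters("dmey"), w.DenoiseConfig())

    def test_grow_reuses_same_answer(self, white_fixture):
        sig = white_fixture.annotated.audio
        cfg = w.DenoiseConfig()
        spec = w.wavelet_filters("dmey")
        level, tree = _grow_to_best_level(sig, spec, cfg)
        assert level == w.best_level(sig, spec, cfg)
        assert tree.max_level >= level


class TestDenoise:
    def test_zero_in_zero_out(self):
        sig = w.AudioSignal(np.zeros(4096), 8000)
        out = w.denoise(sig)
        assert len(out) == 4096 and out.sample_rate == 8000
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_reduces_pure_white_noise_variance(self):
        cfg = w.DenoiseConfig()
        for seed in range(5):
            x = 0.2 * np.random.default_rng(seed).standard_normal(8192)
            out = w.denoise(w.AudioSignal(x, 8000), cfg)
            assert out.samples.var() < x.var()

    def test_preserves_clean_tone(self):
        tone = w.stepped_tone(w.ToneSpec((440.0, 880.0), 0.25, 0.5, 8000))
        out = w.denoise(tone)
        assert w.pearson_correlation(tone.samples, out.samples) >= 0.99

    def test_improves_noisy_tone_fixture(self, white_fixture):
        rec = white_fixture.annotated
        out = w.denoise(rec.audio)
        assert w.snnr(rec, out.samples) > w.snnr(rec)
        assert w.success_ratio(rec.extract("noise"),
                               rec.extract("noise", out.samples)) > 0


class TestSelectWavelet:
    def test_single_candidate(self, white_fixture):
        name, scores = w.select_wavelet(white_fixture.annotated.audio, ["db6"])
        assert name == "db6" and len(scores) == 1

    def test_scores_bounded_and_argmax_matches_reloop(self):
        fx = w.noisy_tone_fixture(50.0, seed=11)
        sig = fx.annotated.audio
        candidates = ["db2", "db6", "db10", "dmey"]
        name, scores = w.select_wavelet(sig, candidates)
        assert all(-1.0 <= s <= 1.0 for s in scores)
        redone = [
            w.pearson_correlation(
                sig.samples,
                w.denoise(sig, w.DenoiseConfig(wavelet_name=c)).samples,
            )
            for c in candidates
        ]
        assert name == candidates[int(np.argmax(redone))]
        np.testing.assert_allclose(scores, redone, atol=1e-12)

    def test_constant_signal_rejected(self):
        sig = w.AudioSignal(np.full(4096, 0.25), 8000)
        with pytest.raises(DegenerateInputError):
            w.select_wavelet(sig, ["db4"])

    def test_empty_candidates_rejected(self, random_signal):
        with pytest.raises(ParameterError):
            w.select_wavelet(random_signal, [])


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"threshold_multiplier": 0.0},
        {"threshold_multiplier": -1.0},
        {"level_cap": 0},
        {"threshold_mode": "medium"},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ParameterError):
            w.DenoiseConfig(**kw)
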
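"""Analysis operations against exact hand-built and closed-form oracles."""

import numpy as np
import pytest

from dendsnn import (ClampSpec, Network, NetworkConfig, SimulationConfig,
                     class_structure_score, delta_rate, energy_and_rate_metrics,
                     fit_linear_decoder, msd, reconstruction_quality,
                     rsa_matrix, run_mismatch_experiment, uncertainty_sweep)
from dendsnn.experiments import _linear_fits
from dendsnn.network import TraceRecord


def _trace(v_soma, v_apical=None, spikes=None, v_mem=None):
    """Hand-built single-layer trace; arrays shaped (steps, batch, n)."""
    v_soma = np.asarray(v_soma, dtype=np.float32)
    if v_apical is None:
        v_apical = np.zeros_like(v_soma)
    if spikes is None:
        spikes = np.zeros_like(v_soma)
    if v_mem is None:
        v_mem = np.zeros((v_soma.shape[0], v_soma.shape[1], 2), np.float32)
    z = np.zeros_like(v_soma)
    return TraceRecord([v_soma], [np.asarray(v_apical, np.float32)], [z],
                       [np.asarray(spikes, np.float32)], [z], v_mem, {})


class TestRateRepresentation:
    def test_extreme_and_fractional_rates(self):
        spikes = np.zeros((50, 1, 3), np.float32)
        spikes[:, 0, 0] = 1.0            # every step
        spikes[:3, 0, 2] = 1.0           # 3 spikes in 50 steps
        tr = _trace(np.zeros((50, 1, 3)), spikes=spikes)
        rates = tr.spike_rate(0)
        assert rates[0, 0] == 1.0
        assert rates[0, 1] == 0.0
        assert np.isclose(rates[0, 2], 0.06)

    def test_empty_window_rejected(self):
        tr = _trace(np.zeros((10, 1, 2)))
        with pytest.raises(ValueError):
            tr.spike_rate(0, (5, 5))


class TestLinearDecoder:
    def test_recovers_known_map_vs_least_squares(self, rng):
        # noiseless linear data: gradient training matches lstsq closely
        w_true = rng.normal(size=(12, 6))
        rates = rng.uniform(size=(80, 6))
        images = rates @ w_true.T + 0.3
        dec = fit_linear_decoder(rates, images, epochs=4000, lr=1e-2,
                                 batch_size=None, seed=0)
        x = np.hstack([rates, np.ones((80, 1))])
        beta, *_ = np.linalg.lstsq(x, images, rcond=None)
        pred_lstsq = x @ beta
        pred_dec = dec.predict(rates)
        rel = (np.linalg.norm(pred_dec - pred_lstsq)
               / np.linalg.norm(pred_lstsq))
        assert rel < 1e-3

    def test_zero_rates_predict_intercept(self, rng):
        rates = np.zeros((40, 5))
        images = np.full((40, 8), 0.6)
        dec = fit_linear_decoder(rates, images, epochs=2000, lr=1e-2,
                                 batch_size=None, seed=0)
        assert np.allclose(dec.predict(np.zeros(5)), dec.intercept)
        assert np.allclose(dec.intercept, 0.6, atol=1e-3)

    def test_loss_curve_decreases(self, rng):
        rates = rng.uniform(size=(60, 10))
        images = rates @ rng.normal(size=(16, 10)).T
        dec = fit_linear_decoder(rates, images, epochs=20, seed=0)
        assert dec.loss_curve[-1] < dec.loss_curve[0]

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_decoder(np.zeros((4, 2)), np.zeros((5, 8)))


class TestRsa:
    def test_hand_cosine(self):
        normal = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
        clamped = np.array([[1.0, 0.0, 1.0], [0.0, 0.0, 2.0]])
        mat = rsa_matrix(normal, clamped)
        # u=(1,0,1) vs v=(1,1,0): 1/(sqrt2*sqrt2) = 0.5
        assert np.isclose(mat[0, 0], 0.5)
        assert np.isclose(mat[1, 1], 2 / (2 * np.sqrt(2)))

    def test_identical_and_orthogonal(self):
        reps = np.eye(3)
        mat = rsa_matrix(reps, reps)
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat[~np.eye(3, dtype=bool)], 0.0)

    def test_scale_invariance(self, rng):
        a = np.abs(rng.uniform(size=(4, 6))) + 0.1
        b = np.abs(rng.uniform(size=(4, 6))) + 0.1
        scale = np.diag(rng.uniform(1, 5, size=4))
        assert np.allclose(rsa_matrix(a, scale @ b), rsa_matrix(a, b))

    def test_zero_norm_marked_missing(self):
        normal = np.array([[1.0, 0.0], [0.0, 0.0]])
        mat = rsa_matrix(normal, normal)
        assert np.isnan(mat[1, 1]) and np.isnan(mat[0, 1])
        assert not np.isnan(mat[0, 0])


class TestClassStructure:
    def test_identity_matrix(self):
        score = class_structure_score(np.eye(5))
        assert score["same_mean"] == 1.0
        assert score["diff_mean"] == 0.0
        assert score["p_value"] < 0.05

    def test_constant_matrix_no_structure(self):
        score = class_structure_score(np.full((5, 5), 0.4))
        assert np.isclose(score["same_mean"], score["diff_mean"])
        assert score["p_value"] >= 0.05

    def test_permuted_labels_destroy_structure(self, rng):
        mat = 0.2 + 0.6 * np.eye(8) + rng.normal(0, 0.02, (8, 8))
        structured = class_structure_score(mat)
        perm = rng.permutation(8)
        shuffled = class_structure_score(mat[perm][:, rng.permutation(8)])
        assert structured["p_value"] < 0.01
        gap = structured["same_mean"] - structured["diff_mean"]
        shuffled_gap = shuffled["same_mean"] - shuffled["diff_mean"]
        assert shuffled_gap < gap / 2


class TestMsd:
    def test_identical_traces_zero(self):
        tr = _trace(np.random.default_rng(0).normal(size=(8, 2, 3)))
        assert np.all(msd(tr, tr, 0, "soma", (2, 6)) == 0.0)

    def test_constant_offset_recovered_exactly(self):
        base = np.random.default_rng(1).normal(size=(8, 1, 4)).astype(np.float32)
        tr_a = _trace(base)
        tr_b = _trace(base - 0.25)
        out = msd(tr_a, tr_b, 0, "soma", (2, 6))
        assert np.allclose(out, 0.25, atol=1e-6)

    def test_matches_brute_force_average(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 10, 3, 5)).astype(np.float32)
        tr_a, tr_b = _trace(a), _trace(b)
        lo, hi = 3, 8
        brute = np.mean([a[t] - b[t] for t in range(lo, hi)], axis=0)
        assert np.allclose(msd(tr_a, tr_b, 0, "soma", (lo, hi)),
                           brute, atol=1e-6)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 6, 1, 4)).astype(np.float32)
        tr_a, tr_b = _trace(a), _trace(b)
        assert np.allclose(msd(tr_a, tr_b, 0, "apical", (1, 5)),
                           -msd(tr_b, tr_a, 0, "apical", (1, 5)))

    def test_window_mismatch_rejected(self):
        tr = _trace(np.zeros((6, 1, 2)))
        with pytest.raises(ValueError):
            msd(tr, tr, 0, "soma", (2, 9))


class TestMismatchExperiment:
    def test_uninformative_clamp_gives_exact_null(self, tiny_glyphs):
        cfg = NetworkConfig(layer_sizes=(12, 8, 8),
                            sim=SimulationConfig(T=8), seed=4)
        net = Network(cfg)
        res = run_mismatch_experiment(net, tiny_glyphs, n_pairs=6,
                                      clamp_strength=0.0, seed=0)
        for layer in range(3):
            assert np.all(res.msd_apical[layer] == 0.0)
            assert np.all(res.msd_soma[layer] == 0.0)
            assert np.all(res.delta_r[layer] == 0.0)

    def test_sweep_zero_strength_point_is_zero(self, tiny_glyphs):
        cfg = NetworkConfig(layer_sizes=(12, 8, 8),
                            sim=SimulationConfig(T=8), seed=4)
        net = Network(cfg)
        sweep = uncertainty_sweep(net, tiny_glyphs, strengths=(1.0, 0.0),
                                  n_pairs=4, seed=0)
        assert sweep["mean_abs_msd"]["soma"][-1] == 0.0
        assert sweep["mean_abs_msd"]["apical"][-1] == 0.0
        assert sweep["mean_abs_msd"]["soma"][0] > 0.0

    def test_invalid_pair_count(self, tiny_glyphs, tiny_network):
        with pytest.raises(ValueError):
            run_mismatch_experiment(tiny_network, tiny_glyphs, n_pairs=0)


class TestStabilityFits:
    def test_constructed_linear_neuron(self):
        offsets = np.array([-0.2, -0.1, 0.0, 0.1, 0.2])
        rates = np.stack([0.1 + 0.3 * offsets,          # perfect slope 0.3
                          np.full(5, 0.4)]).T           # constant neuron
        slopes, intercepts, r2 = _linear_fits(offsets, rates)
        assert np.isclose(slopes[0], 0.3)
        assert np.isclose(intercepts[0], 0.1)
        assert np.isclose(r2[0], 1.0)
        assert slopes[1] == 0.0 and r2[1] == 1.0

    def test_noisy_neuron_has_low_r2(self, rng):
        offsets = np.linspace(-1, 1, 9)
        rates = rng.uniform(size=(9, 1))
        _, _, r2 = _linear_fits(offsets, rates)
        assert r2[0] < 0.9


class TestMetrics:
    def test_hand_built_energy_and_rate(self):
        v_soma = np.array([[[0.0, 1.0]], [[2.0, -1.0]]], np.float32)
        v_apical = np.array([[[1.0, 1.0]], [[0.0, 1.0]]], np.float32)
        spikes = np.array([[[1.0, 0.0]], [[1.0, 1.0]]], np.float32)
        tr = _trace(v_soma, v_apical=v_apical, spikes=spikes)
        m = energy_and_rate_metrics(tr)
        assert np.isclose(m["energy_per_layer"][0], (1 + 0 + 2 + 2) / 4)
        assert np.isclose(m["rate_per_layer"][0], 0.75)

    def test_matched_compartments_zero_energy(self):
        v = np.random.default_rng(0).normal(size=(4, 2, 3)).astype(np.float32)
        tr = _trace(v, v_apical=v)
        assert energy_and_rate_metrics(tr)["energy_per_layer"][0] == 0.0


class TestReconstructionQuality:
    def test_distance_zero_to_own_mean(self):
        means = np.random.default_rng(0).uniform(size=(3, 28, 28))
        d = reconstruction_quality(means[1].reshape(-1), means)
        assert np.isclose(d[1], 0.0, atol=1e-12)

    def test_scale_invariance(self, rng):
        means = rng.uniform(size=(3, 28, 28))
        img = rng.uniform(size=784)
        assert np.allclose(reconstruction_quality(img, means),
                           reconstruction_quality(5 * img, means))

    def test_zero_image_missing(self):
        means = np.random.default_rng(0).uniform(size=(2, 4, 4))
        assert np.all(np.isnan(reconstruction_quality(np.zeros(16), means)))


class TestDeltaRate:
    def test_sign_and_magnitude(self):
        spikes_a = np.zeros((10, 1, 2), np.float32)
        spikes_a[:4, 0, 0] = 1.0
        spikes_b = np.zeros((10, 1, 2), np.float32)
        spikes_b[:2, 0, 0] = 1.0
        tr_a = _trace(np.zeros((10, 1, 2)), spikes=spikes_a)
        tr_b = _trace(np.zeros((10, 1, 2)), spikes=spikes_b)
        out = delta_rate(tr_a, tr_b, 0, (0, 10))
        assert np.isclose(out[0, 0], 0.2)
        assert out[0, 1] == 0.0
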
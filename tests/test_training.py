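"""Objectives and training loop: hand-computed losses and update contracts."""

import numpy as np
import pytest

from dendsnn import (FpttAuxState, Network, NetworkConfig, SimulationConfig,
                     TrainingConfig, classification_loss, energy_loss,
                     fptt_regularizer, make_glyph_dataset, train)
from dendsnn.autodiff import Tensor
from dendsnn.dynamics import LayerState
from dendsnn.optim import AdamW
from dendsnn.training import train_step


def _state(v_apical, v_soma):
    va, vs = np.atleast_2d(v_apical), np.atleast_2d(v_soma)
    z = np.zeros_like(vs)
    return LayerState(Tensor(vs), Tensor(va), Tensor(z), Tensor(z), Tensor(z))


class TestEnergyLoss:
    def test_identical_compartments_zero(self):
        st = _state([0.3, -0.7], [0.3, -0.7])
        assert energy_loss([st], 2).item() == 0.0

    def test_two_neuron_hand_value(self):
        # neurons (Va, Vs) = (0.5, -0.5) and (1, 1): (1 + 0) / 2 = 0.5
        st = _state([0.5, 1.0], [-0.5, 1.0])
        assert np.isclose(energy_loss([st], 2).item(), 0.5)

    def test_positive_homogeneity(self, rng):
        va, vs = rng.normal(size=5), rng.normal(size=5)
        base = energy_loss([_state(va, vs)], 5).item()
        scaled = energy_loss([_state(3 * va, 3 * vs)], 5).item()
        assert np.isclose(scaled, 3 * base)

    def test_permutation_invariance(self, rng):
        va, vs = rng.normal(size=6), rng.normal(size=6)
        perm = rng.permutation(6)
        assert np.isclose(energy_loss([_state(va, vs)], 6).item(),
                          energy_loss([_state(va[perm], vs[perm])], 6).item())


class TestClassificationLoss:
    def test_uniform_potentials_ln10(self):
        loss = classification_loss(Tensor(np.zeros((1, 10))), np.array([4]))
        assert np.isclose(loss.item(), np.log(10))

    def test_peaked_potentials_near_zero(self):
        v = np.full((1, 10), -10.0)
        v[0, 2] = 10.0
        assert classification_loss(Tensor(v), np.array([2])).item() < 1e-6

    def test_monotone_in_true_class_potential(self):
        losses = []
        for target in np.linspace(-1, 3, 9):
            v = np.zeros((1, 10))
            v[0, 0] = target
            losses.append(classification_loss(Tensor(v), np.array([0])).item())
        assert np.all(np.diff(losses) < 0)


class TestFpttRegularizer:
    def _params(self, value):
        return {"p": Tensor(np.array([value]), requires_grad=True)}

    def test_zero_at_anchor(self):
        p = self._params(0.7)
        aux = FpttAuxState(p)
        assert fptt_regularizer(p, aux, 1.0).item() == 0.0

    def test_quadratic_hand_value(self):
        # deviation 0.2, alpha 1, zero correction: 0.5 * 0.04 = 0.02
        p = self._params(0.0)
        aux = FpttAuxState(p)
        p["p"].data[0] = 0.2
        assert np.isclose(fptt_regularizer(p, aux, 1.0).item(), 0.02)

    def test_quadratic_scaling(self):
        p = self._params(0.0)
        aux = FpttAuxState(p)
        p["p"].data[0] = 0.1
        small = fptt_regularizer(p, aux, 1.0).item()
        p["p"].data[0] = 0.2
        assert np.isclose(fptt_regularizer(p, aux, 1.0).item(), 4 * small)

    def test_shape_mismatch_rejected(self):
        p = self._params(0.0)
        aux = FpttAuxState(p)
        p["p"] = Tensor(np.zeros(3), requires_grad=True)
        with pytest.raises(ValueError):
            fptt_regularizer(p, aux, 1.0)

    def test_post_update_tracks_parameters(self):
        p = self._params(0.0)
        aux = FpttAuxState(p)
        for value in (0.1, 0.15, 0.2):
            p["p"].data[0] = value
            aux.post_update(p, 0.1)
        # the running average follows the drifting parameter
        assert abs(aux.running_avg["p"][0] - 0.2) < 0.2


class TestEnergyGradientPath:
    def _unrolled_energy(self, alpha_e):
        cfg = NetworkConfig(input_size=16, layer_sizes=(8, 6, 6),
                            output_size=4, sim=SimulationConfig(T=6), seed=0)
        model = Network(cfg)
        rng = np.random.default_rng(0)
        states, out = model.init_state(3, rng)
        drive = model.input_drive(rng.uniform(size=(3, 16)))
        for _ in range(6):
            states, out = model.step(states, out, drive)
        energy = energy_loss(states, cfg.total_neurons) * alpha_e
        for t in model.params.values():
            t.grad = None
        energy.backward()
        return model

    def test_energy_term_shapes_feedback_weights(self):
        model = self._unrolled_energy(alpha_e=5e-2)
        g = model.params["w_fb_1"].grad
        assert g is not None and np.abs(g).max() > 0

    def test_energy_term_silent_in_control(self):
        model = self._unrolled_energy(alpha_e=0.0)
        for name in ("w_fb_0", "w_fb_1", "w_fb_2"):
            g = model.params[name].grad
            assert g is None or np.abs(g).max() == 0


class TestTrainStep:
    def _setup(self, mode="fptt", lr=1e-2, dropout=0.0):
        net_cfg = NetworkConfig(input_size=64, layer_sizes=(16, 8, 8),
                                output_size=4, sim=SimulationConfig(T=8),
                                seed=1)
        model = Network(net_cfg)
        cfg = TrainingConfig(alpha_e=5e-2, mode=mode, lr=lr, dropout=dropout,
                             seed=0, k_steps=8)
        opt = AdamW(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
        aux = FpttAuxState(model.params) if mode == "fptt" else None
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(8, 64))
        y = rng.integers(0, 4, size=8)
        return model, cfg, opt, aux, x, y

    def test_repeated_steps_reduce_loss_on_frozen_batch(self):
        model, cfg, opt, aux, x, y = self._setup()
        drop_rng = np.random.default_rng(1)
        losses = []
        for _ in range(50):
            states, out = model.init_state(8, np.random.default_rng(42))
            states, out, parts = train_step(model, x, y, states, out, 8,
                                            cfg, aux, opt, drop_rng)
            losses.append(parts["total"])
        assert losses[-1] < losses[0]

    def test_zero_lr_leaves_parameters_unchanged(self):
        model, cfg, opt, aux, x, y = self._setup(lr=0.0)
        opt.weight_decay = 0.0
        before = {k: p.data.copy() for k, p in model.params.items()}
        states, out = model.init_state(8, np.random.default_rng(0))
        train_step(model, x, y, states, out, 8, cfg, aux, opt,
                   np.random.default_rng(1))
        for k, p in model.params.items():
            assert np.array_equal(p.data, before[k])

    def test_time_constants_clipped_above_floor(self):
        model, cfg, opt, aux, x, y = self._setup(lr=0.5)
        for _ in range(5):
            states, out = model.init_state(8, np.random.default_rng(0))
            train_step(model, x, y, states, out, 8, cfg, aux, opt,
                       np.random.default_rng(1))
        dt = model.cfg.sim.dt
        for name, p in model.params.items():
            if name.startswith("tau"):
                assert p.data.min() >= 2 * dt


class TestTrainLoop:
    def _tiny(self, mode="fptt"):
        ds = make_glyph_dataset(n_train=40, n_test=20, seed=0)
        net_cfg = NetworkConfig(layer_sizes=(16, 8, 8),
                                sim=SimulationConfig(T=10), seed=1)
        cfg = TrainingConfig(alpha_e=5e-2, mode=mode, epochs=2, batch_size=8,
                             lr=1e-3, dropout=0.2, seed=3, metrics_subset=10)
        return ds, cfg, net_cfg

    def test_identical_seeds_identical_history(self):
        ds, cfg, net_cfg = self._tiny()
        _, h1 = train(ds, cfg, net_cfg)
        _, h2 = train(ds, cfg, net_cfg)
        assert h1 == h2

    def test_k_equals_t_single_update_matches_budget(self):
        # K = T gives exactly one fptt update per sequence
        ds, cfg, net_cfg = self._tiny()
        cfg_kt = TrainingConfig(alpha_e=cfg.alpha_e, mode="fptt",
                                epochs=1, batch_size=8, lr=cfg.lr,
                                dropout=0.0, seed=3, metrics_subset=10,
                                k_steps=net_cfg.sim.T)
        model, hist = train(ds, cfg_kt, net_cfg)
        assert len(hist) == 1  # runs to completion with the coarse schedule

    def test_history_records_metrics(self):
        ds, cfg, net_cfg = self._tiny(mode="bptt")
        _, hist = train(ds, cfg, net_cfg)
        assert len(hist) == cfg.epochs
        for rec in hist:
            assert 0 <= rec["test_error"] <= 1
            assert len(rec["energy_per_layer"]) == 3
            assert len(rec["rate_per_layer"]) == 3
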
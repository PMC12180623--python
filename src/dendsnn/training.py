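"""Objectives and training loops: energy loss, FPTT online updates, BPTT.

The total loss at an update step is

    L_t = L_clf,t + alpha_reg * L_reg,t + alpha_E * L_E,t

where ``L_clf`` is the negative log-likelihood of the label under the
log-softmax of the readout potentials, ``L_E`` is the network-mean absolute
voltage difference between the apical and somatic compartments (the
inter-compartmental energy proxy; ``alpha_E = 0`` defines the control
condition), and ``L_reg`` is the dynamic regulariser of Forward
Propagation Through Time (FPTT), a quadratic penalty anchoring the
parameters to a running average so that updates can be applied every K
grid steps while the sequence is still unrolling.  BPTT mode instead
applies one update per sequence with no dynamic regulariser.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, cross_entropy
from .dynamics import DivergenceError
from .network import Network, NetworkConfig
from .optim import AdamW

__all__ = [
    "TrainingConfig",
    "FpttAuxState",
    "energy_loss",
    "classification_loss",
    "fptt_regularizer",
    "train_step",
    "train",
    "evaluate",
    "select_matched_epoch",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimiser / loss settings.

    Defaults follow the full-scale digit setup: 10 epochs, lr 1e-3, weight
    decay 1e-4, alpha_E = 5e-2 (energy condition) or 0 (control),
    alpha_reg = 1, updates every K = 10 steps, dropout 0.4 on inter-layer
    spike vectors during training.
    """

    alpha_e: float = 5e-2
    alpha_reg: float = 1.0
    fptt_alpha: float = 0.1  # proximal strength of the dynamic regulariser
    k_steps: int = 10
    lr: float = 1e-3
    weight_decay: float = 1e-4
    dropout: float = 0.4
    epochs: int = 10
    batch_size: int = 128
    mode: str = "fptt"  # or "bptt"
    seed: int = 0
    energy_window_average: bool = False  # average L_E over the K-step window
    eval_steps: int | None = None  # defaults to sim.T
    metrics_subset: int = 200  # test samples for per-epoch energy/rate metrics

    def __post_init__(self):
        if self.mode not in ("fptt", "bptt"):
            raise ValueError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------- losses
def energy_loss(states: list, n_neurons: int) -> Tensor:
    """Mean |V_apical - V_soma| over every spiking neuron (batch-averaged).

    Zero iff the compartments agree everywhere; positively homogeneous in
    the voltages.
    """
    total = None
    batch = states[0].v_soma.shape[0] if hasattr(states[0].v_soma, "shape") else 1
    for st in states:
        diff = ad.absolute(st.v_apical - st.v_soma).sum()
        total = diff if total is None else total + diff
    return total * (1.0 / (n_neurons * batch))


def classification_loss(output_potentials, labels) -> Tensor:
    """NLL of the log-softmax readout potentials at the label(s)."""
    return cross_entropy(output_potentials, labels)


class FpttAuxState:
    """Running-average parameter copies and gradient-correction terms.

    For each trainable parameter W the FPTT regulariser keeps a running
    average ``W_bar`` (initialised to the initial parameters) and a
    gradient-snapshot accumulator ``lam`` (initialised to zero).  After
    each optimiser step: ``lam <- lam - alpha*(W - W_bar)`` and
    ``W_bar <- (W_bar + W)/2 - lam/(2*alpha)``, so the anchor trails the
    parameters with a correction that cancels the systematic pull of the
    quadratic term on the converged trajectory.
    """

    def __init__(self, params: dict[str, Tensor]):
        self.running_avg = {k: p.data.copy() for k, p in params.items()}
        self.lam = {k: np.zeros_like(p.data) for k, p in params.items()}

    def post_update(self, params: dict[str, Tensor], alpha: float) -> None:
        for k, p in params.items():
            sm, lm = self.running_avg[k], self.lam[k]
            lm -= alpha * (p.data - sm)
            self.running_avg[k] = 0.5 * (sm + p.data) - lm / (2.0 * alpha)


def fptt_regularizer(params: dict[str, Tensor], aux: FpttAuxState,
                     alpha: float) -> Tensor:
    """Dynamic proximal term: (alpha/2) sum ||W - W_bar||^2 - sum lam . W.

    ``alpha`` is the proximal strength of the online-learning algorithm
    (distinct from the weight the total loss puts on this term).  With the
    parameters at the running average and ``lam`` zero the penalty is
    zero; it is quadratic in the deviation from the anchor.
    """
    total = None
    for k, p in params.items():
        if p.data.shape != aux.running_avg[k].shape:
            raise ValueError(f"aux shape mismatch for {k}")
        term = ((p - aux.running_avg[k]) ** 2).sum() * (alpha / 2.0) \
            - (p * aux.lam[k]).sum()
        total = term if total is None else total + term
    return total


# ----------------------------------------------------------------- train loop
def _dropout_masks(cfg: NetworkConfig, p: float, batch: int,
                   rng: np.random.Generator) -> dict | None:
    if p <= 0:
        return None
    return {l: (rng.uniform(size=(batch, n)) >= p) / (1.0 - p)
            for l, n in enumerate(cfg.layer_sizes)}


def train_step(model: Network, images: np.ndarray, labels: np.ndarray,
               states: list, out, n_steps: int, cfg: TrainingConfig,
               aux: FpttAuxState | None, opt: AdamW,
               rng: np.random.Generator):
    """Unroll ``n_steps`` grid steps from the given state and apply one update.

    Computes the total loss on the state at the end of the unroll
    (classification on current readout potentials, energy on current
    voltages, FPTT regulariser on the parameters in fptt mode),
    backpropagates through the surrogate spike function, steps the
    optimiser, refreshes the FPTT aux state and clips time constants.
    Returns the detached ``(states, out, loss_components)``.
    """
    drive = model.input_drive(images) if images is not None else None
    batch = states[0].v_soma.shape[0]
    energy_acc = None
    for _ in range(n_steps):
        masks = _dropout_masks(model.cfg, cfg.dropout, batch, rng)
        states, out = model.step(states, out, drive, dropout_masks=masks)
        if cfg.energy_window_average and cfg.alpha_e:
            e = energy_loss(states, model.cfg.total_neurons)
            energy_acc = e if energy_acc is None else energy_acc + e

    clf = classification_loss(out.v_mem, labels)
    if cfg.energy_window_average and energy_acc is not None:
        energy = energy_acc * (1.0 / n_steps)
    else:
        energy = energy_loss(states, model.cfg.total_neurons)
    total = clf + cfg.alpha_e * energy
    if cfg.mode == "fptt":
        total = total + cfg.alpha_reg * fptt_regularizer(model.params, aux,
                                                         cfg.fptt_alpha)
    if not np.isfinite(total.data):
        raise DivergenceError("non-finite training loss")

    opt.zero_grad()
    total.backward()
    opt.step()
    if cfg.mode == "fptt":
        aux.post_update(model.params, cfg.fptt_alpha)
    model.clip_time_constants()

    losses = {"total": total.item(), "clf": clf.item(), "energy": energy.item()}
    return [s.detach() for s in states], out.detach(), losses


def evaluate(model: Network, images: np.ndarray, labels: np.ndarray,
             steps: int | None = None, seed: int = 0) -> float:
    """Test error (fraction misclassified, final-step readout argmax)."""
    preds = model.predict(images, steps=steps, seed=seed)
    return float(np.mean(preds != np.asarray(labels)))


def train(dataset, cfg: TrainingConfig, net_cfg: NetworkConfig,
          checkpoint_dir=None, verbose: bool = False):
    """Full training run; returns ``(model, history)``.

    ``dataset`` provides ``train_images/train_labels/test_images/
    test_labels``.  In fptt mode parameters update every ``k_steps`` of the
    T-step unroll of each mini-batch; in bptt mode once per sequence.
    ``history`` is one dict per epoch with the test error and per-layer
    energy / spike-rate metrics on a fixed test subset.  Fully
    deterministic given the config seeds.
    """
    from .experiments import energy_and_rate_metrics  # local: avoid cycle

    model = Network(net_cfg)
    opt = AdamW(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    aux = FpttAuxState(model.params) if cfg.mode == "fptt" else None
    master = np.random.default_rng(cfg.seed)
    shuffle_rng, state_rng, drop_rng = master.spawn(3)

    x_train = np.asarray(dataset.train_images).reshape(-1, net_cfg.input_size)
    y_train = np.asarray(dataset.train_labels)
    x_test = np.asarray(dataset.test_images).reshape(-1, net_cfg.input_size)
    y_test = np.asarray(dataset.test_labels)
    T = net_cfg.sim.T
    history = []
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(x_train))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            states, out = model.init_state(len(idx), state_rng)
            states = [s.detach() for s in states]
            done = 0
            if cfg.mode == "fptt":
                while done < T:
                    n = min(cfg.k_steps, T - done)
                    states, out, losses = train_step(
                        model, xb, yb, states, out, n, cfg, aux, opt, drop_rng)
                    done += n
            else:
                states, out, losses = train_step(
                    model, xb, yb, states, out, T, cfg, aux, opt, drop_rng)
            epoch_losses.append(losses)

        err = evaluate(model, x_test, y_test, steps=cfg.eval_steps, seed=cfg.seed)
        sub = x_test[:cfg.metrics_subset]
        trace = model.run_inference(sub, steps=T, seed=cfg.seed)
        metrics = energy_and_rate_metrics(trace)
        rec = {
            "epoch": epoch,
            "test_error": err,
            "loss_total": float(np.mean([l["total"] for l in epoch_losses])),
            "loss_clf": float(np.mean([l["clf"] for l in epoch_losses])),
            "loss_energy": float(np.mean([l["energy"] for l in epoch_losses])),
            "energy_per_layer": metrics["energy_per_layer"],
            "rate_per_layer": metrics["rate_per_layer"],
        }
        history.append(rec)
        if verbose:
            print(f"epoch {epoch}: test error {err:.3f}, "
                  f"energy {metrics['energy_per_layer']}, "
                  f"rate {metrics['rate_per_layer']}")
        if checkpoint_dir is not None:
            from .io import save_checkpoint
            from pathlib import Path
            path = Path(checkpoint_dir) / f"epoch_{epoch:03d}.h5"
            save_checkpoint(path, model, extra={"epoch": epoch, "test_error": err})
    return model, history


def select_matched_epoch(history: list, target_error: float) -> int:
    """Earliest epoch whose test error is closest to ``target_error``.

    Used to study a control model at matched accuracy with an energy model
    (pick the control checkpoint of the returned epoch).
    """
    errors = np.array([h["test_error"] for h in history])
    return int(np.argmin(np.abs(errors - target_error)))
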
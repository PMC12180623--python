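"""Three-layer two-compartment spiking network with top-down feedback.

The architecture is a fully connected hierarchy L1 -> L2 -> L3 of spiking
two-compartment neurons followed by a non-spiking readout layer (one leaky
integrator per class).  Feedforward spikes enter the somata of the next
layer; feedback spikes enter the apical tufts of the previous layer.  The
readout potentials are L2-normalised and projected through trainable
feedback weights into the apical tufts of L3, which is also the pathway by
which output *clamping* (fixing the readout potentials to a target vector
for a whole run, modelling top-down expectation) influences the network.

All inter-layer signals travel with one grid-step latency: the update at
step t consumes the spikes and readout potentials of step t-1, which breaks
the instantaneous feedforward/feedback loop deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .dynamics import (LayerState, OutputState, SimulationConfig,
                       step_adaptation, step_apical, step_output,
                       step_soma_and_spike, surrogate_spike)

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "ClampSpec",
    "StimulusSchedule",
    "TraceRecord",
    "Network",
    "encode_input",
    "feedback_projection",
    "apply_clamp",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the spiking hierarchy.

    Defaults mirror the full-scale digit-classification setup (spiking
    layers 600/500/500, ten readout units, 28x28 inputs); the test suite
    and examples use smaller layers with the same structure.
    """

    input_size: int = 784
    layer_sizes: tuple = (600, 500, 500)
    output_size: int = 10
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    gain: float = 1.0
    encoder: str = "current"  # or "bernoulli"
    output_feedback: bool = True  # readout -> L3 apical projection active

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)

    @property
    def total_neurons(self) -> int:
        """Total spiking neuron count (the energy-loss denominator N)."""
        return int(sum(self.layer_sizes))


@dataclass(frozen=True)
class ClampSpec:
    """Target vector for clamping the readout potentials.

    Exactly one of ``class_index``, ``vector`` or ``noise`` selects the base
    vector: a class clamp (+1 at the target class, -1 elsewhere), an
    explicit vector, or a seeded uniform draw from ``noise=(low, high)``.
    ``strength`` in [0, 1] interpolates toward the uniform (fully
    uncertain) vector: the reduction of the target's clamp mass is
    redistributed equally over the other classes.
    """

    class_index: int | None = None
    vector: tuple | None = None
    noise: tuple | None = None
    noise_seed: int = 0
    strength: float = 1.0


@dataclass(frozen=True)
class StimulusSchedule:
    """Window [stim_start, stim_end) during which input and clamp are active.

    Outside the window the network receives zero input and runs free
    (match/mismatch protocol: silence, stimulus + clamp, silence).
    """

    stim_start: int
    stim_end: int

    def validate(self, steps: int) -> None:
        if not (0 <= self.stim_start <= self.stim_end <= steps):
            raise ValueError(
                f"schedule [{self.stim_start}, {self.stim_end}) outside [0, {steps}]")

    def active(self, t: int) -> bool:
        return self.stim_start <= t < self.stim_end


@dataclass
class TraceRecord:
    """Time-indexed record of one inference run (float32, step-major).

    Per layer ``l``: ``v_soma[l]``, ``v_apical[l]``, ``eta[l]``,
    ``spikes[l]``, ``threshold[l]`` with shape ``(steps, batch, n_l)``;
    ``v_mem`` has shape ``(steps, batch, n_classes)``.
    """

    v_soma: list
    v_apical: list
    eta: list
    spikes: list
    threshold: list
    v_mem: np.ndarray
    metadata: dict

    @property
    def steps(self) -> int:
        return self.v_mem.shape[0]

    @property
    def batch(self) -> int:
        return self.v_mem.shape[1]

    def spike_rate(self, layer: int, window: tuple | None = None) -> np.ndarray:
        """Mean spikes per neuron per step over ``window`` -> (batch, n)."""
        lo, hi = (0, self.steps) if window is None else window
        if hi <= lo:
            raise ValueError("empty window")
        return self.spikes[layer][lo:hi].mean(axis=0)


def encode_input(image: np.ndarray, gain: float = 1.0,
                 input_size: int | None = None) -> np.ndarray:
    """Constant per-step input current proportional to pixel intensity.

    Flattens ``image`` to ``(batch, input_size)``; the same vector is
    injected through the first feedforward weight matrix at every step.
    Negative values are allowed (used by the stability sweep).
    """
    arr = np.asarray(image, dtype=np.float64)
    if input_size is not None:
        if arr.size % input_size:
            raise ValueError(f"input size {arr.size} not a multiple of "
                             f"{input_size} pixels")
        arr = arr.reshape(-1, input_size)
    elif arr.ndim <= 1 or arr.ndim > 2:
        # a single vector, or a batch of 2-D images: flatten per sample
        arr = arr.reshape(1, -1) if arr.ndim <= 1 else arr.reshape(arr.shape[0], -1)
    return gain * arr


def feedback_projection(output_potentials, w_fb_out):
    """Top-down current into L3 apical tufts.

    The readout potentials are L2-normalised per sample before being
    projected through the feedback weights; an all-zero vector yields zero
    current (no normalisation blow-up).
    """
    normed = ad.l2_normalize(output_potentials, axis=-1)
    return ad.matmul(normed, w_fb_out.T) if isinstance(normed, Tensor) \
        else normed @ np.asarray(w_fb_out.data if isinstance(w_fb_out, Tensor) else w_fb_out).T


def apply_clamp(spec: ClampSpec, output_size: int) -> np.ndarray:
    """Materialise a :class:`ClampSpec` into a fixed potential vector."""
    n_set = sum(x is not None for x in (spec.class_index, spec.vector, spec.noise))
    if n_set != 1:
        raise ValueError("exactly one of class_index, vector, noise must be set")
    if spec.class_index is not None:
        if not (0 <= spec.class_index < output_size):
            raise ValueError(f"class index {spec.class_index} out of range")
        base = -np.ones(output_size)
        base[spec.class_index] = 1.0
    elif spec.vector is not None:
        base = np.asarray(spec.vector, dtype=np.float64)
        if base.shape != (output_size,):
            raise ValueError("clamp vector has wrong size")
    else:
        low, high = spec.noise
        rng = np.random.default_rng(spec.noise_seed)
        base = rng.uniform(low, high, size=output_size)
    if not (0.0 <= spec.strength <= 1.0):
        raise ValueError("strength must lie in [0, 1]")
    # strength c: keep c of the pattern, spread the rest uniformly so the
    # total clamp mass is conserved and c=0 is fully uncertain (all equal)
    return spec.strength * base + (1.0 - spec.strength) * base.mean()


def _xavier(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_out, fan_in))


class Network:
    """The assembled model: parameters plus stepping / inference logic.

    Trainable parameters (all :class:`Tensor`): feedforward weights
    ``w_ff_l`` (post x pre), feedback weights ``w_fb_l`` (post x next-layer
    size), readout weights ``w_out``, per-neuron bias currents ``bias_l``
    (init 0), and per-neuron time constants ``tau_s_l`` / ``tau_a_l`` /
    ``tau_adp_l`` / ``tau_mem`` (ms), initialised as N(mean, 0.1) around
    15 / 15 / 20 / 5 ms.
    """

    TAU_INIT = {"tau_s": 15.0, "tau_a": 15.0, "tau_adp": 20.0, "tau_mem": 5.0}

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        sizes = list(cfg.layer_sizes)
        pres = [cfg.input_size] + sizes[:-1]
        nexts = sizes[1:] + [cfg.output_size]
        p: dict[str, Tensor] = {}
        for l, (n, pre, nxt) in enumerate(zip(sizes, pres, nexts)):
            p[f"w_ff_{l}"] = Tensor(_xavier(rng, n, pre), requires_grad=True)
            p[f"w_fb_{l}"] = Tensor(_xavier(rng, n, nxt), requires_grad=True)
            p[f"bias_{l}"] = Tensor(np.zeros(n), requires_grad=True)
            for kind in ("tau_s", "tau_a", "tau_adp"):
                p[f"{kind}_{l}"] = Tensor(
                    rng.normal(self.TAU_INIT[kind], 0.1, size=n), requires_grad=True)
        p["w_out"] = Tensor(_xavier(rng, cfg.output_size, sizes[-1]), requires_grad=True)
        p["tau_mem"] = Tensor(np.full(cfg.output_size, self.TAU_INIT["tau_mem"]),
                              requires_grad=True)
        self.params = p

    # ------------------------------------------------------------------ admin
    def parameters(self) -> dict:
        return self.params

    def clip_time_constants(self, lo: float | None = None, hi: float = 1000.0) -> None:
        """Clip all time constants into [lo, hi]; default lo = 2*dt."""
        if lo is None:
            lo = 2.0 * self.cfg.sim.dt
        for name, t in self.params.items():
            if name.startswith("tau"):
                np.clip(t.data, lo, hi, out=t.data)

    # ------------------------------------------------------------------ state
    def init_state(self, batch: int, rng: np.random.Generator):
        """Fresh state: v_soma ~ U[0,1), everything else at rest."""
        states = []
        for n in self.cfg.layer_sizes:
            states.append(LayerState(
                v_soma=Tensor(rng.uniform(0.0, 1.0, size=(batch, n))),
                v_apical=Tensor(np.zeros((batch, n))),
                eta=Tensor(np.zeros((batch, n))),
                spikes=Tensor(np.zeros((batch, n))),
                threshold=Tensor(np.full((batch, n), self.cfg.sim.b0)),
            ))
        out = OutputState(v_mem=Tensor(np.zeros((batch, self.cfg.output_size))))
        return states, out

    # ------------------------------------------------------------------- step
    def step(self, states: list, out: OutputState, in_drive,
             clamp_vec: np.ndarray | None = None,
             dropout_masks: dict | None = None):
        """Advance the whole network by one grid step.

        ``in_drive`` is the encoded input current for L1 (``(batch, n1)``
        already multiplied through ``w_ff_0``), or ``None`` for no input.
        ``clamp_vec`` fixes the readout potentials for this step.
        Consumes only previous-step spikes / readout potentials.
        """
        cfg, sim = self.cfg, self.cfg.sim
        p = self.params
        prev_spikes = [s.spikes for s in states]
        if dropout_masks:
            prev_spikes = [s * dropout_masks[l] if l in dropout_masks else s
                           for l, s in enumerate(prev_spikes)]
        top = len(states) - 1

        # top-down current into each layer's apical tuft
        if clamp_vec is not None:
            fb_src = np.broadcast_to(np.asarray(clamp_vec, dtype=np.float64),
                                     out.v_mem.shape)
        else:
            fb_src = out.v_mem
        if cfg.output_feedback or clamp_vec is not None:
            fb_top = feedback_projection(fb_src, p[f"w_fb_{top}"])
        else:
            fb_top = Tensor(np.zeros((out.v_mem.shape[0], cfg.layer_sizes[top])))

        new_states = []
        for l, st in enumerate(states):
            topdown = fb_top if l == top else ad.matmul(prev_spikes[l + 1], p[f"w_fb_{l}"].T)
            v_a = step_apical(st.v_apical, topdown, p[f"tau_a_{l}"], sim)
            if l == 0:
                ff = p[f"bias_{l}"] + (in_drive if in_drive is not None else 0.0)
            else:
                ff = ad.matmul(prev_spikes[l - 1], p[f"w_ff_{l}"].T) + p[f"bias_{l}"]
            v_s, spikes = step_soma_and_spike(st.v_soma, v_a, ff, st.threshold,
                                              p[f"tau_s_{l}"], sim)
            eta, thr = step_adaptation(st.eta, spikes, p[f"tau_adp_{l}"], sim)
            new_states.append(LayerState(v_s, v_a, eta, spikes, thr))

        if clamp_vec is not None:
            v_mem = Tensor(np.broadcast_to(np.asarray(clamp_vec, dtype=np.float64),
                                           out.v_mem.shape).copy())
        else:
            drive = ad.matmul(prev_spikes[top], p["w_out"].T)
            v_mem = step_output(out.v_mem, drive, p["tau_mem"], sim)
        return new_states, OutputState(v_mem, clamped=clamp_vec)

    def input_drive(self, images: np.ndarray | None,
                    rng: np.random.Generator | None = None):
        """Encoded input current into L1 (through ``w_ff_0``), or ``None``.

        With the default ``current`` encoder this is constant over the run;
        the ``bernoulli`` encoder resamples spikes each call (pass it the
        per-step rng).
        """
        if images is None:
            return None
        enc = encode_input(images, self.cfg.gain, self.cfg.input_size)
        if self.cfg.encoder == "bernoulli":
            if rng is None:
                raise ValueError("bernoulli encoder needs an rng")
            enc = (rng.uniform(size=enc.shape) < np.clip(enc, 0.0, 1.0)).astype(np.float64)
        return ad.matmul(Tensor(enc), self.params["w_ff_0"].T)

    # -------------------------------------------------------------- inference
    def run_inference(self, images: np.ndarray | None = None,
                      steps: int | None = None,
                      clamp: ClampSpec | np.ndarray | None = None,
                      schedule: StimulusSchedule | None = None,
                      seed: int = 0,
                      record: bool = True) -> TraceRecord:
        """Run the network for ``steps`` grid steps from a fresh state.

        The state is re-initialised (seeded) first, so repeated calls with
        identical arguments yield identical traces.  With ``clamp`` set the
        recorded readout potentials equal the clamp vector at every active
        step.  ``schedule`` restricts input and clamp to a stimulus window,
        with silence before and after.
        """
        cfg = self.cfg
        steps = cfg.sim.T if steps is None else int(steps)
        if steps < 1:
            raise ValueError("steps must be >= 1")
        if schedule is not None:
            schedule.validate(steps)
        clamp_vec = None
        if clamp is not None:
            clamp_vec = clamp if isinstance(clamp, np.ndarray) \
                else apply_clamp(clamp, cfg.output_size)
        if images is not None:
            batch = 1 if np.ndim(images) <= 2 and np.size(images) == cfg.input_size \
                else np.asarray(images).reshape(-1, cfg.input_size).shape[0]
        elif clamp_vec is not None and np.ndim(clamp_vec) == 2:
            batch = clamp_vec.shape[0]
        else:
            batch = 1

        rng = np.random.default_rng(seed)
        with ad.no_grad():
            states, out = self.init_state(batch, rng)
            drive_const = None
            if images is not None and cfg.encoder == "current":
                drive_const = self.input_drive(images)
            rec = _TraceBuilder(self, batch, steps) if record else None
            warned_zero = False
            for t in range(steps):
                active = schedule.active(t) if schedule is not None else True
                if images is None or not active:
                    drive = None
                elif cfg.encoder == "current":
                    drive = drive_const
                else:
                    drive = self.input_drive(images, rng)
                cv = clamp_vec if active else None
                if cv is None and not warned_zero:
                    norms = np.linalg.norm(out.v_mem.data, axis=-1)
                    if np.any(norms == 0.0):
                        logger.debug("zero-norm readout potentials at step %d: "
                                     "feedback current is zero", t)
                        warned_zero = True
                states, out = self.step(states, out, drive, cv)
                if rec is not None:
                    rec.append(t, states, out)
        meta = {"steps": steps, "batch": batch, "seed": seed,
                "clamp": None if clamp_vec is None else np.asarray(clamp_vec),
                "schedule": schedule}
        if rec is None:
            return TraceRecord([], [], [], [], [],
                               out.v_mem.data[None].astype(np.float32), meta)
        return rec.finish(meta)

    # ------------------------------------------------------------ prediction
    def predict(self, images: np.ndarray, steps: int | None = None,
                seed: int = 0, batch_size: int = 256) -> np.ndarray:
        """Predicted class per image: argmax of final-step readout potentials."""
        images = np.asarray(images).reshape(-1, self.cfg.input_size)
        preds = []
        for i in range(0, images.shape[0], batch_size):
            tr = self.run_inference(images[i:i + batch_size], steps=steps,
                                    seed=seed + i, record=False)
            preds.append(np.argmax(tr.v_mem[-1], axis=-1))
        return np.concatenate(preds)


class _TraceBuilder:
    def __init__(self, net: Network, batch: int, steps: int):
        cfg = net.cfg
        self.v_soma = [np.empty((steps, batch, n), np.float32) for n in cfg.layer_sizes]
        self.v_apical = [np.empty((steps, batch, n), np.float32) for n in cfg.layer_sizes]
        self.eta = [np.empty((steps, batch, n), np.float32) for n in cfg.layer_sizes]
        self.spikes = [np.empty((steps, batch, n), np.float32) for n in cfg.layer_sizes]
        self.threshold = [np.empty((steps, batch, n), np.float32) for n in cfg.layer_sizes]
        self.v_mem = np.empty((steps, batch, cfg.output_size), np.float32)

    def append(self, t: int, states: list, out: OutputState):
        for l, st in enumerate(states):
            self.v_soma[l][t] = st.v_soma.data
            self.v_apical[l][t] = st.v_apical.data
            self.eta[l][t] = st.eta.data
            self.spikes[l][t] = st.spikes.data
            self.threshold[l][t] = st.threshold.data
        self.v_mem[t] = out.v_mem.data

    def finish(self, meta: dict) -> TraceRecord:
        return TraceRecord(self.v_soma, self.v_apical, self.eta, self.spikes,
                           self.threshold, self.v_mem, meta)
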
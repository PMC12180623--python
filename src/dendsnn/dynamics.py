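"""Per-time-step dynamics of the two-compartment adaptive LIF neuron.

Each model neuron has an apical-tuft compartment integrating top-down spikes
and a somatic compartment integrating feedforward drive plus a bounded
function of the apical voltage.  Spiking follows the adaptive
leaky-integrate-and-fire (ALIF) rule: a spike is emitted when the somatic
voltage reaches an adaptive threshold ``b(t) = b0 + beta * eta(t)``, the
voltage is soft-reset by subtracting the threshold, and the adaptation
variable ``eta`` is incremented and decays with its own time constant.
Non-spiking leaky integrators form the readout layer.

All update functions operate either on plain ``ndarray`` state (inference)
or on :class:`~dendsnn.autodiff.Tensor` state (training), in which case the
spike nonlinearity uses a multi-Gaussian surrogate derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "SimulationConfig",
    "SurrogateConfig",
    "LayerState",
    "OutputState",
    "DivergenceError",
    "apical_drive",
    "decay_step",
    "multi_gaussian_kernel",
    "surrogate_spike",
    "step_apical",
    "step_soma_and_spike",
    "step_adaptation",
    "step_output",
]


class DivergenceError(RuntimeError):
    """Raised when a state variable becomes NaN/Inf during simulation."""


@dataclass(frozen=True)
class SurrogateConfig:
    """Multi-Gaussian surrogate-gradient kernel parameters.

    The backward sensitivity of the spike with respect to ``v - b`` is
    ``gamma * [(1+h) N(x; 0, sigma^2) - h N(x; sigma, (s*sigma)^2)
    - h N(x; -sigma, (s*sigma)^2)]`` — a centre bump with negative side
    lobes, which empirically trains deep spiking networks well.
    """

    h: float = 0.15
    s: float = 6.0
    sigma: float = 0.5
    gamma: float = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Integration-grid and threshold constants shared by all layers.

    dt is the Euler step in ms, T the number of grid steps per inference,
    b0 the baseline spike threshold and beta the adaptation scale (beta = 0
    recovers a plain non-adaptive LIF neuron).
    """

    dt: float = 0.5
    T: int = 50
    b0: float = 0.1
    beta: float = 1.8
    integration_scheme: str = "forward_euler"
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < 1:
            raise ValueError("T must be at least 1")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.integration_scheme not in ("forward_euler", "exponential_euler"):
            raise ValueError(f"unknown scheme {self.integration_scheme!r}")

    def with_steps(self, steps: int) -> "SimulationConfig":
        return replace(self, T=int(steps))


@dataclass
class LayerState:
    """Dynamical variables of one spiking layer at one grid step.

    Arrays (or Tensors) of shape ``(batch, n_neurons)``.  Invariants:
    spikes are binary, ``eta >= 0`` and ``threshold == b0 + beta * eta``.
    """

    v_soma: object
    v_apical: object
    eta: object
    spikes: object
    threshold: object

    def detach(self) -> "LayerState":
        return LayerState(*[x.detach() if isinstance(x, Tensor) else x
                            for x in (self.v_soma, self.v_apical, self.eta,
                                      self.spikes, self.threshold)])


@dataclass
class OutputState:
    """Readout-layer membrane potentials; ``clamped`` overrides integration."""

    v_mem: object
    clamped: object | None = None

    def detach(self) -> "OutputState":
        v = self.v_mem.detach() if isinstance(self.v_mem, Tensor) else self.v_mem
        return OutputState(v, self.clamped)


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def apical_drive(x):
    """Bounded influence of the apical voltage on the soma: 0.25*tanh(x/2).

    Odd and saturating at +-0.25, so however large the apical voltage grows
    its per-step contribution to the soma stays bounded.
    """
    return 0.25 * ad.tanh(x * 0.5 if isinstance(x, Tensor) else np.asarray(x) * 0.5)


def decay_step(value, tau, dt: float, scheme: str = "forward_euler"):
    """One passive-decay step of a leaky state variable.

    forward_euler: ``value * (1 - dt/tau)`` (requires ``tau > dt``);
    exponential_euler: ``value * exp(-dt/tau)`` (unconditionally stable).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau_min = float(np.min(_data(tau)))
    if scheme == "forward_euler":
        if tau_min <= dt:
            raise ValueError(f"forward Euler unstable: min(tau)={tau_min} <= dt={dt}")
        if isinstance(value, Tensor) or isinstance(tau, Tensor):
            return value * (1.0 - dt / ad.as_tensor(tau))
        return np.asarray(value) * (1.0 - dt / np.asarray(tau))
    if scheme == "exponential_euler":
        if tau_min <= 0:
            raise ValueError("tau must be positive")
        if isinstance(value, Tensor) or isinstance(tau, Tensor):
            return value * ad.exp(-dt / ad.as_tensor(tau))
        return np.asarray(value) * np.exp(-dt / np.asarray(tau))
    raise ValueError(f"unknown scheme {scheme!r}")


def multi_gaussian_kernel(x: np.ndarray, cfg: SurrogateConfig = SurrogateConfig()) -> np.ndarray:
    """Evaluate the multi-Gaussian pseudo-derivative at ``x = v - b``."""
    x = np.asarray(x, dtype=np.float64)

    def gauss(x, mu, sig):
        return np.exp(-0.5 * ((x - mu) / sig) ** 2) / (np.sqrt(2.0 * np.pi) * sig)

    k = ((1.0 + cfg.h) * gauss(x, 0.0, cfg.sigma)
         - cfg.h * gauss(x, cfg.sigma, cfg.s * cfg.sigma)
         - cfg.h * gauss(x, -cfg.sigma, cfg.s * cfg.sigma))
    return cfg.gamma * k


def surrogate_spike(v, b, surrogate: SurrogateConfig = SurrogateConfig()):
    """Spike emission: hard step forward, multi-Gaussian derivative backward.

    Returns 1 where ``v >= b`` and 0 elsewhere.  When ``v`` or ``b`` is a
    Tensor the returned Tensor back-propagates
    ``d spike / d(v-b) = multi_gaussian_kernel(v-b)``.
    """
    if isinstance(v, Tensor) or isinstance(b, Tensor):
        v = ad.as_tensor(v)
        b = ad.as_tensor(b)
        x = v.data - b.data
        out = (x >= 0.0).astype(np.float64)
        kern = multi_gaussian_kernel(x, surrogate)

        def vjp(g):
            gk = g * kern
            return (gk, -gk)

        return ad.custom_op(out, (v, b), vjp)
    x = np.asarray(v) - np.asarray(b)
    return (x >= 0.0).astype(np.float64)


def step_apical(v_apical, topdown_current, tau_apical, cfg: SimulationConfig):
    """Apical-compartment update: leaky decay plus top-down synaptic current.

    ``topdown_current`` is the already-weighted feedback input
    (``spikes_{l+1} @ W_fb.T``, or the projected normalised readout
    potentials for the top layer).
    """
    return decay_step(v_apical, tau_apical, cfg.dt, cfg.integration_scheme) + topdown_current


def step_soma_and_spike(v_soma, v_apical_new, ff_drive, threshold, tau_soma,
                        cfg: SimulationConfig, *, check_finite: bool = True):
    """Somatic update, spike emission and soft reset.

    ``ff_drive`` is the weighted feedforward input (including bias and, for
    the first layer, the encoded image current).  The pre-reset voltage is
    decayed soma + ff_drive + bounded apical drive; a spike is emitted where
    it reaches the threshold, and the threshold is subtracted (soft reset,
    keeping the supra-threshold excess).

    Returns ``(v_soma_new, spikes)``.
    """
    v_pre = (decay_step(v_soma, tau_soma, cfg.dt, cfg.integration_scheme)
             + ff_drive + apical_drive(v_apical_new))
    if check_finite and not np.all(np.isfinite(_data(v_pre))):
        raise DivergenceError("non-finite somatic voltage (diverging run)")
    spikes = surrogate_spike(v_pre, threshold, cfg.surrogate)
    v_new = v_pre - threshold * spikes
    return v_new, spikes


def step_adaptation(eta, spikes, tau_adp, cfg: SimulationConfig):
    """Adaptation update after this step's spikes.

    ``eta' = decay(eta) + spikes``; ``threshold' = b0 + beta * eta'``.
    Returns ``(eta_new, threshold_new)``.
    """
    eta_new = decay_step(eta, tau_adp, cfg.dt, cfg.integration_scheme) + spikes
    threshold_new = cfg.b0 + cfg.beta * eta_new
    return eta_new, threshold_new


def step_output(v_mem, drive, tau_mem, cfg: SimulationConfig):
    """Non-spiking readout integrator: leaky decay plus weighted input."""
    return decay_step(v_mem, tau_mem, cfg.dt, cfg.integration_scheme) + drive
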
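"""Canonical desk-scale benchmark protocol on the glyph task.

The full-scale study (600/500/500 neurons, 50-step inference, 60k training
images) is far beyond a single-CPU test budget, so the package defines one
frozen scaled-down protocol on the synthetic glyph task and uses it
everywhere (tests, acceptance script, examples): spiking layers
(128, 64, 64), 20 grid steps per inference, 2000/500 train/test glyphs,
and an optimiser schedule re-tuned once for the ~30x smaller update count
(batch 8, lr 3e-3, dropout 0.2, 10 epochs, window-averaged energy term).
The energy condition uses alpha_E = 5e-2 and the control alpha_E = 0, as
in the full-scale study.  See docs/methods.md for the rationale behind
each departure from the full-scale defaults.
"""

from __future__ import annotations

from .data import GlyphDataset, make_glyph_dataset
from .dynamics import SimulationConfig
from .network import Network, NetworkConfig
from .training import TrainingConfig, train

__all__ = [
    "BENCHMARK_LAYERS",
    "BENCHMARK_T",
    "benchmark_dataset",
    "benchmark_network_config",
    "benchmark_training_config",
    "train_benchmark_model",
]

BENCHMARK_LAYERS = (128, 64, 64)
BENCHMARK_T = 20
_BENCH_TRAIN = dict(lr=3e-3, batch_size=8, dropout=0.2, epochs=10,
                    energy_window_average=True, metrics_subset=100)


def benchmark_dataset(seed: int = 0, n_train: int = 2000,
                      n_test: int = 500) -> GlyphDataset:
    """The benchmark glyph dataset (2000 train / 500 test by default)."""
    return make_glyph_dataset(n_train=n_train, n_test=n_test, seed=seed)


def benchmark_network_config(seed: int = 1) -> NetworkConfig:
    return NetworkConfig(layer_sizes=BENCHMARK_LAYERS,
                         sim=SimulationConfig(T=BENCHMARK_T),
                         seed=seed, gain=1.0)


def benchmark_training_config(alpha_e: float = 5e-2, mode: str = "fptt",
                              seed: int = 1, epochs: int | None = None) -> TrainingConfig:
    kwargs = dict(_BENCH_TRAIN)
    if epochs is not None:
        kwargs["epochs"] = epochs
    return TrainingConfig(alpha_e=alpha_e, mode=mode, seed=seed, **kwargs)


def train_benchmark_model(alpha_e: float = 5e-2, mode: str = "fptt",
                          seed: int = 1, dataset: GlyphDataset | None = None,
                          epochs: int | None = None, verbose: bool = False):
    """Train one benchmark model; returns ``(model, history)``.

    ``alpha_e=5e-2`` gives the energy condition, ``alpha_e=0`` the control;
    ``mode`` selects FPTT (online, K-step) or BPTT (one update per
    sequence) training.
    """
    ds = dataset if dataset is not None else benchmark_dataset(seed=0)
    return train(ds, benchmark_training_config(alpha_e, mode, seed, epochs),
                 benchmark_network_config(seed), verbose=verbose)
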
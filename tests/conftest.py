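import numpy as np
import pytest

from dendsnn import (Network, NetworkConfig, SimulationConfig,
                     benchmark_dataset, make_glyph_dataset,
                     train_benchmark_model)


@pytest.fixture(scope="session")
def glyphs():
    """The benchmark glyph dataset (2000 train / 500 test, seed 0)."""
    return benchmark_dataset(seed=0)


@pytest.fixture(scope="session")
def tiny_glyphs():
    return make_glyph_dataset(n_train=60, n_test=30, seed=0)


@pytest.fixture(scope="session")
def tiny_network():
    """A small untrained network for fast structural tests."""
    cfg = NetworkConfig(input_size=784, layer_sizes=(24, 12, 12),
                        output_size=10, sim=SimulationConfig(T=10), seed=3)
    return Network(cfg)


@pytest.fixture(scope="session")
def trained_models(glyphs):
    """Energy and control models trained under the benchmark protocol.

    Trained once per session and shared by the experiment and acceptance
    tests (a few minutes of compute).
    """
    energy, hist_e = train_benchmark_model(alpha_e=5e-2, mode="fptt",
                                           seed=1, dataset=glyphs)
    control, hist_c = train_benchmark_model(alpha_e=0.0, mode="fptt",
                                            seed=1, dataset=glyphs)
    return {"energy": energy, "control": control,
            "history_energy": hist_e, "history_control": hist_c}


@pytest.fixture(scope="session")
def bptt_energy_model(glyphs):
    """An energy model trained with BPTT under the same budget."""
    model, hist = train_benchmark_model(alpha_e=5e-2, mode="bptt",
                                        seed=1, dataset=glyphs)
    return {"model": model, "history": hist}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
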
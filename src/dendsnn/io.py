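"""Checkpoint and trace archives.

A checkpoint is a single HDF5 file: one dataset per named parameter under
``/params``, with the network configuration serialised as JSON in the root
attributes, so a model can be rebuilt without any side information.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from .dynamics import SimulationConfig, SurrogateConfig
from .network import Network, NetworkConfig

__all__ = ["save_checkpoint", "load_checkpoint", "save_trace_csv"]


def _config_to_json(cfg: NetworkConfig) -> str:
    d = asdict(cfg)
    return json.dumps(d)


def _config_from_json(blob: str) -> NetworkConfig:
    d = json.loads(blob)
    sim = d.pop("sim")
    surrogate = SurrogateConfig(**sim.pop("surrogate"))
    d["sim"] = SimulationConfig(surrogate=surrogate, **sim)
    d["layer_sizes"] = tuple(d["layer_sizes"])
    return NetworkConfig(**d)


def save_checkpoint(path, model: Network, extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.attrs["network_config"] = _config_to_json(model.cfg)
        if extra:
            fh.attrs["extra"] = json.dumps(extra)
        grp = fh.create_group("params")
        for name, tensor in model.params.items():
            grp.create_dataset(name, data=tensor.data)


def load_checkpoint(path) -> Network:
    with h5py.File(path, "r") as fh:
        cfg = _config_from_json(fh.attrs["network_config"])
        model = Network(cfg)
        for name in model.params:
            model.params[name].data[...] = np.asarray(fh["params"][name])
    return model


def save_trace_csv(path, trace, layer_names=None) -> None:
    """Per-layer summary metrics of a trace as CSV (one row per layer)."""
    import pandas as pd

    from .experiments import energy_and_rate_metrics

    metrics = energy_and_rate_metrics(trace)
    n = len(metrics["energy_per_layer"])
    names = layer_names or [f"L{i + 1}" for i in range(n)]
    df = pd.DataFrame({"layer": names,
                       "mean_energy": metrics["energy_per_layer"],
                       "mean_rate": metrics["rate_per_layer"]})
    df.to_csv(path, index=False)
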
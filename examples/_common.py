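"""Shared helpers for the example scripts: train-or-load cached models."""

from pathlib import Path

from dendsnn import (benchmark_dataset, load_checkpoint, save_checkpoint,
                     train_benchmark_model)

CACHE = Path(__file__).resolve().parent.parent / "scratch" / "examples"


def get_dataset():
    return benchmark_dataset(seed=0)


def get_model(condition: str, dataset):
    """Benchmark model for 'energy', 'control' or 'bptt_energy' (cached)."""
    CACHE.mkdir(parents=True, exist_ok=True)
    path = CACHE / f"{condition}.h5"
    if path.exists():
        return load_checkpoint(path)
    alpha_e = 0.0 if condition == "control" else 5e-2
    mode = "bptt" if condition == "bptt_energy" else "fptt"
    print(f"training the {condition} model (about 1-2 minutes on one CPU)...")
    model, _ = train_benchmark_model(alpha_e=alpha_e, mode=mode, seed=1,
                                     dataset=dataset)
    save_checkpoint(path, model)
    return model
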
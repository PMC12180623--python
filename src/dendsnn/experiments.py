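"""Analysis battery for trained models.

Implements the measurements used to characterise energy-optimised versus
control networks: per-layer energy and spike-rate metrics, linear decoding
of images from spike-rate representations, clamped reconstruction and
representational similarity analysis (RSA), match/mismatch voltage and
rate statistics (MSD, delta-R) with a clamping-uncertainty sweep, and the
input-modulation stability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import GlyphDataset, occlude  # noqa: F401  (re-export convenience)
from .network import ClampSpec, Network, StimulusSchedule, TraceRecord, apply_clamp

__all__ = [
    "rate_representation",
    "layer_rates",
    "DecoderModel",
    "fit_linear_decoder",
    "reconstruct",
    "rsa_matrix",
    "class_structure_score",
    "msd",
    "delta_rate",
    "MismatchResult",
    "run_mismatch_experiment",
    "compare_msd_distributions",
    "uncertainty_sweep",
    "StabilityFit",
    "stability_sweep",
    "energy_and_rate_metrics",
    "weight_magnitudes",
    "reconstruction_quality",
    "clamped_class_representations",
    "normal_class_representations",
]


# ----------------------------------------------------------------- rate reps
def rate_representation(trace: TraceRecord, layer: int,
                        window: tuple | None = None) -> np.ndarray:
    """Mean spikes per neuron per step over ``window`` -> ``(batch, n)``."""
    return trace.spike_rate(layer, window)


def layer_rates(model: Network, images: np.ndarray, steps: int | None = None,
                seed: int = 0, batch_size: int = 256) -> list:
    """Per-sample rate representations of every layer -> list of (S, n_l)."""
    images = np.asarray(images).reshape(-1, model.cfg.input_size)
    chunks: list[list[np.ndarray]] = [[] for _ in model.cfg.layer_sizes]
    for i in range(0, images.shape[0], batch_size):
        tr = model.run_inference(images[i:i + batch_size], steps=steps, seed=seed + i)
        for l in range(len(chunks)):
            chunks[l].append(tr.spike_rate(l))
    return [np.concatenate(c, axis=0) for c in chunks]


# -------------------------------------------------------------------- decoder
@dataclass
class DecoderModel:
    """Linear map from one layer's rate vector to a flattened image."""

    weight: np.ndarray            # (n_pixels, n_neurons)
    intercept: np.ndarray         # (n_pixels,)
    layer: int
    loss_curve: list = field(default_factory=list)

    def predict(self, rates: np.ndarray) -> np.ndarray:
        rates = np.atleast_2d(rates)
        return rates @ self.weight.T + self.intercept


def fit_linear_decoder(rates: np.ndarray, images: np.ndarray, layer: int = 0,
                       epochs: int = 20, lr: float = 1e-3,
                       batch_size: int | None = 64, seed: int = 0) -> DecoderModel:
    """Train a linear image decoder by MSE gradient descent (Adam).

    One decoder per layer per model; ``epochs`` passes of mini-batch
    updates (``batch_size=None`` for full-batch).  The per-epoch training
    MSE is recorded in ``loss_curve``.
    """
    rates = np.asarray(rates, dtype=np.float64)
    images = np.asarray(images, dtype=np.float64)
    if rates.shape[0] != images.shape[0]:
        raise ValueError("rates/images pair counts differ")
    targets = images.reshape(rates.shape[0], -1)
    n_samples, n_units = rates.shape
    n_pix = targets.shape[1]
    rng = np.random.default_rng(seed)
    w = np.zeros((n_pix, n_units))
    b = np.zeros(n_pix)
    m = {"w": np.zeros_like(w), "b": np.zeros_like(b)}
    v = {"w": np.zeros_like(w), "b": np.zeros_like(b)}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    bs = n_samples if batch_size is None else min(batch_size, n_samples)
    curve = []
    for _ in range(epochs):
        order = rng.permutation(n_samples)
        for start in range(0, n_samples, bs):
            idx = order[start:start + bs]
            x, y = rates[idx], targets[idx]
            err = x @ w.T + b - y               # (bs, n_pix)
            gw = err.T @ x / len(idx)
            gb = err.mean(axis=0)
            t += 1
            for key, g, p in (("w", gw, w), ("b", gb, b)):
                m[key] = beta1 * m[key] + (1 - beta1) * g
                v[key] = beta2 * v[key] + (1 - beta2) * g * g
                p -= lr * (m[key] / (1 - beta1 ** t)) / (
                    np.sqrt(v[key] / (1 - beta2 ** t)) + eps)
        mse = float(np.mean((rates @ w.T + b - targets) ** 2))
        curve.append(mse)
    return DecoderModel(w, b, layer, curve)


def reconstruct(model: Network, decoder: DecoderModel,
                image: np.ndarray | None = None,
                clamp: ClampSpec | np.ndarray | None = None,
                steps: int | None = None, seed: int = 0) -> np.ndarray:
    """Decode the internal representation of a (possibly clamped) run.

    Runs inference (default ``5T`` steps, the long-inference budget used
    for reduced-input conditions), extracts the decoder's layer rate over
    the whole run and applies the decoder.  Returns the flattened decoded
    image.
    """
    steps = 5 * model.cfg.sim.T if steps is None else steps
    trace = model.run_inference(image, steps=steps, clamp=clamp, seed=seed)
    rates = trace.spike_rate(decoder.layer)
    return decoder.predict(rates)[0]


# ------------------------------------------------------------------------ RSA
def rsa_matrix(normal_reps: np.ndarray, clamped_reps: np.ndarray) -> np.ndarray:
    """Cosine similarity between clamped and normal class representations.

    Entry ``(i, j)`` is the cosine similarity (1 minus cosine distance)
    between the clamped representation of class i and the normal (driven)
    representation of class j.  Zero-norm representations give ``nan``
    entries rather than a silent 0.
    """
    a = np.asarray(clamped_reps, dtype=np.float64)
    b = np.asarray(normal_reps, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("representation sets must cover the same classes")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    sim = a @ b.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = sim / np.outer(na, nb)
    sim[na == 0, :] = np.nan
    sim[:, nb == 0] = np.nan
    return sim


def class_structure_score(matrix: np.ndarray) -> dict:
    """Diagonal (same-class) vs off-diagonal mean similarity + rank test.

    The rank test is a one-sided Mann-Whitney U comparing same-class to
    different-class similarities.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    k = matrix.shape[0]
    if matrix.shape != (k, k):
        raise ValueError("matrix must be square")
    same = np.diag(matrix)
    diff = matrix[~np.eye(k, dtype=bool)]
    same, diff = same[~np.isnan(same)], diff[~np.isnan(diff)]
    if len(same) and len(diff) and np.ptp(np.concatenate([same, diff])) > 0:
        p = stats.mannwhitneyu(same, diff, alternative="greater").pvalue
    else:
        p = 1.0  # all values tied (or a group empty): no evidence of structure
    return {"same_mean": float(np.mean(same)) if len(same) else np.nan,
            "diff_mean": float(np.mean(diff)) if len(diff) else np.nan,
            "p_value": float(p)}


def normal_class_representations(model: Network, dataset: GlyphDataset,
                                 layer: int, steps: int | None = None,
                                 seed: int = 0) -> np.ndarray:
    """Per-class mean rate vectors from driven (input) inference."""
    rates = layer_rates(model, dataset.test_images, steps=steps, seed=seed)[layer]
    labels = np.asarray(dataset.test_labels)
    return np.stack([rates[labels == c].mean(axis=0)
                     for c in range(dataset.n_classes)])


def clamped_class_representations(model: Network, n_classes: int, layer: int,
                                  steps: int | None = None,
                                  seed: int = 0) -> np.ndarray:
    """Per-class rate vectors from no-input, class-clamped inference (5T)."""
    steps = 5 * model.cfg.sim.T if steps is None else steps
    clamps = np.stack([apply_clamp(ClampSpec(class_index=c), n_classes)
                       for c in range(n_classes)])
    trace = model.run_inference(None, steps=steps, clamp=clamps, seed=seed)
    return trace.spike_rate(layer)


def rsa_summary(model: Network, dataset: GlyphDataset, layers=(0, 1, 2),
                normal_seed: int = 3, clamp_seed: int = 4) -> dict:
    """Clamped-vs-normal RSA over several layers with a pooled rank test.

    Computes the per-layer similarity matrices, then groups all pair-wise
    similarities across layers into same-class and different-class sets
    and runs a one-sided Mann-Whitney U between them.  Returns the
    matrices, the pooled gap (same minus different mean) and its p-value.
    """
    matrices, same, diff = {}, [], []
    k = dataset.n_classes
    for layer in layers:
        normal = normal_class_representations(model, dataset, layer,
                                              seed=normal_seed)
        clamped = clamped_class_representations(model, k, layer,
                                                seed=clamp_seed)
        mat = rsa_matrix(normal, clamped)
        matrices[layer] = mat
        same.extend(np.diag(mat))
        diff.extend(mat[~np.eye(k, dtype=bool)])
    same, diff = np.asarray(same), np.asarray(diff)
    ok = ~np.isnan(same), ~np.isnan(diff)
    same, diff = same[ok[0]], diff[ok[1]]
    p = stats.mannwhitneyu(same, diff, alternative="greater").pvalue \
        if len(same) and len(diff) else 1.0
    return {"matrices": matrices, "same": same, "diff": diff,
            "gap": float(same.mean() - diff.mean()), "p_value": float(p)}


def clamped_reconstruction_distance(model: Network, dataset: GlyphDataset,
                                    layer: int = 0, seed: int = 0) -> float:
    """Mean cosine distance of decoded no-input clamped reps to class means.

    Trains the layer's linear decoder on driven training-set rates, then
    for every class decodes the no-input class-clamped representation and
    measures its cosine distance to that class's mean training image.
    Lower is better reconstruction.
    """
    rates = layer_rates(model, dataset.train_images, seed=seed)[layer]
    decoder = fit_linear_decoder(rates, dataset.train_images, layer=layer,
                                 seed=seed)
    means = dataset.class_means("train")
    dists = []
    for c in range(dataset.n_classes):
        decoded = reconstruct(model, decoder, image=None,
                              clamp=ClampSpec(class_index=c), seed=seed + c)
        dists.append(reconstruction_quality(decoded, means)[c])
    return float(np.mean(dists))


# ------------------------------------------------------------ match/mismatch
_COMPARTMENTS = {"apical": "v_apical", "soma": "v_soma"}


def msd(trace_match: TraceRecord, trace_mismatch: TraceRecord, layer: int,
        compartment: str, window: tuple) -> np.ndarray:
    """Mean signed voltage difference (match - mismatch) per neuron.

    Averaged over the ``window`` steps; shape ``(batch, n)``.  Swapping the
    two traces flips the sign.  A layer-level scalar is the mean over
    neurons (the layer-size normalisation applied on aggregation).
    """
    attr = _COMPARTMENTS[compartment]
    lo, hi = window
    va = getattr(trace_match, attr)[layer]
    vb = getattr(trace_mismatch, attr)[layer]
    if va.shape != vb.shape or hi > va.shape[0] or lo < 0 or hi <= lo:
        raise ValueError("window/trace mismatch")
    return (va[lo:hi].astype(np.float64)
            - vb[lo:hi].astype(np.float64)).mean(axis=0)


def delta_rate(trace_match: TraceRecord, trace_mismatch: TraceRecord,
               layer: int, window: tuple) -> np.ndarray:
    """Spike-rate difference (match - mismatch) per neuron over ``window``."""
    return (trace_match.spike_rate(layer, window).astype(np.float64)
            - trace_mismatch.spike_rate(layer, window).astype(np.float64))


@dataclass
class MismatchResult:
    """Per-neuron MSD / delta-R tables from a match-mismatch experiment.

    ``msd_apical[l]`` etc. are pair-averaged per-neuron arrays; ``window``
    is the stimulus window in steps on a run of ``steps`` grid steps.
    """

    msd_apical: list
    msd_soma: list
    delta_r: list
    window: tuple
    steps: int
    n_pairs: int
    clamp_strength: float

    def layer_mean_abs(self, which: str) -> list:
        arrs = getattr(self, which)
        return [float(np.mean(np.abs(a))) for a in arrs]


def run_mismatch_experiment(model: Network, dataset: GlyphDataset,
                            n_pairs: int = 200, clamp_strength: float = 1.0,
                            seed: int = 0) -> MismatchResult:
    """Match vs mismatch clamped runs on randomly sampled test images.

    Each run lasts ``2T`` steps with the stimulus and clamp active during
    the middle half.  The match run clamps the image's true class, the
    mismatch run a uniformly sampled wrong class; both runs of a pair use
    identical initial conditions, so at ``clamp_strength = 0`` (fully
    uncertain clamp) the difference is exactly zero.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    T = model.cfg.sim.T
    steps = 2 * T
    window = (T // 2, 3 * T // 2)
    schedule = StimulusSchedule(*window)
    rng = np.random.default_rng(seed)
    n_test = len(dataset.test_labels)
    idx = rng.integers(0, n_test, size=n_pairs)
    images = np.asarray(dataset.test_images)[idx].reshape(n_pairs, -1)
    true_cls = np.asarray(dataset.test_labels)[idx]
    k = dataset.n_classes
    wrong_cls = (true_cls + rng.integers(1, k, size=n_pairs)) % k

    def clamp_matrix(classes):
        return np.stack([apply_clamp(ClampSpec(class_index=int(c),
                                               strength=clamp_strength), k)
                         for c in classes])

    tr_match = model.run_inference(images, steps=steps,
                                   clamp=clamp_matrix(true_cls),
                                   schedule=schedule, seed=seed)
    tr_mis = model.run_inference(images, steps=steps,
                                 clamp=clamp_matrix(wrong_cls),
                                 schedule=schedule, seed=seed)
    n_layers = len(model.cfg.layer_sizes)
    return MismatchResult(
        msd_apical=[msd(tr_match, tr_mis, l, "apical", window).mean(axis=0)
                    for l in range(n_layers)],
        msd_soma=[msd(tr_match, tr_mis, l, "soma", window).mean(axis=0)
                  for l in range(n_layers)],
        delta_r=[delta_rate(tr_match, tr_mis, l, window).mean(axis=0)
                 for l in range(n_layers)],
        window=window, steps=steps, n_pairs=n_pairs,
        clamp_strength=clamp_strength)


def compare_msd_distributions(result_a: MismatchResult,
                              result_b: MismatchResult) -> dict:
    """Kruskal-Wallis tests of |MSD| / |delta-R| neuron distributions.

    Compares, per layer and per measure, the absolute per-neuron values of
    two models (e.g. energy vs control); also reports which model has the
    larger mean |value|.  Significance threshold 0.05, no multiple-testing
    correction.
    """
    out = {}
    for which in ("msd_apical", "msd_soma", "delta_r"):
        per_layer = []
        for a, b in zip(getattr(result_a, which), getattr(result_b, which)):
            a, b = np.abs(a), np.abs(b)
            stat, p = stats.kruskal(a, b)
            per_layer.append({"statistic": float(stat), "p_value": float(p),
                              "mean_abs_a": float(a.mean()),
                              "mean_abs_b": float(b.mean())})
        out[which] = per_layer
    return out


def uncertainty_sweep(model: Network, dataset: GlyphDataset,
                      strengths=(1.0, 0.75, 0.5, 0.25, 0.0),
                      n_pairs: int = 50, seed: int = 0) -> dict:
    """Mean |MSD| as a function of clamping strength.

    The same image/clamp-class sample (same seed) is reused for every
    strength, so the curve isolates the effect of top-down certainty.
    Reports a monotone-trend statistic (Spearman rho of mean |MSD| vs
    strength) per compartment.
    """
    strengths = list(strengths)
    if not strengths:
        raise ValueError("empty strength grid")
    curves = {"apical": [], "soma": []}
    for c in strengths:
        res = run_mismatch_experiment(model, dataset, n_pairs=n_pairs,
                                      clamp_strength=float(c), seed=seed)
        curves["apical"].append(float(np.mean(
            [np.mean(np.abs(a)) for a in res.msd_apical])))
        curves["soma"].append(float(np.mean(
            [np.mean(np.abs(a)) for a in res.msd_soma])))
    trend = {}
    for comp, vals in curves.items():
        if len(strengths) > 2 and np.ptp(vals) > 0:
            trend[comp] = float(stats.spearmanr(strengths, vals).statistic)
        else:
            trend[comp] = np.nan
    return {"strengths": strengths, "mean_abs_msd": curves, "spearman_rho": trend}


# -------------------------------------------------------------------- stability
@dataclass
class StabilityFit:
    """Per-neuron linear fit of spike rate vs input offset."""

    offsets: np.ndarray
    slopes: np.ndarray      # dS/dA per neuron
    intercepts: np.ndarray
    r_squared: np.ndarray
    layer: int


def _linear_fits(x: np.ndarray, y: np.ndarray):
    """Vectorised least-squares of each column of ``y`` against ``x``.

    ``x``: (m,), ``y``: (m, n).  A column with zero variance is a perfect
    constant fit: slope 0, r^2 = 1.
    """
    xm = x - x.mean()
    denom = float(xm @ xm)
    slopes = xm @ (y - y.mean(axis=0)) / denom
    intercepts = y.mean(axis=0) - slopes * x.mean()
    pred = np.outer(x, slopes) + intercepts
    ss_res = ((y - pred) ** 2).sum(axis=0)
    ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2[ss_tot == 0] = 1.0
    return slopes, intercepts, np.clip(r2, 0.0, 1.0)


def stability_sweep(model: Network, dataset: GlyphDataset,
                    offsets=(-0.2, -0.1, 0.0, 0.1, 0.2),
                    n_samples: int = 200, layer: int = 0,
                    seed: int = 0) -> dict:
    """Spike-rate response to global pixel-value offsets.

    Adds each offset to the (preprocessed) test images — negative values
    allowed, since negative input weights turn subtracted pixels into
    increased drive — and measures per-neuron mean rates.  Returns
    per-neuron linear fits (slope dS/dA, r^2) for ``layer``, the network
    mean-rate curve against the mean input current into L1, and the
    fraction of neurons saturated at rate 1.0.
    """
    offsets = np.asarray(sorted(offsets), dtype=np.float64)
    if offsets.size < 3 or np.unique(offsets).size < 3:
        raise ValueError("need at least 3 distinct offsets")
    images = np.asarray(dataset.test_images)[:n_samples].reshape(n_samples, -1)
    w0 = model.params["w_ff_0"].data
    bias0 = model.params["bias_0"].data
    layer_rate_curves = None
    net_rate, mean_drive = [], []
    per_neuron_max = []
    for off in offsets:
        x = images + off
        rates = layer_rates(model, x, seed=seed)
        if layer_rate_curves is None:
            layer_rate_curves = [[] for _ in rates]
        for l, r in enumerate(rates):
            layer_rate_curves[l].append(r.mean(axis=0))
        all_neurons = np.concatenate([r.mean(axis=0) for r in rates])
        per_neuron_max.append(all_neurons)
        net_rate.append(float(np.mean(np.concatenate(
            [r.reshape(-1) for r in rates]))))
        mean_drive.append(float(np.mean(x @ w0.T + bias0)))
    y = np.stack(layer_rate_curves[layer])          # (n_offsets, n_neurons)
    slopes, intercepts, r2 = _linear_fits(offsets, y)
    rate_matrix = np.stack(per_neuron_max)          # (n_offsets, all neurons)
    saturated = float(np.mean(rate_matrix.max(axis=0) >= 1.0 - 1e-9))
    return {
        "fit": StabilityFit(offsets, slopes, intercepts, r2, layer),
        "network_mean_rate": np.asarray(net_rate),
        "mean_input_drive": np.asarray(mean_drive),
        "saturated_fraction": saturated,
    }


# ------------------------------------------------------------------- metrics
def energy_and_rate_metrics(trace: TraceRecord) -> dict:
    """Per-layer mean |V_apical - V_soma| and mean spike rate of a trace."""
    energy, rate = [], []
    for va, vs, sp in zip(trace.v_apical, trace.v_soma, trace.spikes):
        energy.append(float(np.mean(np.abs(va.astype(np.float64)
                                           - vs.astype(np.float64)))))
        rate.append(float(sp.mean()))
    return {"energy_per_layer": energy, "rate_per_layer": rate}


def weight_magnitudes(model: Network) -> dict:
    """Mean absolute weight per connection type and overall."""
    ff = [np.abs(model.params[f"w_ff_{l}"].data).mean()
          for l in range(len(model.cfg.layer_sizes))]
    fb = [np.abs(model.params[f"w_fb_{l}"].data).mean()
          for l in range(len(model.cfg.layer_sizes))]
    out = float(np.abs(model.params["w_out"].data).mean())
    stacked = np.concatenate([model.params[k].data.reshape(-1)
                              for k in model.params if k.startswith("w_")])
    return {"ff": [float(x) for x in ff], "fb": [float(x) for x in fb],
            "out": out, "all_mean_abs": float(np.abs(stacked).mean())}


def reconstruction_quality(decoded: np.ndarray,
                           class_means: np.ndarray) -> np.ndarray:
    """Cosine distance (1 - cosine similarity) to each class-mean image.

    Scale-invariant in the decoded image; a zero-norm image yields nan.
    """
    decoded = np.asarray(decoded, dtype=np.float64).reshape(-1)
    means = np.asarray(class_means, dtype=np.float64).reshape(
        class_means.shape[0], -1)
    dn = np.linalg.norm(decoded)
    mn = np.linalg.norm(means, axis=1)
    if dn == 0:
        return np.full(means.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = means @ decoded / (mn * dn)
    cos[mn == 0] = np.nan
    return 1.0 - cos
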
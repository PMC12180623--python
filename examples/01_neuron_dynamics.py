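"""A single two-compartment adaptive LIF neuron under constant drive.

Steps one neuron for 40 grid steps (dt = 0.5 ms) with a constant somatic
input current and a sinusoidal top-down current into the apical tuft, and
prints the voltage, threshold and spike trajectory.  Watch three things:
the soft reset (the voltage drops by exactly the threshold at each
spike), the adaptive threshold (it jumps by beta = 1.8 after a spike and
decays back toward b0 = 0.1), and the bounded apical influence (never
more than 0.25 per step however large the apical voltage).
"""

import numpy as np

from dendsnn import SimulationConfig, apical_drive
from dendsnn.dynamics import step_adaptation, step_apical, step_soma_and_spike

cfg = SimulationConfig(T=40)
v_soma, v_apical, eta = np.zeros(1), np.zeros(1), np.zeros(1)
threshold = np.full(1, cfg.b0)
drive = 0.12  # constant feedforward current per step

print(f"{'step':>4} {'v_apical':>9} {'f(v_a)':>8} {'v_soma':>8} "
      f"{'threshold':>10} spike")
for t in range(cfg.T):
    topdown = 0.05 * np.sin(2 * np.pi * t / 20.0)
    v_apical = step_apical(v_apical, topdown, 15.0, cfg)
    v_soma, spike = step_soma_and_spike(v_soma, v_apical, drive, threshold,
                                        15.0, cfg)
    eta, threshold = step_adaptation(eta, spike, 20.0, cfg)
    mark = " *" if spike[0] else ""
    print(f"{t:>4} {v_apical[0]:>9.4f} {apical_drive(v_apical)[0]:>8.4f} "
          f"{v_soma[0]:>8.4f} {threshold[0]:>10.4f}{mark}")

print("\nEach '*' marks a spike: the somatic voltage loses exactly the "
      "threshold (soft reset)\nand the threshold jumps by beta and then "
      "decays with tau_adp = 20 ms.")
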
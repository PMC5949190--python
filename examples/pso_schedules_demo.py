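"""Inertia-weight schedules and swarm convergence on a known optimum.

Prints the six inertia-weight schedules at a few generations, then shows
that a 20-particle swarm under the slow-early-decay quadratic schedule
localizes the maximum of -||x - x*||^2 to centimeter precision.
"""

import numpy as np

from mklsvm_pso import SCHEDULES, SwarmConfig, inertia_weight, pso_optimize

cfg = SwarmConfig(n=20, dim=3, maxgen=200, bounds=((-5.0, 5.0),) * 3, seed=0)
print("generation:      k=0     k=100   k=200")
for s in SCHEDULES:
    w = [inertia_weight(s, k, cfg) for k in (0, 100, 200)]
    print(f"{s:<11} {w[0]:8.4f} {w[1]:8.4f} {w[2]:8.4f}")
print("Dynamic schedules fall from 0.9 (global search) toward 0.4 (local "
      "refinement); exp_ratio approaches but never reaches 0.4.\n")

target = np.array([1.3, -2.1, 0.7])
cfg = SwarmConfig(n=20, dim=3, maxgen=200, schedule="quad_late",
                  bounds=((-5.0, 5.0),) * 3, seed=0)
pos, fit, trace = pso_optimize(lambda x: -float(np.sum((x - target) ** 2)), cfg)
print(f"true optimum  {target}")
print(f"swarm result  {np.round(pos, 4)}  (error {np.linalg.norm(pos - target):.2e})")
print(f"V_best is non-decreasing: {bool(np.all(np.diff(trace.v_best) >= 0))}")
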
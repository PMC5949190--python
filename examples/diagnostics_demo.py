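"""Convergence diagnostics of a swarm fitness trace.

Runs a short swarm on the ring table, then summarizes its trace: when the
average fitness curve settles (convergence generation t), how far it then
sits from the best curve (normalized RMS error F_gy), and Tukey boxplot
statistics of per-repeat fitness values.
"""

import numpy as np

from mklsvm_pso import ExperimentConfig, boxplot_stats, curve_summary
from mklsvm_pso.experiment import tune_pso
from mklsvm_pso.synthetic import generate_ring_classes, split_train_test

data = generate_ring_classes(seed=1)
train, _ = split_train_test(data, n_train=170, seed=1)
cfg = ExperimentConfig(schedules=("quad_late",), n_particles=6, maxgen=60,
                       repeats=1, include_grid=False, d_values=(2,))
_, fit, trace = tune_pso(train, "quad_late", cfg, seed=1)

s = curve_summary(trace)
print(f"best CV fitness: {fit:.4f}%")
print(f"max V_best {s.max_vbest:.4f}%  mean V_ave {s.mean_vave:.4f}%  "
      f"median V_ave {s.median_vave:.4f}%")
print(f"global error norm ||V_best - V_ave||: {s.global_error_norm:.4f}")
if s.convergence_generation is None:
    print("average curve still oscillating at the last generation: "
          "no convergence generation (typical for a constant inertia weight)")
else:
    print(f"convergence generation t={s.convergence_generation}, "
          f"normalized post-convergence error F_gy={s.fgy:.4f}")
    print("F_gy is an RMS, so traces with different convergence generations "
          "remain comparable.")

times = [366.3, 364.2, 369.0, 368.1, 365.5, 410.0]  # e.g. per-repeat timings
bs = boxplot_stats(times)
print(f"\nboxplot of a sample: median {bs.median}, adjacents "
      f"[{bs.lower_adjacent}, {bs.upper_adjacent}], outliers {bs.outlier_count}")
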
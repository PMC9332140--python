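"""Estimate absolute RNA turnover rates from simulated metabolic-labeling data.

Simulates a gene with known degradation rate under one-shot and pulse
(kinetics) labeling designs with the exact stochastic simulator, then runs
the one-shot slope estimator and the two-step estimator and compares the
recovered rates with the ground truth.
"""

import numpy as np

from dynofield.kinetics import LabelingDesign, fit_one_shot, fit_two_step, velocities
from dynofield.simulate import GillespieParams, simulate_expression

# one-shot: a single 2 h labeling window, gamma = 0.3/h
p = GillespieParams(k_on=10.0, k_off=1.0, alpha=30.0, gamma=0.3,
                    splicing=False, n_cells=1000, seed=7)
lm = simulate_expression(p, design="one_shot", t=2.0)
est = fit_one_shot(lm, LabelingDesign("one_shot", [2.0]), extreme_quantile=1.0)
print(f"one-shot:  slope k = {est.k[0]:.4f}, gamma = {est.gamma[0]:.4f}/h "
      f"(true {p.gamma}), half-life = {est.half_life[0]:.2f} h")

v = velocities(lm, est, which="total")
print(f"           mean total-RNA velocity = {v.mean():+.3f} molecules/h "
      "(should be ~0: the population is at steady state)")

# kinetics: labeling durations 0.5-4 h, gamma = 0.5/h
p2 = GillespieParams(k_on=10.0, k_off=1.0, alpha=20.0, gamma=0.5,
                     splicing=False, n_cells=1000, seed=11)
lm2 = simulate_expression(p2, design="kinetics", t=[0.5, 1, 2, 4])
est2 = fit_two_step(lm2, LabelingDesign("kinetics", [0.5, 1, 2, 4]),
                    extreme_quantile=1.0)
print(f"two-step:  gamma = {est2.gamma[0]:.4f}/h (true {p2.gamma}), "
      f"step-2 R^2 = {est2.r2[0]:.4f}")
print("The slope of labeled vs total RNA rises with labeling time exactly as "
      "1 - exp(-gamma t); the step-2 R^2 near 1 confirms that kinetic law.")
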
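"""Reconstruct a continuous velocity vector field from noisy samples.

Draws (state, velocity) pairs from the two-gene toggle-switch benchmark,
contaminates 5% of them with random velocities, fits the sparse RKHS model
with EM outlier rejection, and reports reconstruction accuracy and outlier
recall against the known ground truth.
"""

import numpy as np

from dynofield.simulate import sample_field, toggle_field
from dynofield.vectorfield import detect_outliers, fit_vectorfield

X, V = sample_field(n=2000, seed=2)
rng = np.random.default_rng(3)
planted = rng.choice(2000, 100, replace=False)
V = V.copy()
V[planted] = rng.normal(0, 5.0, size=(100, 2))

model = fit_vectorfield(X, V, seed=0)
mask = detect_outliers(model)
F = model.evaluate(X)
truth = toggle_field(X)
cos = np.sum(F * truth, axis=1) / (np.linalg.norm(F, axis=1)
                                   * np.linalg.norm(truth, axis=1) + 1e-300)

print(f"control points: {model.control_points.shape[0]}, "
      f"inverse bandwidth w = {model.bandwidth:.3f}")
print(f"EM iterations: {len(model.loss_trace)}, final inlier fraction "
      f"q = {model.inlier_fraction:.3f}")
print(f"median cosine similarity to the true field: {np.median(cos):.4f}")
print(f"planted-outlier recall: {np.mean(~mask[planted]):.1%} "
      f"({(~mask).sum()} samples flagged in total)")
print("A median cosine near 1 means the learned analytical field reproduces "
      "the true flow despite the contaminated velocities.")
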
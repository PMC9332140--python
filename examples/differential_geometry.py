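"""Differential geometry of a fitted vector field.

Fits the toggle-switch benchmark, evaluates the analytic Jacobian,
divergence, curl, acceleration and curvature at the saddle and near an
attractor, and ranks mutually inhibiting gene pairs with the toggle score.
"""

import numpy as np

from dynofield import diffgeo
from dynofield.simulate import sample_field
from dynofield.vectorfield import fit_vectorfield

X, V = sample_field(n=5000, seed=1)
model = fit_vectorfield(X, V, seed=0)

pts = np.array([[1.0, 1.0],          # saddle
                [0.07, 1.93]])       # attractor
gf = diffgeo.geometry(model, pts)
J = gf.jacobians
print("Jacobian at the saddle (true [[0,-1],[-1,0]]):")
print(np.round(J[0], 3))
print(f"divergence: saddle {gf.divergence[0]:+.3f}, "
      f"attractor {gf.divergence[1]:+.3f} "
      "(sinks have negative divergence)")
print(f"speed:      saddle {gf.speed[0]:.4f}, attractor {gf.speed[1]:.4f}")

# toggle-switch pair ranking among decoys
sub = X[:300]
J2 = diffgeo.jacobian(model, sub)
rng = np.random.default_rng(5)
J4 = np.zeros((300, 4, 4))
J4[:, :2, :2] = J2
J4[:, 2:, 2:] = rng.normal(0, 1e-3, size=(300, 2, 2))
ranking = diffgeo.toggle_pairs(J4, ["x1", "x2", "decoy1", "decoy2"])
print("\ntop mutual-inhibition pairs (score = |J J^T| gated on J_ij<0, J_ji<0):")
print(ranking.head(3).to_string(index=False))
print("The planted (x1, x2) toggle ranks first; the decoys carry no "
      "regulatory coupling.")
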
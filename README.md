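# dynofield

Absolute RNA kinetics, velocity vector fields and their differential geometry
for single-cell transcriptomics.

Conventional RNA velocity infers only a *relative* rate of change per gene,
because the splicing-based steady-state regression u = γ̃s identifies the
degradation rate γ only up to the splicing rate β (γ̃ = γ/β).  Metabolic
labeling (4sU) experiments measure new (`l`) and total (`r`) RNA over a known
labeling time t, which makes the rate constants absolute: at steady state
l = k·r with k = 1 − e^(−γt), so γ = −ln(1 − k)/t in physical units of 1/h,
and the per-cell total-RNA velocity is ṙ = (γ/k)·l − γ·r.  `dynofield`
implements this estimation framework for one-shot, pulse (kinetics) and chase
(degradation) labeling designs, plus the moment-based estimators for
conventional data, and then goes beyond per-cell velocities:

* **Vector-field reconstruction** — from sample pairs (xᵢ, vᵢ) of cell states
  and velocities it learns a continuous, analytical field
  f(x) = Σⱼ Γ(x, x̃ⱼ)cⱼ in a reproducing-kernel Hilbert space (Gaussian
  kernel Γ(x, x̃) = e^(−w‖x−x̃‖²), sparse control points x̃ⱼ), with an EM loop
  that down-weights outlier velocities via a Gaussian-inlier/uniform-outlier
  mixture (the sparse vector-field-consensus algorithm).
* **Differential geometry** — the closed-form Jacobian J = −2w CᵀKD gives
  divergence ∇·f = tr J, curl, acceleration a = Jv and curvature
  κ = (Jv(v·v) − v(v·Jv))/‖v‖⁴ per cell, a gene-space projection G = QJQᵀ
  through PCA loadings, gene/interaction rankings, mutual-inhibition
  (toggle-switch) pair scores L = (JJᵀ)⊙[J<0][Jᵀ<0], and Hill-derivative fits
  of Jacobian-vs-expression response curves.
* **Topology** — fixed points f(x*) = 0 with eigenvalue classification
  (attractor / repulsor / saddle) and data-proximity confidence, 2D
  nullclines by pseudo-arclength continuation, trajectory integration with
  FFT-based limit-cycle trimming, fate probabilities, and a Hodge-style graph
  pseudotime.
* **Predictions** — least action paths minimizing
  S = (1/2D) Σₖ ‖vₖ − f(yₖ)‖²Δt between cell states (with the exact analytic
  path gradient), fastest-LAP selection at the elbow of the action-vs-time
  curve, gene MSD rankings, relative transition rates exp(−S*), and
  in-silico perturbations Δf = JΔx propagated through the Jacobian.
* **Simulation** — an exact Gillespie simulator of two-state-promoter
  transcription, splicing, degradation and 4sU labeling, and the two-gene
  toggle-switch ODE benchmark, so every stage is testable against known
  ground truth.

## Worked example

`examples/reconstruct_vector_field.py` samples 2,000 states and velocities
from the toggle-switch benchmark, replaces 5% of the velocities with random
vectors, and fits the field:

```
control points: 100, inverse bandwidth w = 1.565
EM iterations: 7, final inlier fraction q = 0.948
median cosine similarity to the true field: 1.0000
planted-outlier recall: 100.0% (104 samples flagged in total)
```

The inlier fraction q ≈ 0.95 matches the 5% contamination, every planted
outlier is rejected, and the reconstructed field's directions agree with the
noiseless ground truth almost everywhere.  The other scripts in `examples/`
walk through kinetic-rate estimation, differential geometry, topology and
fate, least action paths, perturbation, and the binomial mixture model for
labeled-read quantification, each printing the numbers it computes and what
they mean.

A thin command-line interface mirrors the library:

```
dynofield simulate --kind toggle --n-cells 5000 --seed 0 --out data/
dynofield vectorfield --samples data/samples.csv --out fit/
dynofield topology --model fit/model.npz --domain 0,2.5 --out topo/
dynofield lap --model fit/model.npz --start 0.07,1.93 --end 1.93,0.07 --out lap/
```

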
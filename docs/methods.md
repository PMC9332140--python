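# Methods

This note documents the models implemented in `dynofield`, the defaults and
the numerical choices, and what the synthetic benchmarks do and do not show.

## Expression-dynamics models

Three nested ODE models describe a gene's RNA species:

* **Splicing only** (conventional scRNA-seq): u̇ = α − βu, ṡ = βu − γs, with
  transcription rate α (molecules/h), splicing rate constant β (1/h) and
  degradation rate constant γ (1/h).  At pseudo-steady state u = γ̃s with
  γ̃ = γ/β; only this dimensionless ratio is identifiable from splicing data,
  so the conventional velocity v = u − γ̃s is relative (units of molecules,
  not molecules/h).
* **Labeling only**: l̇ = ρα − γl, ṙ = α − γr, where l is labeled (new) RNA,
  r total RNA and ρ the labeling correction coefficient (the ratio of
  estimated to true labeled fraction; ρ = 1 when the mixture model has
  corrected the counts).  Solutions: l(t) = (ρα/γ)(1 − e^(−γt)),
  r(t) = r₀e^(−γt) + (α/γ)(1 − e^(−γt)).
* **Labeling + splicing**: the labeled unspliced/spliced species obey the
  splicing model with transcription rate ρα; closed-form solutions (including
  the degenerate β = γ branch, taken when |β − γ|/γ < 10⁻³) are used by the
  curve-fitting estimators.

A note on one printed relation: the total-RNA velocity is implemented as
ṙ = α − γr throughout; γ and r carry the physical units, so ṙ is an absolute
rate in molecules/h.

### Estimators

* **Steady-state (conventional)**: zero-intercept least squares u = γ̃s over
  "extreme" cells — by default the top 5% of cells by u + s per gene, with a
  floor of 10 cells.  The quantile is exposed because the extreme-cell rule
  exists to isolate steady-state cells in heterogeneous populations; for a
  homogeneous population known to be at steady state (e.g. the bundled
  simulator's output) the whole population is the correct regression set, and
  the recovery benchmarks use `extreme_quantile=1.0` for that reason.
* **Generalized method of moments**: first, second and mixed moments are
  kNN-smoothed (simple average over each cell's neighbor set including
  itself; K = 30 by default, graph built in expression or PCA space).  The
  *stochastic splicing* variant solves the two stacked moment conditions
  y = γ̃x with x = (⟨s⟩, 2⟨s²⟩ − ⟨s⟩), y = (⟨u⟩, ⟨u⟩ + 2⟨us⟩) in weighted
  least squares (weight matrix identity by default; an inverse-covariance
  weighting is accepted but not the default because it is easily
  ill-conditioned on smoothed moments).  The *negative-binomial* variant
  solves {γ̃⟨s⟩ = ⟨u⟩, γ̃²Var(s) = γ̃⟨u⟩ − φ̂⟨u⟩²} with
  φ̂ = (Var(s) − ⟨s⟩)/⟨s⟩² by nonlinear least squares and falls back to the
  stochastic variant for underdispersed genes.
* **One-shot**: slope k of l = k·r (zero-intercept LS or the NB moment
  conditions), γ = −ln(1 − k)/t; fits with k ∉ (0, 1) are flagged unfit.
  Per-cell transcription rates follow as α = γl/(1 − e^(−γt)).
* **Two-step (kinetics)**: per-time-point slopes k(t), then a through-origin
  regression of −ln(1 − k) on t gives γ; the step-2 R² filters genes that do
  not follow the saturation law.  With one time point this reduces exactly to
  the one-shot estimator.
* **Curve fitting**: per-gene nonlinear least squares of the closed-form
  solutions against per-time-point means, species weighted 2:1
  labeled:unlabeled (unlabeled species only approximately follow pure decay
  when labeling is imperfect).  Initial values come from "guesstimation"
  (α ~ mean(l/t); γ, β from log-ratios of species means between the first and
  last time point; degradation initial conditions from the earliest chase
  point), search ranges are (0, 100·θ₀), and 20 Latin-hypercube multi-starts
  (seeded) guard against local minima; ties break by parameter-vector norm.
* **Unification**: an absolute γ from labeling plus a relative γ̃ from
  splicing give β = γ/γ̃, enabling absolute spliced (ṡ = βu − γs), unspliced
  and new-RNA velocities.
* **Goodness of fit**: R² = 1 − Σ(xᵢ−yᵢ)²/Σ(xᵢ−x̄)² for regressions; for
  curve fits a Gaussian log-likelihood on max-normalized species,
  −(n/2)ln 2π − Σᵢ ln σ(xᵢ) − Σᵢ ½‖xᵢ − yᵢ‖², where xᵢ is the normalized
  data vector of species i and yᵢ the prediction.

### Bursting statistics

For the two-state promoter (activation rate k_on, inactivation k_off,
transcription α while active), the stationary total-RNA distribution is
negative binomial in the bursty limit, with reciprocal dispersion φ solving
Var(r) = ⟨r⟩ + φ⟨r⟩².  Burst frequency BF = k_on = γ/φ and burst size
BS = α/k_off = ⟨r⟩φ.  These relations are asymptotic: they hold when
k_off ≫ k_on, γ (short, intense bursts).  The exact stationary variance of
the two-state model gives φ_exact = γk_off/(k_on(k_on + k_off + γ)), so
BF recovered via γ/φ overshoots k_on by the factor (k_on + k_off + γ)/k_off;
at k_off/k_on = 4 that is a 37% systematic deviation, shrinking to 4% at
k_off/k_on = 40.  The recovery benchmark therefore simulates in the burst
regime (k_on = 1, k_off = 40, α = 200, γ = 0.5; BS = 5), where the NB
relations are valid, and the exact SSA serves as ground truth.

### Binomial mixture model for labeled reads

A read with n convertible sites and y observed T-to-C mutations has mass
P(y) = (1 − π)B(y; n, p_e) + πB(y; n, p_c): background rate p_e, labeling
conversion rate p_c, labeled fraction π.  Parameters are estimated by EM
(init p_e = 0.004, p_c = 0.02, π = 0.5; convergence when no parameter moves
by more than 10⁻⁶; at most 1,000 iterations); p_e may be fixed from unlabeled
controls.  The simulated-read benchmark uses 20–50 convertible sites per
read, typical of 100–200 nt reads at ~25% T content; with many fewer sites
the two components overlap strongly and π is only weakly identifiable.

### Velocity confidence

Cell-wise: the Jaccard index between the k-nearest-neighbor sets of x and
x + v (1 for zero velocity by convention), or mean cosine/correlation of a
cell's velocity with its neighbors'.  Gene-wise: given progenitor and
terminal group labels, a gene's phase per lineage is the sign of its median
expression shift; confidence is 1 minus the fraction of cells whose velocity
violates that sign beyond ±0.05 of the gene's velocity scale; genes with
confidence above 0.8 are retained; flat genes are reported missing rather
than zero.

## Vector-field reconstruction (sparse VFC)

The field is f(x) = Σⱼ Γ(x, x̃ⱼ)cⱼ with Gaussian kernel
Γ(x, x̃) = e^(−w‖x−x̃‖²).  Defaults: m = max(50, 5% of n) control points
drawn uniformly without replacement from the data (seeded); λ = 3;
max 500 EM iterations; inverse bandwidth w = 1.5/(2d_m) where d_m is the
mean distance to the nearest 20% of cells.  Inlier velocities are Gaussian
around f(x) with variance σ² (initialized to the mean squared speed per
dimension); outliers are uniform over a velocity-domain volume a
(initialized to the product of per-dimension velocity ranges); the inlier
fraction q starts at 0.9.

Each EM iteration computes the inlier posterior pᵢ (E-step), solves
(UᵀPU + λσ²K)C = UᵀPV for the coefficients — U the n×m kernel matrix, K the
m×m Gram matrix, P = diag(pᵢ) — then updates σ² = Σpᵢ‖vᵢ − f(xᵢ)‖²/(d·tr P)
and q = tr P/n.  Numerical choices:

* The linear system is solved in augmented least-squares form via QR
  (rows [√pᵢ·U; √(λσ²)·Lᵀ] with K = LLᵀ by Cholesky, jitter 10⁻¹²): Gaussian
  Gram matrices are severely ill-conditioned and normal-equation solves lose
  the monotonicity of the EM objective to roundoff.
* Two traces are recorded.  `phi_trace` is the weighted least-squares energy
  Φ = (1/2σ²)Σpᵢ‖vᵢ − f(xᵢ)‖² + (λ/2)‖f‖²_H, evaluated with the weights and
  σ² of the M-step that produced each C.  `loss_trace` is the penalized
  negative mixture log-likelihood — the quantity the generalized EM iteration
  provably decreases — and drives convergence (relative change below 10⁻⁵).
  Φ alone is not monotone across iterations because the 1/2σ² factor
  reweights the data term as σ² shrinks.
* In the noiseless (interpolation) regime σ² collapses; it is floored at
  10⁻¹² of the initial scale and the loop stops when the floor binds, or when
  a step fails to decrease the objective at the floating-point noise floor
  (the step is then rolled back).

Outliers are the samples with posterior pᵢ < 0.5.  Model archives are
single `.npz` files with a format-version header; loading a mismatched
version or truncated file raises rather than returning silent zeros.

## Differential geometry

All operators are exact derivatives of the kernel expansion:
J(x) = −2w Σⱼ Γ(x, x̃ⱼ)cⱼ(x − x̃ⱼ)ᵀ = −2w CᵀKD, divergence = tr J,
2D curl = ∂f₂/∂x₁ − ∂f₁/∂x₂ (3-vector in 3D), acceleration a = Jv,
curvature κ = (Jv(v·v) − v(v·Jv))/‖v‖⁴.  The equivalent 2D cross-product
form κ = v×(Jv×v)/‖v‖⁴ is computed alongside and asserted to agree to 10⁻¹⁰
(the BAC−CAB identity); curvature is reported missing where ‖v‖ = 0.  The
gene-space Jacobian G = QJQᵀ is materialized per requested (effector,
regulator) pair only — Q being the genes×k PCA loading matrix — to avoid the
d² blow-up.  Cluster averages for rankings use inlier cells (pᵢ ≥ 0.5) by
default; ranking ties break by gene identifier.  Hill-derivative fits reduce
the per-cell (expression, Jacobian) cloud to 20 equal-count bins and fit the
derivative of an activating or inhibitory Hill function weighted by inverse
bin standard deviation; the degradation term γ is fitted only for
self-interactions and fixed to 0 for cross-interactions.

Validation of the analytic operators against finite differences uses
fourth-order central differences with step 10⁻³ and a mixed tolerance (each
probe's denominator floored at 10⁻³ of the quantity's scale over the probe
set).  Both choices are about the *oracle*: near-interpolating kernel fits
carry large, cancelling coefficients, so a single field evaluation has
absolute noise around 10⁻¹⁰, which first-order-in-1/h FD amplifies; and a
purely relative error is meaningless at probes where the true quantity is
itself at the numerical noise floor (e.g. curvature on a nearly straight
streamline).

## Topology

Fixed points are found by `fsolve` from Latin-hypercube seeds (25 by
default) over a box containing the data, accepted when ‖f(x*)‖ < 10⁻⁶,
deduplicated within 10⁻² of the domain diagonal, and classified by the signs
of the real parts of the Jacobian eigenvalues.  Confidence is
exp(−dist(x*, nearest datum)/ℓ) with ℓ the mean kNN distance of the data — a
smooth proxy for "how far from any observed cell" the root sits.

Nullclines are traced by pseudo-arclength continuation: from a point p₀ with
tangent v₀, the next vertex solves {f_c(p₁) = 0, (p₁ − p₀)·v₀ = ε}.  The
first tangent is aligned with the zero set (perpendicular to the component's
gradient), with a seeded random draw choosing the branch direction; a purely
random first tangent stalls whenever it lands nearly perpendicular to the
curve.

Trajectories use adaptive Runge–Kutta (`solve_ivp`, rtol 10⁻⁷), backward
integration negates the field, and blow-up beyond 10× a domain bound
truncates with a flag.  Limit-cycle trimming splits the trajectory into k = 4
intervals and removes the last one while the FFT magnitude spectra of the
last two intervals differ by less than 0.05 per point, iterating.

Fate probabilities select the low-speed tail of a trajectory (speed below
the 5th percentile by default), move the selection window backwards until
every point is within distance_threshold × median nearest-neighbor distance
of an observed cell, and for each group score
1 − (#{group-specific second-nearest distances beyond threshold} +
move-back steps)/(#selected + move-back steps).  Second-nearest cells are
used to be robust to single stray cells; the rank is configurable.

Pseudotime solves a discrete Hodge-style least squares: each kNN edge
carries an antisymmetrized flow equal to the cosine similarity between the
cells' velocities and the edge displacement, and the potential φ minimizes
‖grad φ − flow‖² (sparse LSQR, mean-anchored gauge), shifted to minimum 0
per connected component.  A pure rotation field has zero potential — the
curl component carries all the flow — which the tests verify.

## Least action paths and perturbation

The discrete action over a path P = {x₀ … x_n} with step Δt is
S = (1/2D)Σₖ‖vₖ − f(yₖ)‖²Δt, with vₖ = (xₖ − xₖ₋₁)/Δt, midpoints
yₖ = (xₖ₋₁ + xₖ)/2, and diffusion constant D (= σ²/2; default 1, since
absolute rates are only known up to a constant anyway).  The optimal step
for a fixed path is the closed form Δt* = √(Σ‖dₖ‖²/Σ‖f(yₖ)‖²).  The path
gradient used by the quasi-Newton (L-BFGS-B) inner minimization is the exact
derivative of this action: with residuals rₖ = vₖ − f(yₖ),

∂S/∂xₖ = (1/D)(rₖ − rₖ₊₁) − (Δt/2D)(J(yₖ)ᵀrₖ + J(yₖ₊₁)ᵀrₖ₊₁),

verified against finite differences at every optimization start (the run
aborts on disagreement, which would signal an implementation error).  The
outer loop alternates Δt and path minimization and stops when the action
changes by less than 1% — with this tolerance the alternation settles in two
or three iterations; the two coordinate blocks are strongly coupled, so a
much tighter outer tolerance buys third-digit action improvements at the
cost of ten-plus further sweeps.  Initialization interpolates the shortest
path on the kNN graph of the data (falling back to a straight line).  The
fastest LAP re-optimizes at 20 log-spaced fixed traversal times in
[T*/20, T*], cubic-spline interpolates the normalized action-vs-time curve,
and takes the time closest to T* whose curvature exceeds 10% of the maximum.
Relative transition rates are exp(−S*) and MFPT their reciprocal, both up to
an unestimated proportionality constant.

Gene MSD along a path is Σ_t (y_i(t) − y_i(0))² over the path's points
(Δt is constant along a LAP, so point index and time parametrization give
the same ranking); the TF priority score is 1 − R/#TF.

In-silico perturbations map a gene-space perturbation Δy into the field
space as Δx = Qᵀ(Δy − μ), amplify by c, propagate Δf = J(x)Δx per cell and
map back as Δg = QΔf + μ.  The μ-subtraction is applied exactly as specified
even though a difference vector arguably needs no centering; `centered=False`
disables it.  With identity loadings and zero center the two conventions
coincide, which is the configuration of all bundled benchmarks.

## Synthetic data

`simulate_expression` runs an exact stochastic simulation (Gillespie) of the
two-state promoter with transcription, optional splicing, degradation and a
labeling window in which each newly born molecule is labeled with
probability ρ.  Cells are burned in for 10/γ time units before labeling
(enough for the slowest first-order mode to relax), then labeled per design:
one-shot (single window), kinetics (cells split across labeling durations),
degradation (labeling throughout burn-in so the chase starts fully labeled).
Exact SSA is used rather than tau-leaping: copy numbers are small and
correctness matters more than speed at these scales.  The inactive-state
transcription rate defaults to 0.

`toggle_field` is the two-gene mutual-inhibition/self-activation motif
f₁ = a₁x₁ⁿ/(K₁ⁿ + x₁ⁿ) + b₁K₁ⁿ/(K₁ⁿ + x₂ⁿ) − x₁ (symmetrically for f₂),
defaults a = b = K = 1, n = 4, on the domain [0, 2.5]²: one saddle at (1, 1)
with eigenvalues ±1 and two off-diagonal attractors.  `sample_field` draws
uniform states with true velocities and optional Gaussian velocity noise
scaled to the mean speed; the standard benchmark uses 5,000 samples.

**What the benchmarks do not show.**  The simulator produces statistically
homogeneous populations of a single gene (or independent genes): it
exercises the estimators' kinetic laws exactly but not cross-gene
covariance, cell-type heterogeneity, library-size variation or dropout, so
passing recovery tests bounds estimator bias under the model, not under real
data artifacts.  The toggle-switch field is two-dimensional and noiseless at
source; reconstruction quality in high-dimensional PCA spaces with
correlated velocity errors will be lower than the benchmark numbers.  Burst
statistics rely on the burst-limit NB approximation (see above).  Problem
sizes throughout (1,000–5,000 cells, 2,000–5,000 field samples) were chosen
as the smallest scales at which the Monte-Carlo error is comfortably below
the tolerances being tested.

## Known limitations

* No protein layer, no time-varying or stochastic (SDE) field learning, no
  batch correction; velocity samples with strong hidden-variable effects
  violate the single-valued-field assumption and degrade the fit.
* Nullcline tracing and curl are limited to 2D (curl also 3D).
* The scEU-seq mixture (pulse-while-chase) design and read-level
  quantification from alignments are out of scope; inputs are count
  matrices.
* Fixed-point confidence and the fate-probability move-back rule are
  heuristics; their scores are comparative, not calibrated probabilities.
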
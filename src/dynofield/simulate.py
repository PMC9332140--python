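"""Synthetic data generators.

Two generators back the rest of the package:

* an exact stochastic-simulation (Gillespie) model of bursty transcription,
  splicing and degradation with a 4sU-style labeling window, producing layered
  count matrices for one-shot / kinetics / degradation labeling designs;
* the canonical two-gene toggle-switch ODE (mutual inhibition plus
  self-activation) used as the ground-truth vector field for reconstruction,
  differential-geometry and least-action-path benchmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import LayeredMatrix

__all__ = [
    "GillespieParams",
    "ToggleParams",
    "simulate_expression",
    "toggle_field",
    "toggle_jacobian",
    "sample_field",
]


@dataclass
class GillespieParams:
    """Rates of the two-state promoter transcription/splicing/degradation model.

    The promoter switches between an active state A (transcribing at ``alpha``)
    and an inactive state I (transcribing at ``alpha_off``) with activation rate
    ``k_on`` (I -> A) and inactivation rate ``k_off`` (A -> I).  Transcripts are
    spliced at rate ``beta`` (only if ``splicing``) and degraded at rate
    ``gamma``.  During a labeling window each newly born molecule is labeled
    with probability ``rho``.  All rates are per hour.
    """

    k_on: float = 1.0
    k_off: float = 4.0
    alpha: float = 20.0
    alpha_off: float = 0.0
    beta: float = 2.0
    gamma: float = 0.5
    rho: float = 1.0
    splicing: bool = True
    n_cells: int = 1000
    seed: int = 0
    # burn-in before labeling, in multiples of 1/gamma
    burn_in_relax: float = 10.0


@dataclass
class ToggleParams:
    """Parameters of the two-gene toggle switch: self-activation strength a,
    basal/inhibition strength b, Hill threshold K, Hill coefficient n; linear
    degradation with unit rate constant."""

    a1: float = 1.0
    a2: float = 1.0
    b1: float = 1.0
    b2: float = 1.0
    K1: float = 1.0
    K2: float = 1.0
    n: float = 4.0


# ---------------------------------------------------------------------------
# Gillespie simulator
# ---------------------------------------------------------------------------


def _ssa_cell(rng, p: GillespieParams, t_end: float, labeling: tuple[float, float] | None,
              state=None):
    """Exact SSA for one cell from time 0 to t_end.

    ``state`` is (promoter_active, [ul, uu, sl, su]) or (promoter, [l, o]) in the
    no-splicing case; molecules born inside the half-open labeling interval are
    labeled with probability rho.  Returns the final state.
    """
    if state is None:
        active = rng.random() < p.k_on / (p.k_on + p.k_off)
        counts = np.zeros(4 if p.splicing else 2, dtype=np.int64)
    else:
        active, counts = state
        counts = counts.copy()
    t = 0.0
    t0_lab, t1_lab = labeling if labeling is not None else (math.inf, math.inf)
    while True:
        if p.splicing:
            ul, uu, sl, su = counts
            a_switch = p.k_off if active else p.k_on
            a_txn = p.alpha if active else p.alpha_off
            a_spl = p.beta * (ul + uu)
            a_deg = p.gamma * (sl + su)
            a_tot = a_switch + a_txn + a_spl + a_deg
        else:
            l, o = counts
            a_switch = p.k_off if active else p.k_on
            a_txn = p.alpha if active else p.alpha_off
            a_spl = 0.0
            a_deg = p.gamma * (l + o)
            a_tot = a_switch + a_txn + a_deg
        if a_tot <= 0.0:
            break
        t += rng.exponential(1.0 / a_tot)
        if t >= t_end:
            break
        r = rng.random() * a_tot
        if r < a_switch:
            active = not active
        elif r < a_switch + a_txn:
            labeled = (t0_lab <= t < t1_lab) and (rng.random() < p.rho)
            if p.splicing:
                counts[0 if labeled else 1] += 1
            else:
                counts[0 if labeled else 1] += 1
        elif r < a_switch + a_txn + a_spl:
            # splice one unspliced molecule chosen uniformly
            ul, uu = counts[0], counts[1]
            if rng.random() * (ul + uu) < ul:
                counts[0] -= 1
                counts[2] += 1
            else:
                counts[1] -= 1
                counts[3] += 1
        else:
            if p.splicing:
                sl, su = counts[2], counts[3]
                if rng.random() * (sl + su) < sl:
                    counts[2] -= 1
                else:
                    counts[3] -= 1
            else:
                l, o = counts
                if rng.random() * (l + o) < l:
                    counts[0] -= 1
                else:
                    counts[1] -= 1
    return active, counts


def simulate_expression(params: GillespieParams, design: str = "one_shot",
                        t: float | list[float] = 2.0,
                        n_genes: int = 1, gene_params: list[GillespieParams] | None = None,
                        ) -> LayeredMatrix:
    """Simulate labeled scRNA-seq counts with the exact SSA.

    design
        ``one_shot``    burn-in to stationarity, then a single labeling window
                        of duration ``t`` (scalar).
        ``kinetics``    cells split evenly across the labeling durations in
                        ``t`` (list); each cell labeled for its own duration.
        ``degradation`` extended labeling (all molecules labeled) followed by a
                        chase of duration drawn from ``t`` (list, may include 0).

    Returns a :class:`LayeredMatrix` with layers ``u``, ``s``, ``l``, ``r``
    (``u``/``s`` only present when splicing is modeled) and per-cell
    ``label_time``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    times = np.atleast_1d(np.asarray(t, dtype=float))
    if design == "one_shot" and times.size != 1:
        raise ValueError("one_shot design takes a single labeling duration")
    per_cell_t = np.resize(np.repeat(times, max(1, p.n_cells // times.size)), p.n_cells)
    per_cell_t.sort()

    gene_list = gene_params if gene_params is not None else [p] * n_genes
    n_layers = 4 if p.splicing else 2
    out = {name: np.zeros((p.n_cells, len(gene_list)))
           for name in (("ul", "uu", "sl", "su") if p.splicing else ("l", "o"))}

    burn = p.burn_in_relax / p.gamma if p.gamma > 0 else 0.0
    for g, gp in enumerate(gene_list):
        for i in range(p.n_cells):
            ti = per_cell_t[i]
            if design in ("one_shot", "kinetics"):
                # relax, then label for ti
                state = _ssa_cell(rng, gp, burn, labeling=None)
                state = _ssa_cell(rng, gp, ti, labeling=(0.0, ti), state=state)
            elif design == "degradation":
                # label throughout relaxation so everything is labeled, then chase
                state = _ssa_cell(rng, gp, burn, labeling=(0.0, math.inf))
                state = _ssa_cell(rng, gp, ti, labeling=None, state=state)
            else:
                raise ValueError(f"unknown design {design!r}")
            _, counts = state
            if gp.splicing:
                out["ul"][i, g], out["uu"][i, g] = counts[0], counts[1]
                out["sl"][i, g], out["su"][i, g] = counts[2], counts[3]
            else:
                out["l"][i, g], out["o"][i, g] = counts[0], counts[1]

    cell_ids = [f"cell{i}" for i in range(p.n_cells)]
    gene_ids = [f"gene{g}" for g in range(len(gene_list))]
    if p.splicing:
        layers = {
            "u": out["ul"] + out["uu"],
            "s": out["sl"] + out["su"],
            "l": out["ul"] + out["sl"],
            "r": out["ul"] + out["uu"] + out["sl"] + out["su"],
        }
        extra = {"ul": out["ul"], "uu": out["uu"], "sl": out["sl"], "su": out["su"]}
    else:
        layers = {"l": out["l"], "r": out["l"] + out["o"]}
        extra = {}
    lm = LayeredMatrix(
        layers=layers,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        label_time=per_cell_t,
        experiment_type=design,
    )
    lm.extra_layers = extra
    return lm


# ---------------------------------------------------------------------------
# Toggle-switch benchmark field
# ---------------------------------------------------------------------------


def toggle_field(x, params: ToggleParams | None = None):
    """Velocity of the two-gene toggle switch at state(s) ``x`` (shape (2,) or (n, 2)).

    f1 = a1*x1^n/(K1^n + x1^n) + b1*K1^n/(K1^n + x2^n) - x1 and symmetrically
    for f2; with the default a = b = K = 1, n = 4 the diagonal point (1, 1)
    is a saddle and the two off-diagonal stable states are attractors.
    """
    p = params or ToggleParams()
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    x1, x2 = X[:, 0], X[:, 1]
    n = p.n
    f1 = p.a1 * x1**n / (p.K1**n + x1**n) + p.b1 * p.K1**n / (p.K1**n + x2**n) - x1
    f2 = p.a2 * x2**n / (p.K2**n + x2**n) + p.b2 * p.K2**n / (p.K2**n + x1**n) - x2
    V = np.stack([f1, f2], axis=1)
    return V[0] if single else V


def toggle_jacobian(x, params: ToggleParams | None = None):
    """Analytic Jacobian of :func:`toggle_field` at one state or a batch."""
    p = params or ToggleParams()
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    x1, x2 = X[:, 0], X[:, 1]
    n = p.n

    def hill_act_deriv(a, K, v):
        return a * n * K**n * v**(n - 1) / (K**n + v**n) ** 2

    def hill_inh_deriv(b, K, v):
        return -b * n * K**n * v**(n - 1) / (K**n + v**n) ** 2

    J = np.empty((X.shape[0], 2, 2))
    J[:, 0, 0] = hill_act_deriv(p.a1, p.K1, x1) - 1.0
    J[:, 0, 1] = hill_inh_deriv(p.b1, p.K1, x2)
    J[:, 1, 0] = hill_inh_deriv(p.b2, p.K2, x1)
    J[:, 1, 1] = hill_act_deriv(p.a2, p.K2, x2) - 1.0
    return J[0] if single else J


def sample_field(params: ToggleParams | None = None, n: int = 5000,
                 domain: tuple[float, float] = (0.0, 2.5), noise_sd: float = 0.0,
                 seed: int = 0):
    """Uniformly sample states in ``domain``^2 with their true toggle-switch
    velocities, optionally adding Gaussian velocity noise whose s.d. is
    ``noise_sd`` times the mean speed.  Returns (X, V)."""
    p = params or ToggleParams()
    rng = np.random.default_rng(seed)
    lo, hi = domain
    X = rng.uniform(lo, hi, size=(n, 2))
    V = toggle_field(X, p)
    if noise_sd > 0:
        scale = noise_sd * float(np.mean(np.linalg.norm(V, axis=1)))
        V = V + rng.normal(0.0, scale, size=V.shape)
    return X, V
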
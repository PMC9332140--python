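"""Kinetic rate-constant and RNA-velocity estimation.

Supports conventional (splicing-based) experiments and the three metabolic
labeling designs:

* conventional: steady-state regression u = gamma~ s (gamma~ = gamma/beta is
  the degradation rate relative to splicing), generalized method of moments
  (stochastic splicing and negative-binomial variants) on kNN-smoothed moments;
  conventional velocity v = u - gamma~ s.
* one-shot labeling: slope k from l = k r on extreme cells, gamma =
  -ln(1 - k)/t, absolute total velocity r. = (gamma/k) l - gamma r.
* kinetics (pulse): the two-step estimator (per-time slopes k(t), then
  -ln(1 - k) regressed through the origin on t) and nonlinear curve fits of
  the closed-form solutions of the labeling ODEs.
* degradation (chase): first-order decay fits l = l0 exp(-gamma t) (and the
  spliced/unspliced labeled solutions when splicing is modeled).

Relative and absolute scales are unified through beta = gamma/gamma~, after
which absolute spliced, unspliced and new-RNA velocities follow.  Burst
statistics, the binomial mixture model for labeled-fraction quantification,
and velocity confidence metrics live here too.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as _field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import binom, qmc

from .datamodel import LayeredMatrix, NeighborGraph, knn_graph

__all__ = [
    "MomentSet",
    "LabelingDesign",
    "KineticEstimate",
    "BurstStats",
    "MixtureQuantification",
    "smooth_moments",
    "extreme_cell_mask",
    "fit_gamma_tilde_ss",
    "fit_gamma_tilde_gmm",
    "fit_one_shot",
    "fit_two_step",
    "fit_curve",
    "guesstimate_ranges",
    "unify_beta",
    "velocities",
    "labeling_bias",
    "burst_stats",
    "mixture_likelihood",
    "fit_mixture_em",
    "cell_velocity_confidence",
    "gene_velocity_confidence",
    "r_squared",
    "gaussian_loglik",
]


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------


@dataclass
class MomentSet:
    """kNN-smoothed first, second and mixed moments, each cells x genes."""

    u: np.ndarray | None = None
    s: np.ndarray | None = None
    l: np.ndarray | None = None
    r: np.ndarray | None = None
    uu: np.ndarray | None = None     # <u^2>
    ss: np.ndarray | None = None     # <s^2>
    rr: np.ndarray | None = None     # <r^2>
    us: np.ndarray | None = None     # <us>


def smooth_moments(lm: LayeredMatrix, g: NeighborGraph) -> MomentSet:
    """First/second/mixed moments as simple averages over each cell's neighbor
    set (neighbors plus the cell itself)."""
    n = lm.n_cells
    hood = np.column_stack([np.arange(n), g.indices])     # include self

    def avg(M):
        return M[hood].mean(axis=1)

    ms = MomentSet()
    for name in ("u", "s", "l", "r"):
        if name in lm.layers:
            setattr(ms, name, avg(lm.layers[name]))
    if "u" in lm.layers:
        ms.uu = avg(lm.layers["u"] ** 2)
    if "s" in lm.layers:
        ms.ss = avg(lm.layers["s"] ** 2)
    if "r" in lm.layers:
        ms.rr = avg(lm.layers["r"] ** 2)
    if "u" in lm.layers and "s" in lm.layers:
        ms.us = avg(lm.layers["u"] * lm.layers["s"])
    return ms


def extreme_cell_mask(a: np.ndarray, b: np.ndarray, quantile: float = 0.05,
                      min_cells: int = 10) -> np.ndarray:
    """Per-gene mask of 'extreme' cells: the top ``quantile`` fraction by
    a + b (at least ``min_cells``).  Shape cells x genes, boolean."""
    total = a + b
    n = total.shape[0]
    k = max(min_cells, int(np.ceil(quantile * n)))
    k = min(k, n)
    order = np.argsort(-total, axis=0, kind="stable")
    mask = np.zeros_like(total, dtype=bool)
    rows = order[:k]
    cols = np.broadcast_to(np.arange(total.shape[1]), rows.shape)
    mask[rows, cols] = True
    return mask


# ---------------------------------------------------------------------------
# designs / results
# ---------------------------------------------------------------------------


@dataclass
class LabelingDesign:
    strategy: str                       # one_shot | kinetics | degradation
    time_points: np.ndarray
    rho: float = 1.0

    def __post_init__(self):
        self.time_points = np.atleast_1d(np.asarray(self.time_points, dtype=float))
        if self.strategy == "one_shot" and self.time_points.size != 1:
            raise ValueError("one_shot design has a single time point")
        if self.rho <= 0:
            raise ValueError("labeling correction coefficient rho must be > 0")


@dataclass
class KineticEstimate:
    """Per-gene rate constants; alpha is per cell x gene where available."""

    gene_ids: list[str]
    gamma_tilde: np.ndarray | None = None    # dimensionless gamma/beta
    gamma: np.ndarray | None = None          # 1/h
    beta: np.ndarray | None = None           # 1/h
    k: np.ndarray | None = None              # regression slope(s)
    alpha: np.ndarray | None = None          # molecules/h, cells x genes
    r2: np.ndarray | None = None
    loglik: np.ndarray | None = None
    ok: np.ndarray | None = None             # per-gene fit accepted
    method: str = ""

    @property
    def half_life(self) -> np.ndarray:
        return np.log(2.0) / self.gamma


@dataclass
class BurstStats:
    phi: np.ndarray                  # reciprocal dispersion
    burst_frequency: np.ndarray      # 1/h
    burst_size: np.ndarray           # molecules
    ok: np.ndarray


@dataclass
class MixtureQuantification:
    p_e: float
    p_c: float
    pi_g: float
    loglik: float
    n_iter: int


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 = 1 - sum (x - y)^2 / sum (x - mean x)^2 for data x, predictions y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if np.allclose(x, y) else 0.0
    return 1.0 - float(np.sum((x - y) ** 2)) / ss_tot


def gaussian_loglik(data: list[np.ndarray], pred: list[np.ndarray]) -> float:
    """Gaussian goodness of fit across species, each normalized by its data
    maximum: -(n/2)ln 2pi - sum_i ln sd(x_i) - sum_i 0.5 ||x_i - y_i||^2."""
    total_n = sum(np.asarray(x).size for x in data)
    ll = -0.5 * total_n * math.log(2.0 * math.pi)
    for x, y in zip(data, pred):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        scale = np.abs(x).max()
        if scale > 0:
            x, y = x / scale, y / scale
        sd = x.std()
        ll -= math.log(sd) if sd > 0 else 0.0
        ll -= 0.5 * float(np.sum((x - y) ** 2))
    return ll


# ---------------------------------------------------------------------------
# conventional (splicing) estimators
# ---------------------------------------------------------------------------


def fit_gamma_tilde_ss(ms: MomentSet, extreme_quantile: float = 0.05,
                       min_cells: int = 10) -> KineticEstimate:
    """Steady-state slope per gene: zero-intercept LS of u on s over extreme
    cells, gamma~ = sum u s / sum s^2."""
    u, s = ms.u, ms.s
    if u is None or s is None:
        raise ValueError("u and s moments required")
    n_genes = u.shape[1]
    gamma_tilde = np.full(n_genes, np.nan)
    r2 = np.full(n_genes, np.nan)
    ok = np.zeros(n_genes, dtype=bool)
    mask = extreme_cell_mask(u, s, extreme_quantile, min_cells)
    for j in range(n_genes):
        m = mask[:, j]
        sj, uj = s[m, j], u[m, j]
        denom = float(np.sum(sj**2))
        if m.sum() < min(5, min_cells) or denom == 0:
            continue
        gamma_tilde[j] = float(np.sum(uj * sj)) / denom
        r2[j] = r_squared(uj, gamma_tilde[j] * sj)
        ok[j] = True
    return KineticEstimate(gene_ids=[f"g{j}" for j in range(n_genes)],
                           gamma_tilde=gamma_tilde, r2=r2, ok=ok, method="ss")


def fit_gamma_tilde_gmm(ms: MomentSet, variant: str = "stochastic",
                        extreme_quantile: float = 0.05, min_cells: int = 10,
                        weights: np.ndarray | None = None) -> KineticEstimate:
    """Generalized-method-of-moments slope using second moments.

    stochastic: weighted LS over the stacked moment conditions
    x = (<s>, 2<s^2> - <s>), y = (<u>, <u> + 2<us>), gamma~ = sum xᵀWy / sum xᵀWx
    (W identity by default).  negbin: solve {gamma~<s> = <u>,
    gamma~^2 Var(s) = gamma~<u> - phi <u>^2} with phi = (Var(s) - <s>)/<s>^2 by
    nonlinear least squares; underdispersed genes fall back to stochastic.
    """
    u, s, uu_, ss_, us_ = ms.u, ms.s, ms.uu, ms.ss, ms.us
    if any(v is None for v in (u, s, ss_, us_)):
        raise ValueError("first, second and mixed moments required")
    n_genes = u.shape[1]
    gamma_tilde = np.full(n_genes, np.nan)
    ok = np.zeros(n_genes, dtype=bool)
    mask = extreme_cell_mask(u, s, extreme_quantile, min_cells)
    W = np.eye(2) if weights is None else np.asarray(weights, dtype=float)
    for j in range(n_genes):
        m = mask[:, j]
        if m.sum() < min(5, min_cells):
            continue
        x = np.stack([s[m, j], 2 * ss_[m, j] - s[m, j]], axis=1)     # n x 2
        y = np.stack([u[m, j], u[m, j] + 2 * us_[m, j]], axis=1)
        num = float(np.einsum("ni,ij,nj->", x, W, y))
        den = float(np.einsum("ni,ij,nj->", x, W, x))
        if den == 0:
            continue
        g_sto = num / den
        if variant == "stochastic":
            gamma_tilde[j] = g_sto
        elif variant == "negbin":
            var_s = ss_[m, j] - s[m, j] ** 2
            mean_s = s[m, j]
            with np.errstate(divide="ignore", invalid="ignore"):
                phis = (var_s - mean_s) / mean_s**2
            phis = phis[np.isfinite(phis)]
            phi = float(np.mean(phis)) if phis.size else -1.0
            if phi <= 0:
                warnings.warn(f"gene {j}: underdispersed; negbin falls back to "
                              "stochastic")
                gamma_tilde[j] = g_sto
            else:
                uj = u[m, j]

                def resid(theta):
                    gt = theta[0]
                    return np.concatenate([
                        gt * mean_s - uj,
                        gt**2 * var_s - gt * uj + phi * uj**2])

                sol = least_squares(resid, x0=[max(g_sto, 1e-6)],
                                    bounds=([1e-12], [np.inf]))
                gamma_tilde[j] = float(sol.x[0])
        else:
            raise ValueError(f"unknown variant {variant!r}")
        ok[j] = np.isfinite(gamma_tilde[j])
    return KineticEstimate(gene_ids=[f"g{j}" for j in range(n_genes)],
                           gamma_tilde=gamma_tilde, ok=ok, method=f"gmm-{variant}")


# ---------------------------------------------------------------------------
# labeling estimators
# ---------------------------------------------------------------------------


def _slope_lr(lvals, rvals):
    denom = float(np.sum(rvals**2))
    return float(np.sum(lvals * rvals)) / denom if denom > 0 else np.nan


def _slope_negbin(lvals, rvals):
    var_r = float(np.var(rvals))
    mean_r = float(np.mean(rvals))
    if mean_r <= 0:
        return np.nan
    phi = (var_r - mean_r) / mean_r**2
    k0 = _slope_lr(lvals, rvals)
    if phi <= 0 or not np.isfinite(k0):
        return k0

    def resid(theta):
        kk = theta[0]
        return np.array([kk * mean_r - np.mean(lvals),
                         kk**2 * var_r - kk * np.mean(lvals)
                         + phi * np.mean(lvals) ** 2])

    sol = least_squares(resid, x0=[min(max(k0, 1e-6), 0.999)],
                        bounds=([1e-9], [1.0]))
    return float(sol.x[0])


def fit_one_shot(lm: LayeredMatrix, design: LabelingDesign,
                 use_negbin: bool = False, extreme_quantile: float = 0.05,
                 min_cells: int = 10,
                 ms: MomentSet | None = None) -> KineticEstimate:
    """One-shot labeling: slope k of l = k r on extreme cells, then
    gamma = -ln(1 - k)/t; per-cell alpha = gamma l/(1 - e^(-gamma t))."""
    L = ms.l if ms is not None and ms.l is not None else lm.layers["l"]
    R = ms.r if ms is not None and ms.r is not None else lm.layers["r"]
    t = float(design.time_points[0])
    n_genes = L.shape[1]
    k_arr = np.full(n_genes, np.nan)
    gamma = np.full(n_genes, np.nan)
    r2 = np.full(n_genes, np.nan)
    ok = np.zeros(n_genes, dtype=bool)
    mask = extreme_cell_mask(L, R, extreme_quantile, min_cells)
    for j in range(n_genes):
        m = mask[:, j]
        if m.sum() < 5:
            continue
        k = (_slope_negbin if use_negbin else _slope_lr)(L[m, j], R[m, j])
        if not np.isfinite(k) or k <= 0 or k >= 1:
            continue
        k_arr[j] = k
        gamma[j] = -math.log1p(-k) / t
        r2[j] = r_squared(L[m, j], k * R[m, j])
        ok[j] = True
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = gamma[None, :] * L / (1.0 - np.exp(-gamma[None, :] * t))
    return KineticEstimate(gene_ids=list(lm.gene_ids), gamma=gamma, k=k_arr,
                           alpha=alpha, r2=r2, ok=ok, method="one_shot")


def fit_two_step(lm: LayeredMatrix, design: LabelingDesign,
                 use_negbin: bool = False, extreme_quantile: float = 0.05,
                 min_cells: int = 10) -> KineticEstimate:
    """Two-step kinetics estimator.

    Step 1: per labeling duration, slope k(t) of l = k r on extreme cells.
    Step 2: gamma is the through-origin slope of -ln(1 - k) on t; the step-2
    R^2 flags genes whose slopes do not grow with labeling time.  With a single
    time point this reduces exactly to the one-shot estimator.
    """
    L, R = lm.layers["l"], lm.layers["r"]
    times = np.unique(lm.label_time)
    n_genes = L.shape[1]
    gamma = np.full(n_genes, np.nan)
    r2 = np.full(n_genes, np.nan)
    ok = np.zeros(n_genes, dtype=bool)
    k_per_t = np.full((times.size, n_genes), np.nan)
    for ti, t in enumerate(times):
        cells = lm.label_time == t
        Lt, Rt = L[cells], R[cells]
        mask = extreme_cell_mask(Lt, Rt, extreme_quantile, min_cells)
        for j in range(n_genes):
            m = mask[:, j]
            if m.sum() < 5:
                continue
            k = (_slope_negbin if use_negbin else _slope_lr)(Lt[m, j], Rt[m, j])
            if np.isfinite(k) and 0 < k < 1:
                k_per_t[ti, j] = k
    for j in range(n_genes):
        valid = np.isfinite(k_per_t[:, j])
        if times.size == 1:
            if valid[0]:
                gamma[j] = -math.log1p(-k_per_t[0, j]) / times[0]
                r2[j] = 1.0
                ok[j] = True
            continue
        if valid.sum() < 2:
            continue
        tv = times[valid]
        yv = -np.log1p(-k_per_t[valid, j])
        denom = float(np.sum(tv**2))
        if denom == 0:
            continue
        gamma[j] = float(np.sum(tv * yv)) / denom
        r2[j] = r_squared(yv, gamma[j] * tv)
        ok[j] = gamma[j] > 0
    # per-cell slope from each cell's own labeling duration
    k_cell = np.full((lm.n_cells, n_genes), np.nan)
    for ti, t in enumerate(times):
        k_cell[lm.label_time == t] = k_per_t[ti]
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = gamma[None, :] * L / (1.0 - np.exp(-gamma[None, :]
                                                   * lm.label_time[:, None]))
    est = KineticEstimate(gene_ids=list(lm.gene_ids), gamma=gamma, k=k_cell,
                          alpha=alpha, r2=r2, ok=ok, method="two_step")
    est.k_per_time = k_per_t
    est.time_points = times
    return est


# ---------------------------------------------------------------------------
# curve fitting
# ---------------------------------------------------------------------------


def _kinetics_model2(t, alpha, gamma, rho=1.0):
    return rho * alpha / gamma * (1.0 - np.exp(-gamma * t))


def _kinetics_model3(t, alpha, beta, gamma, rho=1.0):
    """(u_l, s_l) solutions with zero initial labeled RNA."""
    ul = rho * alpha / beta * (1.0 - np.exp(-beta * t))
    if abs(beta - gamma) / max(gamma, 1e-300) < 1e-3:
        # degenerate beta ~ gamma branch of the spliced-labeled solution
        sl = rho * alpha / gamma * (1.0 - np.exp(-gamma * t)) \
            - rho * alpha * t * np.exp(-gamma * t)
    else:
        sl = rho * alpha / gamma * (1.0 - np.exp(-gamma * t)) \
            + rho * alpha / (gamma - beta) * (np.exp(-gamma * t) - np.exp(-beta * t))
    return ul, sl


def _degradation_model2(t, l0, gamma):
    return l0 * np.exp(-gamma * t)


def _degradation_model3(t, ul0, sl0, beta, gamma):
    ul = ul0 * np.exp(-beta * t)
    if abs(beta - gamma) / max(gamma, 1e-300) < 1e-3:
        sl = sl0 * np.exp(-gamma * t) + beta * ul0 * t * np.exp(-gamma * t)
    else:
        sl = sl0 * np.exp(-gamma * t) - beta * ul0 / (gamma - beta) * (
            np.exp(-gamma * t) - np.exp(-beta * t))
    return ul, sl


def guesstimate_ranges(lm: LayeredMatrix, design: LabelingDesign,
                       gene: int = 0) -> dict[str, tuple[float, float, float]]:
    """Order-of-magnitude initial values theta0 per parameter with search
    range (0, 100 theta0); zero/invalid denominators fall back to theta0 = 1.

    Kinetics: alpha ~ mean(l/t); gamma ~ (1/t) ln(o_0/o_t);
    beta ~ (1/t) ln(u_u(0)/u_u(t)).  Degradation: gamma ~ -(1/t) ln(l_t/l_0)
    (sign-corrected positive), beta similarly from u_l; initial conditions are
    means at the earliest chase time.
    """
    t = lm.label_time
    out = {}

    def entry(theta0, flag=False):
        theta0 = float(theta0) if np.isfinite(theta0) and theta0 > 0 else 1.0
        e = (theta0, 0.0, 100.0 * theta0)
        return e

    times = np.unique(t)
    if design.strategy == "kinetics":
        L = lm.layers["l"][:, gene]
        with np.errstate(divide="ignore", invalid="ignore"):
            out["alpha"] = entry(np.nanmean(np.where(t > 0, L / t, np.nan)))
        o = lm.layers["r"][:, gene] - L
        o_by_t = np.array([o[t == tv].mean() for tv in times])
        span = times[-1] - times[0]
        if span > 0 and o_by_t[0] > 0 and o_by_t[-1] > 0:
            out["gamma"] = entry(math.log(o_by_t[0] / o_by_t[-1]) / span)
        else:
            out["gamma"] = entry(np.nan)
        if "ul" in lm.extra_layers and "uu" in lm.extra_layers:
            uu = lm.extra_layers["uu"][:, gene]
            uu_by_t = np.array([uu[t == tv].mean() for tv in times])
            if span > 0 and uu_by_t[0] > 0 and uu_by_t[-1] > 0:
                out["beta"] = entry(math.log(uu_by_t[0] / uu_by_t[-1]) / span)
            else:
                out["beta"] = entry(np.nan)
        else:
            out["beta"] = entry(np.nan)
    elif design.strategy == "degradation":
        L = lm.layers["l"][:, gene]
        l_by_t = np.array([L[t == tv].mean() for tv in times])
        span = times[-1] - times[0]
        if span > 0 and l_by_t[0] > 0 and l_by_t[-1] > 0:
            out["gamma"] = entry(abs(math.log(l_by_t[-1] / l_by_t[0])) / span)
        else:
            out["gamma"] = entry(np.nan)
        out["l0"] = entry(l_by_t[0])
        if "ul" in lm.extra_layers:
            ul = lm.extra_layers["ul"][:, gene]
            ul_by_t = np.array([ul[t == tv].mean() for tv in times])
            if span > 0 and ul_by_t[0] > 0 and ul_by_t[-1] > 0:
                out["beta"] = entry(abs(math.log(ul_by_t[-1] / ul_by_t[0])) / span)
            else:
                out["beta"] = entry(np.nan)
            out["ul0"] = entry(ul_by_t[0])
            if "sl" in lm.extra_layers:
                sl = lm.extra_layers["sl"][:, gene]
                out["sl0"] = entry(sl[t == times[0]].mean())
    else:
        raise ValueError("guesstimation applies to kinetics/degradation designs")
    return out


def fit_curve(lm: LayeredMatrix, design: LabelingDesign, model: str = "model2",
              weights: dict[str, float] | None = None, n_starts: int = 20,
              seed: int = 0, groups: np.ndarray | None = None) -> KineticEstimate:
    """Nonlinear least-squares fit of the closed-form labeling solutions.

    Fits per-gene means at each time point, minimizing the species-weighted
    sum of squares (labeled weighted 2:1 over unlabeled by default), with 20
    Latin-hypercube multi-starts over guesstimated ranges; best loss wins,
    ties broken by parameter-vector norm.  ``model2`` ignores splicing
    (parameters alpha, gamma for kinetics; l0, gamma for degradation);
    ``model3`` adds beta using the (u_l, s_l) layers.  ``groups`` fits a
    separate transcription rate per cell cluster (kinetics only).
    """
    strategy = design.strategy
    t = lm.label_time
    times = np.unique(t)
    n_genes = lm.n_genes
    gamma = np.full(n_genes, np.nan)
    beta = np.full(n_genes, np.nan)
    alpha_g = np.full(n_genes, np.nan)
    loglik = np.full(n_genes, np.nan)
    r2 = np.full(n_genes, np.nan)
    ok = np.zeros(n_genes, dtype=bool)
    rng = np.random.default_rng(seed)
    w_lab = (weights or {}).get("labeled", 2.0)
    w_unl = (weights or {}).get("unlabeled", 1.0)

    for j in range(n_genes):
        ranges = guesstimate_ranges(lm, design, gene=j)
        if strategy == "kinetics" and model == "model2":
            names = ["alpha", "gamma"]
            data = [np.array([lm.layers["l"][t == tv, j].mean() for tv in times])]

            def predict(theta):
                return [_kinetics_model2(times, theta[0], theta[1], design.rho)]
            wts = [w_lab]
        elif strategy == "kinetics" and model == "model3":
            names = ["alpha", "beta", "gamma"]
            ul = lm.extra_layers["ul"][:, j]
            sl = lm.extra_layers["sl"][:, j]
            data = [np.array([ul[t == tv].mean() for tv in times]),
                    np.array([sl[t == tv].mean() for tv in times])]

            def predict(theta):
                return list(_kinetics_model3(times, *theta, design.rho))
            wts = [w_lab, w_lab]
        elif strategy == "degradation" and model == "model2":
            names = ["l0", "gamma"]
            data = [np.array([lm.layers["l"][t == tv, j].mean() for tv in times])]

            def predict(theta):
                return [_degradation_model2(times, theta[0], theta[1])]
            wts = [w_lab]
        elif strategy == "degradation" and model == "model3":
            names = ["ul0", "sl0", "beta", "gamma"]
            ul = lm.extra_layers["ul"][:, j]
            sl = lm.extra_layers["sl"][:, j]
            data = [np.array([ul[t == tv].mean() for tv in times]),
                    np.array([sl[t == tv].mean() for tv in times])]

            def predict(theta):
                return list(_degradation_model3(times, *theta))
            wts = [w_lab, w_lab]
        else:
            raise ValueError(f"unsupported strategy/model: {strategy}/{model}")

        theta0 = np.array([ranges.get(nm, (1.0, 0.0, 100.0))[0] for nm in names])
        hi = np.array([ranges.get(nm, (1.0, 0.0, 100.0))[2] for nm in names])
        sampler = qmc.LatinHypercube(d=len(names),
                                     seed=int(rng.integers(2**31 - 1)))
        starts = qmc.scale(sampler.random(n_starts), 1e-6 * np.ones_like(hi), hi)
        starts = np.vstack([theta0, starts])

        def resid(theta):
            preds = predict(theta)
            return np.concatenate([np.sqrt(wv) * (d - p)
                                   for wv, d, p in zip(wts, data, preds)])

        best = None
        for x0 in starts:
            try:
                sol = least_squares(resid, x0=np.clip(x0, 1e-9, hi),
                                    bounds=(np.zeros(len(names)), hi))
            except Exception:
                continue
            key = (sol.cost, float(np.linalg.norm(sol.x)))
            if best is None or key < best[0]:
                best = (key, sol)
        if best is None:
            continue
        sol = best[1]
        params = dict(zip(names, sol.x))
        gamma[j] = params.get("gamma", np.nan)
        beta[j] = params.get("beta", np.nan)
        alpha_g[j] = params.get("alpha", np.nan)
        preds = predict(sol.x)
        loglik[j] = gaussian_loglik(data, preds)
        r2[j] = r_squared(np.concatenate(data), np.concatenate(preds))
        ok[j] = np.isfinite(gamma[j]) and gamma[j] > 0

    alpha = None
    if strategy == "kinetics":
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = gamma[None, :] * lm.layers["l"] / (
                1.0 - np.exp(-gamma[None, :] * t[:, None]))
    est = KineticEstimate(gene_ids=list(lm.gene_ids), gamma=gamma, beta=beta,
                          alpha=alpha, r2=r2, loglik=loglik, ok=ok,
                          method=f"curve-{model}")
    est.alpha_gene = alpha_g
    if groups is not None and strategy == "kinetics":
        est.alpha_by_group = _alpha_per_group(lm, gamma, groups)
    return est


def _alpha_per_group(lm, gamma, groups):
    t = lm.label_time
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_cell = gamma[None, :] * lm.layers["l"] / (
            1.0 - np.exp(-gamma[None, :] * t[:, None]))
    for g in np.unique(np.asarray(groups)):
        out[g] = np.nanmean(alpha_cell[np.asarray(groups) == g], axis=0)
    return out


# ---------------------------------------------------------------------------
# unification / velocities / bias
# ---------------------------------------------------------------------------


def unify_beta(est: KineticEstimate, gamma_tilde: np.ndarray) -> KineticEstimate:
    """Fill beta = gamma/gamma~ from an absolute-gamma estimate and a relative
    splicing-based gamma~ (genes with gamma~ <= 0 are skipped)."""
    gt = np.asarray(gamma_tilde, dtype=float)
    beta = np.full_like(gt, np.nan)
    valid = np.isfinite(gt) & (gt > 0) & np.isfinite(est.gamma)
    beta[valid] = est.gamma[valid] / gt[valid]
    est.beta = beta
    est.gamma_tilde = gt
    return est


def velocities(lm: LayeredMatrix, est: KineticEstimate,
               which: str = "total") -> np.ndarray:
    """Cell x gene RNA velocities from a fitted estimate.

    total:     r. = (gamma/k) l - gamma r   (one-shot/two-step slope k)
    spliced:   s. = beta u - gamma s
    unspliced: u. = beta u_l/(1 - e^(-beta t)) - beta u
    new:       l. = gamma l/(1 - e^(-gamma t)) - gamma l
    conventional: v = u - gamma~ s
    """
    if which == "conventional":
        return lm.layers["u"] - est.gamma_tilde[None, :] * lm.layers["s"]
    if which == "total":
        k = est.k if est.k is not None else None
        if k is None:
            raise ValueError("slope k required for total velocity")
        k2 = k if k.ndim == 2 else np.broadcast_to(k, lm.layers["l"].shape)
        with np.errstate(divide="ignore", invalid="ignore"):
            return est.gamma[None, :] / k2 * lm.layers["l"] \
                - est.gamma[None, :] * lm.layers["r"]
    if which == "spliced":
        return est.beta[None, :] * lm.layers["u"] - est.gamma[None, :] * lm.layers["s"]
    if which == "unspliced":
        t = lm.label_time[:, None]
        ul = lm.extra_layers.get("ul", lm.layers.get("l"))
        with np.errstate(divide="ignore", invalid="ignore"):
            return est.beta[None, :] * ul / (1.0 - np.exp(-est.beta[None, :] * t)) \
                - est.beta[None, :] * lm.layers["u"]
    if which == "new":
        t = lm.label_time[:, None]
        L = lm.layers["l"]
        with np.errstate(divide="ignore", invalid="ignore"):
            return est.gamma[None, :] * L / (1.0 - np.exp(-est.gamma[None, :] * t)) \
                - est.gamma[None, :] * L
    raise ValueError(f"unknown velocity kind {which!r}")


def labeling_bias(rho: float, k: float, t: float) -> tuple[float, int]:
    """Bias of gamma from mis-estimated labeled fractions:
    gamma - gamma_true = -(1/t) ln((1 - k rho)/(1 - k)); returns the bias and
    its sign (rho < 1 under-estimates, rho > 1 over-estimates)."""
    if k * rho >= 1:
        raise ValueError("k*rho must be < 1")
    bias = -math.log((1.0 - k * rho) / (1.0 - k)) / t
    return bias, int(np.sign(bias))


# ---------------------------------------------------------------------------
# bursting
# ---------------------------------------------------------------------------


def burst_stats(mean_r: np.ndarray, var_r: np.ndarray,
                gamma: np.ndarray) -> BurstStats:
    """Negative-binomial burst statistics from total-RNA mean/variance.

    phi solves Var = mean + phi mean^2; burst frequency BF = k_on = gamma/phi
    and burst size BS = alpha/k_off = mean * phi.  Genes at or below the
    Poisson limit (Var <= mean) are flagged."""
    mean_r = np.asarray(mean_r, dtype=float)
    var_r = np.asarray(var_r, dtype=float)
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), mean_r.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (var_r - mean_r) / mean_r**2
    ok = np.isfinite(phi) & (phi > 0)
    phi = np.where(ok, phi, np.nan)
    bf = gamma / phi
    bs = mean_r * phi
    return BurstStats(phi=phi, burst_frequency=bf, burst_size=bs, ok=ok)


# ---------------------------------------------------------------------------
# binomial mixture model
# ---------------------------------------------------------------------------


def mixture_likelihood(y, n, p_e: float, p_c: float, pi_g: float):
    """Two-component binomial mixture mass
    P(y) = (1 - pi) B(y; n, p_e) + pi B(y; n, p_c)."""
    if p_e >= p_c:
        raise ValueError("identifiability requires p_e < p_c")
    return (1.0 - pi_g) * binom.pmf(y, n, p_e) + pi_g * binom.pmf(y, n, p_c)


def fit_mixture_em(y: np.ndarray, n: np.ndarray, p_e: float | None = None,
                   init=(0.004, 0.02, 0.5), tol: float = 1e-6,
                   max_iter: int = 1000) -> MixtureQuantification:
    """EM for (p_e, p_c, pi) from per-read mutation counts y out of n sites.

    ``p_e`` may be fixed from unlabeled controls, otherwise it is estimated.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    pe = init[0] if p_e is None else p_e
    pc, pi = init[1], init[2]
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            log_bg = binom.logpmf(y, n, pe) + np.log1p(-pi)
            log_lab = binom.logpmf(y, n, pc) + np.log(pi)
        mx = np.maximum(log_bg, log_lab)
        denom = mx + np.log(np.exp(log_bg - mx) + np.exp(log_lab - mx))
        resp = np.exp(log_lab - denom)                     # P(labeled | read)
        ll = float(denom.sum())
        pi = float(resp.mean())
        wl = resp.sum()
        wb = (1.0 - resp).sum()
        pc = float((resp * y).sum() / max((resp * n).sum(), 1e-300))
        if p_e is None:
            pe = float(((1.0 - resp) * y).sum() /
                       max(((1.0 - resp) * n).sum(), 1e-300))
        pe = min(max(pe, 1e-9), 1 - 1e-9)
        pc = min(max(pc, pe + 1e-9), 1 - 1e-9)
        pi = min(max(pi, 1e-9), 1 - 1e-9)
        delta = max(abs(pe - old[0]), abs(pc - old[1]), abs(pi - old[2])) \
            if it > 1 else np.inf
        old = (pe, pc, pi)
        if delta < tol:
            break
        ll_old = ll
    return MixtureQuantification(p_e=pe, p_c=pc, pi_g=pi, loglik=ll, n_iter=it)


# ---------------------------------------------------------------------------
# velocity confidence
# ---------------------------------------------------------------------------


def cell_velocity_confidence(X: np.ndarray, V: np.ndarray,
                             g: NeighborGraph | None = None, K: int = 30,
                             method: str = "jaccard") -> np.ndarray:
    """Per-cell velocity confidence.

    jaccard: |S(x) ∩ S(x + v)| / |S(x) ∪ S(x + v)| with neighbor sets
    recomputed at the current and extrapolated states (zero-velocity cells
    score 1 by convention).  cosine/correlation: mean similarity of each
    cell's velocity to its neighbors'.
    """
    X = np.asarray(X, dtype=float)
    V = np.asarray(V, dtype=float)
    if X.shape != V.shape:
        raise ValueError("X and V must share shape")
    n = X.shape[0]
    if g is None:
        g = knn_graph(X, K=min(K, n - 1))
    if method == "jaccard":
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=g.K, algorithm="brute").fit(X)
        _, future_idx = nn.kneighbors(X + V)
        scores = np.empty(n)
        for i in range(n):
            if not np.any(V[i]):
                scores[i] = 1.0
                continue
            cur = set(g.indices[i])
            fut = set(future_idx[i])
            scores[i] = len(cur & fut) / len(cur | fut)
        return scores
    if method in ("cosine", "correlation"):
        scores = np.empty(n)
        for i in range(n):
            sims = []
            for j in g.indices[i]:
                a, b = V[i], V[int(j)]
                if method == "correlation":
                    a = a - a.mean()
                    b = b - b.mean()
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                sims.append(a @ b / (na * nb) if na > 0 and nb > 0 else 0.0)
            scores[i] = float(np.mean(sims))
        return scores
    raise ValueError(f"unknown method {method!r}")


def gene_velocity_confidence(expr: np.ndarray, velocities: np.ndarray,
                             groups: np.ndarray, progenitor_groups,
                             terminal_groups, gene_ids: list[str] | None = None,
                             threshold_frac: float = 0.05,
                             keep_above: float = 0.8):
    """Lineage-prior gene confidence for velocity-flow correction.

    For each progenitor -> terminal pair a gene's phase (induction/repression)
    is the sign of the median expression shift; its confidence is 1 minus the
    fraction of cells in the two groups whose velocity violates the phase sign
    beyond a tolerance of ``threshold_frac`` times the gene's velocity scale.
    Flat genes get NaN (phase undefined), not 0.  Returns (confidence per
    gene, boolean retained mask with confidence > ``keep_above``).
    """
    expr = np.asarray(expr, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    groups = np.asarray(groups)
    known = set(np.unique(groups))
    for grp in list(progenitor_groups) + list(terminal_groups):
        if grp not in known:
            raise ValueError(f"unknown group label {grp!r}")
    n_genes = expr.shape[1]
    scale = np.maximum(np.abs(velocities).max(axis=0), 1e-12)
    tol = threshold_frac * scale
    confs = []
    for pg in progenitor_groups:
        for tg in terminal_groups:
            pm = groups == pg
            tm = groups == tg
            shift = np.median(expr[tm], axis=0) - np.median(expr[pm], axis=0)
            conf = np.full(n_genes, np.nan)
            cells = pm | tm
            for j in range(n_genes):
                if shift[j] == 0:
                    continue
                v = velocities[cells, j]
                if shift[j] > 0:       # induction: velocities mostly >= -tol
                    violate = v < -tol[j]
                else:                  # repression: velocities mostly <= tol
                    violate = v > tol[j]
                conf[j] = 1.0 - violate.mean()
            confs.append(conf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN gene columns
        confidence = np.nanmean(np.vstack(confs), axis=0) if confs \
            else np.full(n_genes, np.nan)
        retained = confidence > keep_above
    return confidence, retained
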
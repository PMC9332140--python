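"""Least-action paths, fastest-LAP selection, gene rankings and in-silico
perturbation.

For a discrete path P = {x_0 ... x_n} with time step dt, segment velocities
v_k = (x_k - x_{k-1})/dt and midpoints y_k, the Onsager-Machlup-type action is

    S(P, dt) = (1/2D) * sum_k ||v_k - f(y_k)||^2 * dt,

with diffusion constant D (= sigma^2/2 for white noise of size sigma).  The
LAP alternates a closed-form dt minimization with a quasi-Newton path
minimization using the exact analytic action gradient; the fastest LAP
(F-LAP) re-optimizes at fixed traversal times and picks the elbow of the
normalized action-vs-time curve.  Transition rates follow the large-deviation
estimate R ~ C exp(-S*), known only up to the constant C.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

from .datamodel import EmbeddingSpace
from .diffgeo import jacobian

__all__ = [
    "action",
    "action_gradient",
    "optimal_dt",
    "LAPResult",
    "optimize_lap",
    "flap",
    "msd_ranking",
    "transition_stats",
    "PerturbationResult",
    "perturb",
]


def _segments(path: np.ndarray, dt: float):
    diffs = np.diff(path, axis=0)
    v = diffs / dt
    y = 0.5 * (path[:-1] + path[1:])
    return diffs, v, y


def action(path: np.ndarray, field, dt: float, D: float = 1.0) -> float:
    """S = (1/2D) sum_k ||v_k - f(y_k)||^2 dt over the path's segments."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    path = np.asarray(path, dtype=float)
    _, v, y = _segments(path, dt)
    F = np.atleast_2d(field(y))
    return float(np.sum((v - F) ** 2) * dt / (2.0 * D))


def action_gradient(path: np.ndarray, field, jac, dt: float, D: float = 1.0
                    ) -> np.ndarray:
    """Exact gradient of the action w.r.t. the interior path points.

    With residuals r_k = v_k - f(y_k),

        dS/dx_k = (1/D)(r_k - r_{k+1})
                  - (dt/2D) (J(y_k)ᵀ r_k + J(y_{k+1})ᵀ r_{k+1}),

    for k = 1..n-1 (endpoints pinned).  ``jac`` maps a batch of points to
    stacked Jacobians.
    """
    path = np.asarray(path, dtype=float)
    _, v, y = _segments(path, dt)
    F = np.atleast_2d(field(y))
    R = v - F                                  # n_seg x d
    J = np.asarray(jac(y))                     # n_seg x d x d
    JtR = np.einsum("kji,kj->ki", J, R)        # J(y_k)ᵀ r_k
    grad = (R[:-1] - R[1:]) / D - (dt / (2.0 * D)) * (JtR[:-1] + JtR[1:])
    return grad


def optimal_dt(path: np.ndarray, field, D: float = 1.0) -> float:
    """Closed-form minimizer of S over dt for a fixed path:
    dt* = sqrt(sum ||d_k||^2 / sum ||f(y_k)||^2)."""
    path = np.asarray(path, dtype=float)
    diffs = np.diff(path, axis=0)
    y = 0.5 * (path[:-1] + path[1:])
    F = np.atleast_2d(field(y))
    denom = float(np.sum(F**2))
    if denom == 0:
        raise ValueError("field vanishes along the path; optimal dt unbounded")
    return float(np.sqrt(np.sum(diffs**2) / denom))


@dataclass
class LAPResult:
    path: np.ndarray
    dt: float
    action: float
    traversal_time: float
    outer_iterations: int
    D: float = 1.0
    elbow_time: float | None = None
    action_curve: pd.DataFrame | None = None


def _init_path(x_start, x_end, n_points, X_data=None, K=10):
    """Interpolated kNN-graph shortest path between the data points nearest the
    endpoints, falling back to straight-line interpolation."""
    x_start = np.asarray(x_start, dtype=float)
    x_end = np.asarray(x_end, dtype=float)
    if X_data is not None and len(X_data) > K + 1:
        try:
            from scipy.sparse.csgraph import shortest_path
            from sklearn.neighbors import kneighbors_graph

            X_data = np.asarray(X_data, dtype=float)
            i0 = int(np.argmin(np.linalg.norm(X_data - x_start, axis=1)))
            i1 = int(np.argmin(np.linalg.norm(X_data - x_end, axis=1)))
            G = kneighbors_graph(X_data, K, mode="distance")
            dist, pred = shortest_path(G, directed=False, indices=i0,
                                       return_predecessors=True)
            if np.isfinite(dist[i1]):
                nodes = [i1]
                while nodes[-1] != i0:
                    nodes.append(int(pred[nodes[-1]]))
                way = np.vstack([x_start, X_data[nodes[::-1]], x_end])
                # arclength-parametrized resample to n_points
                seg = np.linalg.norm(np.diff(way, axis=0), axis=1)
                s = np.concatenate([[0.0], np.cumsum(seg)])
                if s[-1] > 0:
                    ts = np.linspace(0, s[-1], n_points)
                    return np.column_stack(
                        [np.interp(ts, s, way[:, j]) for j in range(way.shape[1])])
        except Exception:
            pass
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    return x_start + t * (x_end - x_start)


def _minimize_path(path, field, jac, dt, D, maxiter=500):
    shape = path[1:-1].shape

    def fun(z):
        p = np.vstack([path[0], z.reshape(shape), path[-1]])
        return action(p, field, dt, D)

    def grad(z):
        p = np.vstack([path[0], z.reshape(shape), path[-1]])
        return action_gradient(p, field, jac, dt, D).ravel()

    res = minimize(fun, path[1:-1].ravel(), jac=grad, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    return np.vstack([path[0], res.x.reshape(shape), path[-1]]), float(res.fun)


def optimize_lap(field, x_start, x_end, jac=None, n_points: int = 25,
                 D: float = 1.0, max_outer: int = 10, tol: float = 1e-2,
                 X_data=None, seed: int = 0, check_gradient: bool = True,
                 ) -> LAPResult:
    """Find the least action path between two states.

    Alternates (i) the closed-form optimal time step and (ii) quasi-Newton
    minimization over the interior points with the analytic gradient, until
    the relative action change drops below ``tol``.  ``field``/``jac`` may be
    a fitted VectorFieldModel (Jacobian derived automatically) or explicit
    callables.  A finite-difference check of the analytic gradient on the
    initial path aborts on disagreement (implementation-error guard).
    """
    from .vectorfield import VectorFieldModel

    if isinstance(field, VectorFieldModel):
        model = field
        field = model.evaluate
        jac = jac or (lambda Y: jacobian(model, Y))
    elif jac is None:
        raise ValueError("jac required for a bare callable field")

    x_start = np.asarray(x_start, dtype=float)
    x_end = np.asarray(x_end, dtype=float)
    path = _init_path(x_start, x_end, n_points, X_data)
    if np.allclose(x_start, x_end):
        return LAPResult(path=path, dt=1.0, action=0.0, traversal_time=0.0,
                         outer_iterations=0, D=D)

    dt = optimal_dt(path, field, D)

    if check_gradient:
        g_an = action_gradient(path, field, jac, dt, D)
        g_fd = _fd_gradient(path, field, dt, D)
        denom = max(np.abs(g_fd).max(), 1e-8)
        if np.abs(g_an - g_fd).max() / denom > 1e-3:
            raise AssertionError("analytic action gradient disagrees with finite "
                                 "differences; aborting")

    S_prev = action(path, field, dt, D)
    outer = 0
    for outer in range(1, max_outer + 1):
        path, S = _minimize_path(path, field, jac, dt, D)
        dt = optimal_dt(path, field, D)
        S = action(path, field, dt, D)
        if abs(S_prev - S) <= tol * max(abs(S_prev), 1e-12):
            break
        S_prev = S
    return LAPResult(path=path, dt=dt, action=S,
                     traversal_time=dt * (n_points - 1),
                     outer_iterations=outer, D=D)


def _fd_gradient(path, field, dt, D, h=1e-4):
    base = path.copy()
    grad = np.zeros_like(path[1:-1])
    for k in range(1, path.shape[0] - 1):
        for a in range(path.shape[1]):
            p1, p2 = base.copy(), base.copy()
            p1[k, a] += h
            p2[k, a] -= h
            grad[k - 1, a] = (action(p1, field, dt, D) -
                              action(p2, field, dt, D)) / (2 * h)
    return grad


def flap(field, lap: LAPResult, jac=None, T_grid: np.ndarray | None = None,
         elbow_threshold_frac: float = 0.1) -> LAPResult:
    """Fastest LAP: re-optimize the path at fixed traversal times T < T* and
    return the path at the elbow of the normalized action-vs-T curve.

    The curve is cubic-spline interpolated; the elbow is the grid time closest
    to T* whose numerical second derivative exceeds
    ``elbow_threshold_frac`` x max curvature.  A flat curve returns T* itself.
    """
    from .vectorfield import VectorFieldModel

    if isinstance(field, VectorFieldModel):
        model = field
        field = model.evaluate
        jac = jac or (lambda Y: jacobian(model, Y))
    T_star = lap.traversal_time
    n_seg = lap.path.shape[0] - 1
    if T_grid is None:
        T_grid = np.geomspace(T_star / 20.0, T_star, 20)
    T_grid = np.sort(np.asarray(T_grid, dtype=float))

    actions, paths = [], []
    for T in T_grid:
        dt = T / n_seg
        p, S = _minimize_path(lap.path, field, jac, dt, lap.D)
        actions.append(S)
        paths.append(p)
    actions = np.asarray(actions)

    if len(T_grid) == 1:
        best = 0
        elbow_T = float(T_grid[0])
    else:
        norm = actions / max(actions.max(), 1e-300)
        spline = CubicSpline(T_grid, norm)
        tt = np.linspace(T_grid[0], T_grid[-1], 400)
        curv = np.abs(spline(tt, 2))
        thresh = elbow_threshold_frac * curv.max()
        above = tt[curv > thresh]
        if above.size == 0 or curv.max() == 0:
            elbow_T = T_star
        else:
            elbow_T = float(above[np.argmin(np.abs(above - T_star))])
        best = int(np.argmin(np.abs(T_grid - elbow_T)))

    curve = pd.DataFrame({"T": T_grid, "action": actions})
    return LAPResult(path=paths[best], dt=float(T_grid[best] / n_seg),
                     action=float(actions[best]), traversal_time=float(T_grid[best]),
                     outer_iterations=lap.outer_iterations, D=lap.D,
                     elbow_time=elbow_T, action_curve=curve)


def msd_ranking(path_genes: np.ndarray, gene_ids: list[str],
                tf_list: list[str] | None = None) -> pd.DataFrame:
    """Rank genes by mean square displacement along a gene-space path.

    MSD_i = sum_t (y_i(t) - y_i(0))^2 over the path's points.  When a TF list
    is given the ranking is restricted to it and each TF gets the priority
    score S = 1 - R/#TF.
    """
    Y = np.asarray(path_genes, dtype=float)
    msd = np.sum((Y - Y[0]) ** 2, axis=0)
    df = pd.DataFrame({"gene": gene_ids, "msd": msd})
    if tf_list is not None:
        df = df[df["gene"].isin(tf_list)].reset_index(drop=True)
    df = df.sort_values(["msd", "gene"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if tf_list is not None:
        df["priority"] = 1.0 - df["rank"] / len(df)
    return df


def transition_stats(S_star: float) -> tuple[float, float]:
    """Relative transition rate exp(-S*) and relative MFPT exp(S*); both are
    known only up to the unestimated proportionality constant C."""
    if S_star < 0:
        raise ValueError("action must be non-negative")
    rate = float(np.exp(-S_star))
    return rate, 1.0 / rate


@dataclass
class PerturbationResult:
    delta_x: np.ndarray          # field-space perturbation (k,)
    delta_f: np.ndarray          # per-cell field-space response (n x k)
    delta_g: np.ndarray          # per-cell gene-space response (n x d_genes)
    amplification: float


def perturb(model, emb: EmbeddingSpace, delta_y: dict[str, float] | np.ndarray,
            X_cells: np.ndarray, c: float = 1.0, centered: bool = True,
            ) -> PerturbationResult:
    """Propagate a finite gene-space perturbation through the field Jacobian.

    The gene-space perturbation Δy (dict gene -> shift, or dense vector) is
    mapped to field space as Δx = Qᵀ(Δy - mu) (``centered=False`` drops the
    mean subtraction), amplified by c, pushed through Δf = J(x)Δx per cell and
    mapped back as Δg = QΔf + mu.  The (X, Δg) pairs can then be projected
    onto embeddings exactly like velocity pairs.
    """
    Q = emb.loadings
    mu = emb.center
    if isinstance(delta_y, dict):
        dy = np.zeros(Q.shape[0])
        for gene, val in delta_y.items():
            dy[emb.gene_index(gene)] = float(val)
    else:
        dy = np.asarray(delta_y, dtype=float)
        if dy.shape[0] != Q.shape[0]:
            raise ValueError("delta_y length must equal the number of genes")
    dx = Q.T @ ((dy - mu) if centered else dy)
    dx = c * dx
    J = jacobian(model, np.atleast_2d(X_cells))
    df = np.einsum("nij,j->ni", J, dx)
    dg = df @ Q.T + (mu if centered else 0.0)
    return PerturbationResult(delta_x=dx, delta_f=df, delta_g=dg, amplification=c)
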
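"""Topological analysis of a vector field and graph pseudotime.

Fixed points f(x*) = 0 are located by root-finding from Latin-hypercube seeds,
deduplicated and classified by the eigenvalue signs of the analytic Jacobian;
nullclines are traced by pseudo-arclength continuation from fixed points;
trajectories come from adaptive ODE integration with FFT-based limit-cycle
trimming; fate probabilities follow the move-back counting rule; pseudotime
is a discrete Hodge-style scalar potential on the velocity-oriented kNN graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve
from scipy.sparse.linalg import lsqr
from scipy.stats import qmc

from .datamodel import NeighborGraph, knn_graph
from .diffgeo import jacobian

__all__ = [
    "FixedPoint",
    "find_fixed_points",
    "nullclines_2d",
    "Trajectory",
    "integrate",
    "trim_limit_cycles",
    "FateProfile",
    "fate_probability",
    "PseudotimeResult",
    "pseudotime",
]


@dataclass
class FixedPoint:
    position: np.ndarray
    eigenvalues: np.ndarray
    kind: str                      # attractor | repulsor | saddle
    confidence: float = 1.0

    @property
    def is_stable(self) -> bool:
        return self.kind == "attractor"


def _classify(eigvals: np.ndarray) -> str:
    re = np.real(eigvals)
    if np.all(re < 0):
        return "attractor"
    if np.all(re > 0):
        return "repulsor"
    return "saddle"


def find_fixed_points(field, domain, n_seeds: int = 25, tol: float = 1e-8,
                      jac=None, X_data: np.ndarray | None = None,
                      seed: int = 0, dedup_scale: float = 1e-2) -> list[FixedPoint]:
    """Locate and classify fixed points of ``field`` inside a box domain.

    ``field`` maps a d-vector to a d-vector (a fitted model's ``evaluate`` or
    any callable); ``jac`` is its Jacobian (defaults to the analytic kernel
    Jacobian for VectorFieldModel, else finite differences).  ``domain`` is a
    (d, 2) array of [lo, hi] bounds sampled with Latin hypercube seeds.  Roots
    closer than ``dedup_scale`` times the domain diagonal are merged.  When
    ``X_data`` is given, each fixed point's confidence is
    exp(-dist(x*, nearest datum)/l) with l the mean kNN distance of the data.
    """
    from .vectorfield import VectorFieldModel

    if isinstance(field, VectorFieldModel):
        model = field
        f = model.evaluate
        jac = jac or (lambda x: jacobian(model, x))
    else:
        f = field
        if jac is None:
            def jac(x, _f=f):
                x = np.asarray(x, dtype=float)
                d = x.size
                J = np.empty((d, d))
                h = 1e-6
                for j in range(d):
                    e = np.zeros(d)
                    e[j] = h
                    J[:, j] = (np.asarray(_f(x + e)) - np.asarray(_f(x - e))) / (2 * h)
                return J

    domain = np.asarray(domain, dtype=float)
    d = domain.shape[0]
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    seeds = qmc.scale(sampler.random(n_seeds), domain[:, 0], domain[:, 1])
    diag = float(np.linalg.norm(domain[:, 1] - domain[:, 0]))
    dedup_r = dedup_scale * diag

    ell = None
    if X_data is not None and len(X_data) > 1:
        g = knn_graph(np.asarray(X_data, dtype=float),
                      K=min(30, len(X_data) - 1))
        ell = float(g.distances.mean())

    roots: list[np.ndarray] = []
    for x0 in seeds:
        try:
            sol, info, ier, _ = fsolve(lambda x: np.asarray(f(x), dtype=float),
                                       x0, full_output=True, xtol=tol)
        except Exception:
            continue
        if ier != 1:
            continue
        if np.linalg.norm(np.asarray(f(sol))) > 1e-6:
            continue
        pad = 0.05 * (domain[:, 1] - domain[:, 0])
        if np.any(sol < domain[:, 0] - pad) or np.any(sol > domain[:, 1] + pad):
            continue
        if any(np.linalg.norm(sol - r) < dedup_r for r in roots):
            continue
        roots.append(sol)

    out = []
    for r in roots:
        J = np.asarray(jac(r))
        ev = np.linalg.eigvals(J)
        conf = 1.0
        if ell is not None:
            dmin = float(np.min(np.linalg.norm(np.asarray(X_data) - r, axis=1)))
            conf = float(np.exp(-dmin / ell))
        out.append(FixedPoint(position=r, eigenvalues=ev, kind=_classify(ev),
                              confidence=conf))
    out.sort(key=lambda fp: tuple(np.round(fp.position, 6)))
    return out


def nullclines_2d(field, fixed_points, component: int, domain,
                  eps: float = 0.01, max_points: int = 2000,
                  seed: int = 0) -> list[np.ndarray]:
    """Trace the zero set of one velocity component through each fixed point
    by pseudo-arclength continuation.

    From p0 on the nullcline with tangent v0, the next vertex solves
    {f_c(p1) = 0, (p1 - p0).v0 - eps = 0}; the first tangent is a normalized
    random direction (seeded) and each curve is traced in both directions
    until it leaves ``domain`` or reaches ``max_points`` vertices.
    """
    domain = np.asarray(domain, dtype=float)
    rng = np.random.default_rng(seed)
    polylines = []
    for fp in fixed_points:
        p_start = np.asarray(fp.position if hasattr(fp, "position") else fp, dtype=float)
        v_first = rng.normal(size=2)
        v_first /= np.linalg.norm(v_first)
        # align the first tangent with the zero set (perpendicular to the
        # component's gradient); the random draw only selects the branch sign
        h = 1e-6
        grad = np.array([
            (field(p_start + [h, 0])[component] - field(p_start - [h, 0])[component]),
            (field(p_start + [0, h])[component] - field(p_start - [0, h])[component]),
        ]) / (2 * h)
        gn = np.linalg.norm(grad)
        if gn > 1e-12:
            tangent = np.array([-grad[1], grad[0]]) / gn
            v_first = tangent if tangent @ v_first >= 0 else -tangent
        branches = []
        for direction in (v_first, -v_first):
            pts = [p_start]
            p0, v0 = p_start, direction
            for _ in range(max_points):
                def eqs(p):
                    return [float(np.asarray(field(p))[component]),
                            float(np.dot(p - p0, v0) - eps)]
                p1, info, ier, _ = fsolve(eqs, p0 + eps * v0, full_output=True)
                if ier != 1 or np.linalg.norm(eqs(p1)) > 1e-6:
                    break
                if np.any(p1 < domain[:, 0]) or np.any(p1 > domain[:, 1]):
                    break
                pts.append(p1)
                v0 = (p1 - p0) / np.linalg.norm(p1 - p0)
                p0 = p1
            branches.append(pts)
        line = np.asarray(branches[1][::-1] + branches[0][1:])
        polylines.append(line)
    return polylines


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray
    terminal: bool = False
    trimmed_intervals: int = 0


def integrate(field, x0, t_span: tuple[float, float] | float,
              direction: str = "forward", max_step: float = np.inf,
              rtol: float = 1e-7, atol: float = 1e-9,
              domain_bound: float | None = None,
              n_eval: int = 200) -> Trajectory:
    """Adaptive explicit integration of dx/dt = f(x) (or -f for backward).

    Truncates with a flag if the state norm exceeds 10x ``domain_bound``.
    """
    x0 = np.asarray(x0, dtype=float)
    if not np.isfinite(x0).all():
        raise ValueError("non-finite initial state")
    if np.isscalar(t_span):
        t_span = (0.0, float(t_span))
    sign = -1.0 if direction == "backward" else 1.0

    def rhs(t, x):
        return sign * np.asarray(field(x), dtype=float)

    events = None
    if domain_bound is not None:
        def blowup(t, x):
            return float(np.linalg.norm(x) - 10.0 * domain_bound)
        blowup.terminal = True
        events = blowup

    t_eval = np.linspace(t_span[0], t_span[1], n_eval)
    sol = solve_ivp(rhs, t_span, x0, t_eval=t_eval, rtol=rtol, atol=atol,
                    max_step=max_step, events=events, dense_output=False)
    truncated = sol.status == 1
    return Trajectory(times=sol.t, states=sol.y.T, terminal=truncated)


def trim_limit_cycles(traj: Trajectory, k_intervals: int = 4,
                      threshold: float = 0.05) -> Trajectory:
    """Iteratively remove the last of ``k_intervals`` trajectory intervals when
    its coordinate-wise FFT spectrum matches the preceding interval's within
    ``threshold`` (per-point norm) — the signature of orbiting a stable limit
    cycle."""
    times, states = traj.times, traj.states
    removed = 0
    while True:
        n = len(times)
        if n < 2 * k_intervals:
            break
        idx = np.array_split(np.arange(n), k_intervals)
        last, prev = idx[-1], idx[-2]
        m = min(len(last), len(prev))
        if m < 2:
            break
        spectra = []
        for seg in (prev[:m], last[:m]):
            fx = np.abs(np.fft.fft(states[seg], axis=0))
            spectra.append(fx.ravel())
        diff = np.linalg.norm(spectra[0] - spectra[1]) / m
        if diff < threshold:
            keep = np.concatenate(idx[:-1])
            times, states = times[keep], states[keep]
            removed += 1
        else:
            break
    return Trajectory(times=times, states=states, terminal=traj.terminal,
                      trimmed_intervals=removed)


@dataclass
class FateProfile:
    probabilities: dict
    move_back_steps: int
    n_selected: int


def fate_probability(traj: Trajectory, X_data: np.ndarray, groups,
                     speed_threshold: float | None = None,
                     distance_threshold: float = 3.0,
                     field=None, neighbor_rank: int = 2) -> FateProfile:
    """Assign fate probabilities from the low-speed tail of a trajectory.

    Tail points with speed below ``speed_threshold`` (default: the 5th
    percentile of speeds along the trajectory) are selected; the window is
    moved backwards one step at a time until every selected point lies within
    ``distance_threshold`` x (median nearest-neighbor distance of the data) of
    an observed cell.  For each cell group, with the ``neighbor_rank``-th
    nearest cell of each selected point providing the label,

        P(group) = 1 - (#{distances > threshold} + move_back_steps)
                       / (#selected + move_back_steps).
    """
    X_data = np.asarray(X_data, dtype=float)
    groups = np.asarray(groups)
    states = traj.states
    n = len(states)
    if field is not None:
        speeds = np.linalg.norm(np.vstack([np.asarray(field(s)) for s in states]), axis=1)
    else:
        dt = np.gradient(traj.times)
        speeds = np.linalg.norm(np.gradient(states, axis=0), axis=1) / np.maximum(dt, 1e-12)
    if speed_threshold is None:
        speed_threshold = float(np.percentile(speeds, 5))

    tail = np.flatnonzero(speeds <= speed_threshold)
    tail = tail[tail >= n // 2] if (tail >= n // 2).any() else tail
    if tail.size == 0:
        tail = np.array([n - 1])
    start, n_sel = int(tail.min()), int(tail.size)
    n_sel = min(n_sel, n - start)

    g = knn_graph(X_data, K=1)
    median_nn = float(np.median(g.distances[:, 0]))
    cutoff = distance_threshold * median_nn

    move_back = 0
    while True:
        sel = states[start:start + n_sel]
        d2 = np.linalg.norm(sel[:, None, :] - X_data[None, :, :], axis=2)
        nearest = np.min(d2, axis=1)
        if np.all(nearest <= cutoff) or start == 0:
            break
        start -= 1
        move_back += 1

    never_near = bool(np.any(nearest > cutoff))
    probs = {}
    for g_ in np.unique(groups):
        members = np.flatnonzero(groups == g_)
        if members.size == 0 or never_near:
            probs[g_] = 0.0
            continue
        rank = min(neighbor_rank, members.size) - 1
        dg = np.sort(d2[:, members], axis=1)[:, rank]
        n_far = int(np.sum(dg > cutoff))
        probs[g_] = max(0.0, 1.0 - (n_far + move_back) / (n_sel + move_back))
    return FateProfile(probabilities=probs, move_back_steps=move_back, n_selected=n_sel)


@dataclass
class PseudotimeResult:
    pseudotime: np.ndarray
    graph: NeighborGraph
    components: np.ndarray | None = None


def pseudotime(X: np.ndarray, V: np.ndarray, g: NeighborGraph | None = None,
               K: int = 15) -> PseudotimeResult:
    """Scalar potential (pseudotime) from a Hodge-style least squares on the
    velocity-oriented kNN graph.

    Each edge (i, j) carries an antisymmetric flow equal to the cosine
    similarity between v_i and the displacement x_j - x_i (symmetrized with
    the reverse edge); the potential solves grad(phi) ~ flow in least squares
    per connected component and is shifted to min 0 (sources low, sinks high).
    """
    X = np.asarray(X, dtype=float)
    V = np.asarray(V, dtype=float)
    n = X.shape[0]
    if g is None:
        g = knn_graph(X, K=min(K, n - 1))

    edges = {}
    for i in range(n):
        for j in g.indices[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) in edges:
                continue
            disp = X[b] - X[a]
            nd = np.linalg.norm(disp)
            if nd == 0:
                flow = 0.0
            else:
                def cos(v, dvec):
                    nv = np.linalg.norm(v)
                    return float(v @ dvec / (nv * np.linalg.norm(dvec))) if nv > 0 else 0.0
                # antisymmetrized: flow a->b positive if velocities point a->b
                flow = 0.5 * (cos(V[a], disp) - cos(V[b], -disp))
            edges[(a, b)] = flow

    rows, cols, vals, rhs = [], [], [], []
    for k, ((a, b), flow) in enumerate(edges.items()):
        rows += [k, k]
        cols += [b, a]
        vals += [1.0, -1.0]
        rhs.append(flow)
    # gauge: anchor the mean potential at zero
    k = len(edges)
    rows += list(range(k, k + 1)) * n
    cols += list(range(n))
    vals += [1e-3] * n
    rhs.append(0.0)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(k + 1, n)).tocsr()
    phi = lsqr(A, np.asarray(rhs), atol=1e-10, btol=1e-10)[0]

    # flag disconnected graphs: shift each component independently
    from scipy.sparse.csgraph import connected_components
    adj = sp.coo_matrix((np.ones(len(edges)),
                         tuple(zip(*edges.keys()))), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    for c in range(n_comp):
        mask = labels == c
        phi[mask] -= phi[mask].min()
    return PseudotimeResult(pseudotime=phi, graph=g,
                            components=labels if n_comp > 1 else None)
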
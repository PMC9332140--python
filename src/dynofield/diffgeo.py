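"""Analytical differential geometry on a fitted kernel vector field.

Because the field is a finite Gaussian-kernel expansion, its Jacobian has the
closed form J(x) = -2w Cᵀ K D with K = diag(Gamma(x, x~_j)) and D the matrix
of rows (x - x~_j).  Divergence, curl, acceleration a = Jv and the curvature
kappa = (Jv (v.v) - v (v.Jv)) / ||v||^4 all follow pointwise.  The Jacobian
learned in a linear embedding (PCA) projects to gene space as G = Q J Qᵀ,
whose entries are read as state-dependent regulatory influences and feed the
gene / interaction rankings and the Hill-derivative fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .datamodel import EmbeddingSpace
from .vectorfield import VectorFieldModel

__all__ = [
    "jacobian",
    "GeometryFields",
    "geometry",
    "project_jacobian",
    "rank_quantity",
    "rank_jacobian",
    "toggle_pairs",
    "HillFit",
    "fit_hill",
]


def jacobian(model: VectorFieldModel, X: np.ndarray) -> np.ndarray:
    """Analytic Jacobian J_ij = df_i/dx_j of the fitted field at each query.

    Returns shape (d, d) for a single point, (n, d, d) for a batch.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    Xq = np.atleast_2d(X)
    w = model.bandwidth
    C = model.coefficients                       # m x d
    G = model.kernel(Xq)                         # n x m
    D = Xq[:, None, :] - model.control_points[None, :, :]   # n x m x d
    # J(x) = -2w sum_j Gamma_j c_j (x - x~_j)ᵀ
    J = -2.0 * w * np.einsum("nm,md,nme->nde", G, C, D)
    return J[0] if single else J


@dataclass
class GeometryFields:
    divergence: np.ndarray          # n
    curl: np.ndarray                # n (2D scalar) or n x 3
    acceleration: np.ndarray        # n x d
    curvature: np.ndarray           # n x d (NaN rows where ||v|| = 0)
    speed: np.ndarray               # n
    jacobians: np.ndarray           # n x d x d


def curvature_vector(J: np.ndarray, v: np.ndarray) -> np.ndarray:
    """kappa = (Jv (v.v) - v (v.Jv)) / ||v||^4 for stacked J (n,d,d), v (n,d)."""
    Jv = np.einsum("nij,nj->ni", J, v)
    vv = np.sum(v * v, axis=1)
    vJv = np.sum(v * Jv, axis=1)
    out = np.full_like(v, np.nan, dtype=float)
    ok = vv > 0
    out[ok] = (Jv[ok] * vv[ok, None] - v[ok] * vJv[ok, None]) / (vv[ok, None] ** 2)
    return out


def curvature_2d_cross(J: np.ndarray, v: np.ndarray) -> np.ndarray:
    """2D curvature via kappa = v x (Jv x v) / ||v||^4, using scalar z-crosses."""
    Jv = np.einsum("nij,nj->ni", J, v)
    z = Jv[:, 0] * v[:, 1] - Jv[:, 1] * v[:, 0]      # (Jv x v)_z
    vv = np.sum(v * v, axis=1)
    out = np.full_like(v, np.nan, dtype=float)
    ok = vv > 0
    out[ok, 0] = v[ok, 1] * z[ok] / vv[ok] ** 2
    out[ok, 1] = -v[ok, 0] * z[ok] / vv[ok] ** 2
    return out


def geometry(model: VectorFieldModel, X: np.ndarray,
             V: np.ndarray | None = None) -> GeometryFields:
    """Per-point divergence, curl, acceleration and curvature.

    Velocities default to the field's own evaluations.  Curl is the scalar
    df2/dx1 - df1/dx2 in 2D and the standard 3-vector in 3D; curvature rows
    are NaN where the speed vanishes (undefined direction).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    V = model.evaluate(X) if V is None else np.atleast_2d(np.asarray(V, dtype=float))
    J = jacobian(model, X)
    d = X.shape[1]
    div = np.trace(J, axis1=1, axis2=2)
    if d == 2:
        curl = J[:, 1, 0] - J[:, 0, 1]
    elif d == 3:
        curl = np.stack([J[:, 2, 1] - J[:, 1, 2],
                         J[:, 0, 2] - J[:, 2, 0],
                         J[:, 1, 0] - J[:, 0, 1]], axis=1)
    else:
        curl = np.full(X.shape[0], np.nan)
    acc = np.einsum("nij,nj->ni", J, V)
    kappa = curvature_vector(J, V)
    if d == 2:
        # cross-product identity (BAC-CAB); both printed 2D forms must agree
        kappa_alt = curvature_2d_cross(J, V)
        ok = ~np.isnan(kappa).any(axis=1)
        if ok.any() and not np.allclose(kappa[ok], kappa_alt[ok], atol=1e-10):
            raise AssertionError("2D curvature forms disagree beyond 1e-10")
    return GeometryFields(divergence=div, curl=curl, acceleration=acc,
                          curvature=kappa, speed=np.linalg.norm(V, axis=1),
                          jacobians=J)


def project_jacobian(J: np.ndarray, emb: EmbeddingSpace,
                     gene_pairs: list[tuple[str, str]]) -> dict[tuple[str, str], np.ndarray]:
    """Gene-space Jacobian entries G_ij = q_iᵀ J q_j for requested
    (effector, regulator) pairs, computed lazily so the full genes x genes
    matrix is never materialized.

    ``J`` is (d, d) or (n, d, d) in the embedded space; returns per-pair
    scalars (or length-n vectors).
    """
    J = np.asarray(J, dtype=float)
    single = J.ndim == 2
    Jb = J[None] if single else J
    out = {}
    for eff, reg in gene_pairs:
        qi = emb.loadings[emb.gene_index(eff)]
        qj = emb.loadings[emb.gene_index(reg)]
        vals = np.einsum("i,nij,j->n", qi, Jb, qj)
        out[(eff, reg)] = vals[0] if single else vals
    return out


def rank_quantity(Q: np.ndarray, gene_ids: list[str],
                  clusters: np.ndarray | None = None,
                  mode: str = "raw") -> pd.DataFrame:
    """Rank genes by the per-cluster mean (or mean-absolute) of a cells x genes
    quantity matrix.  Ties break by gene identifier; empty clusters are
    excluded with a warning.  Returns a tidy frame with columns
    (cluster, gene, value, rank)."""
    import warnings

    Q = np.asarray(Q, dtype=float)
    if mode == "abs":
        Q = np.abs(Q)
    elif mode != "raw":
        raise ValueError("mode must be 'raw' or 'abs'")
    if clusters is None:
        clusters = np.zeros(Q.shape[0], dtype=int)
    clusters = np.asarray(clusters)
    rows = []
    for c in pd.unique(clusters):
        mask = clusters == c
        if not mask.any():
            warnings.warn(f"cluster {c!r} is empty; excluded")
            continue
        means = Q[mask].mean(axis=0)
        df = pd.DataFrame({"cluster": c, "gene": gene_ids, "value": means})
        df = df.sort_values(["value", "gene"], ascending=[False, True], kind="mergesort")
        df["rank"] = np.arange(1, len(df) + 1)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def rank_jacobian(J_genes: np.ndarray, gene_ids: list[str],
                  clusters: np.ndarray | None = None,
                  mode: str = "interactions", use_abs: bool = True) -> pd.DataFrame:
    """Rank entries of per-cell gene-space Jacobians (n x g x g, axis order
    effector x regulator) after cluster averaging.

    Modes: ``interactions`` (all entries), ``regulators`` (rows per effector),
    ``effectors`` (columns per regulator), ``top_regulators`` (row sums R),
    ``top_effectors`` (column sums E).
    """
    J_genes = np.asarray(J_genes, dtype=float)
    if clusters is None:
        clusters = np.zeros(J_genes.shape[0], dtype=int)
    clusters = np.asarray(clusters)
    frames = []
    for c in pd.unique(clusters):
        avg = J_genes[clusters == c].mean(axis=0)          # g x g
        key = np.abs(avg) if use_abs else avg
        if mode == "interactions":
            eff, reg = np.meshgrid(range(len(gene_ids)), range(len(gene_ids)), indexing="ij")
            df = pd.DataFrame({
                "cluster": c,
                "effector": np.asarray(gene_ids)[eff.ravel()],
                "regulator": np.asarray(gene_ids)[reg.ravel()],
                "value": avg.ravel(), "key": key.ravel()})
            df = df.sort_values(["key", "effector", "regulator"],
                                ascending=[False, True, True], kind="mergesort")
        elif mode == "regulators":
            recs = []
            for i, g in enumerate(gene_ids):
                order = np.lexsort((gene_ids, -key[i]))
                for r, j in enumerate(order, 1):
                    recs.append((c, g, gene_ids[j], avg[i, j], r))
            df = pd.DataFrame(recs, columns=["cluster", "effector", "regulator",
                                             "value", "rank"])
            frames.append(df)
            continue
        elif mode == "effectors":
            recs = []
            for j, g in enumerate(gene_ids):
                order = np.lexsort((gene_ids, -key[:, j]))
                for r, i in enumerate(order, 1):
                    recs.append((c, g, gene_ids[i], avg[i, j], r))
            df = pd.DataFrame(recs, columns=["cluster", "regulator", "effector",
                                             "value", "rank"])
            frames.append(df)
            continue
        elif mode == "top_regulators":
            vals = avg.sum(axis=1)     # R_zeta: sum over regulators for each effector row
            df = pd.DataFrame({"cluster": c, "gene": gene_ids, "value": vals})
            df = df.sort_values(["value", "gene"], ascending=[False, True], kind="mergesort")
        elif mode == "top_effectors":
            vals = avg.sum(axis=0)     # E_xi: sum over effectors for each regulator column
            df = pd.DataFrame({"cluster": c, "gene": gene_ids, "value": vals})
            df = df.sort_values(["value", "gene"], ascending=[False, True], kind="mergesort")
        else:
            raise ValueError(f"unknown mode {mode!r}")
        df["rank"] = np.arange(1, len(df) + 1)
        frames.append(df.drop(columns="key", errors="ignore"))
    return pd.concat(frames, ignore_index=True)


def toggle_pairs(J_genes: np.ndarray, gene_ids: list[str]) -> pd.DataFrame:
    """Score mutually inhibiting (toggle-switch) gene pairs.

    Per cell, K = J Jᵀ and L_ij = K_ij [J_ij < 0][J_ji < 0] (Iverson brackets
    gate out non-mutual-inhibition pairs); |L| is averaged over cells and the
    upper triangle ranked descending.
    """
    J = np.asarray(J_genes, dtype=float)
    if J.ndim == 2:
        J = J[None]
    K = np.einsum("nij,nkj->nik", J, J)          # J Jᵀ per cell
    gate = (J < 0) & (np.swapaxes(J, 1, 2) < 0)
    L = np.abs(K * gate).mean(axis=0)
    iu, ju = np.triu_indices(len(gene_ids), k=1)
    df = pd.DataFrame({
        "gene_a": np.asarray(gene_ids)[iu],
        "gene_b": np.asarray(gene_ids)[ju],
        "score": L[iu, ju]})
    df = df.sort_values(["score", "gene_a", "gene_b"],
                        ascending=[False, True, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


@dataclass
class HillFit:
    n: float
    K: float
    gamma: float
    cov: np.ndarray
    residual: float
    interaction: str


def hill_activation_derivative(x, n, K, gamma=0.0):
    """d/dx [x^n/(K^n + x^n) - gamma x] = n K^n x^(n-1)/(K^n + x^n)^2 - gamma."""
    return n * K**n * x**(n - 1) / (K**n + x**n) ** 2 - gamma


def hill_inhibition_derivative(x, n, K, gamma=0.0):
    return -n * K**n * x**(n - 1) / (K**n + x**n) ** 2 - gamma


def fit_hill(expression: np.ndarray, jacobian_values: np.ndarray,
             interaction: str = "activation", n_bins: int = 20,
             fit_gamma: bool | None = None) -> HillFit:
    """Fit the derivative of a Hill response to a Jacobian-vs-expression cloud.

    The cloud is reduced to ``n_bins`` equal-count bins (mean x, mean J,
    s.d. J); the fit is weighted by inverse bin s.d.  ``interaction`` is
    ``activation``, ``inhibition`` or ``self`` (self-interactions add a linear
    degradation -gamma x; cross-interactions fix gamma = 0).
    """
    x = np.asarray(expression, dtype=float)
    jvals = np.asarray(jacobian_values, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 (expression, jacobian) pairs")
    if fit_gamma is None:
        fit_gamma = interaction == "self"
    order = np.argsort(x)
    xs, js = x[order], jvals[order]
    edges = np.array_split(np.arange(x.size), n_bins)
    bx = np.array([xs[e].mean() for e in edges if e.size])
    bj = np.array([js[e].mean() for e in edges if e.size])
    bs = np.array([js[e].std() if e.size > 1 else 0.0 for e in edges if e.size])
    sd = np.where(bs > 0, bs, max(bs[bs > 0].mean() if (bs > 0).any() else 1.0, 1e-6))

    base = hill_inhibition_derivative if interaction == "inhibition" else \
        hill_activation_derivative

    if fit_gamma:
        def f(xv, n, K, gamma):
            return base(xv, n, K, gamma)
        p0, bounds = (2.0, max(np.median(bx), 1e-3), 0.1), \
            ([1e-3, 1e-6, 0.0], [50.0, 1e3, 1e3])
    else:
        def f(xv, n, K):
            return base(xv, n, K, 0.0)
        p0, bounds = (2.0, max(np.median(bx), 1e-3)), ([1e-3, 1e-6], [50.0, 1e3])
    try:
        popt, pcov = curve_fit(f, bx, bj, p0=p0, sigma=sd, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"Hill fit failed to converge: {exc}") from exc
    resid = float(np.sum(((f(bx, *popt) - bj) / sd) ** 2))
    gamma = float(popt[2]) if fit_gamma else 0.0
    return HillFit(n=float(popt[0]), K=float(popt[1]), gamma=gamma,
                   cov=pcov, residual=resid, interaction=interaction)
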
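"""Sparse RKHS vector-field reconstruction with EM outlier rejection (sparseVFC).

Given sample pairs (x_i, v_i) of cell states and velocities, the field is
approximated as f(x) = sum_j Gamma(x, x~_j) c_j with Gaussian kernel
Gamma(x, x~) = exp(-w ||x - x~||^2) centered on m control points.  Inlier
velocities are modeled as Gaussian around f(x) with variance sigma^2; outliers
as uniform over a velocity domain of volume a.  An EM loop alternates the
inlier posterior (E-step) with the ridge-regularized kernel regression

    (Uᵀ P U + lambda sigma^2 K) C = Uᵀ P V

plus closed-form sigma^2 and inlier-fraction updates (M-step).
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np

from .datamodel import knn_graph

__all__ = ["VectorFieldModel", "default_bandwidth", "fit_vectorfield", "detect_outliers"]


@dataclass
class VectorFieldModel:
    control_points: np.ndarray       # m x d
    coefficients: np.ndarray         # m x d (row j is c_j)
    bandwidth: float                 # inverse bandwidth w
    regularization: float            # lambda
    sigma2: float                    # inlier noise variance
    inlier_fraction: float           # q
    outlier_volume: float            # a
    posterior: np.ndarray            # n, inlier posteriors p_i at the samples
    loss_trace: list = _field(default_factory=list)   # penalized neg. log-lik (monotone)
    phi_trace: list = _field(default_factory=list)    # weighted LS energy Phi(f)

    @property
    def dim(self) -> int:
        return self.control_points.shape[1]

    def kernel(self, X: np.ndarray) -> np.ndarray:
        """n_query x m Gaussian kernel matrix against the control points."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.control_points[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.bandwidth * d2)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """f(x) = sum_j Gamma(x, x~_j) c_j at each query point."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        Xq = np.atleast_2d(X)
        if Xq.shape[1] != self.dim:
            raise ValueError(f"query dimension {Xq.shape[1]} != model dimension {self.dim}")
        F = self.kernel(Xq) @ self.coefficients
        return F[0] if single else F

    __call__ = evaluate

    def norm_h2(self) -> float:
        """RKHS norm ||f||_H^2 = sum_ij c_iᵀ Gamma(x~_i, x~_j) c_j."""
        K = self.kernel(self.control_points)
        return float(np.sum((K @ self.coefficients) * self.coefficients))


def default_bandwidth(X: np.ndarray, neighbor_fraction: float = 0.2) -> float:
    """Data-driven inverse bandwidth.

    K = max(2, round(neighbor_fraction * n)) nearest neighbors are found for
    each point; with d_m the mean neighbor distance, w = 1.5 / (2 d_m), i.e.
    the kernel standard deviation is d_m / 1.5.  Scaling all points by a
    factor scales w by its inverse.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    K = min(max(2, round(neighbor_fraction * n)), n - 1)
    g = knn_graph(X, K=K)
    d_m = float(g.distances.mean())
    if d_m <= 0:
        raise ValueError("all points identical; bandwidth undefined")
    return 1.5 / (2.0 * d_m)


def _phi(P, resid2, sigma2, lam, norm_h2):
    """Weighted least-squares energy Phi(f) = (1/2s^2) sum p_i r_i^2 + (l/2)||f||_H^2."""
    return float(resid2 @ P) / (2.0 * sigma2) + 0.5 * lam * norm_h2


def _neg_log_lik(resid2, sigma2, q, a, d, lam, norm_h2):
    """Penalized negative mixture log-likelihood; the quantity the (generalized)
    EM iteration decreases monotonically and the convergence criterion."""
    inlier = q * np.exp(-resid2 / (2.0 * sigma2)) / (2.0 * np.pi * sigma2) ** (d / 2.0)
    mix = inlier + (1.0 - q) / a
    return -float(np.sum(np.log(np.maximum(mix, 1e-300)))) + 0.5 * lam * norm_h2


def fit_vectorfield(X: np.ndarray, V: np.ndarray, m: int | None = None,
                    lam: float = 3.0, w: float | None = None,
                    a: float | None = None, max_iter: int = 500,
                    tol: float = 1e-5, seed: int = 0,
                    q_init: float = 0.9) -> VectorFieldModel:
    """Fit the sparse vector-field-consensus model to (state, velocity) samples.

    Defaults follow the reconstruction algorithm's standard settings:
    m = max(50, 5% of n) control points drawn uniformly without replacement
    from the data, lambda = 3, max_iter = 500, bandwidth from
    :func:`default_bandwidth`.  ``a`` defaults to the product of per-dimension
    velocity ranges (the aggressiveness of outlier detection).  Convergence is
    declared when the relative change of the loss falls below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    V = np.asarray(V, dtype=float)
    if X.shape != V.shape:
        raise ValueError("X and V must have the same shape")
    if not (np.isfinite(X).all() and np.isfinite(V).all()):
        raise ValueError("non-finite entries in samples")
    n, d = X.shape
    if m is None:
        m = max(50, round(0.05 * n))
    m = min(m, n)
    if w is None:
        w = default_bandwidth(X)
    if a is None:
        rng_ext = V.max(axis=0) - V.min(axis=0)
        a = float(np.prod(np.where(rng_ext > 0, rng_ext, 1.0)))

    rng = np.random.default_rng(seed)
    ctrl_idx = rng.choice(n, size=m, replace=False)
    Xc = X[ctrl_idx]

    def kmat(A, B):
        d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-w * d2)

    U = kmat(X, Xc)            # n x m
    K = kmat(Xc, Xc)           # m x m Gram
    C = np.zeros((m, d))
    sigma2 = float(np.mean(np.sum(V**2, axis=1)) / d)
    q = q_init
    p = np.ones(n)

    loss_trace = []
    phi_trace = []
    prev_loss = np.inf
    prev_state = None
    for _ in range(max_iter):
        # E-step: inlier posterior with the current field
        F = U @ C
        resid2 = np.sum((V - F) ** 2, axis=1)
        gauss = np.exp(-resid2 / (2.0 * sigma2))
        ratio = (1.0 - q) / q * (2.0 * np.pi * sigma2) ** (d / 2.0) / a
        p = gauss / (gauss + ratio)

        # M-step: weighted ridge kernel regression (UᵀPU + lam s^2 K)C = UᵀPV,
        # solved in augmented least-squares form through QR for numerical
        # stability (Gaussian Gram matrices are severely ill-conditioned)
        sp_ = np.sqrt(p)
        Kreg = K + 1e-12 * np.eye(m)
        try:
            Lk = np.linalg.cholesky(Kreg)
        except np.linalg.LinAlgError:
            import warnings
            warnings.warn("singular Gram matrix; adding ridge jitter 1e-8")
            Lk = np.linalg.cholesky(K + 1e-8 * np.eye(m))
        Aug = np.vstack([U * sp_[:, None], np.sqrt(lam * sigma2) * Lk.T])
        rhs = np.vstack([V * sp_[:, None], np.zeros((m, d))])
        C = np.linalg.lstsq(Aug, rhs, rcond=None)[0]

        F = U @ C
        resid2 = np.sum((V - F) ** 2, axis=1)
        norm_h2 = float(np.sum((K @ C) * C))
        phi_trace.append(_phi(p, resid2, sigma2, lam, norm_h2))

        tr_p = float(p.sum())
        sigma2_floor = 1e-12 * max(float(np.mean(np.sum(V**2, axis=1))) / d, 1e-300)
        sigma2_new = float(resid2 @ p) / (d * tr_p)
        floored = sigma2_new < sigma2_floor
        sigma2 = max(sigma2_new, sigma2_floor)
        q = min(max(tr_p / n, 1e-6), 1.0 - 1e-6)

        loss = _neg_log_lik(resid2, sigma2, q, a, d, lam, norm_h2)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite loss during EM; diagnostics: "
                                     f"sigma2={sigma2}, q={q}")
        if loss > prev_loss:
            # descent exhausted at the floating-point noise floor (EM is
            # monotone in exact arithmetic): roll back the step and stop
            C, sigma2, q, p = prev_state
            phi_trace.pop()
            break
        loss_trace.append(loss)
        if floored:  # residuals at numerical zero: converged (interpolation limit)
            break
        if abs(prev_loss - loss) < tol * max(abs(prev_loss), 1e-12):
            break
        prev_loss = loss
        prev_state = (C, sigma2, q, p)

    return VectorFieldModel(
        control_points=Xc, coefficients=C, bandwidth=w, regularization=lam,
        sigma2=sigma2, inlier_fraction=q, outlier_volume=a, posterior=p,
        loss_trace=loss_trace, phi_trace=phi_trace)


def detect_outliers(model: VectorFieldModel, threshold: float = 0.5) -> np.ndarray:
    """Inlier mask from the fitted posterior: True where p_i >= threshold."""
    return model.posterior >= threshold
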
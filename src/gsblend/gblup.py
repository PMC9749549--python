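"""GBLUP: genomic relationship matrix, REML variance components, Henderson
mixed-model equations, and prediction of unobserved individuals.

The linear mixed model is

    y = X beta + Z m + e,   m ~ N(0, G),   e ~ N(0, R),

with G = sigma2_g * GRM and R = sigma2_e * I for genomic prediction.  The
GRM is VanRaden method 1: centered dose cross-product scaled by
2 * sum_k p_k (1 - p_k).  Variance components are restricted-maximum-
likelihood estimates obtained by a one-dimensional search over the variance
ratio delta = sigma2_e / sigma2_g on the eigenbasis of the GRM, which makes
the fit deterministic and fast for the dense, small-n matrices typical of
genomic selection.  BLUE/BLUP solutions come from the Henderson block
system solved exactly.

New individuals are predicted by conditional expectation through a joint
(train + test) GRM: g_test = G[test, train] G[train, train]^-1 m_hat, which
is algebraically the ridge-regression-on-markers (RR-BLUP) predictor under
the same scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "GRM",
    "MixedModelSpec",
    "MixedModelFit",
    "GBLUPError",
    "compute_grm",
    "reml_variances",
    "solve_mme",
    "predict_gblup",
    "GBLUPRegressor",
]


class GBLUPError(RuntimeError):
    pass


@dataclass
class GRM:
    """VanRaden method-1 genomic relationship matrix."""

    matrix: np.ndarray  # (q, q), ridge already added
    scaling: float  # 2 * sum p_k (1 - p_k)
    ridge_epsilon: float
    allele_freq: np.ndarray  # per retained marker
    kept_markers: np.ndarray  # indices of polymorphic markers


@dataclass
class MixedModelSpec:
    """One instance of Henderson's mixed model y = X beta + Z m + e."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    G: np.ndarray  # covariance of m
    R: np.ndarray  # covariance of e

    def validate(self) -> None:
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("X and Z must have one row per observation")
        q = self.Z.shape[1]
        if self.G.shape != (q, q):
            raise ValueError("G must be q x q for q random effects")
        if self.R.shape != (n, n):
            raise ValueError("R must be n x n")


@dataclass
class MixedModelFit:
    beta_hat: np.ndarray
    m_hat: np.ndarray
    sigma2_g: float | None = None
    sigma2_e: float | None = None
    log_likelihood: float | None = None
    converged: bool = True


def compute_grm(genotypes: np.ndarray, ridge_epsilon: float = 1e-6) -> GRM:
    """G = W W' / (2 sum p_k (1-p_k)) with W the column-centered dose matrix.

    Allele frequencies are estimated from the supplied matrix (p_k = mean
    dose / 2); monomorphic markers carry no relationship information and are
    dropped.  A small ridge on the diagonal guarantees invertibility.
    """
    M = np.asarray(genotypes, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-D dose matrix with at least 2 individuals")
    col_mean = M.mean(axis=0)
    p = col_mean / 2.0
    kept = np.flatnonzero(M.var(axis=0) > 0)
    if kept.size == 0:
        raise GBLUPError("all markers are monomorphic; GRM undefined")
    W = M[:, kept] - col_mean[kept]
    pk = p[kept]
    scaling = float(2.0 * np.sum(pk * (1.0 - pk)))
    G = W @ W.T / scaling
    G[np.diag_indices_from(G)] += ridge_epsilon
    return GRM(matrix=G, scaling=scaling, ridge_epsilon=ridge_epsilon, allele_freq=pk, kept_markers=kept)


def reml_variances(
    y: np.ndarray,
    X: np.ndarray,
    G: np.ndarray | GRM,
    log_delta_bounds: tuple[float, float] = (-12.0, 12.0),
) -> tuple[float, float, float]:
    """REML estimates of (sigma2_g, sigma2_e) for y = X beta + g + e,
    g ~ N(0, sigma2_g G), e ~ N(0, sigma2_e I).

    Profiles the restricted likelihood over delta = sigma2_e / sigma2_g using
    the spectral decomposition of G, then 1-D bounded minimization on
    log(delta).  Returns (sigma2_g, sigma2_e, restricted log-likelihood).
    A boundary optimum is returned with a warning rather than raised.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, p_fix = X.shape
    if n < 3:
        raise ValueError("need at least 3 observations for REML")
    if not np.isfinite(y).all():
        raise ValueError("phenotypes must be finite")
    Gm = G.matrix if isinstance(G, GRM) else np.asarray(G, dtype=float)
    s, U = np.linalg.eigh(Gm)
    s = np.clip(s, 0.0, None)
    y_r = U.T @ y
    X_r = U.T @ X

    def neg2_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        d = s + delta
        w = 1.0 / d
        XtWX = (X_r * w[:, None]).T @ X_r
        XtWy = (X_r * w[:, None]).T @ y_r
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return np.inf
        r = y_r - X_r @ beta
        q = float(np.sum(r * r * w))
        if q <= 0.0:
            q = np.finfo(float).tiny
        sigma2_g = q / (n - p_fix)
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return (n - p_fix) * np.log(sigma2_g) + float(np.sum(np.log(d))) + logdet_XtWX + (n - p_fix)

    res = minimize_scalar(neg2_reml, bounds=log_delta_bounds, method="bounded",
                          options={"xatol": 1e-8})
    log_delta = float(res.x)
    at_bound = (log_delta - log_delta_bounds[0] < 1e-3) or (log_delta_bounds[1] - log_delta < 1e-3)
    if at_bound:
        warnings.warn("REML variance-ratio estimate at search boundary", RuntimeWarning)
    delta = np.exp(log_delta)
    d = s + delta
    w = 1.0 / d
    XtWX = (X_r * w[:, None]).T @ X_r
    beta = np.linalg.solve(XtWX, (X_r * w[:, None]).T @ y_r)
    r = y_r - X_r @ beta
    q = float(np.sum(r * r * w))
    sigma2_g = max(q / (n - p_fix), 0.0)
    sigma2_e = delta * sigma2_g
    loglik = -0.5 * neg2_reml(log_delta)
    return sigma2_g, sigma2_e, loglik


def solve_mme(spec: MixedModelSpec, rel_tol: float = 1e-8) -> MixedModelFit:
    """Solve Henderson's mixed-model equations exactly as the block system

        [X'R^-1 X   X'R^-1 Z      ] [beta]   [X'R^-1 y]
        [Z'R^-1 X   Z'R^-1 Z + G^-1] [m   ] = [Z'R^-1 y]

    The solution is the BLUE of beta and BLUP of m; it also maximizes the
    joint density f(y, m) over (beta, m).
    """
    spec.validate()
    y, X, Z = spec.y, spec.X, spec.Z
    Rinv = np.linalg.inv(spec.R)
    Ginv = np.linalg.inv(spec.G)
    XtR = X.T @ Rinv
    ZtR = Z.T @ Rinv
    C = np.block([[XtR @ X, XtR @ Z], [ZtR @ X, ZtR @ Z + Ginv]])
    rhs = np.concatenate([XtR @ y, ZtR @ y])
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError:
        C_reg = C + 1e-10 * np.eye(C.shape[0])
        try:
            sol = np.linalg.solve(C_reg, rhs)
        except np.linalg.LinAlgError as exc:
            raise GBLUPError("singular Henderson coefficient matrix") from exc
    resid = np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1.0)
    if resid > rel_tol:
        raise GBLUPError(f"Henderson system solved only to relative residual {resid:.2e}")
    p_fix = X.shape[1]
    return MixedModelFit(beta_hat=sol[:p_fix], m_hat=sol[p_fix:])


def predict_gblup(
    fit: MixedModelFit,
    grm_joint: GRM | np.ndarray,
    train_index: np.ndarray,
    test_index: np.ndarray,
    X_test: np.ndarray | None = None,
) -> np.ndarray:
    """Predict phenotypes for unobserved individuals through the joint GRM.

    g_test = G[test, train] G[train, train]^-1 m_hat; Y = X_test beta + g_test.
    """
    train_index = np.asarray(train_index)
    test_index = np.asarray(test_index)
    if np.intersect1d(train_index, test_index).size:
        raise ValueError("train and test indices overlap")
    Gm = grm_joint.matrix if isinstance(grm_joint, GRM) else np.asarray(grm_joint)
    Gtt = Gm[np.ix_(train_index, train_index)]
    Gst = Gm[np.ix_(test_index, train_index)]
    g_test = Gst @ np.linalg.solve(Gtt, fit.m_hat)
    if X_test is None:
        X_test = np.ones((test_index.size, fit.beta_hat.size))
    return X_test @ fit.beta_hat + g_test


class GBLUPRegressor:
    """Sklearn-style fit/predict wrapper around GRM + REML + Henderson MME.

    fit() estimates variance components on the training GRM and solves the
    MME; predict() rebuilds a joint GRM over train + new individuals so that
    relationships to the training set drive the projection.
    """

    def __init__(self, ridge_epsilon: float = 1e-6, variance_ratio: float | None = None):
        self.ridge_epsilon = ridge_epsilon
        self.variance_ratio = variance_ratio  # fixed delta = s2e/s2g, skips REML

    def fit(self, genotypes: np.ndarray, y: np.ndarray) -> "GBLUPRegressor":
        self.X_train_ = np.asarray(genotypes, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self.y_train_ = y
        n = y.shape[0]
        grm = compute_grm(self.X_train_, self.ridge_epsilon)
        ones = np.ones((n, 1))
        if self.variance_ratio is None:
            s2g, s2e, ll = reml_variances(y, ones, grm)
        else:
            s2g, s2e, ll = 1.0, float(self.variance_ratio), None
        # keep variances off exact zero so the Henderson system stays regular
        s2g = max(s2g, 1e-8)
        s2e = max(s2e, 1e-8)
        spec = MixedModelSpec(y=y, X=ones, Z=np.eye(n), G=s2g * grm.matrix, R=s2e * np.eye(n))
        mme = solve_mme(spec)
        self.fit_ = MixedModelFit(
            beta_hat=mme.beta_hat, m_hat=mme.m_hat, sigma2_g=s2g, sigma2_e=s2e, log_likelihood=ll
        )
        return self

    def predict(self, genotypes: np.ndarray) -> np.ndarray:
        check = getattr(self, "fit_", None)
        if check is None:
            raise GBLUPError("regressor is not fitted")
        Xnew = np.asarray(genotypes, dtype=float)
        n_tr = self.X_train_.shape[0]
        joint = np.vstack([self.X_train_, Xnew])
        grm_joint = compute_grm(joint, self.ridge_epsilon)
        train_idx = np.arange(n_tr)
        test_idx = np.arange(n_tr, n_tr + Xnew.shape[0])
        # refit BLUPs on the train block of the joint GRM so the projection
        # and the random-effect solutions share one relationship scale
        Gtt = grm_joint.matrix[np.ix_(train_idx, train_idx)]
        spec = MixedModelSpec(
            y=self.y_train_,
            X=np.ones((n_tr, 1)),
            Z=np.eye(n_tr),
            G=self.fit_.sigma2_g * Gtt,
            R=self.fit_.sigma2_e * np.eye(n_tr),
        )
        mme = solve_mme(spec)
        fit = MixedModelFit(beta_hat=mme.beta_hat, m_hat=mme.m_hat)
        return predict_gblup(fit, grm_joint, train_idx, test_idx)
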
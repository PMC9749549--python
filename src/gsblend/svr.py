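"""Epsilon-insensitive support vector regression on marker matrices.

The learner minimizes  ||w||^2 / 2 + c * sum_i L_eps(y_i - f(x_i))  with the
epsilon-insensitive L1 loss, for a linear or radial-basis kernel.  The RBF
kernel is the default: its implicit feature space contains marker products,
which is what lets the model pick up epistatic (non-additive) signal that a
linear genomic model cannot.  The quadratic program is solved by
scikit-learn's SVR; this module owns the configuration surface,
standardization, and the dual representation used for prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVR as _SkSVR

__all__ = ["SVRConfig", "SVRFit", "fit_svr", "predict_svr", "SVREngine"]


@dataclass(frozen=True)
class SVRConfig:
    """Hyperparameters of the epsilon-SVR learner.

    gamma is the RBF bandwidth; None means 1/p on the standardized marker
    matrix.  loss_exponent is fixed at 1 (standard epsilon-insensitive L1
    loss); it is recorded for completeness only.
    """

    kernel: str = "rbf"  # "rbf" or "linear"
    regularization_c: float = 1.0
    epsilon_tube: float = 0.1
    gamma: float | None = None
    standardize: bool = True
    loss_exponent: int = 1

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if self.regularization_c <= 0:
            raise ValueError("regularization_c must be positive")
        if self.epsilon_tube < 0:
            raise ValueError("epsilon_tube must be non-negative")
        if self.loss_exponent != 1:
            raise ValueError("only the L1 epsilon-insensitive loss (exponent 1) is supported")


@dataclass
class SVRFit:
    """Fitted SVR in dual form plus the standardization applied to markers."""

    support_coefficients: np.ndarray  # length n_train; zero off the support
    bias: float
    column_means: np.ndarray
    column_scales: np.ndarray
    X_train_std: np.ndarray  # standardized training matrix (kernel expansion)
    config: SVRConfig
    gamma_: float | None  # resolved RBF bandwidth

    @property
    def training_column_stats(self) -> tuple[np.ndarray, np.ndarray]:
        return self.column_means, self.column_scales


def _standardize_stats(X: np.ndarray, enabled: bool) -> tuple[np.ndarray, np.ndarray]:
    if not enabled:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0  # constant markers carry no signal; leave them
    return mean, scale


def fit_svr(X: np.ndarray, y: np.ndarray, config: SVRConfig = SVRConfig()) -> SVRFit:
    """Fit epsilon-SVR; deterministic for fixed inputs.

    Zero-variance phenotypes degrade to a bias-only constant predictor with a
    warning instead of failing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of individuals")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    mean, scale = _standardize_stats(X, config.standardize)
    Xs = (X - mean) / scale
    gamma = config.gamma if config.gamma is not None else 1.0 / X.shape[1]
    if np.var(y) == 0.0:
        warnings.warn("constant phenotype; SVR degenerates to a bias-only predictor", RuntimeWarning)
        return SVRFit(
            support_coefficients=np.zeros(X.shape[0]),
            bias=float(y[0]),
            column_means=mean,
            column_scales=scale,
            X_train_std=Xs,
            config=config,
            gamma_=gamma if config.kernel == "rbf" else None,
        )
    sk = _SkSVR(
        kernel=config.kernel,
        C=config.regularization_c,
        epsilon=config.epsilon_tube,
        gamma=gamma if config.kernel == "rbf" else "scale",
        tol=1e-6,
        max_iter=-1,
    )
    sk.fit(Xs, y)
    coef = np.zeros(X.shape[0])
    coef[sk.support_] = sk.dual_coef_.ravel()
    return SVRFit(
        support_coefficients=coef,
        bias=float(sk.intercept_[0]),
        column_means=mean,
        column_scales=scale,
        X_train_std=Xs,
        config=config,
        gamma_=gamma if config.kernel == "rbf" else None,
    )


def _kernel_matrix(fit: SVRFit, A: np.ndarray) -> np.ndarray:
    """K(A, X_train) for the fitted kernel."""
    B = fit.X_train_std
    if fit.config.kernel == "linear":
        return A @ B.T
    sq = (A * A).sum(axis=1)[:, None] + (B * B).sum(axis=1)[None, :] - 2.0 * A @ B.T
    np.clip(sq, 0.0, None, out=sq)
    return np.exp(-fit.gamma_ * sq)


def predict_svr(fit: SVRFit, X_new: np.ndarray) -> np.ndarray:
    """Kernel expansion over the support set plus bias, after applying the
    training-time standardization."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != fit.column_means.shape[0]:
        raise ValueError(
            f"expected {fit.column_means.shape[0]} marker columns, got "
            f"{X_new.shape[1] if X_new.ndim == 2 else 'non-2D input'}"
        )
    Xs = (X_new - fit.column_means) / fit.column_scales
    return _kernel_matrix(fit, Xs) @ fit.support_coefficients + fit.bias


def linear_weights(fit: SVRFit) -> tuple[np.ndarray, float]:
    """Primal weights w = sum_i alpha_i x_i for a linear-kernel fit (on the
    standardized scale), plus the bias."""
    if fit.config.kernel != "linear":
        raise ValueError("primal weights are defined for the linear kernel only")
    return fit.X_train_std.T @ fit.support_coefficients, fit.bias


class SVREngine:
    """fit/predict facade matching GBLUPRegressor for use in CV loops."""

    def __init__(self, config: SVRConfig = SVRConfig()):
        self.config = config

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVREngine":
        self.fit_ = fit_svr(X, y, self.config)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_svr(self.fit_, X)
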
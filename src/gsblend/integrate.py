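"""Inverse-error-variance integration of GBLUP and SVR predictions, and the
repeated-holdout evaluation protocol.

The integrated predictor is the convex combination

    Y_Est = w * Y_GBLUP + (1 - w) * Y_SVR,
    w     = sigma2_SVR / (sigma2_GBLUP + sigma2_SVR),

the weight that minimizes the variance of the combination when the two
component errors are uncorrelated.  Its theoretical error variance is the
harmonic form

    sigma2_Est = sigma2_GBLUP * sigma2_SVR / (sigma2_GBLUP + sigma2_SVR),

which is strictly below min(sigma2_GBLUP, sigma2_SVR) whenever both are
positive — blending never hurts in this idealization.

Evaluation follows the standard genomic-selection protocol: repeated random
70/30 train/validation splits; models are fitted, and error variances
estimated by RCV or k-RCV, inside the training split only; predictive
ability (Pearson r between observed and predicted phenotype) and MSE are
computed on the validation split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .gblup import GBLUPRegressor
from .rcv import VariancePair, variance_pair
from .svr import SVRConfig, SVREngine

__all__ = [
    "IntegrationResult",
    "EvalMetrics",
    "RepResult",
    "CVResult",
    "integration_weight",
    "integrated_variance",
    "integrate_predictions",
    "integrate",
    "predictive_ability",
    "mse",
    "evaluate_predictions",
    "repeated_holdout",
]

logger = logging.getLogger(__name__)

MODELS = ("gblup", "svr", "integrated")


@dataclass
class IntegrationResult:
    weight: float
    y_est: np.ndarray
    sigma2_est: float
    variance_pair: VariancePair

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("integration weight must lie in [0, 1]")


@dataclass
class EvalMetrics:
    predictive_ability: float
    mse: float
    covariance_term: float
    sd_observed: float
    sd_predicted: float
    n_eval: int


@dataclass
class RepResult:
    rep: int
    seed: int
    metrics: dict[str, EvalMetrics]
    weight: float
    variance_pair: VariancePair
    sigma2_est: float


@dataclass
class CVResult:
    per_rep: list[RepResult]
    mean_pa: dict[str, float]
    se_pa: dict[str, float]
    mean_mse: dict[str, float]
    n_reps: int
    train_fraction: float
    n_excluded: int = 0


def _check_variances(sigma2_gblup: float, sigma2_svr: float) -> None:
    if sigma2_gblup < 0 or sigma2_svr < 0:
        raise ValueError("error variances must be non-negative")
    if sigma2_gblup + sigma2_svr == 0:
        raise ValueError("both error variances are zero; weight undefined")


def integration_weight(sigma2_gblup: float, sigma2_svr: float) -> float:
    """w = sigma2_SVR / (sigma2_GBLUP + sigma2_SVR): the weight on the GBLUP
    prediction grows as the SVR error variance grows."""
    _check_variances(sigma2_gblup, sigma2_svr)
    return sigma2_svr / (sigma2_gblup + sigma2_svr)


def integrated_variance(sigma2_gblup: float, sigma2_svr: float) -> float:
    """Theoretical error variance of the blend: product over sum."""
    _check_variances(sigma2_gblup, sigma2_svr)
    return sigma2_gblup * sigma2_svr / (sigma2_gblup + sigma2_svr)


def integrate_predictions(y_gblup: np.ndarray, y_svr: np.ndarray, w: float) -> np.ndarray:
    """Elementwise convex combination w * Y_GBLUP + (1 - w) * Y_SVR."""
    y_gblup = np.asarray(y_gblup, dtype=float)
    y_svr = np.asarray(y_svr, dtype=float)
    if y_gblup.shape != y_svr.shape:
        raise ValueError("component prediction vectors differ in length")
    if not 0.0 <= w <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    return w * y_gblup + (1.0 - w) * y_svr


def integrate(y_gblup: np.ndarray, y_svr: np.ndarray, pair: VariancePair) -> IntegrationResult:
    """Blend two prediction vectors using an estimated variance pair.

    If both estimated variances are exactly zero (both components predicted
    the held-out data perfectly) the weight is undefined; equal weights are
    used, which changes nothing when the components agree.
    """
    if pair.sigma2_gblup == 0.0 and pair.sigma2_svr == 0.0:
        return IntegrationResult(
            weight=0.5,
            y_est=integrate_predictions(y_gblup, y_svr, 0.5),
            sigma2_est=0.0,
            variance_pair=pair,
        )
    w = integration_weight(pair.sigma2_gblup, pair.sigma2_svr)
    return IntegrationResult(
        weight=w,
        y_est=integrate_predictions(y_gblup, y_svr, w),
        sigma2_est=integrated_variance(pair.sigma2_gblup, pair.sigma2_svr),
        variance_pair=pair,
    )


def predictive_ability(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation between observed and predicted phenotypes."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.shape != y_pred.shape or y_obs.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    s_obs = y_obs.std(ddof=1)
    s_pred = y_pred.std(ddof=1)
    if s_obs == 0.0 or s_pred == 0.0:
        raise ValueError("predictive ability undefined for a constant vector")
    cov = np.cov(y_obs, y_pred, ddof=1)[0, 1]
    return float(cov / (s_obs * s_pred))


def mse(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared error (1/n) sum (Y_i - Yhat_i)^2."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(np.mean((y_obs - y_pred) ** 2))


def evaluate_predictions(y_obs: np.ndarray, y_pred: np.ndarray) -> EvalMetrics:
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    return EvalMetrics(
        predictive_ability=predictive_ability(y_obs, y_pred),
        mse=mse(y_obs, y_pred),
        covariance_term=float(np.cov(y_obs, y_pred, ddof=1)[0, 1]),
        sd_observed=float(y_obs.std(ddof=1)),
        sd_predicted=float(y_pred.std(ddof=1)),
        n_eval=int(y_obs.size),
    )


def _rep_seed(base_seed: int, rep: int) -> int:
    # deterministic per-rep seed, kept within int32 range
    return (base_seed * 100_003 + rep) % (2**31 - 1)


def repeated_holdout(
    genotypes: np.ndarray,
    phenotypes: np.ndarray,
    n_reps: int = 100,
    train_fraction: float = 0.7,
    variance_method: str = "rcv",
    k: int = 5,
    base_seed: int = 0,
    gblup_model: GBLUPRegressor | None = None,
    svr_model: SVREngine | None = None,
) -> CVResult:
    """Repeated 70/30 holdout evaluation of GBLUP, SVR and the integrated model.

    Per repetition: random train/validation split; both component models are
    fitted on the training split; the error-variance pair is estimated by RCV
    or k-RCV *within the training split*; the integration weight is formed;
    all three models predict the validation split and are scored by
    predictive ability and MSE.  Results aggregate to means and standard
    errors across repetitions.  Fully reproducible from ``base_seed``.

    Repetitions whose validation phenotypes are constant (predictive ability
    undefined) are excluded from the aggregates and counted.
    """
    X = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotypes, dtype=float).ravel()
    n = y.shape[0]
    if n < 10:
        raise ValueError("need at least 10 individuals for holdout evaluation")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    gblup_model = gblup_model if gblup_model is not None else GBLUPRegressor()
    svr_model = svr_model if svr_model is not None else SVREngine(SVRConfig())

    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 2), n - 1)
    per_rep: list[RepResult] = []
    excluded = 0
    for rep in range(n_reps):
        seed = _rep_seed(base_seed, rep)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        train, valid = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        if np.std(y[valid]) == 0.0 or np.std(y[train]) == 0.0:
            excluded += 1
            logger.warning("rep %d: degenerate split (constant phenotypes); excluded", rep)
            continue
        import copy

        g = copy.deepcopy(gblup_model).fit(X[train], y[train])
        s = copy.deepcopy(svr_model).fit(X[train], y[train])
        pair = variance_pair(
            gblup_model, svr_model, X[train], y[train],
            method=variance_method, k=k, seed=seed,
        )
        pred_g = g.predict(X[valid])
        pred_s = s.predict(X[valid])
        result = integrate(pred_g, pred_s, pair)
        metrics = {
            "gblup": evaluate_predictions(y[valid], pred_g),
            "svr": evaluate_predictions(y[valid], pred_s),
            "integrated": evaluate_predictions(y[valid], result.y_est),
        }
        per_rep.append(
            RepResult(rep=rep, seed=seed, metrics=metrics, weight=result.weight,
                      variance_pair=pair, sigma2_est=result.sigma2_est)
        )
    if not per_rep:
        raise ValueError("all repetitions produced degenerate validation splits")
    mean_pa, se_pa, mean_mse = {}, {}, {}
    n_ok = len(per_rep)
    for model in MODELS:
        pas = np.array([r.metrics[model].predictive_ability for r in per_rep])
        mses = np.array([r.metrics[model].mse for r in per_rep])
        mean_pa[model] = float(pas.mean())
        se_pa[model] = float(pas.std(ddof=1) / math.sqrt(n_ok)) if n_ok > 1 else 0.0
        mean_mse[model] = float(mses.mean())
    return CVResult(
        per_rep=per_rep,
        mean_pa=mean_pa,
        se_pa=se_pa,
        mean_mse=mean_mse,
        n_reps=n_ok,
        train_fraction=train_fraction,
        n_excluded=excluded,
    )
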
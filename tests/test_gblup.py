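"""GBLUP engine: GRM construction, REML variance components, Henderson
mixed-model equations, and out-of-sample prediction."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

import gsblend
from gsblend import GBLUPRegressor, compute_grm, predict_gblup, reml_variances, solve_mme
from gsblend.gblup import GBLUPError, MixedModelSpec


def test_grm_hand_example():
    """M = [[0,2],[2,0]]: p = (0.5, 0.5), centered W = [[-1,1],[1,-1]],
    denominator 2*2*0.25 = 1, so G = [[2,-2],[-2,2]] plus the ridge."""
    grm = compute_grm(np.array([[0, 2], [2, 0]]))
    np.testing.assert_allclose(grm.matrix, [[2, -2], [-2, 2]], atol=1e-5)
    assert grm.scaling == pytest.approx(1.0)


def test_grm_duplicate_individuals_share_relationship():
    rng = np.random.default_rng(0)
    M = rng.integers(0, 3, size=(4, 30))
    M[1] = M[0]
    grm = compute_grm(M)
    assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0] - grm.ridge_epsilon)


def test_grm_drops_monomorphic_and_centers():
    M = np.array([[0, 1, 2], [0, 2, 0], [0, 0, 1]])  # first marker monomorphic
    grm = compute_grm(M)
    assert list(grm.kept_markers) == [1, 2]
    with pytest.raises(GBLUPError):
        compute_grm(np.ones((3, 4)))


def test_solve_mme_toy_instance():
    """y = [1, 3], intercept-only X, Z = G = R = I: the 3x3 Henderson system
    gives beta = 2 and m = (-1/2, 1/2)."""
    spec = MixedModelSpec(y=np.array([1.0, 3.0]), X=np.ones((2, 1)),
                          Z=np.eye(2), G=np.eye(2), R=np.eye(2))
    fit = solve_mme(spec)
    assert fit.beta_hat == pytest.approx([2.0])
    np.testing.assert_allclose(fit.m_hat, [-0.5, 0.5], atol=1e-10)


def test_mme_equals_joint_density_maximizer():
    """On random 5-individual instances the Henderson solution matches a
    brute-force maximizer of the joint log-density of (y, m)."""
    rng = np.random.default_rng(42)
    n = 5
    for _ in range(20):
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        A = rng.normal(size=(n, n))
        G = A @ A.T + n * np.eye(n)
        B = rng.normal(size=(n, n))
        R = B @ B.T / 4 + n * np.eye(n)
        y = 2 * rng.normal(size=n)
        fit = solve_mme(MixedModelSpec(y=y, X=X, Z=np.eye(n), G=G, R=R))
        Ri, Gi = np.linalg.inv(R), np.linalg.inv(G)

        def neg_joint(v):
            b, m = v[:2], v[2:]
            r = y - X @ b - m
            return 0.5 * r @ Ri @ r + 0.5 * m @ Gi @ m

        def grad(v):
            b, m = v[:2], v[2:]
            r = y - X @ b - m
            return np.concatenate([-X.T @ Ri @ r, -Ri @ r + Gi @ m])

        res = minimize(neg_joint, np.zeros(n + 2), jac=grad, method="Newton-CG",
                       hess=lambda v: np.block([[X.T @ Ri @ X, X.T @ Ri],
                                                [Ri @ X, Ri + Gi]]),
                       options={"xtol": 1e-12})
        np.testing.assert_allclose(res.x[:2], fit.beta_hat, atol=1e-6)
        np.testing.assert_allclose(res.x[2:], fit.m_hat, atol=1e-6)


def test_no_shrinkage_limit_recovers_ols_residuals():
    """As G -> infinity * I the BLUPs approach the OLS residuals."""
    rng = np.random.default_rng(1)
    n = 8
    y = rng.normal(size=n)
    X = np.ones((n, 1))
    fit = solve_mme(MixedModelSpec(y=y, X=X, Z=np.eye(n), G=1e10 * np.eye(n), R=np.eye(n)))
    np.testing.assert_allclose(fit.m_hat, y - y.mean(), atol=1e-6)


def test_shrinkage_monotone_in_variance_ratio(small_f2):
    """||m_hat|| is non-increasing as delta = sigma2_e/sigma2_g grows."""
    ds = small_f2
    norms = []
    for delta in (0.1, 1.0, 10.0, 100.0):
        model = GBLUPRegressor(variance_ratio=delta).fit(ds.genotypes, ds.phenotypes)
        norms.append(np.linalg.norm(model.fit_.m_hat))
    assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))


def test_location_equivariance(small_f2):
    ds = small_f2
    m1 = GBLUPRegressor(variance_ratio=1.0).fit(ds.genotypes, ds.phenotypes)
    m2 = GBLUPRegressor(variance_ratio=1.0).fit(ds.genotypes, ds.phenotypes + 100.0)
    assert m2.fit_.beta_hat[0] - m1.fit_.beta_hat[0] == pytest.approx(100.0, abs=1e-6)
    np.testing.assert_allclose(m1.fit_.m_hat, m2.fit_.m_hat, atol=1e-6)
    np.testing.assert_allclose(
        m2.predict(ds.genotypes[:5]) - m1.predict(ds.genotypes[:5]), 100.0, atol=1e-6
    )


def test_reml_recovers_simulated_heritability():
    """Mean REML h2-hat over 20 F2 simulations at h2 = 0.7, n = 200 lands
    within 0.15 of the target."""
    h2_hats = []
    for seed in range(20):
        ds = gsblend.simulate_dataset(gsblend.SimulationConfig(
            heritability=0.7, markers_per_chromosome=50, seed=100 + seed))
        grm = compute_grm(ds.genotypes)
        s2g, s2e, _ = reml_variances(ds.phenotypes, np.ones((200, 1)), grm)
        h2_hats.append(s2g / (s2g + s2e))
    assert abs(np.mean(h2_hats) - 0.7) < 0.15


def test_reml_constant_y_hits_zero_genetic_variance():
    rng = np.random.default_rng(2)
    M = rng.integers(0, 3, size=(30, 50))
    grm = compute_grm(M)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s2g, s2e, _ = reml_variances(np.full(30, 3.0), np.ones((30, 1)), grm)
    assert s2g < 1e-8


def test_reml_rejects_bad_input():
    grm = compute_grm(np.array([[0, 1], [2, 0], [1, 2]]))
    with pytest.raises(ValueError):
        reml_variances(np.array([1.0, np.nan, 2.0]), np.ones((3, 1)), grm)


def test_gblup_matches_marker_ridge():
    """GBLUP predictions coincide (r > 0.999) with ridge regression on
    centered marker dosages at penalty sigma2_e / sigma2_m, the classical
    RR-BLUP equivalence, on a 50-train / 20-test instance with 100 markers."""
    cfg = gsblend.SimulationConfig(n_individuals=70, n_chromosomes=5,
                                   markers_per_chromosome=20, heritability=0.5, seed=7)
    ds = gsblend.simulate_dataset(cfg)
    X, y, Xte = ds.genotypes[:50], ds.phenotypes[:50], ds.genotypes[50:]
    model = GBLUPRegressor().fit(X, y)
    pred_gblup = model.predict(Xte)
    fit, grm = model.fit_, compute_grm(X)
    lam = fit.sigma2_e / (fit.sigma2_g / grm.scaling)
    W = X.astype(float) - X.mean(axis=0)
    u = W.T @ np.linalg.solve(W @ W.T + lam * np.eye(50), y - y.mean())
    pred_ridge = y.mean() + (Xte - X.mean(axis=0)) @ u
    assert np.corrcoef(pred_gblup, pred_ridge)[0, 1] > 0.999


def test_predict_duplicate_of_training_individual(small_f2):
    """A test individual genotypically identical to a training one receives
    (within ridge tolerance) that individual's fitted value."""
    ds = small_f2
    model = GBLUPRegressor().fit(ds.genotypes, ds.phenotypes)
    fitted = model.fit_.beta_hat[0] + model.fit_.m_hat
    pred = model.predict(ds.genotypes[:5])
    np.testing.assert_allclose(pred, fitted[:5], atol=1e-3)


def test_predict_gblup_rejects_index_overlap():
    grm = compute_grm(np.array([[0, 1], [2, 0], [1, 2]]))
    fit = solve_mme(MixedModelSpec(y=np.array([1.0, 2.0]), X=np.ones((2, 1)),
                                   Z=np.eye(2), G=np.eye(2), R=np.eye(2)))
    with pytest.raises(ValueError):
        predict_gblup(fit, grm, np.array([0, 1]), np.array([1, 2]))
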
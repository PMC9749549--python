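"""Shared fixtures: small simulated datasets and the reduced-scale
repeated-holdout runs reused across evaluation tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import gsblend
from gsblend import GBLUPRegressor, SVREngine, SimulationConfig


class OracleModel:
    """Predictor that returns a fixed known function of the features,
    ignoring the training data (true-signal oracle for RCV checks)."""

    def __init__(self, fn):
        self.fn = fn

    def fit(self, X, y):
        return self

    def predict(self, X):
        return self.fn(X)


@pytest.fixture(scope="session")
def small_f2():
    """60 individuals x 100 markers, additive architecture, h2 = 0.5."""
    cfg = SimulationConfig(
        n_individuals=60, n_chromosomes=4, markers_per_chromosome=25,
        heritability=0.5, architecture_tag="a_e0", seed=5,
    )
    return gsblend.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def holdout_results():
    """Reduced-scale repeated-holdout (20 reps) on the four study scenarios:
    (a,e0) and (a,e1) architectures at h2 in {0.3, 0.5}, full 200 x 2000
    scale.  Session-scoped because several orderings are read off it."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tag in ("a_e0", "a_e1"):
            for h2 in (0.3, 0.5):
                ds = gsblend.simulate_dataset(
                    SimulationConfig(heritability=h2, architecture_tag=tag, seed=11)
                )
                out[(tag, h2)] = gsblend.repeated_holdout(
                    ds.genotypes, ds.phenotypes, n_reps=20, base_seed=17
                )
    return out
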
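"""F2 simulator: Cockerham contrasts, meiosis along the map, heritability
calibration, and architecture construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gsblend
from gsblend import SimulationConfig, cockerham_codes, genetic_values, simulate_dataset
from gsblend.simulate import (
    QTLArchitecture,
    build_architecture,
    build_marker_map,
    haldane_r,
    simulate_gametes,
    simulate_phenotypes,
)


@pytest.mark.parametrize("dose,x,z", [(0, -1.0, -0.5), (1, 0.0, 0.5), (2, 1.0, -0.5)])
def test_cockerham_codes(dose, x, z):
    assert cockerham_codes(dose) == (x, z)


def test_cockerham_codes_rejects_bad_dose():
    with pytest.raises(ValueError):
        cockerham_codes(3)
    with pytest.raises(ValueError):
        cockerham_codes(np.array([0, 1, 5]))


@pytest.mark.parametrize(
    "arch,doses,expected",
    [
        # single additive QTL, homozygous AA: G = a * x = 1
        (QTLArchitecture(0.0, ((0, 1.0),), (), ()), [[2]], [1.0]),
        # pure additive-by-additive pair at doses (2, 0): x1 x2 = -1
        (QTLArchitecture(0.0, (), (), ((0, 1, 1.0, 0.0, 0.0, 0.0),)), [[2, 0]], [-1.0]),
        # mean + additive + dominance at a heterozygote: 5 + 0 + 2 * 1/2 = 6
        (QTLArchitecture(5.0, ((0, 1.0),), ((0, 2.0),), ()), [[1]], [6.0]),
    ],
)
def test_genetic_values_hand_examples(arch, doses, expected):
    np.testing.assert_allclose(genetic_values(np.array(doses), arch), expected)


def test_genetic_values_locus_out_of_range():
    arch = QTLArchitecture(0.0, ((5, 1.0),), (), ())
    with pytest.raises(IndexError):
        genetic_values(np.array([[0, 1]]), arch)


def test_f2_segregation_is_1_2_1():
    """Single-locus genotype counts pass a chi-square test against 1:2:1."""
    cfg = SimulationConfig(n_individuals=4000, n_chromosomes=1,
                           markers_per_chromosome=1, chromosome_length=1.0, seed=2)
    geno, _ = gsblend.simulate_f2_genotypes(cfg)
    counts = np.bincount(geno[:, 0], minlength=3)
    stat, p = stats.chisquare(counts, f_exp=4000 * np.array([0.25, 0.5, 0.25]))
    assert p > 0.01


def test_zero_distance_markers_never_recombine():
    rng = np.random.default_rng(0)
    gametes = simulate_gametes(5000, [10.0, 10.0], rng)
    assert np.array_equal(gametes[:, 0], gametes[:, 1])


def test_recombinant_fraction_matches_haldane():
    """Empirical recombinant fraction over 1e5 gametes at 10 cM matches the
    Haldane closed form 0.5 (1 - exp(-0.2)) within 0.003."""
    rng = np.random.default_rng(3)
    gametes = simulate_gametes(100_000, [0.0, 10.0], rng)
    observed = np.mean(gametes[:, 0] != gametes[:, 1])
    assert abs(observed - haldane_r(10.0)) < 0.003
    assert abs(haldane_r(10.0) - 0.0906) < 5e-4


def test_phenotype_noise_calibration():
    rng = np.random.default_rng(4)
    g = rng.normal(size=5000)
    y, e, realized = simulate_phenotypes(g, 0.5, seed=1)
    # (1 - h2)/h2 = 1 at h2 = 0.5, so noise variance matches Var(G)
    assert abs(e.var(ddof=1) - g.var(ddof=1)) < 0.1
    y_hi, e_hi, _ = simulate_phenotypes(g, 0.999, seed=1)
    assert e_hi.var(ddof=1) < 0.005
    with pytest.raises(ValueError):
        simulate_phenotypes(np.ones(10), 0.5)


def test_realized_h2_converges():
    """Broad-sense Var(G)/Var(Y) tracks the configured h2 at n = 2000."""
    for seed in range(3):
        ds = simulate_dataset(SimulationConfig(
            n_individuals=2000, heritability=0.3, seed=300 + seed))
        assert abs(ds.realized_h2 - 0.3) < 0.03


def test_fixed_seed_is_bit_identical():
    cfg = SimulationConfig(n_individuals=30, n_chromosomes=2,
                           markers_per_chromosome=10, seed=9)
    a, b = simulate_dataset(cfg), simulate_dataset(cfg)
    assert np.array_equal(a.genotypes, b.genotypes)
    assert np.array_equal(a.phenotypes, b.phenotypes)
    assert a.realized_h2 == b.realized_h2


def test_contrast_orthogonality():
    """At any locus, E[x] = 0 and corr(x, z) = 0 under 1:2:1 segregation."""
    cfg = SimulationConfig(n_individuals=5000, n_chromosomes=1,
                           markers_per_chromosome=5, seed=6)
    geno, _ = gsblend.simulate_f2_genotypes(cfg)
    x, z = cockerham_codes(geno)
    assert np.all(np.abs(x.mean(axis=0)) < 0.05)
    for j in range(geno.shape[1]):
        assert abs(np.corrcoef(x[:, j], z[:, j])[0, 1]) < 0.05


def test_additive_architecture_fully_additive(small_f2):
    """(a,e0) genetic values are exactly linear in the QTL x-contrasts."""
    ds = small_f2
    loci = [l for l, _ in ds.architecture.additive_effects]
    x, _ = cockerham_codes(ds.genotypes[:, loci])
    X = np.column_stack([np.ones(ds.n_individuals), x])
    resid = ds.genetic_values - X @ np.linalg.lstsq(X, ds.genetic_values, rcond=None)[0]
    ss_res = np.sum(resid**2)
    ss_tot = np.sum((ds.genetic_values - ds.genetic_values.mean()) ** 2)
    assert 1.0 - ss_res / ss_tot > 0.999999


@pytest.mark.parametrize("tag,n_pairs", [("a_e0", 0), ("a_e1", 5), ("a_e2", 7), ("a_e3", 10)])
def test_architecture_counts(tag, n_pairs):
    cfg = SimulationConfig(architecture_tag=tag)
    arch = build_architecture(cfg)
    assert len(arch.epistatic_effects) == n_pairs
    if n_pairs == 0:
        # one additive QTL per chromosome, alternating sign
        assert len(arch.additive_effects) == cfg.n_chromosomes
        signs = [np.sign(a) for _, a in arch.additive_effects]
        assert signs == [1.0 if c % 2 == 0 else -1.0 for c in range(cfg.n_chromosomes)]
    else:
        # two QTL on each affected chromosome, within-chromosome interaction
        chroms = {l // cfg.markers_per_chromosome for l, _ in arch.additive_effects}
        assert chroms == set(range(n_pairs))
        for la, lb, *_ in arch.epistatic_effects:
            assert la // cfg.markers_per_chromosome == lb // cfg.markers_per_chromosome


def test_architecture_tag_spellings():
    assert SimulationConfig(architecture_tag="(a,e1)").architecture_tag == "a_e1"
    with pytest.raises(ValueError):
        SimulationConfig(architecture_tag="a_e4")


def test_marker_map_is_equispaced_and_increasing():
    cfg = SimulationConfig(n_chromosomes=3, markers_per_chromosome=10, chromosome_length=50.0)
    mm = build_marker_map(cfg)
    for _, grp in mm.groupby("chrom"):
        d = np.diff(grp["pos_cM"].to_numpy())
        np.testing.assert_allclose(d, 5.0)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_individuals": 0},
        {"chromosome_length": 0.0},
        {"heritability": 0.0},
        {"heritability": 1.0},
        {"architecture_tag": "a_e3", "n_chromosomes": 5},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs)
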
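"""F2 population simulator under Cockerham's orthogonal QTL model.

Simulates biallelic SNP genotypes for an F2 intercross by dropping gametes
along a genetic map (Haldane map function, no interference) and builds
phenotypes as

    Y = G + e,   G = mu + sum_l a_l x_l + d_l z_l
                      + sum_pairs i_aa w_aa + i_ad w_ad + i_da w_da + i_dd w_dd

where x is the additive contrast (-1, 0, +1 for the three dose classes),
z the dominance contrast (-1/2, +1/2, -1/2), and the two-locus design values
are products w_aa = x1 x2, w_ad = x1 z2, w_da = z1 x2, w_dd = z1 z2.  Under
1:2:1 F2 segregation x and z are orthogonal, so additive and dominance
variance partition cleanly.

Residuals are drawn i.i.d. normal with variance calibrated so that the
broad-sense heritability Var(G)/Var(Y) matches the configured h^2 in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "QTLArchitecture",
    "F2Dataset",
    "ARCHITECTURE_TAGS",
    "cockerham_codes",
    "build_marker_map",
    "build_architecture",
    "simulate_gametes",
    "simulate_f2_genotypes",
    "genetic_values",
    "simulate_phenotypes",
    "simulate_dataset",
]

#: number of interacting QTL pairs per architecture tag
ARCHITECTURE_TAGS = {"a_e0": 0, "a_e1": 5, "a_e2": 7, "a_e3": 10}


def _normalize_tag(tag: str) -> str:
    # accept both "a_e1" and the "(a,e1)" notation
    t = tag.strip().lower().replace("(", "").replace(")", "").replace(",", "_").replace(" ", "")
    t = t.replace("__", "_")
    if t not in ARCHITECTURE_TAGS:
        raise ValueError(f"unknown architecture tag {tag!r}; expected one of {sorted(ARCHITECTURE_TAGS)}")
    return t


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated F2 study.

    Defaults reproduce the reference scenario: 200 individuals, 10
    chromosomes of 100 cM carrying 200 equispaced SNPs each (2000 markers),
    heritability in {0.3, 0.5, 0.7}.
    """

    n_individuals: int = 200
    n_chromosomes: int = 10
    markers_per_chromosome: int = 200
    chromosome_length: float = 100.0  # cM
    heritability: float = 0.5
    architecture_tag: str = "a_e0"
    seed: int = 0
    # effect magnitudes; the additive scenario uses |a| = additive_effect with
    # alternating sign per chromosome, epistatic scenarios use i_aa by default
    mu: float = 0.0
    additive_effect: float = 1.0
    dominance_effect: float = 0.0
    i_aa: float = 1.0
    i_ad: float = 0.0
    i_da: float = 0.0
    i_dd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_chromosomes <= 0 or self.markers_per_chromosome <= 0:
            raise ValueError("population and map dimensions must be positive")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive (cM)")
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must lie strictly in (0, 1)")
        object.__setattr__(self, "architecture_tag", _normalize_tag(self.architecture_tag))
        n_pairs = ARCHITECTURE_TAGS[self.architecture_tag]
        if n_pairs > self.n_chromosomes:
            raise ValueError(
                f"architecture {self.architecture_tag} needs {n_pairs} chromosomes, "
                f"config has {self.n_chromosomes}"
            )

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


@dataclass(frozen=True)
class QTLArchitecture:
    """Effect set of the genotype-to-genetic-value map.

    Loci are global 0-based column indices into the genotype matrix.
    Epistatic entries are (locusA, locusB, i_aa, i_ad, i_da, i_dd).
    """

    mu: float
    additive_effects: tuple[tuple[int, float], ...]
    dominance_effects: tuple[tuple[int, float], ...]
    epistatic_effects: tuple[tuple[int, int, float, float, float, float], ...]

    def validate(self, n_markers: int) -> None:
        loci = [l for l, _ in self.additive_effects]
        loci += [l for l, _ in self.dominance_effects]
        for la, lb, *_ in self.epistatic_effects:
            loci += [la, lb]
        for l in loci:
            if not 0 <= l < n_markers:
                raise IndexError(f"QTL locus {l} outside marker map of size {n_markers}")


@dataclass
class F2Dataset:
    """One simulated F2 dataset: genotypes, truth, and phenotypes."""

    genotypes: np.ndarray  # (n, p) int8 doses in {0,1,2}
    marker_map: pd.DataFrame  # columns marker, chrom, pos_cM
    genetic_values: np.ndarray
    phenotypes: np.ndarray
    residuals: np.ndarray
    architecture: QTLArchitecture
    realized_h2: float
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.phenotypes, self.genetic_values + self.residuals):
            raise ValueError("phenotypes must equal genetic_values + residuals")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotype doses must be in {0, 1, 2}")
        for _, grp in self.marker_map.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos_cM"].to_numpy()) > 0):
                raise ValueError("marker positions must be strictly increasing within chromosomes")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]


def cockerham_codes(dose):
    """Map allele doses {0,1,2} to Cockerham contrasts (x, z).

    x = dose - 1 in {-1, 0, +1}; z = 1/2 - |dose - 1| in {-1/2, +1/2, -1/2}.
    Accepts scalars or arrays.
    """
    d = np.asarray(dose)
    if not np.isin(d, (0, 1, 2)).all():
        raise ValueError("dose values must be in {0, 1, 2}")
    x = d.astype(float) - 1.0
    z = 0.5 - np.abs(x)
    if np.isscalar(dose) or d.ndim == 0:
        return float(x), float(z)
    return x, z


def build_marker_map(config: SimulationConfig) -> pd.DataFrame:
    """Equispaced marker map: marker k of a chromosome sits at k * L/m cM."""
    m = config.markers_per_chromosome
    spacing = config.chromosome_length / m
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1), m)
    pos = np.tile(np.arange(m) * spacing, config.n_chromosomes)
    markers = [f"M{c}_{k + 1}" for c in range(1, config.n_chromosomes + 1) for k in range(m)]
    return pd.DataFrame({"marker": markers, "chrom": chroms, "pos_cM": pos})


def build_architecture(config: SimulationConfig) -> QTLArchitecture:
    """Place QTL on the map according to the architecture tag.

    a_e0: one additive QTL at the middle marker of every chromosome, effect
    sign alternating (+, -, +, ...) across chromosomes.

    a_e1/a_e2/a_e3: two QTL (at the 1/3 and 2/3 markers) on each of the first
    5/7/10 chromosomes, interacting within-chromosome with the configured
    epistatic magnitudes (i_aa = 1 by default); each QTL also carries an
    additive effect with sign alternating by chromosome.  Remaining
    chromosomes are empty.
    """
    m = config.markers_per_chromosome
    n_pairs = ARCHITECTURE_TAGS[config.architecture_tag]
    additive: list[tuple[int, float]] = []
    dominance: list[tuple[int, float]] = []
    epistatic: list[tuple[int, int, float, float, float, float]] = []
    if n_pairs == 0:
        for c in range(config.n_chromosomes):
            locus = c * m + m // 2
            sign = 1.0 if c % 2 == 0 else -1.0
            additive.append((locus, sign * config.additive_effect))
            if config.dominance_effect != 0.0:
                dominance.append((locus, config.dominance_effect))
    else:
        for c in range(n_pairs):
            la = c * m + m // 3
            lb = c * m + (2 * m) // 3
            sign = 1.0 if c % 2 == 0 else -1.0
            if config.additive_effect != 0.0:
                additive.append((la, sign * config.additive_effect))
                additive.append((lb, sign * config.additive_effect))
            if config.dominance_effect != 0.0:
                dominance.append((la, config.dominance_effect))
                dominance.append((lb, config.dominance_effect))
            epistatic.append((la, lb, config.i_aa, config.i_ad, config.i_da, config.i_dd))
    arch = QTLArchitecture(
        mu=config.mu,
        additive_effects=tuple(additive),
        dominance_effects=tuple(dominance),
        epistatic_effects=tuple(epistatic),
    )
    arch.validate(config.n_markers)
    return arch


def haldane_r(d_cM) -> np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def simulate_gametes(n_gametes: int, positions: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Drop gametes from an F1 along one chromosome.

    Returns an (n_gametes, m) boolean array; True marks the allele inherited
    from parent B.  The first marker's phase is Bernoulli(1/2); each interval
    switches phase with the Haldane recombination fraction of its length.
    """
    positions = np.asarray(positions, dtype=float)
    m = positions.size
    start = rng.random(n_gametes) < 0.5
    if m == 1:
        return start[:, None]
    r = haldane_r(np.diff(positions))
    crossovers = rng.random((n_gametes, m - 1)) < r
    # parity of accumulated crossovers flips the parental phase
    phase_flips = np.cumsum(crossovers, axis=1) % 2 == 1
    alleles = np.empty((n_gametes, m), dtype=bool)
    alleles[:, 0] = start
    alleles[:, 1:] = start[:, None] ^ phase_flips
    return alleles


def simulate_f2_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate the (n, p) dose matrix and its marker map.

    Each individual is the union of two independent gametes; chromosomes
    segregate independently.  Doses count alleles from parent B, so every
    locus is 1:2:1 in expectation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    marker_map = build_marker_map(config)
    n, m = config.n_individuals, config.markers_per_chromosome
    geno = np.empty((n, config.n_markers), dtype=np.int8)
    positions = marker_map["pos_cM"].to_numpy()[:m]  # identical per chromosome
    for c in range(config.n_chromosomes):
        gametes = simulate_gametes(2 * n, positions, rng)
        doses = gametes[:n].astype(np.int8) + gametes[n:].astype(np.int8)
        geno[:, c * m : (c + 1) * m] = doses
    return geno, marker_map


def genetic_values(genotypes: np.ndarray, architecture: QTLArchitecture) -> np.ndarray:
    """Evaluate the Cockerham genotype-to-value map for every individual."""
    genotypes = np.asarray(genotypes)
    architecture.validate(genotypes.shape[1])
    x, z = cockerham_codes(genotypes)
    g = np.full(genotypes.shape[0], architecture.mu, dtype=float)
    for locus, a in architecture.additive_effects:
        g += a * x[:, locus]
    for locus, d in architecture.dominance_effects:
        g += d * z[:, locus]
    for la, lb, iaa, iad, ida, idd in architecture.epistatic_effects:
        g += iaa * x[:, la] * x[:, lb]
        g += iad * x[:, la] * z[:, lb]
        g += ida * z[:, la] * x[:, lb]
        g += idd * z[:, la] * z[:, lb]
    return g


def simulate_phenotypes(
    genetic_values: np.ndarray,
    heritability: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Add i.i.d. normal noise calibrated to the target broad-sense h^2.

    sigma2_e = Var(G) (1 - h2) / h2, so that Var(G)/(Var(G)+sigma2_e) = h2.
    Returns (phenotypes, residuals, realized_h2) with realized_h2 the sample
    ratio Var(G)/Var(Y).
    """
    if not 0.0 < heritability < 1.0:
        raise ValueError("heritability must lie strictly in (0, 1)")
    g = np.asarray(genetic_values, dtype=float)
    var_g = g.var(ddof=1)
    if var_g <= 0.0:
        raise ValueError("genetic values are constant; heritability undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma2_e = var_g * (1.0 - heritability) / heritability
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=g.shape)
    y = g + e
    realized = var_g / y.var(ddof=1)
    return y, e, realized


def simulate_dataset(config: SimulationConfig) -> F2Dataset:
    """Full simulation: genotypes, architecture, genetic values, phenotypes.

    A single generator seeded from ``config.seed`` drives every random draw,
    so a fixed config reproduces the dataset bit-identically.
    """
    rng = np.random.default_rng(config.seed)
    geno, marker_map = simulate_f2_genotypes(config, rng)
    arch = build_architecture(config)
    g = genetic_values(geno, arch)
    y, e, realized = simulate_phenotypes(g, config.heritability, rng)
    return F2Dataset(
        genotypes=geno,
        marker_map=marker_map,
        genetic_values=g,
        phenotypes=y,
        residuals=e,
        architecture=arch,
        realized_h2=realized,
        config=config,
    )
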
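"""Tabular file formats (TSV with headers), run configuration, and the
end-to-end pipeline.

All matrices are small and dense, so plain TSV keeps every artifact
human-inspectable: genotype tables (rows = individuals, columns = markers),
two-column phenotype tables, marker maps (marker, chrom, pos_cM), and QTL
truth tables.  Genotype tables declare a coding — allele doses 0/1/2 for F2
SNPs or presence/absence 0/1 for dominant (DArT-style) markers — and
readers reject anything outside the declared alphabet.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gblup import GBLUPRegressor
from .integrate import CVResult, repeated_holdout
from .simulate import ARCHITECTURE_TAGS, F2Dataset, QTLArchitecture, SimulationConfig, simulate_dataset
from .svr import SVRConfig, SVREngine

__all__ = [
    "GenotypeTable",
    "RunConfig",
    "CodingError",
    "AlignmentError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "write_marker_map",
    "write_qtl_truth",
    "write_dataset",
    "load_run_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

CODINGS = {"dose012": (0, 1, 2), "presence01": (0, 1)}


class CodingError(ValueError):
    """A genotype value outside the declared coding's alphabet."""


class AlignmentError(ValueError):
    """Phenotype and genotype tables share no usable individuals."""


@dataclass
class GenotypeTable:
    individual_ids: list[str]
    marker_ids: list[str]
    doses: np.ndarray  # (n, p) integer matrix
    coding: str = "dose012"

    def __post_init__(self) -> None:
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual IDs")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker IDs")
        alphabet = CODINGS[self.coding]
        bad = ~np.isin(self.doses, alphabet)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CodingError(
                f"value {self.doses[i, j]} at individual {self.individual_ids[i]!r}, "
                f"marker {self.marker_ids[j]!r} outside coding {self.coding!r}"
            )


def read_genotypes(path: str | Path, coding: str = "dose012") -> GenotypeTable:
    """Read a genotype TSV (first column = individual ID, remaining columns =
    markers) and validate it against the declared coding."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty genotype table")
    try:
        doses = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise CodingError(f"{path}: non-numeric genotype value ({exc})") from exc
    if not np.all(doses == np.round(doses)):
        raise CodingError(f"{path}: genotype values must be integers")
    return GenotypeTable(
        individual_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
        doses=doses.astype(np.int64),
        coding=coding,
    )


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame(table.doses, index=table.individual_ids, columns=table.marker_ids)
    df.index.name = "individual"
    df.to_csv(path, sep="\t")


def read_phenotypes(path: str | Path, genotypes: GenotypeTable | None = None) -> pd.Series:
    """Read a two-column (ID, value) phenotype TSV.

    When a GenotypeTable is given, the result is reindexed to its individual
    order; individuals with missing phenotypes are dropped with a logged
    count, and disjoint ID sets raise AlignmentError.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns (ID, value)")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"{path}: duplicate individual IDs")
    values = pd.to_numeric(df.iloc[:, 1], errors="raise")
    series = pd.Series(values.to_numpy(), index=ids.to_numpy(), name="phenotype")
    if genotypes is None:
        return series
    aligned = series.reindex(genotypes.individual_ids)
    missing = int(aligned.isna().sum())
    if missing == len(aligned):
        raise AlignmentError("no overlapping individual IDs between phenotypes and genotypes")
    if missing:
        logger.warning("dropping %d individuals without phenotypes", missing)
        aligned = aligned.dropna()
    return aligned


def write_phenotypes(values: np.ndarray, individual_ids: list[str], path: str | Path) -> None:
    # 6 significant digits keeps files diff-stable across platforms
    df = pd.DataFrame({"individual": individual_ids, "phenotype": [f"{v:.6g}" for v in values]})
    df.to_csv(path, sep="\t", index=False)


def write_marker_map(marker_map: pd.DataFrame, path: str | Path) -> None:
    marker_map.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_qtl_truth(arch: QTLArchitecture, marker_ids: list[str], path: str | Path) -> None:
    """QTL truth table: one row per effect, loci as 1-based marker indices."""
    rows = []
    for locus, a in arch.additive_effects:
        rows.append({"locusA": locus + 1, "locusB": "", "markerA": marker_ids[locus],
                     "markerB": "", "effect_class": "additive", "magnitude": a})
    for locus, d in arch.dominance_effects:
        rows.append({"locusA": locus + 1, "locusB": "", "markerA": marker_ids[locus],
                     "markerB": "", "effect_class": "dominance", "magnitude": d})
    for la, lb, iaa, iad, ida, idd in arch.epistatic_effects:
        for cls, val in (("aa", iaa), ("ad", iad), ("da", ida), ("dd", idd)):
            if val != 0.0:
                rows.append({"locusA": la + 1, "locusB": lb + 1, "markerA": marker_ids[la],
                             "markerB": marker_ids[lb], "effect_class": f"epistasis_{cls}",
                             "magnitude": val})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_dataset(dataset: F2Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset (genotypes, phenotypes, map, truth) to a
    directory and return the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = [f"I{i + 1}" for i in range(dataset.n_individuals)]
    marker_ids = dataset.marker_map["marker"].tolist()
    table = GenotypeTable(ids, marker_ids, dataset.genotypes.astype(np.int64))
    paths = {
        "genotypes": out / "genotypes.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "genetic_values": out / "genetic_values.tsv",
        "marker_map": out / "marker_map.tsv",
        "qtl_truth": out / "qtl_truth.tsv",
    }
    write_genotypes(table, paths["genotypes"])
    write_phenotypes(dataset.phenotypes, ids, paths["phenotypes"])
    write_phenotypes(dataset.genetic_values, ids, paths["genetic_values"])
    write_marker_map(dataset.marker_map, paths["marker_map"])
    write_qtl_truth(dataset.architecture, marker_ids, paths["qtl_truth"])
    return paths


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Serializable configuration for the full simulate -> evaluate pipeline."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    svr: SVRConfig = field(default_factory=SVRConfig)
    gblup_ridge_epsilon: float = 1e-6
    variance_method: str = "rcv"
    k: int = 5
    n_reps: int = 100
    train_fraction: float = 0.7
    seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        svr = d.pop("svr", {})
        return cls(simulation=SimulationConfig(**sim), svr=SVRConfig(**svr), **d)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def _summary_frame(cv: CVResult, tag: str) -> pd.DataFrame:
    rows = []
    for model in ("gblup", "svr", "integrated"):
        rows.append({
            "model": model,
            "architecture": tag,
            "PA": cv.mean_pa[model],
            "SE_PA": cv.se_pa[model],
            "MSE": cv.mean_mse[model],
            "n_reps": cv.n_reps,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Simulate, evaluate all three models, and write results + provenance.

    The output directory contains the simulated dataset, a per-repetition
    table, a summary table (model x PA / SE / MSE), and a provenance JSON
    with the full configuration and seed, enough to regenerate everything.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
    logger.info("simulate: n=%d p=%d tag=%s h2=%.2f seed=%d", sim_cfg.n_individuals,
                sim_cfg.n_markers, sim_cfg.architecture_tag, sim_cfg.heritability, config.seed)
    dataset = simulate_dataset(sim_cfg)
    write_dataset(dataset, out / "data")
    logger.info("evaluate: reps=%d train_fraction=%.2f method=%s",
                config.n_reps, config.train_fraction, config.variance_method)
    cv = repeated_holdout(
        dataset.genotypes,
        dataset.phenotypes,
        n_reps=config.n_reps,
        train_fraction=config.train_fraction,
        variance_method=config.variance_method,
        k=config.k,
        base_seed=config.seed,
        gblup_model=GBLUPRegressor(ridge_epsilon=config.gblup_ridge_epsilon),
        svr_model=SVREngine(config.svr),
    )
    per_rep_rows = []
    for r in cv.per_rep:
        for model, m in r.metrics.items():
            per_rep_rows.append({
                "rep": r.rep, "seed": r.seed, "model": model,
                "PA": f"{m.predictive_ability:.6g}", "MSE": f"{m.mse:.6g}",
                "weight": f"{r.weight:.6g}",
                "sigma2_gblup": f"{r.variance_pair.sigma2_gblup:.6g}",
                "sigma2_svr": f"{r.variance_pair.sigma2_svr:.6g}",
                "sigma2_est": f"{r.sigma2_est:.6g}",
            })
    pd.DataFrame(per_rep_rows).to_csv(out / "per_rep.tsv", sep="\t", index=False)
    summary = _summary_frame(cv, sim_cfg.architecture_tag)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.6g")
    provenance = {
        "config": config.to_dict(),
        "realized_h2": dataset.realized_h2,
        "n_excluded_reps": cv.n_excluded,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return out
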
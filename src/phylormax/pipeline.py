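"""End-to-end orchestration: data in, comparison tables and reports out.

A run either simulates its inputs (tree, traits, ocean, rasters) from a
:class:`~phylormax.simulate.SimulationConfig`, or loads them from files
(Newick tree or multi-tree file, trait CSV, long-format grid/raster CSVs).
Stages execute in a fixed order — demography (if r_max must be solved from
life-history columns), thermal-habitat extraction (if grids are supplied),
design matrices, PGLS comparison over the ten candidate models, multi-tree
sensitivity when several trees are given — and every artifact is written
with a provenance header (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .demography import solve_rmax_table
from .models import enumerate_models, spec_by_name
from .pgls import ModelComparison, compare_models, multi_tree_sensitivity, vif
from .simulate import SimulationConfig, simulate_pgls_dataset, simulate_tree
from .thermal import (
    CORE_THRESHOLD,
    MESOTHERM_CORRECTION_C,
    TemperatureGrid,
    DistributionMap,
    thermal_summary,
)
from .trees import read_newick_trees

logger = logging.getLogger("phylormax")

__all__ = ["RunConfig", "run_pipeline", "render_report", "load_trait_table"]


@dataclass
class RunConfig:
    """Declarative configuration of one analysis run.

    Exactly one of ``simulation`` or ``tree_path``+``traits_path`` must be
    set. Option defaults are the analysis' stated values: core-distribution
    threshold 0.9, mesothermy correction +3.5 degC, natural logs, scaled
    inverse temperature and depth, AICc counting regression coefficients.
    """

    simulation: SimulationConfig | None = None
    tree_path: str | None = None
    traits_path: str | None = None
    grid_path: str | None = None
    maps_dir: str | None = None
    models: list = field(default_factory=list)  # empty = all ten
    core_threshold: float = CORE_THRESHOLD
    mesotherm_correction: float = MESOTHERM_CORRECTION_C
    scale_covariates: bool = True
    k_convention: str = "coefficients"
    seed: int = 0
    outdir: str = "phylormax_run"

    def __post_init__(self) -> None:
        simulated = self.simulation is not None
        loaded = self.tree_path is not None and self.traits_path is not None
        if simulated == loaded:
            raise ValueError(
                "provide exactly one of a simulation block or "
                "tree_path+traits_path"
            )

    def hash(self) -> str:
        payload = asdict(self)
        if self.simulation is not None:
            payload["simulation"] = asdict(self.simulation)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_trait_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a species trait CSV.

    Requires a ``species`` column plus either ``rmax`` or the life-history
    columns (``alpha_mat, fecundity_b, mortality_M``) from which r_max is
    solved; mass as ``mass``/``log_mass``; temperature and depth columns as
    accepted by the design-matrix builder.
    """
    table = pd.read_csv(path)
    if "species" not in table.columns:
        raise ValueError(f"{path}: trait table needs a 'species' column")
    if table["species"].duplicated().any():
        dups = table.loc[table["species"].duplicated(), "species"].tolist()
        raise ValueError(f"{path}: duplicated species: {dups}")
    lh_cols = {"alpha_mat", "fecundity_b", "mortality_M"}
    if "rmax" not in table.columns or table["rmax"].isna().any():
        if not lh_cols <= set(table.columns):
            raise ValueError(
                f"{path}: no usable rmax column and no life-history columns "
                f"({sorted(lh_cols)}) to solve it from"
            )
        logger.info("solving r_max from life-history columns")
        solved = solve_rmax_table(table)
        rmax = table.get("rmax", pd.Series(np.nan, index=table.index))
        filler = pd.Series(
            solved.set_index("species")["rmax"]
            .reindex(table["species"])
            .to_numpy(),
            index=table.index,
        )
        table["rmax"] = rmax.fillna(filler)
    if "mesotherm" not in table.columns:
        table["mesotherm"] = False
    return table


def _provenance(config: RunConfig) -> str:
    return (
        f"# phylormax {__version__} | config {config.hash()} | "
        f"seed {config.seed}\n"
    )


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns artifacts and writes reports.

    Returned dict keys: ``trees`` (list), ``traits`` (DataFrame),
    ``comparison`` (:class:`ModelComparison`), ``sensitivity`` (DataFrame or
    None), ``predictions`` (DataFrame), ``thermal_failures`` (list), and
    ``outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = (
        [spec_by_name(m) for m in config.models]
        if config.models
        else enumerate_models()
    )

    if config.simulation is not None:
        sim = config.simulation
        trees = [simulate_tree(sim.n_species, seed=sim.seed)]
        traits = simulate_pgls_dataset(trees[0], sim)
    else:
        trees = read_newick_trees(config.tree_path)
        if not trees:
            raise ValueError(f"no trees found in {config.tree_path}")
        traits = load_trait_table(config.traits_path)

    thermal_failures: list = []
    if config.grid_path is not None:
        grid = TemperatureGrid.from_csv(config.grid_path)
        maps_dir = Path(config.maps_dir)
        maps = {
            p.stem: DistributionMap.from_csv(p, species=p.stem)
            for p in sorted(maps_dir.glob("*.csv"))
        }
        summaries, thermal_failures = thermal_summary(
            traits, grid, maps,
            threshold=config.core_threshold,
            correction=config.mesotherm_correction,
        )
        for sp, msg in thermal_failures:
            logger.warning("thermal extraction failed for %s: %s", sp, msg)
        traits = traits.drop(
            columns=[c for c in ("median_temp", "temp_c") if c in traits],
        ).merge(
            summaries[["species", "median_temp", "depth_layer_used",
                       "n_cells"]],
            on="species",
            how="inner",
        )

    comparison = compare_models(
        specs, traits, trees[0],
        scale=config.scale_covariates,
        k_convention=config.k_convention,
    )

    sensitivity = None
    if len(trees) > 1:
        sensitivity = multi_tree_sensitivity(
            trees, specs, traits, scale=config.scale_covariates
        )

    best = comparison.best_fit
    curves = []
    for depth in (10.0, 500.0, 1000.0):
        curves.append(best.predict_rmax_curve(
            np.geomspace(1e2, 1e6, 50), fixed_temp=6.0, fixed_depth=depth))
    for temp in (6.0, 10.0, 20.0):
        curves.append(best.predict_rmax_curve(
            np.geomspace(1e2, 1e6, 50), fixed_temp=temp, fixed_depth=10.0))
    predictions = pd.concat(curves, ignore_index=True)

    artifacts = {
        "trees": trees,
        "traits": traits,
        "comparison": comparison,
        "sensitivity": sensitivity,
        "predictions": predictions,
        "thermal_failures": thermal_failures,
        "outdir": outdir,
    }
    render_report(artifacts, config)
    return artifacts


def render_report(artifacts: dict, config: RunConfig) -> None:
    """Write comparison/coefficient/sensitivity/prediction files plus a
    human-readable text report echoing the comparison-table layout."""
    outdir = Path(artifacts["outdir"])
    header = _provenance(config)
    comparison: ModelComparison = artifacts["comparison"]
    _write_csv(comparison.table, outdir / "comparison.csv", header)
    _write_csv(
        comparison.coefficient_table(), outdir / "coefficients.csv", header
    )
    _write_csv(artifacts["predictions"], outdir / "predictions.csv", header)
    if artifacts["sensitivity"] is not None:
        with open(outdir / "sensitivity.csv", "w") as fh:
            fh.write(header)
            artifacts["sensitivity"].to_csv(fh)

    best = comparison.best_fit
    lines = [header.rstrip("\n"), ""]
    lines.append("Model comparison (AICc, ML Pagel's lambda PGLS)")
    lines.append("-" * 72)
    tbl = comparison.table
    lines.append(
        f"{'model':<34}{'k':>3}{'-LL':>8}{'AICc':>8}{'adjR2':>7}"
        f"{'dAICc':>7}{'w':>7}"
    )
    for row in tbl.itertuples(index=False):
        if np.isnan(row.aicc):
            lines.append(f"{row.model:<34}  failed: {row.error}")
            continue
        lines.append(
            f"{row.model:<34}{row.k:>3}{row.neg_loglik:>8.1f}"
            f"{row.aicc:>8.1f}{row.adj_r2:>7.2f}{row.delta_aicc:>7.1f}"
            f"{row.weight:>7.3f}"
        )
    lines += ["", "Best model", "-" * 72, best.summary(), ""]
    dm = best.model.design
    lines.append("VIF (best model, ordinary design):")
    lines.append(vif(dm).round(2).to_string())
    if comparison.uninformative:
        lines += ["", "Uninformative added parameters (AICc gain < 2):"]
        for u in comparison.uninformative:
            lines.append(
                f"  {u['added_term']} ({u['base']} -> {u['extended']}): "
                f"improvement {u['aicc_improvement']:.2f}"
            )
    if artifacts["thermal_failures"]:
        lines += ["", "Species skipped during thermal extraction:"]
        for sp, msg in artifacts["thermal_failures"]:
            lines.append(f"  {sp}: {msg}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
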
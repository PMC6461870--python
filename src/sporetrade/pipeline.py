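"""End-to-end orchestration: traits -> biomass -> signal -> allometry.

``run_pipeline`` executes the full comparative analysis on a trait CSV, a
colonization CSV and (optionally) a rooted newick tree, writing one report
file per stage plus a run log of every constant in effect.  Stage failures
abort with the stage named, so a broken input is easy to localize.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sporetrade import __version__
from sporetrade.allometry import scaling_analysis, tradeoff_analysis
from sporetrade.biomass import (
    ConversionConstants,
    build_allocation_table,
    read_colonization_table,
)
from sporetrade.phylo_signal import fit_pagel_lambda, load_tree
from sporetrade.trait_db import (
    TaxaDistribution,
    compare_taxa,
    parse_trait_table,
    select_morph,
    size_table,
)

logger = logging.getLogger(__name__)

REPORT_FILES = (
    "spore_sizes.csv", "taxa_comparison.csv", "lambda_report.json",
    "allocation.csv", "tradeoff_report.json", "scaling_report.json",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    trait_csv: str | Path
    colonization_csv: str | Path | None = None
    tree_newick: str | Path | None = None
    out_dir: str | Path = "sporetrade_out"
    range_basis: str = "inner"
    morphs: tuple[str, ...] = ("glomoid", "acaulosporoid")
    alpha: float = 0.05
    seed: int = 0
    aggregate_replicates: bool = True
    constants: ConversionConstants = field(default_factory=ConversionConstants)

    def validate(self) -> None:
        for name in ("trait_csv", "colonization_csv", "tree_newick"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"[config] missing input file for {name}: {p}")
        if self.range_basis not in ("inner", "outer"):
            raise PipelineError(f"[config] bad range_basis {self.range_basis!r}")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


@_stage("spores")
def _spore_stage(cfg: PipelineConfig, out: Path):
    records = parse_trait_table(cfg.trait_csv, cfg.range_basis)
    sizes = size_table(records, cfg.range_basis)
    sizes.to_csv(out / "spore_sizes.csv", index=False)

    fam = pd.Series([r.family for r in records], name="family")
    groups = []
    merged = sizes.assign(family=fam.to_numpy())
    for family, sub in merged.groupby("family", sort=True):
        if len(sub) >= 2:
            groups.append(TaxaDistribution(family, sub["volume_um3"].to_numpy()))
    if len(sizes) >= 2:
        groups.append(TaxaDistribution("all", sizes["volume_um3"].to_numpy()))
    comparison = compare_taxa(groups)
    comparison.to_csv(out / "taxa_comparison.csv", index=False)
    return records, sizes


@_stage("signal")
def _signal_stage(cfg: PipelineConfig, out: Path, records):
    """Pagel's lambda on log10 spore volume, once per morph set."""
    tree = load_tree(cfg.tree_newick)
    report = {}
    for morph in cfg.morphs:
        subset = select_morph(records, morph)
        sizes = size_table(subset, cfg.range_basis)
        trait = pd.Series(
            np.log10(sizes["volume_um3"].to_numpy()),
            index=sizes["species"].to_numpy(),
        )
        tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        trait = trait[trait.index.isin(tip_labels)]
        work_tree = tree.clone(depth=1)
        work_tree.retain_taxa_with_labels(list(trait.index))
        res = fit_pagel_lambda(work_tree, trait)
        report[morph] = res.as_dict()
    (out / "lambda_report.json").write_text(json.dumps(report, indent=2))
    return report


@_stage("biomass")
def _biomass_stage(cfg: PipelineConfig, out: Path, records):
    colonization = read_colonization_table(cfg.colonization_csv)
    # single-trait analyses use one morph set; the first configured morph
    subset = select_morph(records, cfg.morphs[0])
    sizes = size_table(subset, cfg.range_basis)
    spore_mass = pd.Series(sizes["mass_ug"].to_numpy(),
                           index=sizes["species"].to_numpy())
    allocation = build_allocation_table(
        colonization, spore_mass, cfg.constants,
        aggregate_replicates=cfg.aggregate_replicates)
    allocation.to_csv(out / "allocation.csv", index=False)
    return allocation


@_stage("tradeoff")
def _tradeoff_stage(cfg: PipelineConfig, out: Path, allocation, tree):
    report = tradeoff_analysis(allocation, tree=tree, alpha=cfg.alpha)
    (out / "tradeoff_report.json").write_text(json.dumps(report.as_dict(), indent=2))
    return report


@_stage("scaling")
def _scaling_stage(cfg: PipelineConfig, out: Path, allocation):
    report = scaling_analysis(allocation, alpha=cfg.alpha)
    (out / "scaling_report.json").write_text(json.dumps(report.as_dict(), indent=2))
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns the in-memory report bundle."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle: dict = {}
    records, sizes = _spore_stage(cfg, out)
    bundle["spore_sizes"] = sizes

    tree = None
    if cfg.tree_newick is not None:
        bundle["lambda"] = _signal_stage(cfg, out, records)
        tree = load_tree(cfg.tree_newick)
    else:
        (out / "lambda_report.json").write_text(json.dumps(
            {"skipped": "no tree supplied"}, indent=2))

    if cfg.colonization_csv is not None:
        allocation = _biomass_stage(cfg, out, records)
        bundle["allocation"] = allocation
        bundle["tradeoff"] = _tradeoff_stage(cfg, out, allocation, tree)
        bundle["scaling"] = _scaling_stage(cfg, out, allocation)
    else:
        for name in ("allocation.csv", "tradeoff_report.json", "scaling_report.json"):
            (out / name).write_text("" if name.endswith(".csv")
                                    else json.dumps({"skipped": "no colonization data"}))

    log = {
        "version": __version__,
        "seed": cfg.seed,
        "range_basis": cfg.range_basis,
        "morphs": list(cfg.morphs),
        "alpha": cfg.alpha,
        "aggregate_replicates": cfg.aggregate_replicates,
        "constants": dataclasses.asdict(cfg.constants),
        "inputs": {
            "trait_csv": str(cfg.trait_csv),
            "colonization_csv": str(cfg.colonization_csv),
            "tree_newick": str(cfg.tree_newick),
        },
        "reports": [name for name in REPORT_FILES if (out / name).exists()],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    bundle["run_log"] = log
    return bundle
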
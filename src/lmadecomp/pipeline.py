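"""End-to-end analysis: from a trait table and a tree to all result tables.

One call reproduces the full study workflow on any conforming dataset:
pairwise morphology regressions, the covariation-free partitions of LMA
(into LVA and LD) and of LVA (into the four tissue groups), leaf-density
vs tissue-fraction regressions, the C/N relationship table, PGLS
deciduous-vs-evergreen comparisons, soil-water-gradient regressions, and
the per-group trait correlation networks.  Everything is returned as tidy
DataFrames (or network objects) keyed by name, and can be written to a
results directory alongside a manifest recording versions, seed and a
configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .network import DEFAULT_TRAITS, CorrelationNetwork, build_network, export_network
from .phylo import habit_comparison, validate_species_coverage
from .regress import (GROUPS, decompose_multi, decompose_two_factor, fit_ols,
                      gradient_regressions, regression_table, select_group)
from .traits import SpeciesTraitRecord, records_to_frame

logger = logging.getLogger("lmadecomp")

TISSUE_VA_COLUMNS = (
    "epidermis_va", "mesophyll_va", "vascular_sclerenchyma_va", "air_spaces_va",
)
FRACTION_COLUMNS = (
    "epidermis_frac", "mesophyll_frac", "vascular_sclerenchyma_frac",
    "air_spaces_frac",
)
MORPHOLOGY_COLUMNS = ("lma_g_m2", "lva_ml_m2", "ld_g_ml")


@dataclass
class AnalysisConfig:
    """Knobs of the end-to-end analysis."""

    alpha: float = 0.05
    include_interaction: bool = False
    lambda_mode: str = "fixed_1"
    groups: tuple = GROUPS
    network_traits: tuple = DEFAULT_TRAITS
    gradient_traits: tuple = MORPHOLOGY_COLUMNS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _partition_frame(vp, group: str) -> pd.DataFrame:
    df = vp.to_frame()
    df.insert(0, "group", group)
    return df


def _groups_with_enough(records, groups, minimum=5):
    for group in groups:
        subset = select_group(records, group)
        if len(subset) < minimum:
            logger.warning("group %s has only %d species; skipped", group, len(subset))
            continue
        yield group, subset


def run_analysis(
    records: Sequence[SpeciesTraitRecord],
    tree: dendropy.Tree | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run every analysis stage; returns a name -> table/network mapping."""
    config = config or AnalysisConfig()
    if tree is not None:
        validate_species_coverage(tree, [r.species_id for r in records])

    results: dict = {}
    habit = {r.species_id: r.habit for r in records}

    # pairwise morphology regressions (LMA~LVA, LMA~LD, LD~LVA) per group
    rows = []
    for group, subset in _groups_with_enough(records, config.groups):
        frame = records_to_frame(subset)
        for resp, pred in (("lma_g_m2", "lva_ml_m2"), ("lma_g_m2", "ld_g_ml"),
                           ("ld_g_ml", "lva_ml_m2")):
            res = fit_ols(frame[resp].to_numpy(), frame[pred].to_numpy(), names=[pred])
            rows.append({"group": group, "response": resp, "predictor": pred,
                         "slope": res.slope, "r_squared": res.r_squared,
                         "p_value": res.p_value, "tier": res.tier, "n": res.n})
    results["morphology_regressions"] = pd.DataFrame(rows)

    # LVA ~ each tissue VA simple regressions per group
    rows = []
    for group, subset in _groups_with_enough(records, config.groups):
        frame = records_to_frame(subset)
        for pred in TISSUE_VA_COLUMNS:
            res = fit_ols(frame["lva_ml_m2"].to_numpy(), frame[pred].to_numpy(),
                          names=[pred])
            rows.append({"group": group, "response": "lva_ml_m2", "predictor": pred,
                         "slope": res.slope, "r_squared": res.r_squared,
                         "p_value": res.p_value, "tier": res.tier, "n": res.n})
    results["tissue_regressions"] = pd.DataFrame(rows)

    # covariation-free partitions
    parts = []
    for group, subset in _groups_with_enough(records, config.groups):
        frame = records_to_frame(subset)
        vp = decompose_two_factor(
            frame["lma_g_m2"].to_numpy(),
            frame["lva_ml_m2"].to_numpy(),
            frame["ld_g_ml"].to_numpy(),
            include_interaction=config.include_interaction,
            names=("lva_ml_m2", "ld_g_ml"),
            response="lma_g_m2",
        )
        parts.append(_partition_frame(vp, group))
    results["lma_partition"] = pd.concat(parts, ignore_index=True)

    parts = []
    for group, subset in _groups_with_enough(records, config.groups,
                                             minimum=len(TISSUE_VA_COLUMNS) + 2):
        frame = records_to_frame(subset)
        vp = decompose_multi(
            frame["lva_ml_m2"].to_numpy(),
            frame[list(TISSUE_VA_COLUMNS)].to_numpy(),
            names=list(TISSUE_VA_COLUMNS),
            response="lva_ml_m2",
        )
        parts.append(_partition_frame(vp, group))
    results["lva_partition"] = pd.concat(parts, ignore_index=True)

    # LD ~ tissue fractions, simple regressions per group
    rows = []
    for group, subset in _groups_with_enough(records, config.groups):
        frame = records_to_frame(subset)
        for pred in FRACTION_COLUMNS:
            res = fit_ols(frame["ld_g_ml"].to_numpy(), frame[pred].to_numpy(),
                          names=[pred])
            rows.append({"group": group, "response": "ld_g_ml", "predictor": pred,
                         "slope": res.slope, "r_squared": res.r_squared,
                         "p_value": res.p_value, "tier": res.tier, "n": res.n})
    results["ld_fraction_regressions"] = pd.DataFrame(rows)

    # C and N relationship tables (sign / R2 / tier per group)
    chem_responses = list(MORPHOLOGY_COLUMNS) + list(TISSUE_VA_COLUMNS)
    chem = []
    for predictor in ("lcc_mg_g", "lnc_mg_g"):
        tbl = regression_table(records, responses=chem_responses, predictor=predictor)
        if len(tbl):
            chem.append(tbl)
    results["chemistry_table"] = (
        pd.concat(chem, ignore_index=True) if chem else pd.DataFrame()
    )

    # PGLS habit comparisons (tree required)
    if tree is not None and len(set(habit.values())) == 2:
        rows = []
        frame = records_to_frame(records)
        for trait in chem_responses + list(FRACTION_COLUMNS):
            values = dict(zip(frame["species"], frame[trait]))
            res = habit_comparison(tree, values, habit, lambda_mode=config.lambda_mode)
            rows.append({"trait": trait, "evergreen_effect": res.slope,
                         "p_value": res.p_value, "tier": res.tier,
                         "lambda": res.lambda_, "n": res.n})
        results["habit_comparisons"] = pd.DataFrame(rows)

    # soil-water-gradient regressions
    frame_all = records_to_frame(records)
    if frame_all["swc_l_m2"].notna().any():
        rows = []
        for group, subset in _groups_with_enough(records, config.groups):
            fits = gradient_regressions(subset, "all", traits=config.gradient_traits)
            for trait, res in fits.items():
                rows.append({"group": group, "trait": trait, "slope": res.slope,
                             "r_squared": res.r_squared, "p_value": res.p_value,
                             "tier": res.tier, "n": res.n})
        results["gradient_regressions"] = pd.DataFrame(rows)

    # correlation networks per group
    networks: dict[str, CorrelationNetwork] = {}
    for group, _ in _groups_with_enough(records, config.groups):
        networks[group] = build_network(
            records, tree=tree, group=group, alpha=config.alpha,
            traits=config.network_traits,
        )
    results["networks"] = networks

    results["manifest"] = {
        "package": "lmadecomp",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "n_species": len(records),
        "seed": config.seed,
        "alpha": config.alpha,
        "lambda_mode": config.lambda_mode,
        "config_hash": config.digest(),
    }
    return results


def write_results(results: dict, outdir) -> list[str]:
    """Write every table as CSV, networks as CSV+GraphML, manifest as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in results.items():
        if name == "networks":
            for group, net in obj.items():
                for fmt, suffix in (("csv", "csv"), ("graphml", "graphml")):
                    path = outdir / f"network_{group}.{suffix}"
                    export_network(net, path, format=fmt)
                    written.append(path.name)
        elif name == "manifest":
            path = outdir / "manifest.json"
            path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
            written.append(path.name)
        elif isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.csv"
            obj.to_csv(path, index=False)
            written.append(path.name)
    return sorted(written)
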
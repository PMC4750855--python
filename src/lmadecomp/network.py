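"""Trait correlation networks with phylogeny-dependence annotation.

All unordered pairs of the selected morphological, anatomical and chemical
traits are tested by Pearson correlation within a species group; an edge
is drawn only when the correlation is both significant (p below alpha)
and substantial (|r| > 0.5, i.e. at least a quarter of the variance
shared).  Edge strength is binned by |r| at 0.5, sqrt(0.5) and sqrt(0.75)
-- the R-squared quartiles 0.25, 0.50, 0.75 -- and every edge carries a
flag saying whether the relationship survives phylogenetic correction
(companion PGLS on the same pair) or rides on shared ancestry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import phylo as _phylo
from .regress import fit_ols, select_group
from .traits import SpeciesTraitRecord, records_to_frame

logger = logging.getLogger("lmadecomp")

#: |r| bin edges shared with the display convention: thin below sqrt(0.5),
#: intermediate below sqrt(0.75), bold above.
STRENGTH_BINS = (0.5, np.sqrt(0.5), np.sqrt(0.75))

#: default trait set: morphology, grouped tissue volumes, fractions, chemistry
DEFAULT_TRAITS = (
    "lma_g_m2", "lva_ml_m2", "ld_g_ml",
    "epidermis_va", "mesophyll_va", "vascular_sclerenchyma_va", "air_spaces_va",
    "epidermis_frac", "mesophyll_frac", "vascular_sclerenchyma_frac",
    "air_spaces_frac",
    "lcc_mg_g", "lnc_mg_g",
)

TRAIT_CATEGORIES = {
    "lma_g_m2": "focal",
    "lva_ml_m2": "morphological",
    "ld_g_ml": "morphological",
    "lcc_mg_g": "chemical",
    "lnc_mg_g": "chemical",
}


def trait_category(trait: str) -> str:
    return TRAIT_CATEGORIES.get(trait, "anatomical")


def strength_class(r: float) -> str:
    """Bin |r| into thin / intermediate / bold; below 0.5 is no edge."""
    a = abs(r)
    if a <= STRENGTH_BINS[0]:
        raise ValueError(f"|r| = {a:.3f} is below the edge threshold {STRENGTH_BINS[0]}")
    if a < STRENGTH_BINS[1]:
        return "thin"
    if a < STRENGTH_BINS[2]:
        return "intermediate"
    return "bold"


@dataclass
class CorrelationEdge:
    trait_a: str
    trait_b: str
    r: float
    p: float
    strength_class: str
    sign: str
    phylo_flag: str


@dataclass
class CorrelationNetwork:
    """Undirected trait network for one species group."""

    group: str
    nodes: dict[str, str]        # trait -> category
    edges: list[CorrelationEdge]

    def edge_frame(self) -> pd.DataFrame:
        cols = ["trait_a", "trait_b", "r", "p", "strength_class", "sign",
                "phylo_flag", "group"]
        rows = [{**vars(e), "group": self.group} for e in self.edges]
        return pd.DataFrame(rows, columns=cols)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(group=self.group)
        for trait, cat in self.nodes.items():
            g.add_node(trait, category=cat)
        for e in self.edges:
            g.add_edge(e.trait_a, e.trait_b, r=e.r, p=e.p,
                       strength_class=e.strength_class, sign=e.sign,
                       phylo_flag=e.phylo_flag)
        return g


def build_network(
    records: Sequence[SpeciesTraitRecord],
    tree: dendropy.Tree | None = None,
    group: str = "all",
    alpha: float = 0.05,
    traits: Sequence[str] = DEFAULT_TRAITS,
    r_threshold: float = STRENGTH_BINS[0],
    holm: bool = False,
) -> CorrelationNetwork:
    """Pairwise Pearson network over the trait table of one species group.

    An edge requires p < alpha AND |r| > ``r_threshold``.  When a tree is
    supplied each retained pair also gets a companion PGLS fit; the edge's
    ``phylo_flag`` says whether the correlation persists under phylogenetic
    correction.  Constant traits are excluded with a warning.  ``holm``
    applies a Holm step-down correction to the Pearson p-values (off by
    default).
    """
    subset = select_group(records, group)
    if len(subset) < 5:
        raise ValueError(f"group {group!r} has {len(subset)} species; need >= 5")
    frame = records_to_frame(subset)
    usable = []
    for t in traits:
        if t not in frame.columns:
            raise ValueError(f"unknown trait column {t!r}")
        col = frame[t].to_numpy(dtype=float)
        if np.all(~np.isfinite(col)):
            logger.warning("trait %s has no finite values in group %s; excluded", t, group)
            continue
        if np.nanstd(col) == 0:
            logger.warning("trait %s is constant in group %s; excluded", t, group)
            continue
        usable.append(t)

    pairs, rvals, pvals = [], [], []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i], usable[j]
            sub = frame[[a, b]].dropna()
            if len(sub) < 5:
                continue
            r, p = stats.pearsonr(sub[a], sub[b])
            pairs.append((a, b, sub))
            rvals.append(float(r))
            pvals.append(float(p))
    if holm and pvals:
        pvals = list(multipletests(pvals, alpha=alpha, method="holm")[1])

    edges = []
    species = [r.species_id for r in subset]
    for (a, b, sub), r, p in zip(pairs, rvals, pvals):
        if p >= alpha or abs(r) <= r_threshold:
            continue
        flag = "independent"
        if tree is not None:
            ols = fit_ols(sub[b].to_numpy(), sub[a].to_numpy(), names=[a])
            pg = _phylo.pgls_fit(
                tree,
                pd.Series(sub[b].to_numpy(), index=[species[k] for k in sub.index]),
                sub[a].to_numpy(),
                names=[a],
            )
            flag = _phylo.phylo_dependence(ols, pg, alpha=alpha)
            if flag == "absent":
                # the Pearson gate was passed, so the OLS gate agrees except
                # in borderline rounding; treat as dependent for annotation
                flag = "dependent"
        edges.append(CorrelationEdge(
            trait_a=a, trait_b=b, r=r, p=p,
            strength_class=strength_class(r),
            sign="positive" if r >= 0 else "negative",
            phylo_flag=flag,
        ))
    return CorrelationNetwork(
        group=group,
        nodes={t: trait_category(t) for t in usable},
        edges=edges,
    )


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def export_network(net: CorrelationNetwork, path, format: str = "csv") -> None:
    """Write the network as an edge-list CSV or GraphML."""
    if format == "csv":
        net.edge_frame().to_csv(path, index=False)
    elif format == "graphml":
        nx.write_graphml(net.to_graph(), path)
    else:
        raise ValueError(f"unknown network format {format!r}; use 'csv' or 'graphml'")


def read_network_csv(path, nodes: dict[str, str] | None = None) -> CorrelationNetwork:
    """Rebuild a network from its edge-list CSV (inverse of csv export)."""
    df = pd.read_csv(path)
    group = str(df["group"].iloc[0]) if len(df) else "all"
    edges = [
        CorrelationEdge(
            trait_a=row.trait_a, trait_b=row.trait_b, r=float(row.r), p=float(row.p),
            strength_class=row.strength_class, sign=row.sign,
            phylo_flag=row.phylo_flag,
        )
        for row in df.itertuples()
    ]
    if nodes is None:
        names = sorted({e.trait_a for e in edges} | {e.trait_b for e in edges})
        nodes = {t: trait_category(t) for t in names}
    return CorrelationNetwork(group=group, nodes=nodes, edges=edges)
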
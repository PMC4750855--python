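"""Synthetic Mediterranean-woodland leaf trait datasets with known truth.

The generator emulates the structure of a species-mean field study: a
dated ultrametric phylogeny over ~34 woody species, two phylogenetically
clustered leaf habits (a mostly-evergreen clade plus nearby tips), six
anatomical tissue volumes per area evolving as geometric Brownian motion
on the tree with a multiplicative evergreen mesophyll offset, leaf
density built mechanistically as the volume-fraction-weighted mean of
tissue densities, LMA as the exact product LVA x LD, leaf C and N
concentrations as noisy linear readouts of tissue composition, and site
soil water content rank-coupled (Gaussian copula) to log LMA with a
configurable negative correlation.

Every stage draws from an independent child stream of one master seed, so
a dataset is bit-reproducible and stages can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import dendropy
import numpy as np
from scipy import stats

from .traits import SpeciesTraitRecord, TissueProfile
from .phylo import brownian_vcv, normalize_label, tip_labels

_TISSUES = ("ue", "le", "pal", "spo", "vs", "air")

#: map each of the six measured tissues to its density class
_DENSITY_CLASS = {
    "ue": "epidermis", "le": "epidermis",
    "pal": "mesophyll", "spo": "mesophyll",
    "vs": "vascular_sclerenchyma", "air": "air",
}


@dataclass
class GeneratorConfig:
    """Study-scale defaults for the synthetic dataset.

    ``sigma2`` is the Brownian rate per log-trait over a unit-depth tree;
    ``habit_offsets`` are additive log-scale shifts applied to evergreen
    species per tissue group (the default thickens evergreen mesophyll by
    a factor e^0.4 ~ 1.5).  Tissue density means (g mL-1) and the baseline
    tissue volumes per area (mL m-2) are free choices sized so generated
    LMA spans roughly the 27-207 g m-2 range observed for Mediterranean
    woody floras.  ``swc_coupling`` is the target correlation between
    log LMA and site soil water content (negative: dense, high-LMA leaves
    occupy the dry end of the gradient).
    """

    n_species: int = 34
    n_evergreen: int = 20
    sigma2: float = 0.04
    tissue_mean_va: dict = field(default_factory=lambda: {
        "ue": 20.0, "le": 15.0, "pal": 100.0, "spo": 80.0, "vs": 30.0, "air": 60.0,
    })
    habit_offsets: dict = field(default_factory=lambda: {
        "epidermis": 0.0, "mesophyll": 0.4, "vascular_sclerenchyma": 0.0, "air": 0.0,
    })
    tissue_density: dict = field(default_factory=lambda: {
        "epidermis": 0.3, "mesophyll": 0.3, "vascular_sclerenchyma": 1.0, "air": 0.0,
    })
    density_noise: float = 0.05
    c_weights: dict = field(default_factory=lambda: {
        "intercept": 400.0, "mesophyll_frac": 0.8, "vascular_sclerenchyma_frac": 1.2,
        "noise_sd": 8.0,
    })
    n_weights: dict = field(default_factory=lambda: {
        "intercept": 40.0, "mesophyll_frac": -0.25, "vascular_sclerenchyma_frac": -0.3,
        "noise_sd": 1.5,
    })
    swc_range: tuple = (100.0, 500.0)
    swc_coupling: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not (0 < self.n_evergreen < self.n_species):
            raise ValueError("need 0 < n_evergreen < n_species")
        if not (self.sigma2 > 0):
            raise ValueError("sigma2 must be > 0")
        if self.tissue_density.get("air", 0.0) != 0.0:
            raise ValueError("air spaces carry no mass; their density is fixed at 0")
        if not (abs(self.swc_coupling) < 1):
            raise ValueError("|swc_coupling| must be < 1")


@dataclass
class GroundTruth:
    """Everything the generator knew: tree, latent values, parameters."""

    newick: str
    habits: dict
    log_va: dict            # species -> {tissue: log VA actually realized}
    densities: dict         # species -> {tissue: density actually realized}
    config: GeneratorConfig

    def to_dict(self) -> dict:
        d = asdict(self)
        d["config"]["swc_range"] = list(self.config.swc_range)
        return d


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------


def generate_tree(n: int, seed: int) -> dendropy.Tree:
    """Ultrametric Yule (pure-birth) tree with depth normalized to 1.

    Lineages split at unit rate; waiting times are exponential with rate
    equal to the current lineage count; a final exponential stretch runs
    to the present.  Tips are labelled sp01..spNN in birth order.
    """
    if n < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    # active lineages as (node, birth_time)
    a = dendropy.Node()
    b = dendropy.Node()
    root.add_child(a)
    root.add_child(b)
    active = [(a, 0.0), (b, 0.0)]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node, born = active.pop(idx)
        node.edge.length = t - born
        c1, c2 = dendropy.Node(), dendropy.Node()
        node.add_child(c1)
        node.add_child(c2)
        active.append((c1, t))
        active.append((c2, t))
    t += rng.exponential(1.0 / n)
    order = 0
    for node, born in active:
        node.edge.length = t - born
    for leaf in tree.leaf_node_iter():
        order += 1
        leaf.taxon = taxa.new_taxon(label=f"sp{order:02d}")
    # normalize depth to 1
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(node.edge.length) / t
    return tree


# ---------------------------------------------------------------------------
# habits
# ---------------------------------------------------------------------------


def assign_habits(tree: dendropy.Tree, n_evergreen: int, seed: int = 0) -> dict[str, str]:
    """Phylogenetically clustered evergreen assignment.

    The largest clade not exceeding ``n_evergreen`` tips seeds the
    evergreen set, which is then topped up with the outside tips nearest
    (patristic distance) to it; everything else is deciduous.  The result
    carries phylogenetic signal in habit by construction.
    """
    labels = tip_labels(tree)
    n = len(labels)
    if not (0 < n_evergreen < n):
        raise ValueError(f"need 0 < n_evergreen < {n}, got {n_evergreen}")
    best: list[str] = []
    for node in tree.preorder_node_iter():
        tips = [normalize_label(l.taxon.label) for l in node.leaf_iter()]
        if len(tips) <= n_evergreen and len(tips) > len(best):
            best = tips
    evergreen = list(best)
    if len(evergreen) < n_evergreen:
        C = brownian_vcv(tree, labels)
        depth = np.diag(C)
        dist = depth[:, None] + depth[None, :] - 2 * C
        idx = {l: i for i, l in enumerate(labels)}
        while len(evergreen) < n_evergreen:
            outside = [l for l in labels if l not in evergreen]
            nearest = min(
                outside,
                key=lambda l: (min(dist[idx[l], idx[e]] for e in evergreen), l),
            )
            evergreen.append(nearest)
    ever = set(evergreen)
    return {l: ("evergreen" if l in ever else "deciduous") for l in labels}


# ---------------------------------------------------------------------------
# traits and sites
# ---------------------------------------------------------------------------


def _simulate_bm(tree: dendropy.Tree, root_value: float, sigma2: float,
                 rng: np.random.Generator) -> dict[str, float]:
    """One Brownian realization on the tree; returns tip values."""
    value = {id(tree.seed_node): root_value}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        v = value[id(node.parent_node)]
        step = rng.normal(0.0, np.sqrt(sigma2 * float(node.edge.length)))
        value[id(node)] = v + step
    return {
        normalize_label(leaf.taxon.label): value[id(leaf)]
        for leaf in tree.leaf_node_iter()
    }


def simulate_records(
    tree: dendropy.Tree,
    habits: Mapping[str, str],
    config: GeneratorConfig,
) -> tuple[list[SpeciesTraitRecord], GroundTruth]:
    """Species-mean trait records on a given tree and habit map.

    Per tissue, log VA follows Brownian motion around the configured
    baseline plus the evergreen offset of its group; LVA is the exact
    tissue sum, LD the fraction-weighted density mean (air contributing
    volume but no mass), and LMA the exact product LVA x LD.  C and N are
    linear in the mesophyll and vascular fractions plus Gaussian noise;
    soil water content couples to log LMA through a Gaussian copula.
    """
    seeds = _child_seeds(config.seed, 4)
    trait_rng = np.random.default_rng(seeds[2])
    site_rng = np.random.default_rng(seeds[3])
    species = tip_labels(tree)

    log_va: dict[str, dict[str, float]] = {s: {} for s in species}
    for tissue in _TISSUES:
        base = float(np.log(config.tissue_mean_va[tissue]))
        tips = _simulate_bm(tree, base, config.sigma2, trait_rng)
        offset = config.habit_offsets.get(_DENSITY_CLASS[tissue], 0.0)
        for s in species:
            log_va[s][tissue] = tips[s] + (offset if habits[s] == "evergreen" else 0.0)

    densities: dict[str, dict[str, float]] = {}
    for s in species:
        densities[s] = {}
        for tissue in _TISSUES:
            mean = config.tissue_density[_DENSITY_CLASS[tissue]]
            if tissue == "air":
                densities[s][tissue] = 0.0
            else:
                rho = mean + trait_rng.normal(0.0, config.density_noise)
                densities[s][tissue] = max(rho, 0.01)

    records = []
    log_lma = {}
    for s in species:
        va = {t: float(np.exp(log_va[s][t])) for t in _TISSUES}
        lva = sum(va.values())
        fracs = {t: va[t] / lva for t in _TISSUES}
        ld = sum(fracs[t] * densities[s][t] for t in _TISSUES)
        lma = lva * ld
        log_lma[s] = np.log(lma)
        groups = {
            "mesophyll_frac": 100.0 * (fracs["pal"] + fracs["spo"]),
            "vascular_sclerenchyma_frac": 100.0 * fracs["vs"],
        }
        cw, nw = config.c_weights, config.n_weights
        lcc = (cw["intercept"]
               + cw["mesophyll_frac"] * groups["mesophyll_frac"]
               + cw["vascular_sclerenchyma_frac"] * groups["vascular_sclerenchyma_frac"]
               + trait_rng.normal(0.0, cw["noise_sd"]))
        lnc = (nw["intercept"]
               + nw["mesophyll_frac"] * groups["mesophyll_frac"]
               + nw["vascular_sclerenchyma_frac"] * groups["vascular_sclerenchyma_frac"]
               + trait_rng.normal(0.0, nw["noise_sd"]))
        records.append(SpeciesTraitRecord(
            species_id=s,
            habit=habits[s],
            lma=lma,
            lva=lva,
            ld=ld,
            lcc=max(lcc, 1.0),
            lnc=max(lnc, 0.5),
            tissues=TissueProfile(
                upper_epidermis_va=va["ue"],
                lower_epidermis_va=va["le"],
                palisade_va=va["pal"],
                spongy_va=va["spo"],
                vascular_sclerenchyma_va=va["vs"],
                air_space_va=va["air"],
            ),
        ))

    # Gaussian-copula coupling of site water to log LMA
    rho = config.swc_coupling
    x = np.array([log_lma[s] for s in species])
    xz = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    z = rho * xz + np.sqrt(1 - rho ** 2) * site_rng.normal(size=len(species))
    u = stats.norm.cdf(z)
    lo, hi = config.swc_range
    swc = lo + (hi - lo) * u
    order = np.argsort(-swc)  # wettest site first
    site_rank = np.empty(len(species), dtype=int)
    site_rank[order] = np.arange(1, len(species) + 1)
    for i, rec in enumerate(records):
        rec.swc = float(swc[i])
        rec.site = f"site{site_rank[i]:02d}"

    truth = GroundTruth(
        newick=tree.as_string(schema="newick", unquoted_underscores=True).strip(),
        habits=dict(habits),
        log_va=log_va,
        densities=densities,
        config=config,
    )
    return records, truth


def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[list[SpeciesTraitRecord], dendropy.Tree, GroundTruth]:
    """Full dataset from one master seed: tree, habits, traits, sites."""
    config = config or GeneratorConfig()
    seeds = _child_seeds(config.seed, 4)
    tree = generate_tree(config.n_species, seeds[0])
    habits = assign_habits(tree, config.n_evergreen, seeds[1])
    records, truth = simulate_records(tree, habits, config)
    return records, tree, truth
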
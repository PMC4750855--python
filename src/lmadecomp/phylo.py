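"""Phylogenetic comparative machinery: trees, contrasts, and PGLS.

Species are not independent samples: close relatives inherit similar trait
values from common ancestors.  Two classical corrections are provided.
Felsenstein's phylogenetically independent contrasts (PIC) replace n tip
values with n-1 standardized differences at the internal nodes, each
scaled by the expected Brownian-motion standard deviation of the pair.
Phylogenetic generalized least squares (PGLS) keeps the regression on the
original scale but gives the residuals a covariance matrix C whose entry
C_ij is the shared root-to-tip path length of species i and j -- the
Brownian expectation.  Under a Brownian model with lambda = 1 the two are
equivalent: the PGLS slope equals the through-origin regression of the y
contrasts on the x contrasts.

Pagel's lambda scales the off-diagonal of C between 0 (star phylogeny,
ordinary least squares) and 1 (full Brownian covariance); it can be fixed
at 1 or estimated by restricted maximum likelihood.

Also here: a branch-length adjustment in the style of Phylocom's BLADJ --
given ages for a subset of internal nodes (root included, tips at age 0),
undated nodes are interpolated evenly in age between their nearest dated
neighbours, yielding an ultrametric time tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .regress import RegressionResult, significance_tier

logger = logging.getLogger("lmadecomp")

#: relative perturbation applied to zero-length terminal branches before PIC
ZERO_BRANCH_EPS = 1e-8


class TreeError(ValueError):
    """Malformed tree or tree/trait mismatch."""


def normalize_label(label: str) -> str:
    """Canonical tip label: stripped, underscores as spaces, single-spaced."""
    return " ".join(str(label).replace("_", " ").split())


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------


def read_newick(path) -> dendropy.Tree:
    """Read a rooted newick tree; polytomies are preserved.

    Duplicate tip labels (after normalization) are rejected.  Trees without
    branch lengths parse fine; length-requiring operations check later.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse newick file {path}: {exc}") from exc
    labels = [normalize_label(leaf.taxon.label) for leaf in tree.leaf_node_iter()]
    seen: set[str] = set()
    dups = {l for l in labels if l in seen or seen.add(l)}
    if dups:
        raise TreeError(f"duplicate tip labels: {sorted(dups)}")
    return tree


def read_newick_string(newick: str) -> dendropy.Tree:
    """Parse a newick string (same validation as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise TreeError(f"could not parse newick string: {exc}") from exc
    labels = [normalize_label(leaf.taxon.label) for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate tip labels")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", unquoted_underscores=True))


def has_branch_lengths(tree: dendropy.Tree) -> bool:
    return all(
        node.edge.length is not None
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [normalize_label(leaf.taxon.label) for leaf in tree.leaf_node_iter()]


def validate_species_coverage(tree: dendropy.Tree, species: Sequence[str]) -> None:
    """Every analyzed species must be a tip of the tree (normalized match)."""
    tips = set(tip_labels(tree))
    missing = [s for s in species if normalize_label(s) not in tips]
    if missing:
        raise TreeError(f"species absent from tree: {sorted(missing)}")


# ---------------------------------------------------------------------------
# BLADJ-style branch length adjustment
# ---------------------------------------------------------------------------


def bladj_adjust(tree: dendropy.Tree, node_ages: Mapping[str, float]) -> dendropy.Tree:
    """Space undated internal nodes evenly in age between dated neighbours.

    ``node_ages`` maps internal-node labels to ages (time before present);
    the root must be dated and tips sit at age 0.  Each undated node is
    interpolated, in preorder, between its (already aged) parent and the
    oldest dated node below it reachable without crossing another dated
    node -- on a bare chain this reduces to exact even spacing.  Dated
    nodes keep their ages; branch lengths become parent-child age
    differences, so the result is exactly ultrametric and re-running the
    adjustment is the identity.
    """
    tree = tree.clone(depth=1)
    ages: dict[int, float] = {}
    dated: set[int] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ages[id(node)] = 0.0
            dated.add(id(node))
        else:
            label = node.label if node.label else None
            if label is not None and label in node_ages:
                ages[id(node)] = float(node_ages[label])
                dated.add(id(node))
    root = tree.seed_node
    if id(root) not in dated:
        raise TreeError("root must have an age for branch-length adjustment")

    # inversion check among dated nodes
    for node in tree.preorder_node_iter():
        if id(node) not in dated or node.parent_node is None:
            continue
        anc = node.parent_node
        while anc is not None and id(anc) not in dated:
            anc = anc.parent_node
        if anc is not None and ages[id(anc)] < ages[id(node)]:
            raise TreeError(
                f"age inversion: node {node.label!r} (age {ages[id(node)]}) is older "
                f"than its dated ancestor {anc.label!r} (age {ages[id(anc)]})"
            )

    def _anchor_below(node):
        """Oldest aged node below, reachable without crossing an aged node.

        Returns (age, undated_steps_between) where undated_steps_between is
        the count of unaged nodes strictly between ``node`` and the anchor.
        Ties on age resolve to the fewest intervening nodes.
        """
        best = None
        stack = [(child, 0) for child in node.child_nodes()]
        while stack:
            cur, between = stack.pop(0)
            if id(cur) in ages:
                key = (ages[id(cur)], -between)
                if best is None or key > best[0]:
                    best = (key, ages[id(cur)], between)
            else:
                stack.extend((c, between + 1) for c in cur.child_nodes())
        assert best is not None  # every path ends at a tip, age 0
        return best[1], best[2]

    for node in tree.preorder_node_iter():
        if id(node) in ages:
            continue
        parent_age = ages[id(node.parent_node)]
        anchor_age, below = _anchor_below(node)
        span = parent_age - anchor_age
        ages[id(node)] = parent_age - span / (below + 2)

    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = ages[id(node.parent_node)] - ages[id(node)]
    return tree


# ---------------------------------------------------------------------------
# independent contrasts
# ---------------------------------------------------------------------------


@dataclass
class ContrastSet:
    """Standardized independent contrasts, one per (resolved) internal node."""

    node_ids: list[str]
    contrasts: np.ndarray
    expected_sd: np.ndarray

    def __len__(self) -> int:
        return len(self.contrasts)


def _resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    """Binary tree via zero-length internal branches, preserving child order."""
    tree = tree.clone(depth=1)
    for node in list(tree.preorder_node_iter()):
        while len(node.child_nodes()) > 2:
            children = node.child_nodes()
            a, b = children[0], children[1]
            new = dendropy.Node()
            new.edge.length = 0.0
            node.remove_child(a)
            node.remove_child(b)
            new.add_child(a)
            new.add_child(b)
            node.insert_child(0, new)
    return tree


def pic(tree: dendropy.Tree, trait: Mapping[str, float]) -> ContrastSet:
    """Felsenstein's phylogenetically independent contrasts.

    At each internal node of the (polytomy-resolved) tree the contrast is
    (x_i - x_j) / sqrt(v_i + v_j), the ancestral value is the
    branch-length-weighted average of the daughters, and the node's branch
    is lengthened by v_i v_j / (v_i + v_j).  Zero-length terminal branches
    are perturbed by a relative epsilon so the recursion stays defined.
    """
    if not has_branch_lengths(tree):
        raise TreeError("tree has missing branch lengths; contrasts need them")
    work = _resolve_polytomies(tree)
    trait = {normalize_label(k): float(v) for k, v in trait.items()}
    missing = [l for l in tip_labels(work) if l not in trait]
    if missing:
        raise TreeError(f"tips without trait values: {sorted(missing)}")

    depth = max(
        leaf.distance_from_root() for leaf in work.leaf_node_iter()
    ) or 1.0
    for leaf in work.leaf_node_iter():
        if leaf.edge.length == 0:
            logger.warning(
                "zero-length terminal branch at %s perturbed for contrasts",
                leaf.taxon.label,
            )
            leaf.edge.length = ZERO_BRANCH_EPS * depth

    node_ids, contrasts, sds = [], [], []
    value: dict[int, float] = {}
    length: dict[int, float] = {}
    counter = 0
    for node in work.postorder_node_iter():
        if node.is_leaf():
            value[id(node)] = trait[normalize_label(node.taxon.label)]
            length[id(node)] = float(node.edge.length)
            continue
        kids = node.child_nodes()
        (a, b) = kids
        va, vb = length[id(a)], length[id(b)]
        if va + vb <= 0:
            raise TreeError("zero total branch length at an internal node pair")
        counter += 1
        node_ids.append(node.label or f"node{counter}")
        contrasts.append((value[id(a)] - value[id(b)]) / np.sqrt(va + vb))
        sds.append(np.sqrt(va + vb))
        value[id(node)] = (value[id(a)] / va + value[id(b)] / vb) / (1 / va + 1 / vb)
        base = float(node.edge.length) if node.edge.length is not None else 0.0
        length[id(node)] = base + va * vb / (va + vb)
    return ContrastSet(node_ids, np.asarray(contrasts), np.asarray(sds))


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------


def brownian_vcv(tree: dendropy.Tree, taxa: Sequence[str]) -> np.ndarray:
    """Brownian covariance matrix: C_ij = shared root-to-tip path length."""
    if not has_branch_lengths(tree):
        raise TreeError("tree has missing branch lengths; covariance needs them")
    taxa = [normalize_label(t) for t in taxa]
    index = {t: i for i, t in enumerate(taxa)}
    if len(index) != len(taxa):
        raise TreeError("duplicate taxa in covariance request")
    validate_species_coverage(tree, taxa)
    n = len(taxa)
    C = np.zeros((n, n))
    depth: dict[int, float] = {}
    tipsets: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[id(parent)] + float(node.edge.length or 0.0)
        depth[id(node)] = d
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lbl = normalize_label(node.taxon.label)
            own = [index[lbl]] if lbl in index else []
            if own:
                C[own[0], own[0]] = depth[id(node)]
            tipsets[id(node)] = own
            continue
        child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                for a in child_sets[i]:
                    for b in child_sets[j]:
                        C[a, b] = C[b, a] = depth[id(node)]
        tipsets[id(node)] = [t for s in child_sets for t in s]
    return C


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


@dataclass
class PGLSResult(RegressionResult):
    """GLS regression under Brownian phylogenetic covariance.

    ``r_squared`` is the GLS analogue 1 - RSS_gls / TSS_gls, both sums
    evaluated on the phylogenetically whitened scale (TSS from the
    GLS-intercept-only model).
    """

    lambda_: float = 1.0
    lambda_mode: str = "fixed_1"


def _gls_core(y, X, C):
    n = len(y)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        bad = _degenerate_taxa(C)
        raise TreeError(
            f"phylogenetic covariance is singular (taxa with identical/zero "
            f"shared paths: indices {bad})"
        ) from exc
    Z = np.linalg.solve(L, np.column_stack([np.ones(n), X]))
    w = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Z, w, rcond=None)
    resid = w - Z @ beta
    rss = float(resid @ resid)
    # intercept-only model on the same whitened scale
    z0 = np.linalg.solve(L, np.ones(n))
    mu = float(z0 @ w / (z0 @ z0))
    tss_resid = w - z0 * mu
    tss = float(tss_resid @ tss_resid)
    XtX_inv = np.linalg.inv(Z.T @ Z)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return beta, rss, tss, XtX_inv, logdet


def _degenerate_taxa(C: np.ndarray) -> list[int]:
    bad = [i for i in range(len(C)) if C[i, i] <= 0]
    if bad:
        return bad
    # rows identical up to tolerance imply zero-length split
    for i in range(len(C)):
        for j in range(i + 1, len(C)):
            if np.allclose(C[i], C[j]):
                bad.extend([i, j])
    return sorted(set(bad))


def _reml_neg_loglik(lam, y, X, C):
    beta, rss, _, XtX_inv, logdet_c = _gls_core(y, X, _lambda_transform(C, lam))
    n = len(y)
    p = X.shape[1] + 1
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    sign, logdet_xtx = np.linalg.slogdet(np.linalg.inv(XtX_inv) / sigma2)
    return 0.5 * ((n - p) * np.log(sigma2) + logdet_c + logdet_xtx + (n - p))


def pgls_fit(
    tree: dendropy.Tree,
    y,
    X,
    names: Sequence[str] | None = None,
    taxa: Sequence[str] | None = None,
    lambda_mode: str = "fixed_1",
) -> PGLSResult:
    """Phylogenetic GLS of y on X with an intercept.

    ``y`` may be a mapping/Series keyed by species (taxa inferred) or an
    array aligned with ``taxa``.  ``lambda_mode`` is ``fixed_1`` (full
    Brownian covariance) or ``ml`` (Pagel's lambda estimated by REML on a
    grid over [0, 1] with local refinement).
    """
    if isinstance(y, Mapping):
        y = pd.Series(y)
    if isinstance(y, pd.Series):
        if taxa is None:
            taxa = list(y.index)
        y = y.to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
        if taxa is None:
            raise ValueError("taxa must be given when y is a bare array")
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i + 1}" for i in range(X.shape[1])]
    if lambda_mode not in ("fixed_1", "ml"):
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")

    n, k = X.shape
    if len(y) != n or len(taxa) != n:
        raise ValueError("y, X and taxa are not aligned")
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} species, got {n}")

    C = brownian_vcv(tree, taxa)
    if lambda_mode == "ml":
        grid = np.linspace(0.0, 1.0, 21)
        vals = [_reml_neg_loglik(l, y, X, C) for l in grid]
        best = grid[int(np.argmin(vals))]
        lo, hi = max(0.0, best - 0.05), min(1.0, best + 0.05)
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(lo, hi), args=(y, X, C), method="bounded"
        )
        lam = float(res.x) if res.fun <= min(vals) else float(best)
    else:
        lam = 1.0

    beta, rss, tss, XtX_inv, _ = _gls_core(y, X, _lambda_transform(C, lam))
    p = k + 1
    sigma2 = rss / (n - p)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=n - p)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if tss > rss and k >= 1:
        fstat = ((tss - rss) / k) / sigma2
        model_p = float(stats.f.sf(fstat, k, n - p))
    else:
        model_p = 1.0
    return PGLSResult(
        slopes=dict(zip(names, map(float, beta[1:]))),
        intercept=float(beta[0]),
        r_squared=float(r2),
        p_values=dict(zip(names, map(float, pvals[1:]))),
        n=n,
        tier=significance_tier(model_p),
        model_p=model_p,
        lambda_=lam,
        lambda_mode=lambda_mode,
    )


def habit_comparison(
    tree: dendropy.Tree,
    trait: Mapping[str, float],
    habit: Mapping[str, str],
    lambda_mode: str = "fixed_1",
) -> PGLSResult:
    """Deciduous-vs-evergreen contrast for a trait, as PGLS on a 0/1 indicator.

    The slope is the evergreen-minus-deciduous difference adjusted for
    phylogenetic covariance; on a star tree this reduces to the ordinary
    two-sample comparison.
    """
    species = sorted(trait, key=normalize_label)
    habits = {normalize_label(s): h for s, h in habit.items()}
    classes = {habits[normalize_label(s)] for s in species}
    if len(classes) < 2:
        raise ValueError(f"habit comparison needs both classes, found {sorted(classes)}")
    indicator = np.array(
        [1.0 if habits[normalize_label(s)] == "evergreen" else 0.0 for s in species]
    )
    values = pd.Series({s: trait[s] for s in species})
    return pgls_fit(tree, values, indicator, names=["evergreen"],
                    lambda_mode=lambda_mode)


def phylo_dependence(ols: RegressionResult, pgls: PGLSResult, alpha: float = 0.05) -> str:
    """Classify a pairwise relationship by its robustness to phylogeny.

    ``dependent``: significant ordinarily but not after phylogenetic
    correction (the relationship rides on shared ancestry);
    ``independent``: significant both ways; ``absent``: not significant
    ordinarily.
    """
    if ols.model_p >= alpha:
        return "absent"
    return "independent" if pgls.model_p < alpha else "dependent"
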
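"""Tree handling, age-based branch adjustment, contrasts, PGLS."""

import numpy as np
import pandas as pd
import pytest

from lmadecomp import (
    TreeError,
    bladj_adjust,
    brownian_vcv,
    fit_ols,
    habit_comparison,
    pgls_fit,
    phylo_dependence,
    pic,
    read_newick,
    read_newick_string,
    write_newick,
)
from lmadecomp.phylo import has_branch_lengths
from lmadecomp.simulate import _simulate_bm, generate_tree

# fixed 8-tip fixture; expected contrasts and the Brownian GLS fit were
# computed independently with R (ape::pic and nlme::gls with corBrownian)
# and frozen here
ORACLE_NEWICK = "(((A:1,B:1):2,(C:1.5,D:1.5):1.5):1,((E:0.5,F:0.5):2.5,(G:2,H:2):1):1);"
ORACLE_X = dict(A=1.2, B=3.4, C=2.2, D=5.1, E=0.7, F=1.9, G=4.4, H=2.8)
ORACLE_Y = dict(A=2.0, B=4.1, C=3.0, D=6.6, E=1.1, F=2.4, G=5.9, H=3.1)
ORACLE_ABS_PIC_X = sorted([
    0.181856455302, 0.619422481451, 1.555634918610, 1.674315780650,
    1.055312375805, 1.200000000000, 0.800000000000,
])
ORACLE_GLS = dict(slope=1.172074118903, intercept=0.349536191149, p=8.0234e-06)


def star_tree(n, length=1.0):
    tips = ",".join(f"t{i}:{length}" for i in range(n))
    return read_newick_string(f"({tips});")


class TestNewickIO:
    def test_two_tip_tree_with_lengths(self):
        tree = read_newick_string("(A:1,B:1);")
        leaves = list(tree.leaf_node_iter())
        assert len(leaves) == 2
        assert all(l.edge.length == 1.0 for l in leaves)

    def test_lengths_flagged_missing(self):
        tree = read_newick_string("((A,B),C);")
        assert len(list(tree.leaf_node_iter())) == 3
        assert not has_branch_lengths(tree)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            read_newick_string("(A:1,(A:0.5,B:0.5):0.5);")

    def test_write_read_round_trip(self, tmp_path):
        tree = generate_tree(12, seed=4)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        assert sorted(l.taxon.label for l in back.leaf_node_iter()) == taxa
        C1 = brownian_vcv(tree, taxa)
        C2 = brownian_vcv(back, taxa)
        np.testing.assert_allclose(C2, C1, rtol=1e-9)


class TestBladj:
    def test_chain_midpoint_forced_by_even_spacing(self):
        tree = read_newick_string("((A)X)R;")
        out = bladj_adjust(tree, {"R": 10.0})
        lengths = {n.label or (n.taxon.label if n.taxon else None): n.edge.length
                   for n in out.preorder_node_iter() if n.parent_node is not None}
        assert lengths["X"] == pytest.approx(5.0)
        assert lengths["A"] == pytest.approx(5.0)

    def test_fully_dated_tree_is_fixed_point(self):
        tree = read_newick_string("((A,B)N1,(C,D)N2)R;")
        ages = {"R": 12.0, "N1": 4.0, "N2": 7.0}
        once = bladj_adjust(tree, ages)
        twice = bladj_adjust(once, ages)

        def lengths(t):
            return [n.edge.length for n in t.preorder_node_iter() if n.parent_node]

        assert lengths(once) == pytest.approx([8.0, 4.0, 4.0, 5.0, 7.0, 7.0])
        assert lengths(twice) == pytest.approx(lengths(once))

    def test_age_inversion_rejected(self):
        tree = read_newick_string("((A,B)N1,C)R;")
        with pytest.raises(TreeError, match="inversion"):
            bladj_adjust(tree, {"R": 5.0, "N1": 9.0})

    def test_undated_root_rejected(self):
        tree = read_newick_string("((A,B)N1,C)R;")
        with pytest.raises(TreeError, match="root"):
            bladj_adjust(tree, {"N1": 2.0})

    @pytest.mark.parametrize("seed", range(6))
    def test_random_partial_dating_yields_ultrametric_monotone_ages(self, seed):
        rng = np.random.default_rng(seed)
        tree = generate_tree(16, seed=seed)
        # name internal nodes, date root plus a random subset consistently
        root_age = 50.0
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        depth = {}
        for n in tree.preorder_node_iter():
            depth[id(n)] = 0.0 if n.parent_node is None else (
                depth[id(n.parent_node)] + n.edge.length)
        for i, n in enumerate(internal):
            n.label = f"N{i}"
        ages = {"N0": root_age}
        for n in internal[1:]:
            if rng.random() < 0.4:
                ages[n.label] = root_age * (1.0 - depth[id(n)])
        out = bladj_adjust(tree, ages)
        tip_depths = [l.distance_from_root() for l in out.leaf_node_iter()]
        np.testing.assert_allclose(tip_depths, root_age, rtol=1e-9)
        assert all(
            n.edge.length >= -1e-9
            for n in out.preorder_node_iter() if n.parent_node is not None
        )


class TestIndependentContrasts:
    def test_two_tip_closed_form(self):
        tree = read_newick_string("(A:1,B:1);")
        cs = pic(tree, {"A": 3.0, "B": 1.0})
        assert len(cs) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(2.0 / np.sqrt(2.0))

    def test_identical_tip_values_contrast_to_zero(self):
        tree = generate_tree(10, seed=1)
        cs = pic(tree, {l: 4.2 for l in
                        (t.taxon.label for t in tree.leaf_node_iter())})
        np.testing.assert_allclose(cs.contrasts, 0.0, atol=1e-12)

    def test_matches_published_recursion_oracle(self):
        tree = read_newick_string(ORACLE_NEWICK)
        cs = pic(tree, ORACLE_X)
        assert len(cs) == 7
        np.testing.assert_allclose(
            sorted(np.abs(cs.contrasts)), ORACLE_ABS_PIC_X, rtol=1e-9)

    def test_contrast_count_after_polytomy_resolution(self):
        tree = read_newick_string("(A:1,B:1,C:1,D:1,E:1);")
        cs = pic(tree, {"A": 1, "B": 2, "C": 3, "D": 4, "E": 5})
        assert len(cs) == 4  # tips - 1 once the polytomy is resolved

    def test_contrast_variance_recovers_brownian_rate(self):
        """Standardized contrasts of a Brownian trait have variance equal
        to the simulating rate (parameter recovery across replicates)."""
        rng = np.random.default_rng(99)
        sigma2 = 0.7
        pooled = []
        for rep in range(500):
            tree = generate_tree(12, seed=rep)
            tips = _simulate_bm(tree, 0.0, sigma2, rng)
            pooled.extend(pic(tree, tips).contrasts)
        assert np.var(pooled) == pytest.approx(sigma2, rel=0.1)


class TestPGLS:
    def test_star_tree_reduces_to_ols(self, rng):
        n = 16
        tree = star_tree(n)
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        taxa = [f"t{i}" for i in range(n)]
        gls = pgls_fit(tree, pd.Series(y, index=taxa), x, names=["x"])
        ols = fit_ols(y, x, names=["x"])
        assert gls.slope == pytest.approx(ols.slope, abs=1e-10)
        assert gls.intercept == pytest.approx(ols.intercept, abs=1e-10)
        assert gls.r_squared == pytest.approx(ols.r_squared, abs=1e-10)
        assert gls.p_value == pytest.approx(ols.p_value, abs=1e-10)

    def test_constant_response_has_zero_slope(self):
        tree = generate_tree(10, seed=2)
        taxa = [l.taxon.label for l in tree.leaf_node_iter()]
        res = pgls_fit(tree, pd.Series(np.ones(10), index=taxa),
                       np.arange(10.0), names=["x"])
        assert res.slope == pytest.approx(0.0, abs=1e-10)

    def test_matches_r_gls_oracle(self):
        tree = read_newick_string(ORACLE_NEWICK)
        x = np.array([ORACLE_X[k] for k in ORACLE_Y])
        res = pgls_fit(tree, pd.Series(ORACLE_Y), x, names=["x"])
        assert res.slope == pytest.approx(ORACLE_GLS["slope"], rel=1e-9)
        assert res.intercept == pytest.approx(ORACLE_GLS["intercept"], rel=1e-9)
        assert res.p_value == pytest.approx(ORACLE_GLS["p"], rel=1e-4)

    def test_slope_equals_through_origin_pic_regression(self):
        rng = np.random.default_rng(7)
        for rep in range(10):
            tree = generate_tree(int(rng.integers(6, 24)), seed=100 + rep)
            x = _simulate_bm(tree, 0.0, 1.0, rng)
            noise = _simulate_bm(tree, 0.0, 0.5, rng)
            y = {k: 2.0 * x[k] + noise[k] for k in x}
            res = pgls_fit(tree, pd.Series(y), np.array([x[k] for k in y]),
                           names=["x"])
            cx, cy = pic(tree, x).contrasts, pic(tree, y).contrasts
            assert res.slope == pytest.approx((cx @ cy) / (cx @ cx), rel=1e-8)

    def test_zero_length_cherry_makes_covariance_singular(self):
        tree = read_newick_string("((A:0,B:0):1,(C:0.6,D:0.4):0.5);")
        with pytest.raises(TreeError, match="singular"):
            pgls_fit(tree, pd.Series({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}),
                     np.array([1.0, 2.0, 3.0, 4.0]), names=["x"])

    def test_lambda_ml_recovers_signal_extremes(self):
        rng = np.random.default_rng(13)
        tree = generate_tree(40, seed=21)
        tips = _simulate_bm(tree, 0.0, 1.0, rng)
        taxa = list(tips)
        x = rng.normal(size=40)
        # strongly phylogenetic residuals -> lambda near 1
        y_bm = pd.Series({t: tips[t] for t in taxa})
        hi = pgls_fit(tree, y_bm, x, names=["x"], lambda_mode="ml")
        # iid residuals -> lambda near 0
        y_iid = pd.Series(rng.normal(size=40), index=taxa)
        lo = pgls_fit(tree, y_iid, x, names=["x"], lambda_mode="ml")
        assert hi.lambda_ > 0.7
        assert lo.lambda_ < 0.3


class TestHabitComparison:
    def test_identical_trait_across_habits_is_ns(self):
        tree = generate_tree(12, seed=3)
        taxa = [l.taxon.label for l in tree.leaf_node_iter()]
        habit = {t: ("evergreen" if i < 6 else "deciduous") for i, t in enumerate(taxa)}
        res = habit_comparison(tree, {t: 5.0 for t in taxa}, habit)
        assert res.tier == "ns"

    def test_star_tree_equals_two_sample_ols(self, rng):
        n = 14
        tree = star_tree(n)
        taxa = [f"t{i}" for i in range(n)]
        habit = {t: ("evergreen" if i % 2 else "deciduous") for i, t in enumerate(taxa)}
        trait = {t: rng.normal(10 if habit[t] == "evergreen" else 8) for t in taxa}
        res = habit_comparison(tree, trait, habit)
        indicator = np.array([habit[t] == "evergreen" for t in sorted(taxa)], float)
        ols = fit_ols(np.array([trait[t] for t in sorted(taxa)]), indicator)
        assert res.slope == pytest.approx(ols.slope, abs=1e-10)
        assert res.p_value == pytest.approx(ols.p_value, abs=1e-10)

    def test_single_class_rejected(self):
        tree = generate_tree(6, seed=5)
        taxa = [l.taxon.label for l in tree.leaf_node_iter()]
        with pytest.raises(ValueError, match="both classes"):
            habit_comparison(tree, {t: 1.0 for t in taxa},
                             {t: "evergreen" for t in taxa})


@pytest.mark.parametrize(
    "p_ols, p_pgls, flag",
    [(0.01, 0.20, "dependent"), (0.01, 0.01, "independent"), (0.50, 0.01, "absent")],
)
def test_phylo_dependence_classification(p_ols, p_pgls, flag):
    from lmadecomp.regress import RegressionResult
    from lmadecomp.phylo import PGLSResult

    mk = dict(slopes={"x": 1.0}, intercept=0.0, r_squared=0.5,
              p_values={"x": 0.0}, n=30, tier="*")
    ols = RegressionResult(**{**mk, "model_p": p_ols})
    pgls = PGLSResult(**{**mk, "model_p": p_pgls})
    assert phylo_dependence(ols, pgls) == flag
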
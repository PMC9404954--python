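"""Tree surgery, BM machinery, signal tests, phylo-ANOVA and ancestral states."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from cercodent import (
    BMSimulator,
    Chronogram,
    blomberg_k,
    bm_rate,
    independent_contrasts,
    ml_asr,
    phylo_anova,
    phylogenetic_mean,
    phylosignal_test,
    simulate_bm,
)
from conftest import random_ultrametric_newick


# -- grafting ------------------------------------------------------------

def test_graft_at_split_age():
    tree = Chronogram.from_newick(
        "((Presbytis_melalophos:6,Nasalis:6):4,Colobus:10);")
    grafted = tree.graft("Presbytis_rubicunda", "Presbytis_melalophos", 1.3)
    assert grafted.is_ultrametric
    labs, D = grafted.tip_distances()
    i = labs.index("Presbytis_rubicunda")
    j = labs.index("Presbytis_melalophos")
    assert D[i, j] == pytest.approx(2.6)  # both daughter branches 1.3 Ma

    back = grafted.drop_tip("Presbytis_rubicunda")
    l0, D0 = tree.tip_distances()
    l1, D1 = back.tip_distances()
    assert l0 == l1 and np.allclose(D0, D1)  # graft then drop is identity


def test_graft_guards():
    tree = Chronogram.from_newick("((A:1,B:1):1,C:2);")
    with pytest.raises(ValueError, match="split_age"):
        tree.graft("X", "A", 99.0)
    with pytest.raises(ValueError, match="already"):
        tree.graft("C", "A", 0.5)


# -- BM covariance and simulation ----------------------------------------

def test_bm_covariance_three_tips():
    tree = Chronogram.from_newick("((A:1,B:1):1,C:2);")
    labels, V = tree.bm_covariance()
    assert labels == ["A", "B", "C"]
    assert np.allclose(V, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])


def test_bm_covariance_star_and_psd():
    star = Chronogram.from_newick("(A:3,B:3,C:3,D:3);")
    _, V = star.bm_covariance()
    assert np.allclose(V, 3 * np.eye(4))
    rng = np.random.default_rng(4)
    for _ in range(5):
        tree = Chronogram.from_newick(random_ultrametric_newick(rng, 12))
        _, V = tree.bm_covariance()
        assert np.linalg.eigvalsh(V).min() > -1e-9


def test_simulate_bm_moments(nine_tip_tree):
    rng = np.random.default_rng(0)
    sim = BMSimulator(nine_tip_tree, sigma2=2.0, root_state=5.0)
    draws = sim.draw(rng, size=10_000)
    depth = nine_tip_tree.depth
    se = np.sqrt(2.0 * depth / 10_000)
    assert draws[:, 0].mean() == pytest.approx(5.0, abs=3 * se)
    assert draws[:, 0].var() == pytest.approx(2.0 * depth, rel=0.05)
    a = simulate_bm(nine_tip_tree, 1.0, 0.0, seed=33)
    b = simulate_bm(nine_tip_tree, 1.0, 0.0, seed=33)
    pd.testing.assert_series_equal(a, b)


# -- contrasts -----------------------------------------------------------

def test_contrast_cherry_formula():
    tree = Chronogram.from_newick("((A:1.5,B:2.5):1,C:10);")
    u = independent_contrasts(tree, pd.Series({"A": 3.0, "B": 1.0, "C": 0.0}))
    assert u.size == 2  # n - 1 contrasts
    assert u[0] == pytest.approx((3.0 - 1.0) / np.sqrt(1.5 + 2.5))


def test_contrast_variance_matches_bm_rate(nine_tip_tree):
    rng = np.random.default_rng(8)
    sim = BMSimulator(nine_tip_tree, sigma2=1.7)
    draws = sim.draw(rng, size=10_000)
    sq = [np.mean(independent_contrasts(nine_tip_tree,
                                        pd.Series(row, index=sim.labels))**2)
          for row in draws[:2000]]
    assert np.mean(sq) == pytest.approx(1.7, rel=0.05)


def test_polytomy_resolution_keeps_contrast_count():
    tree = Chronogram.from_newick("(A:2,B:2,C:2,D:2,E:2);")
    u = independent_contrasts(tree, pd.Series(
        {"A": 1.0, "B": 2.0, "C": 0.5, "D": 1.5, "E": 0.0}))
    assert u.size == 4


# -- Blomberg's K --------------------------------------------------------

def test_k_is_one_on_average_under_bm(nine_tip_tree):
    rng = np.random.default_rng(12)
    sim = BMSimulator(nine_tip_tree)
    ks = [blomberg_k(nine_tip_tree, sim.draw(rng)) for _ in range(500)]
    assert 0.9 <= np.mean(ks) <= 1.1


def test_k_is_one_on_star_tree_with_iid_values():
    """On a star tree V is proportional to I, so both mean squared errors are
    the ordinary ones and K centres on 1 for iid data."""
    star = Chronogram.from_newick("(A:2,B:2,C:2,D:2,E:2,F:2,G:2,H:2);")
    rng = np.random.default_rng(13)
    ks = [blomberg_k(star, pd.Series(rng.standard_normal(8),
                                     index=star.tip_labels))
          for _ in range(500)]
    assert 0.9 <= np.mean(ks) <= 1.1


def test_k_guards(nine_tip_tree):
    with pytest.raises(ValueError, match="constant"):
        blomberg_k(nine_tip_tree, pd.Series(1.0, index=nine_tip_tree.tip_labels))
    small = Chronogram.from_newick("((A:1,B:1):1,C:2);")
    with pytest.raises(ValueError, match="4 tips"):
        blomberg_k(small, pd.Series({"A": 1.0, "B": 2.0, "C": 3.0}))


def test_phylosignal_detects_two_distinct_clades():
    tree = Chronogram.from_newick(
        "(((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1):3,"
        "((G:1,H:1):1,(I:1,J:1):1,(K:1,L:1):1):3);")
    vals = pd.Series({t: (0.0 if t <= "F" else 5.0) for t in tree.tip_labels})
    res = phylosignal_test(tree, vals, n_perm=999, seed=3)
    assert res.p <= 0.01
    assert res.K > 1.0


def test_phylosignal_uniform_on_star_tree():
    star = Chronogram.from_newick("(" + ",".join(
        f"t{i}:1" for i in range(9)) + ");")
    rng = np.random.default_rng(19)
    ps = [phylosignal_test(
        star, pd.Series(rng.standard_normal(9), index=star.tip_labels),
        n_perm=99, seed=rng).p for _ in range(500)]
    assert 0.45 <= np.mean(ps) <= 0.55
    assert 0.02 <= np.mean(np.asarray(ps) < 0.05) <= 0.09


def test_phylosignal_nperm_guard(nine_tip_tree):
    vals = pd.Series(np.arange(9.0), index=nine_tip_tree.tip_labels)
    with pytest.raises(ValueError, match="99"):
        phylosignal_test(nine_tip_tree, vals, n_perm=10)


# -- phylogenetic ANOVA --------------------------------------------------

GROUPS9 = pd.Series({"A": "g1", "B": "g1", "C": "g1", "D": "g1",
                     "E": "g2", "F": "g2", "G": "g3", "H": "g3", "I": "g3"})


def test_phylo_anova_power_and_degenerate(nine_tip_tree):
    """A genus offset by 10 within-genus SDs is detected; identical tip
    values give F = 0, p = 1. Six genera of three species each keep the BM
    null from confounding a group shift with a single deep branch."""
    parts = ",".join(
        "(" + ",".join(f"{chr(65 + gi)}{k}:4" for k in range(3)) + "):6"
        for gi in range(6))
    tree = Chronogram.from_newick(f"({parts});")
    groups = pd.Series({f"{chr(65 + gi)}{k}": f"g{gi}"
                        for gi in range(6) for k in range(3)})
    rng = np.random.default_rng(23)
    x = BMSimulator(tree, sigma2=0.01).draw(rng)
    within = x.groupby(groups).transform("mean")
    wsd = float(np.sqrt(((x - within) ** 2).sum() / (len(x) - 6)))
    x.loc[groups[groups == "g2"].index] += 10 * wsd
    res = phylo_anova(tree, groups, x, n_sim=999, seed=1)
    assert res.p_phylo <= 0.01
    assert res.per_group_p["g2"] <= 0.05

    flat = pd.Series(2.0, index=nine_tip_tree.tip_labels)
    res0 = phylo_anova(nine_tip_tree, GROUPS9, flat, n_sim=199, seed=1)
    assert res0.F == 0.0 and res0.p_phylo == 1.0


def test_phylo_anova_affine_invariance(nine_tip_tree):
    rng = np.random.default_rng(29)
    x = BMSimulator(nine_tip_tree).draw(rng)
    r1 = phylo_anova(nine_tip_tree, GROUPS9, x, n_sim=499, seed=7)
    r2 = phylo_anova(nine_tip_tree, GROUPS9, 3.0 * x - 11.0, n_sim=499, seed=7)
    assert r1.p_phylo == r2.p_phylo
    assert r1.per_group_p == r2.per_group_p


def test_phylo_anova_drops_empty_groups(nine_tip_tree):
    x = BMSimulator(nine_tip_tree).draw(np.random.default_rng(31))
    x.loc[["G", "H", "I"]] = np.nan
    with pytest.warns(UserWarning, match="dropped"):
        res = phylo_anova(nine_tip_tree, GROUPS9, x, n_sim=199, seed=5)
    assert set(res.per_group_p) == {"g1", "g2"}
    only_one = x.copy()
    only_one.loc[["E", "F", "G", "H", "I"]] = np.nan
    with pytest.warns(UserWarning):
        with pytest.raises(ValueError, match="2 groups"):
            phylo_anova(nine_tip_tree, GROUPS9, only_one, n_sim=199, seed=5)


# -- ancestral states ----------------------------------------------------

def test_root_estimate_examples():
    cherry = Chronogram.from_newick("(A:1,B:1);")
    assert phylogenetic_mean(cherry, pd.Series({"A": 0.0, "B": 4.0})) == \
        pytest.approx(2.0)
    uneven = Chronogram.from_newick("(A:1,B:3);")
    # GLS root: (0/1 + 4/3) / (1/1 + 1/3) = 1.0
    assert phylogenetic_mean(uneven, pd.Series({"A": 0.0, "B": 4.0})) == \
        pytest.approx(1.0)


def _joint_ml_states_grid(tree: Chronogram, values: pd.Series) -> dict:
    """Brute-force oracle: refine a grid over all internal-node states,
    minimizing the sum of squared branch increments weighted by branch
    length (equivalent to maximizing the joint BM likelihood)."""
    nodes = [n for n in tree.tree.preorder_node_iter() if not n.is_leaf()]
    edges = []
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        child = (values[node.taxon.label] if node.is_leaf()
                 else nodes.index(node))
        edges.append((nodes.index(node.parent_node), child,
                      node.edge.length or 0.0))

    def cost(states):
        total = 0.0
        for parent_i, child, t in edges:
            c = child if isinstance(child, float) else states[child]
            total += (c - states[parent_i]) ** 2 / max(t, 1e-12)
        return total

    lo, hi = values.min(), values.max()
    centers = np.full(len(nodes), (lo + hi) / 2)
    width = (hi - lo) if hi > lo else 1.0
    for _ in range(14):
        for _ in range(60):  # sweep until stable at this resolution
            moved = 0.0
            for i in range(len(nodes)):
                grid = centers[i] + np.linspace(-width, width, 21)
                costs = []
                for v in grid:
                    trial = centers.copy()
                    trial[i] = v
                    costs.append(cost(trial))
                best = grid[int(np.argmin(costs))]
                moved = max(moved, abs(best - centers[i]))
                centers[i] = best
            if moved < width / 100.0:
                break
        width /= 4.0
    return {
        "|".join(sorted(tree._leafset[n])): centers[i]
        for i, n in enumerate(nodes)
    }


@pytest.mark.parametrize("newick", [
    "((A:1,B:1):1,(C:1.5,D:0.5):1);",
    "(((A:1,B:1):1,C:2):1,(D:2,E:2):1);",
])
def test_asr_matches_grid_oracle(newick):
    tree = Chronogram.from_newick(newick)
    rng = np.random.default_rng(41)
    values = pd.Series(rng.uniform(0, 4, len(tree)), index=tree.tip_labels)
    oracle = _joint_ml_states_grid(tree, values)
    res = ml_asr(tree, values)
    for _, row in res.table.iterrows():
        assert row["estimate"] == pytest.approx(
            oracle[row["tip_set"]], abs=1e-4)


def test_asr_estimates_inside_tip_range():
    """The convex-hull property: reconstructions can never exceed the range
    of extant values — the mechanism behind fossil under-estimation."""
    rng = np.random.default_rng(43)
    for _ in range(20):
        tree = Chronogram.from_newick(
            random_ultrametric_newick(rng, int(rng.integers(4, 15))))
        values = pd.Series(rng.normal(1.2, 0.3, len(tree)),
                           index=tree.tip_labels)
        res = ml_asr(tree, values)
        assert (res.table["estimate"] >= values.min() - 1e-9).all()
        assert (res.table["estimate"] <= values.max() + 1e-9).all()
        assert (res.table["ci95_low"] <= res.table["estimate"]).all()
        assert (res.table["estimate"] <= res.table["ci95_high"]).all()


def test_asr_guards(nine_tip_tree):
    vals = pd.Series(np.arange(9.0), index=nine_tip_tree.tip_labels)
    with pytest.raises(ValueError, match="missing"):
        ml_asr(nine_tip_tree, vals.mask(vals > 5))
    with pytest.raises(ValueError, match="3 tips"):
        ml_asr(Chronogram.from_newick("(A:1,B:1);"),
               pd.Series({"A": 0.0, "B": 1.0}))


def test_asr_annotated_newick_round_trips(seven_tip_tree):
    vals = pd.Series(np.linspace(0, 1, 7), index=seven_tip_tree.tip_labels)
    res = ml_asr(seven_tip_tree, vals)
    text = res.annotated_newick()
    assert Chronogram.from_newick(text).tip_labels == seven_tip_tree.tip_labels


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_against_r_reference_implementations(tmp_path, seven_tip_tree):
    """Independent cross-check: phytools::fastAnc (estimates and variances,
    which use the REML rate) and picante::Kcalc agree with this
    implementation on a 7-tip chronogram."""
    script = tmp_path / "oracle.R"
    script.write_text("""
suppressMessages(library(phytools)); suppressMessages(library(picante))
tree <- read.tree(text="(((A:2,B:2):3,(C:1,D:1):4):5,((E:4,F:4):2,G:6):4);")
x <- c(A=0.1, B=0.4, C=1.2, D=1.0, E=2.3, F=2.0, G=1.5)
fa <- fastAnc(tree, x, vars=TRUE)
for (i in seq_along(fa$ace)) {
  node <- as.integer(names(fa$ace)[i])
  tips <- sort(extract.clade(tree, node)$tip.label)
  cat("ASR", paste(tips, collapse="|"), fa$ace[i], fa$var[i], "\\n")
}
cat("K", Kcalc(x[tree$tip.label], tree), "\\n")
""")
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, check=True).stdout
    values = pd.Series({"A": 0.1, "B": 0.4, "C": 1.2, "D": 1.0,
                        "E": 2.3, "F": 2.0, "G": 1.5})
    mine = ml_asr(seven_tip_tree, values, rate_method="REML")
    table = mine.table.set_index("tip_set")
    checked = 0
    for line in out.strip().splitlines():
        parts = line.split()
        if parts[0] == "ASR":
            assert table.loc[parts[1], "estimate"] == pytest.approx(
                float(parts[2]), abs=1e-5)
            assert table.loc[parts[1], "variance"] == pytest.approx(
                float(parts[3]), rel=1e-4)
            checked += 1
        elif parts[0] == "K":
            assert blomberg_k(seven_tip_tree, values) == pytest.approx(
                float(parts[1]), abs=1e-5)
            checked += 1
    assert checked == 7  # 6 internal nodes + K
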
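"""Lineage-fate statistics: units, closed forms, and a Fisher oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tapelineage import (
    LineageTree,
    TreeNode,
    clade_composition_enrichment,
    daughter_fate_test,
    knn_mixing_matrix,
    lineage_state_correlation,
    neighbor_pair_frequency,
    phylo_correlation,
    pseudobulk_pcs,
)
from tapelineage.phenostats import phylo_weights


def _balanced_tree(depth):
    def build(d, prefix):
        if d == 0:
            return TreeNode(name=prefix)
        return TreeNode(
            children=[build(d - 1, prefix + "0"), build(d - 1, prefix + "1")],
            height=float(d),
        )

    return LineageTree(build(depth, "t"))


def _star_tree(n, height=1.0):
    tips = [TreeNode(name=f"t{i}") for i in range(n)]
    return LineageTree(TreeNode(children=tips, height=height))


# ---------------------------------------------------------------------------
# lineage_state_correlation
# ---------------------------------------------------------------------------


def test_state_correlation_positive_trend():
    tree = _balanced_tree(4)
    rng = np.random.default_rng(0)
    # embedding coordinates drift with the tip's binary address -> distance
    # in embedding grows with tree distance
    coords = {}
    for t in tree.tip_names():
        bits = np.array([int(b) for b in t[1:]], dtype=float)
        coords[t] = np.concatenate([bits * 3, rng.normal(size=2) * 0.01])
    emb = pd.DataFrame(coords).T
    table, rho = lineage_state_correlation(tree, emb)
    assert rho > 0.9
    assert (table["n_pairs"] > 0).all()


def test_state_correlation_binning():
    tree = _balanced_tree(2)  # pair distances 2 and 4
    emb = pd.DataFrame(
        np.eye(4), index=tree.tip_names(),
    )
    table, _ = lineage_state_correlation(tree, emb)
    assert list(table["bin"])[:2] == ["2", "4"]
    assert table.loc[table["bin"] == "2", "n_pairs"].item() == 2
    assert table.loc[table["bin"] == "4", "n_pairs"].item() == 4


def test_state_correlation_missing_tip_errors():
    tree = _balanced_tree(2)
    emb = pd.DataFrame(np.eye(3), index=tree.tip_names()[:3])
    with pytest.raises(ValueError):
        lineage_state_correlation(tree, emb)


# ---------------------------------------------------------------------------
# neighbor_pair_frequency
# ---------------------------------------------------------------------------


def test_neighbor_pairs_enrich_same_type():
    tree = _balanced_tree(4)
    # sister pairs share their prefix; give both members the same label
    labels = pd.Series(
        {t: "A" if t[:-1].endswith("0") else "B" for t in tree.tip_names()}
    )
    # force identical labels within each cherry
    lab = {}
    for t in tree.tip_names():
        lab[t] = "A" if int(t[1:-1], 2) % 2 == 0 else "B"
    labels = pd.Series(lab)
    out = neighbor_pair_frequency(tree, labels, n_perm=200, seed=0)
    assert out.loc["A", "A"] > 0
    assert out.loc["B", "B"] > 0
    assert out.loc["A", "B"] < 0


def test_neighbor_pairs_symmetric():
    tree = _balanced_tree(3)
    rng = np.random.default_rng(1)
    labels = pd.Series(
        rng.choice(["A", "B"], size=8), index=tree.tip_names()
    )
    out = neighbor_pair_frequency(tree, labels, n_perm=50, seed=0)
    assert np.allclose(out.to_numpy(), out.to_numpy().T, equal_nan=True)


# ---------------------------------------------------------------------------
# phylo weights and Moran's I closed forms
# ---------------------------------------------------------------------------


def test_phylo_weights_rows_normalized():
    tree = _balanced_tree(3)
    W = phylo_weights(tree)
    A = W.to_numpy()
    assert np.allclose(A.sum(axis=1), 1.0)
    assert np.allclose(np.diag(A), 0.0)


def test_moran_two_tips_is_minus_one():
    tree = _star_tree(2)
    labels = pd.Series({"t0": "A", "t1": "B"})
    out = phylo_correlation(tree, labels, mode="auto")
    for _, r in out.iterrows():
        assert r["I"] == pytest.approx(-1.0)


def test_moran_star_tree_closed_form():
    # equal weights: I = sum_{i!=j} z_i z_j / (n-1) / sum z_i^2 = -1/(n-1)
    n = 10
    tree = _star_tree(n)
    labels = pd.Series(
        {f"t{i}": ("A" if i < 4 else "B") for i in range(n)}
    )
    out = phylo_correlation(tree, labels, mode="auto")
    for _, r in out.iterrows():
        assert r["I"] == pytest.approx(-1.0 / (n - 1))


def test_moran_clustered_labels_positive():
    tree = _balanced_tree(4)
    labels = pd.Series(
        {t: ("A" if t[1] == "0" else "B") for t in tree.tip_names()}
    )
    out = phylo_correlation(tree, labels, mode="auto")
    assert (out["I"] > 0.1).all()
    assert (out["p"] < 0.01).all()


def test_moran_constant_indicator_undefined():
    tree = _star_tree(4)
    labels = pd.Series({f"t{i}": "A" for i in range(4)})
    out = phylo_correlation(tree, labels, mode="auto")
    assert out["I"].isna().all()
    assert (out["note"] == "constant indicator").all()


def test_moran_cross_mode():
    tree = _balanced_tree(3)
    rng = np.random.default_rng(0)
    labels = pd.Series(rng.choice(["A", "B", "C"], size=8),
                       index=tree.tip_names())
    out = phylo_correlation(tree, labels, mode="cross", n_perm=99, seed=0)
    assert len(out) == 3
    assert ((out["p"] > 0) & (out["p"] <= 1)).all()


# ---------------------------------------------------------------------------
# daughter_fate_test (oracle: hypergeometric summation)
# ---------------------------------------------------------------------------


def _fisher_two_sided_oracle(table):
    """Two-sided Fisher p by summing hypergeometric pmf <= observed."""
    (a, b), (c, d) = table
    n1, n2 = a + b, c + d
    k = a + c
    rv = stats.hypergeom(n1 + n2, n1, k)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def test_fisher_matches_hypergeometric_summation():
    for a, b, c, d in itertools.product(range(6), repeat=4):
        table = np.array([[a, b], [c, d]])
        if table.sum() == 0 or (table.sum(axis=0) == 0).any():
            continue
        _, p = stats.fisher_exact(table, alternative="two-sided")
        assert p == pytest.approx(_fisher_two_sided_oracle(table), abs=1e-9)


def test_daughter_fate_test_detects_split():
    tree = _balanced_tree(5)  # 32 tips; root split of 16 vs 16
    labels = pd.Series(
        {t: ("A" if t[1] == "0" else "B") for t in tree.tip_names()}
    )
    out = daughter_fate_test(tree, labels, group1={"A"}, min_clade=10)
    assert not out.empty
    top = out.iloc[0]
    assert top["q"] < 0.01
    assert {top["n1"], top["n2"]} == {16}


def test_daughter_fate_test_skips_zero_margin():
    tree = _balanced_tree(5)
    labels = pd.Series({t: "A" for t in tree.tip_names()})
    out = daughter_fate_test(tree, labels, group1={"B"}, min_clade=10)
    assert out.empty
    assert out.attrs["skipped_zero_margin"] >= 1


# ---------------------------------------------------------------------------
# clade enrichment
# ---------------------------------------------------------------------------


def test_clade_enrichment_detects_planted_signal():
    rng = np.random.default_rng(0)
    wells = [f"W{i:02d}" for i in range(18)]
    props = pd.DataFrame(rng.dirichlet([5, 5], size=18),
                         index=wells, columns=["hi", "lo"])
    clade = pd.Series(["X"] * 6 + ["Y"] * 12, index=wells)
    props.loc[clade == "X", "hi"] += 0.8   # planted enrichment
    out = clade_composition_enrichment(props, clade, n_perm=999, seed=0)
    row = out[(out["clade"] == "X") & (out["type"] == "hi")].iloc[0]
    assert row["p"] < 0.01


def test_clade_enrichment_skips_singletons():
    rng = np.random.default_rng(1)
    wells = [f"W{i}" for i in range(5)]
    props = pd.DataFrame(rng.dirichlet([1, 1], size=5),
                         index=wells, columns=["a", "b"])
    clade = pd.Series(["X", "X", "Y", "Y", "Z"], index=wells)
    out = clade_composition_enrichment(props, clade, n_perm=99, seed=0)
    assert set(out["clade"]) == {"X", "Y"}


# ---------------------------------------------------------------------------
# pseudobulk and mixing
# ---------------------------------------------------------------------------


def test_pseudobulk_requires_three_wells():
    counts = pd.DataFrame(np.ones((4, 5)),
                          index=[f"c{i}" for i in range(4)])
    well_of = pd.Series(["W1"] * 2 + ["W2"] * 2, index=counts.index)
    with pytest.raises(ValueError):
        pseudobulk_pcs(counts, well_of, min_cells=1)


def test_pseudobulk_shapes_and_variance():
    rng = np.random.default_rng(0)
    cells = [f"c{i}" for i in range(60)]
    counts = pd.DataFrame(rng.poisson(5, size=(60, 30)), index=cells)
    well_of = pd.Series([f"W{i // 10}" for i in range(60)], index=cells)
    pcs, var, cov = pseudobulk_pcs(counts, well_of, min_cells=5, n_pcs=3)
    assert pcs.shape == (6, 3)
    assert np.all(var[:-1] >= var[1:])   # decreasing variance fractions
    assert var.sum() <= 1.0 + 1e-9


def test_knn_mixing_symmetric_and_bounded():
    rng = np.random.default_rng(0)
    cells = [f"c{i}" for i in range(90)]
    emb = pd.DataFrame(rng.normal(size=(90, 5)), index=cells)
    well_of = pd.Series([f"W{i % 3}" for i in range(90)], index=cells)
    M = knn_mixing_matrix(emb, well_of, k=10)
    A = M.to_numpy()
    assert np.allclose(A, A.T)
    assert (A >= 0).all() and (A <= 1).all()


def test_knn_mixing_separated_wells_do_not_mix():
    cells = [f"c{i}" for i in range(40)]
    X = np.zeros((40, 2))
    X[20:, 0] = 100.0   # two far-apart blobs
    rng = np.random.default_rng(0)
    X += rng.normal(scale=0.1, size=X.shape)
    emb = pd.DataFrame(X, index=cells)
    well_of = pd.Series(["W1"] * 20 + ["W2"] * 20, index=cells)
    M = knn_mixing_matrix(emb, well_of, k=5)
    assert M.loc["W1", "W2"] == 0.0
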
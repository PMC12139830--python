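"""Tape edit distance, UPGMA, RF, and TBE — units, properties, oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tapelineage import (
    LineageTree,
    TreeNode,
    bootstrap_tbe,
    build_tree,
    filter_matrix,
    pairwise_cell_distance,
    robinson_foulds,
    tape_edit_distance,
    transfer_distance,
    upgma,
)
from tapelineage.tree import _bipartition_array


# ---------------------------------------------------------------------------
# tape_edit_distance
# ---------------------------------------------------------------------------


def test_distance_worked_example():
    assert tape_edit_distance(("A", "C", "D"), ("B",)) == 4


def test_distance_identity():
    assert tape_edit_distance(("A", "B"), ("A", "B")) == 0
    assert tape_edit_distance((), ()) == 0


def test_distance_disjoint_saturation():
    a = tuple("ABCDEF")
    b = tuple("GHIJKL")
    assert tape_edit_distance(a, b) == 12


def test_distance_single_append():
    assert tape_edit_distance(("A", "B"), ("A", "B", "C")) == 1


def test_distance_too_long_errors():
    with pytest.raises(ValueError):
        tape_edit_distance(tuple("ABCDEFG"), ())


def _bfs_distance(a, b, alphabet, max_len=6):
    """Oracle: BFS over single-step append / remove-last operations."""
    from collections import deque

    start, goal = tuple(a), tuple(b)
    seen = {start: 0}
    q = deque([start])
    while q:
        cur = q.popleft()
        if cur == goal:
            return seen[cur]
        nxt = []
        if cur:
            nxt.append(cur[:-1])
        if len(cur) < max_len:
            nxt.extend(cur + (ch,) for ch in alphabet)
        for n in nxt:
            if n not in seen:
                seen[n] = seen[cur] + 1
                q.append(n)
    raise AssertionError("unreachable")


alleles = st.lists(st.sampled_from("AB"), max_size=6).map(tuple)


@given(alleles, alleles)
def test_distance_matches_bfs_oracle(a, b):
    assert tape_edit_distance(a, b) == _bfs_distance(a, b, "AB")


@given(alleles, alleles, alleles)
def test_distance_metric_axioms(a, b, c):
    dab = tape_edit_distance(a, b)
    assert 0 <= dab <= 12
    assert dab == tape_edit_distance(b, a)
    assert (dab == 0) == (a == b)
    assert dab <= tape_edit_distance(a, c) + tape_edit_distance(c, b)


# ---------------------------------------------------------------------------
# filter_matrix / pairwise_cell_distance
# ---------------------------------------------------------------------------


def _mat(rows, columns):
    return pd.DataFrame(rows).T.reindex(columns=columns)


def test_filter_drops_sparse_locus():
    # locus L1 observed in 9 cells -> removed; L2 observed in all 12 cells
    cells = [f"c{i}" for i in range(12)]
    data = {
        "L1": {c: ("A",) for c in cells[:9]},
        "L2": {c: ("B",) for c in cells},
    }
    out = filter_matrix(pd.DataFrame(data))
    assert list(out.columns) == ["L2"]


def test_filter_homogeneous_keeps_all_cells():
    cells = [f"c{i}" for i in range(12)]
    df = pd.DataFrame({"L1": {c: ("A",) for c in cells},
                       "L2": {c: () for c in cells}})
    out = filter_matrix(df)
    assert sorted(out.index) == sorted(cells)


def test_filter_removes_planted_outliers():
    # 30 cells each observe 20 loci; 2 outliers observe only 2
    rng = np.random.default_rng(0)
    cells = [f"c{i:02d}" for i in range(32)]
    data = {}
    for li in range(20):
        col = {}
        for c in cells[:30]:
            col[c] = ("A",)
        data[f"L{li}"] = col
    for li in (0, 1):
        data[f"L{li}"]["c30"] = ("A",)
        data[f"L{li}"]["c31"] = ("A",)
    out = filter_matrix(pd.DataFrame(data).reindex(index=cells))
    assert "c30" not in out.index and "c31" not in out.index
    assert len(out.index) == 30


def test_filter_all_removed_errors():
    with pytest.raises(ValueError):
        filter_matrix(pd.DataFrame({"L1": {"c1": ("A",)}}),
                      min_cells_per_locus=10)


def test_pairwise_distance_hand_example():
    # two shared loci with per-locus distances 4 and 0 -> mean 2.0
    df = pd.DataFrame({
        "L1": {"x": ("A", "C", "D"), "y": ("B",)},
        "L2": {"x": ("A",), "y": ("A",)},
    })
    D = pairwise_cell_distance(df)
    assert D.loc["x", "y"] == 2.0
    assert D.loc["x", "x"] == 0.0


def test_pairwise_distance_no_shared_locus():
    # x and y share L1 (d=2); z is observed only on L2
    df = pd.DataFrame({"L1": {"x": ("A",), "y": ("B",)},
                       "L2": {"z": ("B",)}})
    D, report = pairwise_cell_distance(df, return_report=True)
    assert report["n_pairs_no_shared_locus"] == 2
    # max observed is d(x,y)=2 -> placeholder 3 for both z pairs
    assert D.loc["x", "z"] == pytest.approx(3.0)
    assert D.loc["y", "z"] == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def _dm(labels, d):
    n = len(labels)
    M = np.zeros((n, n))
    for (i, j), v in d.items():
        M[i, j] = M[j, i] = v
    return pd.DataFrame(M, index=labels, columns=labels)


def test_upgma_textbook_example():
    D = _dm(["A", "B", "C"], {(0, 1): 2, (0, 2): 8, (1, 2): 8})
    tree = upgma(D)
    root = tree.root
    assert root.height == 4.0
    inner = [c for c in root.children if not c.is_tip()][0]
    assert inner.height == 1.0
    assert sorted(t.name for t in tree.tips()) == ["A", "B", "C"]
    assert {t.name for t in LineageTree(inner).tips()} == {"A", "B"}


def test_upgma_two_taxa():
    tree = upgma(_dm(["A", "B"], {(0, 1): 3.0}))
    assert tree.root.height == 1.5
    assert sorted(t.name for t in tree.tips()) == ["A", "B"]


def test_upgma_rejects_asymmetric():
    M = pd.DataFrame([[0, 1], [2, 0]], index=["A", "B"], columns=["A", "B"])
    with pytest.raises(ValueError):
        upgma(M)


def test_upgma_tie_break_deterministic():
    # all distances equal: merges must follow lexicographic member order
    labels = ["d", "c", "b", "a"]
    D = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=labels,
                     columns=labels)
    t1 = upgma(D).to_newick()
    t2 = upgma(D.loc[sorted(labels), sorted(labels)]).to_newick()
    assert t1 == t2


def _brute_force_upgma_nodes(D: pd.DataFrame):
    """Oracle: naive average linkage recomputing means from the raw matrix.

    Returns the set of (frozenset of tips, height) over internal nodes.
    """
    labels = list(D.index)
    clusters = [frozenset([l]) for l in labels]
    nodes = set()
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = np.mean([D.loc[x, y] for x in a for y in b])
            key = (d, tuple(sorted((min(a), min(b)))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        clusters.remove(a)
        clusters.remove(b)
        merged = a | b
        clusters.append(merged)
        nodes.add((merged, round(d / 2.0, 9)))
    return nodes


def _tree_nodes(tree: LineageTree):
    out = set()
    tip_sets = tree.tip_sets()
    for node in tree.internal_nodes():
        out.add((tip_sets[id(node)], round(node.height, 9)))
    return out


def test_upgma_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    for rep in range(50):
        labels = [f"t{i}" for i in range(8)]
        M = rng.uniform(1, 10, size=(8, 8))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        D = pd.DataFrame(M, index=labels, columns=labels)
        assert _tree_nodes(upgma(D)) == _brute_force_upgma_nodes(D)


@given(st.integers(0, 1000))
def test_upgma_ultrametric(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    M = rng.uniform(0.5, 5, size=(n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0)
    labels = [f"t{i}" for i in range(n)]
    tree = upgma(pd.DataFrame(M, index=labels, columns=labels))
    for node in tree.preorder():
        for c in node.children:
            assert c.height <= node.height + 1e-12
    for t in tree.tips():
        assert t.height == 0.0


# ---------------------------------------------------------------------------
# Robinson-Foulds (oracle: dendropy)
# ---------------------------------------------------------------------------


def _random_tree(labels, rng):
    nodes = [TreeNode(name=l) for l in labels]
    h = 1.0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b], height=h))
        h += 1.0
    return LineageTree(nodes[0])


def test_rf_matches_dendropy():
    import dendropy

    rng = np.random.default_rng(3)
    labels = [f"t{i}" for i in range(8)]
    for rep in range(20):
        t1 = _random_tree(labels, rng)
        t2 = _random_tree(labels, rng)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                               taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert robinson_foulds(t1, t2) == expected


def test_restrict_to():
    rng = np.random.default_rng(5)
    labels = [f"t{i}" for i in range(10)]
    tree = _random_tree(labels, rng)
    sub = tree.restrict_to(labels[:4])
    assert sorted(sub.tip_names()) == sorted(labels[:4])
    for node in sub.preorder():
        assert node.is_tip() or len(node.children) >= 2
    with pytest.raises(ValueError):
        tree.restrict_to(["nope"])


# ---------------------------------------------------------------------------
# Transfer distance and TBE
# ---------------------------------------------------------------------------


def _oracle_transfer(clade, boot_tree, all_tips):
    """Min bipartition Hamming distance over the bootstrap tree's branches."""
    order = {t: i for i, t in enumerate(sorted(all_tips))}
    n = len(all_tips)
    b = np.zeros(n, dtype=bool)
    for t in clade:
        b[order[t]] = True
    best = n
    tip_sets = boot_tree.tip_sets()
    for node in boot_tree.preorder():
        c = np.zeros(n, dtype=bool)
        for t in tip_sets[id(node)]:
            c[order[t]] = True
        h = int((b != c).sum())
        best = min(best, h, n - h)
    return best


def test_transfer_distance_matches_exhaustive():
    rng = np.random.default_rng(11)
    labels = [f"t{i}" for i in range(6)]
    order = {t: i for i, t in enumerate(sorted(labels))}
    for rep in range(20):
        t_ref = _random_tree(labels, rng)
        t_boot = _random_tree(labels, rng)
        parts = []
        tip_sets = t_boot.tip_sets()
        for node in t_boot.preorder():
            parts.append(_bipartition_array(tip_sets[id(node)], order, 6))
        boot_parts = np.array(parts)
        for clade in t_ref.tip_sets().values():
            b = _bipartition_array(clade, order, 6)
            assert transfer_distance(b, boot_parts) == _oracle_transfer(
                clade, t_boot, labels
            )


def test_self_bootstrap_tbe_is_one(true_matrix):
    mat = filter_matrix(true_matrix, min_cells_per_locus=5)
    report = bootstrap_tbe(mat, n_bootstraps=5, seed=0, resample=False)
    vals = list(report.tbe.values())
    assert vals and all(v == pytest.approx(1.0) for v in vals)


def test_tbe_in_unit_interval(true_matrix):
    mat = filter_matrix(true_matrix, min_cells_per_locus=5)
    report = bootstrap_tbe(mat, n_bootstraps=10, seed=0)
    assert report.n_bootstraps == 10
    for v in report.tbe.values():
        assert 0.0 <= v <= 1.0
    assert 0.0 <= report.fraction_supported <= 1.0


def test_build_tree_end_to_end(true_matrix):
    tree = build_tree(true_matrix, min_cells_per_locus=5)
    assert tree.n_tips() > 30
    heights = [n.height for n in tree.preorder()]
    assert max(heights) == tree.root.height
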
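"""Lineage-tree reconstruction from sequential-insertion tape records.

A DNA Typewriter tape holds up to six ordered 3-base insertions written in
strict 5'->3' order, so two tape alleles always share a (possibly empty)
common prefix of edits.  The distance between two alleles is the number of
single-edit steps needed to turn one into the other: revert the edits that
lie beyond the shared prefix, then write the other allele's remaining edits.
Cell-cell distances average this per-tape distance over the tape loci
observed in both cells, and trees are built with UPGMA (average linkage),
with branch support quantified by the transfer bootstrap expectation (TBE)
over column (locus) resamples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAX_TAPE_SITES = 6

# ---------------------------------------------------------------------------
# Tree container
# ---------------------------------------------------------------------------


class TreeNode:
    """Node of a rooted tree with heights (ultrametric for UPGMA output)."""

    __slots__ = ("name", "children", "height", "support", "parent")

    def __init__(self, name=None, children=None, height=0.0, support=None):
        self.name = name
        self.children = list(children) if children else []
        self.height = height
        self.support = support
        self.parent = None
        for c in self.children:
            c.parent = self

    def add_child(self, node: "TreeNode") -> None:
        node.parent = self
        self.children.append(node)

    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, h={self.height:.3g}, k={len(self.children)})"


class LineageTree:
    """Rooted tree over cells (or wells) with heights and optional support."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable[TreeNode]:
        out = list(self.preorder())
        return reversed(out)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip()]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def internal_nodes(self, skip_root: bool = False) -> list[TreeNode]:
        nodes = [n for n in self.preorder() if not n.is_tip()]
        if skip_root:
            nodes = [n for n in nodes if n is not self.root]
        return nodes

    def n_tips(self) -> int:
        return len(self.tips())

    # -- bipartitions ------------------------------------------------------
    def tip_sets(self) -> dict[int, frozenset]:
        """Map id(node) -> frozenset of descendant tip names."""
        out: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_tip():
                out[id(node)] = frozenset([node.name])
            else:
                acc: set = set()
                for c in node.children:
                    acc |= out[id(c)]
                out[id(node)] = frozenset(acc)
        return out

    def bipartitions(self) -> list[tuple[TreeNode, frozenset]]:
        """Non-trivial bipartitions, one per internal non-root node.

        Each is returned as (node, tip-name set of the clade).
        """
        tip_sets = self.tip_sets()
        all_tips = tip_sets[id(self.root)]
        out = []
        for node in self.preorder():
            if node is self.root or node.is_tip():
                continue
            clade = tip_sets[id(node)]
            if 1 < len(clade) < len(all_tips):
                out.append((node, clade))
        return out

    # -- distances ---------------------------------------------------------
    def cophenetic_matrix(self, order: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Patristic (cophenetic) tip-tip distances, 2x the MRCA height."""
        names = list(order) if order is not None else self.tip_names()
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        D = np.zeros((n, n))
        tip_lists: dict[int, list[int]] = {}
        for node in self.postorder():
            if node.is_tip():
                tip_lists[id(node)] = [idx[node.name]]
            else:
                kids = [tip_lists[id(c)] for c in node.children]
                for a, b in itertools.combinations(range(len(kids)), 2):
                    for i in kids[a]:
                        D[i, kids[b]] = 2.0 * node.height
                        D[kids[b], i] = 2.0 * node.height
                tip_lists[id(node)] = [i for k in kids for i in k]
        return pd.DataFrame(D, index=names, columns=names)

    def nearest_neighbor_pairs(self) -> list[tuple[str, str]]:
        """Ordered (tip, co-minimal nearest tip) pairs.

        A tip may have several co-equal nearest neighbors, in which case all
        are returned; redundant ordered pairs (a,b) and (b,a) are retained.
        """
        D = self.cophenetic_matrix()
        names = list(D.index)
        A = D.to_numpy(copy=True)
        np.fill_diagonal(A, np.inf)
        pairs = []
        for i, name in enumerate(names):
            m = A[i].min()
            for j in np.flatnonzero(A[i] == m):
                pairs.append((name, names[j]))
        return pairs

    def restrict_to(self, tip_names: Iterable[str]) -> "LineageTree":
        """Copy of the tree pruned to the given tips.

        Internal nodes left with a single child are collapsed (the child is
        promoted, keeping its own height), so the result has no unary nodes.
        """
        keep = set(tip_names)
        missing = keep - set(self.tip_names())
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)[:5]}")

        def prune(node: TreeNode) -> Optional[TreeNode]:
            if node.is_tip():
                if node.name in keep:
                    return TreeNode(name=node.name, height=node.height,
                                    support=node.support)
                return None
            kids = [k for k in (prune(c) for c in node.children)
                    if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return TreeNode(name=node.name, children=kids,
                            height=node.height, support=node.support)

        root = prune(self.root)
        if root is None:
            raise ValueError("no tips retained")
        return LineageTree(root)

    # -- IO ----------------------------------------------------------------
    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode, parent_height: Optional[float]) -> str:
            bl = ""
            if parent_height is not None:
                bl = f":{parent_height - node.height:g}"
            if node.is_tip():
                return f"{_quote(node.name)}{bl}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            elif node.name:
                label = _quote(node.name)
            return f"({inner}){label}{bl}"

        return fmt(self.root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "LineageTree":
        import dendropy

        dt = dendropy.Tree.get(data=text, schema="newick")
        # heights from root-to-node depths: height = max depth - depth
        depths: dict = {}

        def depth_of(nd, acc):
            depths[nd] = acc
            for ch in nd.child_nodes():
                depth_of(ch, acc + (ch.edge.length or 0.0))

        depth_of(dt.seed_node, 0.0)
        max_depth = max(depths.values()) if depths else 0.0

        def convert(nd) -> TreeNode:
            kids = [convert(c) for c in nd.child_nodes()]
            name = nd.taxon.label if nd.taxon is not None else nd.label
            support = None
            if kids and nd.label is not None:
                try:
                    support = float(nd.label)
                    name = None
                except ValueError:
                    pass
            node = TreeNode(name=name, children=kids,
                            height=max_depth - depths[nd], support=support)
            return node

        return cls(convert(dt.seed_node))


def _quote(name) -> str:
    s = str(name)
    if any(ch in s for ch in "(),:; \t"):
        return "'" + s.replace("'", "''") + "'"
    return s


def robinson_foulds(t1: LineageTree, t2: LineageTree) -> int:
    """Symmetric-difference (RF) distance over non-trivial bipartitions."""
    names = set(t1.tip_names())
    if names != set(t2.tip_names()):
        raise ValueError("trees must share the same tip set")
    ref = min(names)

    def canon(tree: LineageTree) -> set[frozenset]:
        out = set()
        all_tips = frozenset(names)
        for _, clade in tree.bipartitions():
            side = clade if ref not in clade else all_tips - clade
            # non-trivial: both sides of the bipartition have >= 2 tips
            if 1 < len(side) < len(all_tips) - 1:
                out.add(side)
        return out

    b1, b2 = canon(t1), canon(t2)
    return len(b1 ^ b2)


# ---------------------------------------------------------------------------
# Tape edit distance
# ---------------------------------------------------------------------------


def tape_edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Steps to transform one tape allele into another.

    Edits beyond the longest common prefix are reverted (one step each) and
    the other allele's non-shared edits are then written (one step each):
    d = (|a| - L) + (|b| - L) with L the common prefix length.  For six-site
    tapes the distance ranges from 0 to 12.
    """
    if len(a) > MAX_TAPE_SITES or len(b) > MAX_TAPE_SITES:
        raise ValueError("tape alleles carry at most six edits")
    L = 0
    for x, y in zip(a, b):
        if x != y:
            break
        L += 1
    return (len(a) - L) + (len(b) - L)


# ---------------------------------------------------------------------------
# Cell x locus matrix filtering and distances
# ---------------------------------------------------------------------------
#
# The matrix is a pandas DataFrame: rows = cells, columns = loci, entries =
# tuples of 3-base insert codes (possibly empty = observed-but-unedited) or
# None/NaN = not observed.  Missing and empty are distinct observations.


def _is_present(v) -> bool:
    return isinstance(v, tuple)


def filter_matrix(
    matrix: pd.DataFrame,
    min_cells_per_locus: int = 10,
    sd_low: float = 1.5,
    sd_high: float = 2.0,
) -> pd.DataFrame:
    """Drop sparse loci, then cells with outlying observed-locus counts.

    Loci observed in fewer than ``min_cells_per_locus`` cells are removed;
    cells whose number of observed loci falls outside
    [mean - sd_low*SD, mean + sd_high*SD] (over the remaining cells) are then
    excluded.
    """
    if matrix.empty:
        raise ValueError("empty cell x locus matrix")
    present = matrix.map(_is_present)
    keep_loci = present.sum(axis=0) >= min_cells_per_locus
    matrix = matrix.loc[:, keep_loci]
    present = present.loc[:, keep_loci]
    if matrix.shape[1] == 0:
        raise ValueError(
            f"no locus observed in >= {min_cells_per_locus} cells"
        )
    counts = present.sum(axis=1).to_numpy(dtype=float)
    mu, sd = counts.mean(), counts.std(ddof=0)
    keep = (counts >= mu - sd_low * sd) & (counts <= mu + sd_high * sd)
    out = matrix.loc[keep]
    if out.shape[0] == 0:
        raise ValueError(
            f"all cells removed by filtering (mean={mu:.2f}, sd={sd:.2f})"
        )
    logger.info(
        "filter_matrix: kept %d/%d loci, %d/%d cells",
        keep_loci.sum(), keep_loci.size, out.shape[0], matrix.shape[0],
    )
    return out


def pairwise_cell_distance(
    matrix: pd.DataFrame, return_report: bool = False
):
    """Mean tape edit distance over loci observed in both cells.

    Pairs sharing no locus get the global maximum observed distance + 1
    (a conservative "very distant" placeholder); their count is reported.
    """
    cells = list(matrix.index)
    n = len(cells)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for locus in matrix.columns:
        col = matrix[locus]
        present_idx = np.flatnonzero(col.map(_is_present).to_numpy())
        if present_idx.size < 2:
            continue
        alleles = [col.iloc[i] for i in present_idx]
        uniq = sorted(set(alleles))
        code = {a: k for k, a in enumerate(uniq)}
        ids = np.array([code[a] for a in alleles])
        m = len(uniq)
        D = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                D[i, j] = D[j, i] = tape_edit_distance(uniq[i], uniq[j])
        sub = D[np.ix_(ids, ids)]
        ix = np.ix_(present_idx, present_idx)
        sums[ix] += sub
        counts[ix] += 1
    with np.errstate(invalid="ignore"):
        dist = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(dist, 0.0)
    no_shared = np.isnan(dist)
    n_no_shared = int(no_shared.sum() // 2)
    if n_no_shared:
        dmax = np.nanmax(dist) if np.isfinite(np.nanmax(dist)) else 0.0
        dist[no_shared] = dmax + 1.0
        logger.warning(
            "pairwise_cell_distance: %d cell pairs share no locus; "
            "set to max observed + 1", n_no_shared,
        )
    out = pd.DataFrame(dist, index=cells, columns=cells)
    if return_report:
        return out, {"n_pairs_no_shared_locus": n_no_shared}
    return out


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def upgma(distances: pd.DataFrame) -> LineageTree:
    """Average-linkage (UPGMA) tree; node height = half the merge distance.

    Ties in the minimum pairwise distance are broken lexicographically on
    the smallest member identifier of each cluster, so the merge sequence is
    deterministic.
    """
    D = np.asarray(distances, dtype=float)
    labels = [str(x) for x in distances.index]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = len(labels)
    if n == 1:
        return LineageTree(TreeNode(name=labels[0], height=0.0))
    D = D.copy()
    np.fill_diagonal(D, np.inf)
    active = list(range(n))
    nodes = {i: TreeNode(name=labels[i], height=0.0) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    minlab = {i: labels[i] for i in range(n)}
    work = np.full((2 * n, 2 * n), np.inf)
    work[:n, :n] = D
    nxt = n
    while len(active) > 1:
        sub = work[np.ix_(active, active)]
        m = sub.min()
        cand = []
        for a, b in zip(*np.where(sub <= m)):
            if a < b:
                i, j = active[a], active[b]
                key = tuple(sorted((minlab[i], minlab[j])))
                cand.append((key, i, j))
        _, i, j = min(cand)
        if minlab[j] < minlab[i]:
            i, j = j, i
        d = work[i, j]
        node = TreeNode(children=[nodes[i], nodes[j]], height=d / 2.0)
        si, sj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nd = (si * work[i, k] + sj * work[j, k]) / (si + sj)
            work[nxt, k] = work[k, nxt] = nd
        nodes[nxt] = node
        sizes[nxt] = si + sj
        minlab[nxt] = min(minlab[i], minlab[j])
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return LineageTree(nodes[active[0]])


def build_tree(matrix: pd.DataFrame, **filter_kwargs) -> LineageTree:
    """Filter a cell x locus matrix, compute distances, and run UPGMA."""
    filtered = filter_matrix(matrix, **filter_kwargs)
    return upgma(pairwise_cell_distance(filtered))


# ---------------------------------------------------------------------------
# Transfer bootstrap expectation
# ---------------------------------------------------------------------------


@dataclass
class BootstrapReport:
    """Per-branch transfer bootstrap support for a UPGMA tree."""

    tree: LineageTree
    n_bootstraps: int
    tbe: dict = field(default_factory=dict)          # node id -> TBE
    raw_delta: dict = field(default_factory=dict)    # node id -> mean transfer dist
    fraction_supported: float = float("nan")         # share of branches TBE > cutoff
    cutoff: float = 0.7


def _bipartition_array(clade: frozenset, order: dict[str, int], n: int) -> np.ndarray:
    v = np.zeros(n, dtype=bool)
    for name in clade:
        v[order[name]] = True
    return v


def transfer_distance(b: np.ndarray, boot_parts: np.ndarray) -> int:
    """Minimal bipartition Hamming distance of b to any branch of a tree.

    ``boot_parts`` is an m x n boolean matrix of the bootstrap tree's clades
    (trivial single-tip clades included, as any tip is a valid transfer
    target).  Each bipartition is compared on both orientations.
    """
    n = b.size
    h = (b[None, :] ^ boot_parts).sum(axis=1)
    return int(min(h.min(), (n - h).min()))


def _all_clades_matrix(tree: LineageTree, order: dict[str, int]) -> np.ndarray:
    n = len(order)
    rows = []
    for _, clade in tree.bipartitions():
        rows.append(_bipartition_array(clade, order, n))
    # trivial bipartitions (single tips) are transfer targets too
    for name in order:
        v = np.zeros(n, dtype=bool)
        v[order[name]] = True
        rows.append(v)
    return np.array(rows, dtype=bool)


def bootstrap_tbe(
    matrix: pd.DataFrame,
    n_bootstraps: int = 100,
    seed: int = 0,
    cutoff: float = 0.7,
    tree: Optional[LineageTree] = None,
    prefiltered: bool = True,
    resample: bool = True,
    **filter_kwargs,
) -> BootstrapReport:
    """Transfer bootstrap expectation over locus-column resamples.

    Loci (columns of the cell x locus matrix) are resampled with replacement
    ``n_bootstraps`` times; each resample yields a new UPGMA tree.  For each
    internal branch of the original tree with lighter-side size p, the
    transfer distance delta to the closest branch of each bootstrap tree is
    computed, and TBE = 1 - mean(delta / (p - 1)), clamped to [0, 1].
    Branches with p = 1 have support 1 by convention and are excluded from
    the summary fraction.  ``resample=False`` keeps the original columns in
    every bootstrap (a self-consistency check: all TBE become 1).
    """
    if not prefiltered:
        matrix = filter_matrix(matrix, **filter_kwargs)
    if matrix.shape[0] < 4:
        raise ValueError("need at least 4 cells for bootstrap support")
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = upgma(pairwise_cell_distance(matrix))
    names = tree.tip_names()
    order = {nm: i for i, nm in enumerate(names)}
    n = len(names)
    branches = tree.bipartitions()
    b_arrays = [_bipartition_array(clade, order, n) for _, clade in branches]
    p_sizes = [min(int(v.sum()), n - int(v.sum())) for v in b_arrays]
    deltas = np.zeros((len(branches), n_bootstraps))
    L = matrix.shape[1]
    for t in range(n_bootstraps):
        cols = rng.integers(0, L, size=L) if resample else np.arange(L)
        boot = matrix.iloc[:, cols]
        boot.columns = [f"b{j}" for j in range(L)]
        bt = upgma(pairwise_cell_distance(boot))
        parts = _all_clades_matrix(bt, order)
        for bi, v in enumerate(b_arrays):
            deltas[bi, t] = transfer_distance(v, parts)
    report = BootstrapReport(tree=tree, n_bootstraps=n_bootstraps, cutoff=cutoff)
    supported = []
    for (node, _), v, p, drow in zip(branches, b_arrays, p_sizes, deltas):
        raw = float(drow.mean())
        if p <= 1:
            tbe = 1.0
        else:
            tbe = float(np.clip(1.0 - np.mean(drow / (p - 1)), 0.0, 1.0))
            supported.append(tbe > cutoff)
        node.support = tbe
        report.tbe[id(node)] = tbe
        report.raw_delta[id(node)] = raw
    report.fraction_supported = (
        float(np.mean(supported)) if supported else float("nan")
    )
    return report
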
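"""Assigning cells to wells, wells to a founder tree, and founders to nodes.

Monoclonal gastruloids grow one per well; bulk debris sequencing of each
well yields a per-well tape profile, and single-cell capture yields per-cell
tape observations.  Cells are assigned to their well of origin by overlap
with well-exclusive alleles (with a margin rule), with a PCA/kNN rescue pass
for cells the overlap rule leaves unassigned.  At the well level, dominant
(TapeBC, site, edit) combinations fingerprint each gastruloid's founder;
Jaccard distances between fingerprints give a founder ("tree of trees")
phylogeny, and a fold-change heuristic maps each well/clade onto a
pseudo-ancestral internal node of the single-cell tree.
"""

from __future__ import annotations

import itertools
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .tape_io import N_SITES, SITE_COLUMNS, pattern_of_row
from .tree import LineageTree, TreeNode, upgma

logger = logging.getLogger(__name__)

# an allele token: (tapebc, full edit-pattern tuple)
Allele = tuple


# ---------------------------------------------------------------------------
# Whitelist and matching
# ---------------------------------------------------------------------------


def build_well_whitelist(
    profiles: pd.DataFrame,
) -> tuple[dict[str, set], dict[Allele, str], list[str]]:
    """Well-exclusive alleles from Debris-seq profiles.

    ``profiles`` rows: well_id, tapebc, insertbc1, site1..site6, reads (one
    retained pattern per (well, TapeBC, InsertBC(1))).  Alleles appearing in
    exactly one well are retained.  Returns (well -> allele set,
    allele -> well, wells dropped for lacking exclusive alleles).
    """
    if profiles.empty:
        logger.warning("build_well_whitelist: empty profile set")
        return {}, {}, []
    seen: dict[Allele, set] = {}
    for _, r in profiles.iterrows():
        allele = (r["tapebc"], pattern_of_row(r))
        seen.setdefault(allele, set()).add(r["well_id"])
    allele_well = {a: next(iter(ws)) for a, ws in seen.items() if len(ws) == 1}
    whitelist: dict[str, set] = {}
    for a, w in allele_well.items():
        whitelist.setdefault(w, set()).add(a)
    dropped = sorted(set(profiles["well_id"]) - set(whitelist))
    if dropped:
        logger.info("wells without exclusive alleles dropped: %s", dropped)
    return whitelist, allele_well, dropped


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _sites_match(cell_pat: tuple, wl_pat: tuple) -> bool:
    """Site-1 exact; sites 2-4 equal or unedited on the cell side."""
    c1 = cell_pat[0] if cell_pat else ""
    w1 = wl_pat[0] if wl_pat else ""
    if c1 != w1:
        return False
    for s in (1, 2, 3):  # sites 2-4
        c = cell_pat[s] if len(cell_pat) > s else None
        w = wl_pat[s] if len(wl_pat) > s else None
        if c is not None and c != w:
            return False
    return True


def match_cell_alleles(
    cell_obs: pd.DataFrame,
    whitelist: dict[str, set],
    min_loci: int = 3,
) -> tuple[dict[str, set], pd.DataFrame]:
    """Match each cell's tape alleles against the well whitelist.

    A cell allele matches a whitelist allele iff the TapeBCs are within
    Hamming distance 1, site-1 edits are equal, and sites 2-4 are equal or
    unedited on the cell side (earlier capture sees fewer edits).  Cells
    matching fewer than ``min_loci`` distinct whitelist alleles are excluded.
    Returns (cell -> matched allele set, cells x alleles read-count matrix).
    """
    wl_alleles = sorted(a for s in whitelist.values() for a in s)
    by_bc: dict[str, list[Allele]] = {}
    for a in wl_alleles:
        by_bc.setdefault(a[0], []).append(a)
    wl_bcs = sorted(by_bc)

    bc_cache: dict[str, list[str]] = {}

    def near_bcs(bc: str) -> list[str]:
        if bc not in bc_cache:
            bc_cache[bc] = [k for k in wl_bcs if _hamming(bc, k) <= 1]
        return bc_cache[bc]

    matches: dict[str, set] = {}
    counts: dict[tuple[str, Allele], int] = {}
    for _, r in cell_obs.iterrows():
        pat = pattern_of_row(r)
        for k in near_bcs(r["tapebc"]):
            for a in by_bc[k]:
                if _sites_match(pat, a[1]):
                    matches.setdefault(r["cell_id"], set()).add(a)
                    key = (r["cell_id"], a)
                    counts[key] = counts.get(key, 0) + int(r.get("reads", r["umi"]))
    matches = {c: s for c, s in matches.items() if len(s) >= min_loci}
    cells = sorted(matches)
    mat = pd.DataFrame(0, index=cells,
                       columns=pd.Index(wl_alleles, tupleize_cols=False))
    for (c, a), n in counts.items():
        if c in matches:
            mat.loc[c, [a]] = n
    return matches, mat


# ---------------------------------------------------------------------------
# Overlap and neighbor assignment
# ---------------------------------------------------------------------------


def _margin_assign(tallies: dict[str, float], margin: float):
    """Return (well, margin_value) under the 'at least 50% more' rule."""
    if not tallies:
        return None, np.nan
    ranked = sorted(tallies.items(), key=lambda kv: (-kv[1], kv[0]))
    best_w, best = ranked[0]
    second = ranked[1][1] if len(ranked) > 1 else 0.0
    if second == 0 or best >= margin * second:
        return best_w, (best / second if second else np.inf)
    return None, best / second


def assign_by_overlap(
    matches: dict[str, set],
    allele_well: dict[Allele, str],
    margin: float = 1.5,
) -> pd.DataFrame:
    """Assign each cell to the well with dominant exclusive-allele overlap.

    overlap(well) = number of matched alleles exclusive to that well; the
    cell is assigned to the argmax well iff best >= margin x second-best
    (boundary inclusive; a zero second-best always assigns).
    """
    rows = []
    for cell in sorted(matches):
        tallies: dict[str, float] = {}
        for a in matches[cell]:
            w = allele_well.get(a)
            if w is not None:
                tallies[w] = tallies.get(w, 0) + 1
        well, m = _margin_assign(tallies, margin)
        rows.append({"cell_id": cell, "well_id": well,
                     "stage": "overlap" if well else "unassigned",
                     "margin": m})
    return pd.DataFrame(rows, columns=["cell_id", "well_id", "stage", "margin"])


def assign_by_neighbors(
    assignments: pd.DataFrame,
    counts: pd.DataFrame,
    n_components: int = 100,
    k: int = 10,
    margin: float = 1.5,
    min_reads_per_allele: int = 10,
) -> pd.DataFrame:
    """Rescue unassigned cells by their neighbors in tape-space PCA.

    The allele read-count matrix is filtered (alleles with fewer than
    ``min_reads_per_allele`` total reads dropped), per-cell normalized,
    log-transformed, scaled per allele, and projected onto the top
    ``n_components`` principal axes.  Each unassigned cell tallies the wells
    of its ``k`` nearest already-assigned neighbors and is assigned under the
    same margin rule.  Returns the full assignment table with rescued cells
    marked stage="neighbor".
    """
    out = assignments.set_index("cell_id").copy()
    assigned = out[out["well_id"].notna()]
    unassigned = out[out["well_id"].isna()]
    if assigned.empty or unassigned.empty:
        return out.reset_index()
    X = counts.loc[out.index]
    keep = X.sum(axis=0) >= min_reads_per_allele
    X = X.loc[:, keep].to_numpy(dtype=float)
    rowsum = X.sum(axis=1, keepdims=True)
    X = np.divide(X, rowsum, out=np.zeros_like(X), where=rowsum > 0) * 1e4
    X = np.log1p(X)
    X = StandardScaler().fit_transform(X)
    ncomp = int(min(n_components, X.shape[1], X.shape[0] - 1))
    Z = PCA(n_components=ncomp, random_state=0).fit_transform(X)
    is_assigned = out["well_id"].notna().to_numpy()
    idx_assigned = np.flatnonzero(is_assigned)
    k_eff = min(k, idx_assigned.size)
    if k_eff < k:
        logger.warning("assign_by_neighbors: only %d assigned neighbors "
                       "available (k=%d)", k_eff, k)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(Z[idx_assigned])
    _, nbr = nn.kneighbors(Z[~is_assigned])
    wells_assigned = out["well_id"].to_numpy()[idx_assigned]
    for row, cell in zip(nbr, out.index[~is_assigned]):
        tallies: dict[str, float] = {}
        for j in row:
            w = wells_assigned[j]
            tallies[w] = tallies.get(w, 0) + 1
        well, m = _margin_assign(tallies, margin)
        if well is not None:
            out.loc[cell, ["well_id", "stage", "margin"]] = [well, "neighbor", m]
    return out.reset_index()


def finalize_assignments(
    assignments: pd.DataFrame,
    matches: dict[str, set],
    well_alleles: dict[str, set],
    min_cells_per_well: int = 100,
    qc_cell_frac: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Drop small wells and compute the Jaccard QC matrix.

    QC entry (group g, well w) is the Jaccard similarity between the alleles
    seen in at least ``qc_cell_frac`` of g's cells and w's debris alleles
    (``well_alleles``: well -> allele set, not restricted to exclusives).
    Returns (final assignments, QC matrix, diagonal dominance rate).
    """
    final = assignments[assignments["well_id"].notna()].copy()
    sizes = final.groupby("well_id").size()
    keep_wells = sizes[sizes >= min_cells_per_well].index
    final = final[final["well_id"].isin(keep_wells)]
    groups = sorted(final["well_id"].unique())
    wells = sorted(well_alleles)
    qc = pd.DataFrame(0.0, index=groups, columns=wells)
    for g in groups:
        cells = final.loc[final["well_id"] == g, "cell_id"]
        tally: dict[Allele, int] = {}
        for c in cells:
            for a in matches.get(c, ()):
                tally[a] = tally.get(a, 0) + 1
        floor = qc_cell_frac * len(cells)
        g_alleles = {a for a, n in tally.items() if n >= floor}
        for w in wells:
            u = g_alleles | well_alleles[w]
            qc.loc[g, w] = (
                len(g_alleles & well_alleles[w]) / len(u) if u else 0.0
            )
    diag_ok = [
        qc.loc[g, g] == qc.loc[g].max() and qc.loc[g, g] > 0
        for g in groups if g in qc.columns
    ]
    rate = float(np.mean(diag_ok)) if diag_ok else float("nan")
    return final.reset_index(drop=True), qc, rate


# ---------------------------------------------------------------------------
# Dominant combinations and the well ("tree of trees") tree
# ---------------------------------------------------------------------------


def dominant_combos(
    tabulated: pd.DataFrame, dominance: float = 0.2
) -> dict[str, set]:
    """Per-well dominant (TapeBC, site, edit) combinations.

    ``tabulated``: well_id, tapebc, site1..site6, reads (full-pattern read
    counts).  Within each well and TapeBC, the read fraction of each edit at
    each site is computed over that TapeBC's reads; combinations with
    fraction >= ``dominance`` are dominant.
    """
    out: dict[str, set] = {}
    for (well, tapebc), grp in tabulated.groupby(["well_id", "tapebc"]):
        total = grp["reads"].sum()
        if total == 0:
            continue
        combos = out.setdefault(well, set())
        for s, col in enumerate(SITE_COLUMNS, start=1):
            frac: dict[str, float] = {}
            for _, r in grp.iterrows():
                v = r[col]
                if isinstance(v, str) and v:
                    frac[v] = frac.get(v, 0.0) + r["reads"] / total
            for edit, f in frac.items():
                if f >= dominance:
                    combos.add((tapebc, s, edit))
    return out


def build_well_tree(
    tabulated: pd.DataFrame, dominance: float = 0.2
) -> tuple[LineageTree, dict[str, set]]:
    """UPGMA tree over wells from dominant-combination Jaccard distances."""
    wells = sorted(tabulated["well_id"].unique())
    if len(wells) < 2:
        raise ValueError("need at least two wells for a well tree")
    combos = dominant_combos(tabulated, dominance)
    for w in wells:
        if not combos.get(w):
            logger.warning("well %s has an empty dominant-combo set; "
                           "distance 1 to all", w)
            combos.setdefault(w, set())
    n = len(wells)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = combos[wells[i]], combos[wells[j]]
        u = a | b
        jac = len(a & b) / len(u) if u else 0.0
        D[i, j] = D[j, i] = 1.0 - jac
    tree = upgma(pd.DataFrame(D, index=wells, columns=wells))
    return tree, combos


def major_clades(tree: LineageTree, n: int) -> dict[str, list[str]]:
    """Cut a tree into its ``n`` deepest-rooted subtrees (clade -> tips)."""
    roots = [tree.root]
    while len(roots) < n:
        cand = [r for r in roots if not r.is_tip()]
        if not cand:
            break
        split = max(cand, key=lambda nd: nd.height)
        roots.remove(split)
        roots.extend(split.children)
    tip_sets = tree.tip_sets()
    out = {}
    for i, r in enumerate(sorted(roots, key=lambda nd: min(tip_sets[id(nd)]))):
        out[chr(ord("A") + i)] = sorted(tip_sets[id(r)])
    return out


# ---------------------------------------------------------------------------
# Pseudo-ancestor mapping
# ---------------------------------------------------------------------------


def cell_combo_matrix(cell_obs: pd.DataFrame) -> pd.DataFrame:
    """Binary cells x (TapeBC, site, edit) combination matrix."""
    rows: dict[str, set] = {}
    combos: set = set()
    for _, r in cell_obs.iterrows():
        pat = pattern_of_row(r)
        cell = r["cell_id"]
        s = rows.setdefault(cell, set())
        for site, edit in enumerate(pat, start=1):
            combo = (r["tapebc"], site, edit)
            s.add(combo)
            combos.add(combo)
    combo_list = sorted(combos)
    cix = {c: i for i, c in enumerate(combo_list)}
    cells = sorted(rows)
    M = np.zeros((len(cells), len(combo_list)), dtype=np.int8)
    for i, cell in enumerate(cells):
        for c in rows[cell]:
            M[i, cix[c]] = 1
    return pd.DataFrame(M, index=cells,
                        columns=pd.Index(combo_list, tupleize_cols=False))


def _exclusive_combos(
    groups: dict[str, Sequence[str]], combos: dict[str, set]
) -> dict[str, set]:
    """Combos dominant in one group's wells and in no other group's wells."""
    union: dict[str, set] = {
        g: set().union(*(combos.get(w, set()) for w in ws)) if ws else set()
        for g, ws in groups.items()
    }
    out = {}
    for g in groups:
        others = set().union(*(union[h] for h in groups if h != g)) \
            if len(groups) > 1 else set()
        out[g] = union[g] - others
    return out


def _score_nodes(
    tree: LineageTree,
    norm_matrix: pd.DataFrame,
    exclusive: dict[str, set],
    fc_ratio_min: float,
) -> dict[str, tuple[Optional[TreeNode], int]]:
    """Pick, per group, the eligible pseudo-ancestor with the most cells."""
    groups = sorted(exclusive)
    cols = {c: i for i, c in enumerate(norm_matrix.columns)}
    X = norm_matrix.to_numpy(dtype=float)
    cell_ix = {c: i for i, c in enumerate(norm_matrix.index)}
    group_cols = {
        g: [cols[c] for c in sorted(exclusive[g]) if c in cols]
        for g in groups
    }
    tip_sets = tree.tip_sets()
    chosen: dict[str, tuple[Optional[TreeNode], int]] = {g: (None, 0) for g in groups}
    eps = 1e-12
    for node in tree.preorder():
        if node.is_tip():
            continue
        cells = [cell_ix[t] for t in tip_sets[id(node)] if t in cell_ix]
        if not cells:
            continue
        sub = X[cells]
        L = {}
        for g in groups:
            gc = group_cols[g]
            oc = [c for h in groups if h != g for c in group_cols[h]]
            m_g = sub[:, gc].mean() if gc else 0.0
            m_o = sub[:, oc].mean() if oc else 0.0
            fc = m_g / max(m_o, eps)
            L[g] = np.log2(fc + 1.0)
        for g in groups:
            rest = max((L[h] for h in groups if h != g), default=0.0)
            if L[g] > fc_ratio_min * max(rest, eps):
                if len(cells) > chosen[g][1]:
                    chosen[g] = (node, len(cells))
    return chosen


def assign_pseudo_ancestors(
    cell_tree: LineageTree,
    combo_matrix: pd.DataFrame,
    clades: dict[str, Sequence[str]],
    well_combos: dict[str, set],
    fc_ratio_min: float = 2.0,
) -> pd.DataFrame:
    """Map clades, then individual wells, to internal nodes of the cell tree.

    The binary cell x combination matrix is column-normalized; every internal
    node is scored per clade by the fold change of the node's cells' mean
    value over the clade's exclusive dominant combinations versus the other
    clades' exclusive combinations.  Nodes with
    log2(FC+1) > ``fc_ratio_min`` x the best competing clade are eligible and
    the eligible node with the most cells is the clade's pseudo-ancestor; the
    procedure then recurses within each clade's node over its wells.
    Returns rows: level ('clade'|'well'), name, clade, n_cells, tips
    (node's tip set as a sorted tuple); unmapped entries have n_cells = 0.
    """
    colsum = combo_matrix.sum(axis=0).replace(0, 1)
    norm = combo_matrix / colsum
    clade_exclusive = _exclusive_combos(
        {g: list(ws) for g, ws in clades.items()}, well_combos
    )
    chosen = _score_nodes(cell_tree, norm, clade_exclusive, fc_ratio_min)
    tip_sets = cell_tree.tip_sets()
    rows = []
    for g in sorted(clades):
        node, n_cells = chosen[g]
        tips = tuple(sorted(tip_sets[id(node)])) if node else ()
        rows.append({"level": "clade", "name": g, "clade": g,
                     "n_cells": n_cells, "tips": tips})
        if node is None:
            logger.warning("clade %s: no eligible pseudo-ancestor", g)
            continue
        wells = list(clades[g])
        if len(wells) < 2:
            if wells:
                rows.append({"level": "well", "name": wells[0], "clade": g,
                             "n_cells": n_cells, "tips": tips})
            continue
        subtree = LineageTree(node)
        sub_cells = [c for c in norm.index if c in tip_sets[id(node)]]
        sub_norm = norm.loc[sub_cells]
        well_exclusive = _exclusive_combos(
            {w: [w] for w in wells}, well_combos
        )
        sub_chosen = _score_nodes(subtree, sub_norm, well_exclusive,
                                  fc_ratio_min)
        sub_tip_sets = subtree.tip_sets()
        picked = {}
        for w in sorted(wells):
            wnode, wn = sub_chosen[w]
            wtips = tuple(sorted(sub_tip_sets[id(wnode)])) if wnode else ()
            if wnode is None:
                logger.warning("well %s (clade %s): unmapped", w, g)
            picked[w] = set(wtips)
            rows.append({"level": "well", "name": w, "clade": g,
                         "n_cells": wn, "tips": wtips})
        for w1, w2 in itertools.combinations(sorted(picked), 2):
            if picked[w1] and picked[w2] and (
                    picked[w1] < picked[w2] or picked[w2] < picked[w1]):
                logger.info("nested pseudo-ancestors for wells %s and %s; "
                            "the deeper node identifies the contained well",
                            w1, w2)
    return pd.DataFrame(rows, columns=["level", "name", "clade",
                                       "n_cells", "tips"])
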
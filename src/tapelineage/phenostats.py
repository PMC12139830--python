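"""Lineage-phenotype coupling statistics.

Given a reconstructed lineage tree and per-cell fates (categorical labels
plus a low-dimensional expression embedding), these functions quantify how
strongly fate follows lineage: the trend of transcriptomic distance with
phylogenetic distance, fate composition of nearest terminal neighbors, a
Moran's-I adaptation measuring phylogenetic auto-/cross-correlation of cell
types, Fisher tests of fate bias between daughter clades, permutation tests
of clade-level composition enrichment, and founder-relatedness heritability
metrics (pseudo-bulk PC distances and single-cell kNN mixing against
patristic distance on the founder tree).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .tree import LineageTree

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Lineage-state correlation (distance-bin trend)
# ---------------------------------------------------------------------------


def lineage_state_correlation(
    tree: LineageTree,
    embedding: pd.DataFrame,
    bin_edges: Optional[Sequence[float]] = None,
) -> tuple[pd.DataFrame, float]:
    """Mean embedding distance between cell pairs, binned by tree distance.

    Pairwise patristic distances are binned (default integer bins from 2 to
    10 with an open 10+ bin; closer pairs fall in the first bin); per bin the
    mean Euclidean distance between the pair's embedding coordinates is
    reported, along with the Spearman trend of bin means across bins.
    """
    tips = [t for t in tree.tip_names() if t in embedding.index]
    if len(tips) < len(tree.tip_names()):
        missing = len(tree.tip_names()) - len(tips)
        raise ValueError(f"{missing} tree tips missing from the embedding")
    D = tree.cophenetic_matrix(order=tips).to_numpy()
    X = embedding.loc[tips].to_numpy(dtype=float)
    iu = np.triu_indices(len(tips), k=1)
    d_phylo = D[iu]
    diffs = X[iu[0]] - X[iu[1]]
    d_embed = np.sqrt((diffs ** 2).sum(axis=1))
    if bin_edges is None:
        bin_edges = list(range(2, 11))
    edges = np.asarray(list(bin_edges), dtype=float)
    idx = np.clip(np.searchsorted(edges, d_phylo, side="right") - 1, 0, None)
    rows = []
    for b in range(len(edges)):
        mask = idx == b
        if not mask.any():
            logger.info("lineage_state_correlation: empty bin %g", edges[b])
            continue
        label = f"{edges[b]:g}+" if b == len(edges) - 1 else f"{edges[b]:g}"
        rows.append({"bin": label, "bin_low": edges[b],
                     "n_pairs": int(mask.sum()),
                     "mean_state_distance": float(d_embed[mask].mean())})
    table = pd.DataFrame(rows)
    if len(table) >= 2 and table["mean_state_distance"].nunique() > 1:
        rho = float(stats.spearmanr(
            table["bin_low"], table["mean_state_distance"]).statistic)
    else:
        rho = float("nan")
    return table, rho


# ---------------------------------------------------------------------------
# Nearest terminal neighbor fate pairs
# ---------------------------------------------------------------------------


def _pair_counts(pairs, labels: pd.Series, types: list[str]) -> np.ndarray:
    tix = {t: i for i, t in enumerate(types)}
    M = np.zeros((len(types), len(types)))
    for a, b in pairs:
        i, j = tix[labels[a]], tix[labels[b]]
        M[i, j] += 0.5
        M[j, i] += 0.5
    return M


def neighbor_pair_frequency(
    tree: LineageTree,
    labels: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Log ratio of observed to permutation-expected neighbor-pair counts.

    Tip pairs at minimal patristic distance (for at least one member; ties
    and redundant ordered pairs retained) are tallied by the cell-type pair
    they form; scores are log((observed + 0.5) / (mean permuted + 0.5)),
    a symmetric matrix centered on 0 under random labeling.
    """
    if tree.n_tips() < 2:
        raise ValueError("need at least two tips")
    pairs = tree.nearest_neighbor_pairs()
    tips = tree.tip_names()
    lab = labels.loc[tips]
    types = sorted(labels.unique())
    present = set(lab.unique())
    obs = _pair_counts(pairs, lab, types)
    rng = np.random.default_rng(seed)
    perm_sum = np.zeros_like(obs)
    vals = lab.to_numpy()
    for _ in range(n_perm):
        shuffled = pd.Series(rng.permutation(vals), index=tips)
        perm_sum += _pair_counts(pairs, shuffled, types)
    expected = perm_sum / n_perm
    score = np.log((obs + 0.5) / (expected + 0.5))
    out = pd.DataFrame(score, index=types, columns=types)
    absent = [t for t in types if t not in present]
    for t in absent:
        out.loc[t, :] = np.nan
        out.loc[:, t] = np.nan
        logger.warning("neighbor_pair_frequency: type %s absent from tips", t)
    return out


# ---------------------------------------------------------------------------
# Moran's-I phylogenetic auto-/cross-correlation
# ---------------------------------------------------------------------------


def phylo_weights(
    tree: LineageTree, tau: Optional[float] = None, scheme: str = "exp"
) -> pd.DataFrame:
    """Tip-pair weight matrix from patristic distances.

    ``exp``: W_ij = exp(-d_ij / tau) with tau defaulting to the mean tip-pair
    distance; ``inverse``: W_ij = 1/d_ij.  Zero diagonal, rows normalized to
    sum 1.
    """
    D = tree.cophenetic_matrix()
    A = D.to_numpy(dtype=float)
    iu = np.triu_indices(A.shape[0], k=1)
    if scheme == "exp":
        t = tau if tau is not None else float(A[iu].mean())
        W = np.exp(-A / max(t, 1e-300))
    elif scheme == "inverse":
        W = 1.0 / np.maximum(A, 1e-300)
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    np.fill_diagonal(W, 0.0)
    W /= W.sum(axis=1, keepdims=True)
    return pd.DataFrame(W, index=D.index, columns=D.columns)


def _zscore_indicator(labels: pd.Series, t: str) -> Optional[np.ndarray]:
    x = (labels == t).to_numpy(dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        return None
    return (x - x.mean()) / sd


def _moran_analytic_z(z: np.ndarray, W: np.ndarray, I: float) -> float:
    """Cliff-Ord z-score of Moran's I under the randomization assumption."""
    n = z.size
    S0 = W.sum()
    S1 = 0.5 * ((W + W.T) ** 2).sum()
    S2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    b2 = n * (z ** 4).sum() / (z ** 2).sum() ** 2
    EI = -1.0 / (n - 1)
    num = (n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * S0 * S0)
           - b2 * ((n * n - n) * S1 - 2 * n * S2 + 6 * S0 * S0))
    den = (n - 1) * (n - 2) * (n - 3) * S0 * S0
    if den == 0:   # n <= 3: randomization variance undefined
        return float("nan")
    var = num / den - EI * EI
    return (I - EI) / np.sqrt(var) if var > 0 else float("nan")


def phylo_correlation(
    tree: LineageTree,
    labels: pd.Series,
    mode: str = "auto",
    tau: Optional[float] = None,
    scheme: str = "exp",
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Moran's-I statistic of cell-type indicators over the phylogeny.

    Each type's indicator vector is z-scored; I(x, y) = x'Wy / n with W the
    row-normalized tip weight matrix.  ``auto`` gives per-type
    autocorrelation with an analytic (Cliff-Ord randomization) z-score;
    ``cross`` gives type-pair cross-correlation with a Monte Carlo
    permutation z-score.  Constant indicators are reported as undefined.
    """
    tips = tree.tip_names()
    lab = labels.loc[tips]
    Wdf = phylo_weights(tree, tau=tau, scheme=scheme)
    W = Wdf.loc[tips, tips].to_numpy()
    n = len(tips)
    types = sorted(lab.unique())
    zs = {t: _zscore_indicator(lab, t) for t in types}
    rows = []
    if mode == "auto":
        for t in types:
            z = zs[t]
            if z is None:
                rows.append({"type": t, "I": np.nan, "z": np.nan,
                             "p": np.nan, "note": "constant indicator"})
                continue
            I = float(z @ W @ z / n)
            zscore = _moran_analytic_z(z, W, I)
            p = 2 * stats.norm.sf(abs(zscore))
            rows.append({"type": t, "I": I, "z": zscore, "p": p, "note": ""})
        return pd.DataFrame(rows)
    if mode != "cross":
        raise ValueError("mode must be 'auto' or 'cross'")
    rng = np.random.default_rng(seed)
    for t, u in itertools.combinations(types, 2):
        x, y = zs[t], zs[u]
        if x is None or y is None:
            rows.append({"type_x": t, "type_y": u, "I": np.nan, "z": np.nan,
                         "p": np.nan, "note": "constant indicator"})
            continue
        I = float(x @ W @ y / n)
        null = np.empty(n_perm)
        for k in range(n_perm):
            null[k] = x @ W @ y[rng.permutation(n)] / n
        mu, sd = null.mean(), null.std(ddof=1)
        zscore = (I - mu) / sd if sd > 0 else float("nan")
        p = (1 + np.sum(np.abs(null - mu) >= abs(I - mu))) / (n_perm + 1)
        rows.append({"type_x": t, "type_y": u, "I": I, "z": zscore,
                     "p": p, "note": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Daughter-clade fate-bias tests
# ---------------------------------------------------------------------------


def daughter_fate_test(
    tree: LineageTree,
    labels: pd.Series,
    group1: set,
    min_clade: int = 10,
) -> pd.DataFrame:
    """Fisher tests of a binary fate split between daughter clades.

    For every internal node whose two daughter clades each hold at least
    ``min_clade`` tips, the 2x2 table (daughter x in/out of ``group1``) is
    tested with a two-sided Fisher exact test; p-values are BH-adjusted
    across all tested nodes of the tree.  Zero-margin tables (a category
    absent from both daughters) are skipped and counted.
    """
    tip_sets = tree.tip_sets()
    node_ids = {id(n): i for i, n in enumerate(tree.preorder())}
    rows, skipped = [], 0
    for node in tree.preorder():
        if node.is_tip() or len(node.children) != 2:
            continue
        c1, c2 = node.children
        t1, t2 = tip_sets[id(c1)], tip_sets[id(c2)]
        if len(t1) < min_clade or len(t2) < min_clade:
            continue
        a1 = sum(labels[t] in group1 for t in t1)
        a2 = sum(labels[t] in group1 for t in t2)
        table = np.array([[a1, len(t1) - a1], [a2, len(t2) - a2]])
        if (table.sum(axis=0) == 0).any():
            skipped += 1
            continue
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({
            "node_id": node_ids[id(node)],
            "n1": len(t1), "n2": len(t2),
            "a1": int(a1), "a2": int(a2),
            "odds_ratio": odds, "p": p,
            "tbe": node.support,
            "tbe_children": (c1.support, c2.support),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("q").reset_index(drop=True)
    if skipped:
        logger.info("daughter_fate_test: %d zero-margin tables skipped",
                    skipped)
    out.attrs["skipped_zero_margin"] = skipped
    return out


# fate-category presets used for the daughter-clade tests
CATEGORY_SPLITS = {
    "extraembryonic-vs-other": {"extraembryonic endoderm"},
    "undiff-vs-diff": {"PSC-like", "transitional"},
    "meso-vs-neuro": {"somites", "mesodermal progenitors"},
}


# ---------------------------------------------------------------------------
# Clade-composition enrichment
# ---------------------------------------------------------------------------


def clade_composition_enrichment(
    proportions: pd.DataFrame,
    clade_of: pd.Series,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation rank-sum enrichment of cell-type proportions per clade.

    For each (clade, type), the rank sum of member gastruloids' proportions
    is compared with its distribution under ``n_perm`` permutations of the
    clade labels; the one-sided empirical p is the fraction of permutations
    with a rank sum at least as large (enrichment for high proportions).
    Size-1 clades are skipped.
    """
    wells = list(proportions.index)
    clades = clade_of.loc[wells]
    rng = np.random.default_rng(seed)
    n = len(wells)
    clade_names = sorted(clades.unique())
    sizes = {c: int((clades == c).sum()) for c in clade_names}
    testable = [c for c in clade_names if sizes[c] >= 2]
    for c in clade_names:
        if sizes[c] < 2:
            logger.warning("clade %s has %d member(s); skipped", c, sizes[c])
    if len(testable) < 2 and len(clade_names) < 2:
        raise ValueError("need at least two clades")
    ranks = {
        t: stats.rankdata(proportions[t].to_numpy())
        for t in proportions.columns
    }
    members = {c: np.flatnonzero((clades == c).to_numpy()) for c in testable}
    # one shared label permutation per iteration keeps clades comparable
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    rows = []
    for t, r in ranks.items():
        perm_r = r[perm_idx]  # n_perm x n
        csum = np.cumsum(perm_r, axis=1)
        for c in testable:
            obs = float(r[members[c]].sum())
            k = sizes[c]
            # rank sum of a size-k random subset == first k of a permutation
            null = csum[:, k - 1]
            p = (1 + np.sum(null >= obs)) / (n_perm + 1)
            rows.append({"clade": c, "type": t, "rank_sum": obs,
                         "n_members": k, "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pseudo-bulk PCA
# ---------------------------------------------------------------------------


def pseudobulk_pcs(
    counts: pd.DataFrame,
    well_of: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    min_cells: int = 50,
    n_pcs: int = 10,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Per-gastruloid pseudo-bulk PCA with covariate correlations.

    Cells are summed per well; wells with fewer than ``min_cells`` cells are
    excluded.  Profiles are library-normalized (counts per 1e4),
    log-transformed, and decomposed by PCA.  Returns (well x PC scores,
    per-PC variance fractions, Pearson correlations of each PC with each
    covariate column).
    """
    groups = well_of.loc[counts.index]
    sizes = groups.value_counts()
    keep = sizes[sizes >= min_cells].index
    if len(keep) < 3:
        raise ValueError("need at least three gastruloids after filtering")
    bulk = counts.groupby(groups).sum().loc[sorted(keep)]
    X = bulk.to_numpy(dtype=float)
    X = np.log1p(X / X.sum(axis=1, keepdims=True) * 1e4)
    ncomp = int(min(n_pcs, X.shape[0] - 1, X.shape[1]))
    pca = PCA(n_components=ncomp, random_state=0)
    Z = pca.fit_transform(X - X.mean(axis=0))
    pcs = pd.DataFrame(Z, index=bulk.index,
                       columns=[f"PC{i+1}" for i in range(ncomp)])
    var_frac = pca.explained_variance_ratio_
    corr_rows = []
    if covariates is not None:
        cov = covariates.loc[pcs.index]
        for pc in pcs.columns:
            for name in cov.columns:
                y = cov[name].to_numpy(dtype=float)
                if np.std(y) == 0 or np.std(pcs[pc]) == 0:
                    r, p = np.nan, np.nan
                else:
                    r, p = stats.pearsonr(pcs[pc], y)
                corr_rows.append({"pc": pc, "covariate": name,
                                  "r": r, "p": p})
    return pcs, var_frac, pd.DataFrame(corr_rows)


# ---------------------------------------------------------------------------
# Founder heritability
# ---------------------------------------------------------------------------


def knn_mixing_matrix(
    embedding: pd.DataFrame, well_of: pd.Series, k: int = 15
) -> pd.DataFrame:
    """Average cross-gastruloid nearest-neighbor fractions.

    For gastruloids g, h: the mean over g's cells of the fraction of their
    ``k`` nearest neighbors (over all cells, excluding self) that belong to
    h, symmetrized by averaging both directions.
    """
    wells = sorted(well_of.unique())
    wix = {w: i for i, w in enumerate(wells)}
    X = embedding.to_numpy(dtype=float)
    owner = well_of.loc[embedding.index].map(wix).to_numpy()
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(X))).fit(X)
    _, idx = nn.kneighbors(X)
    idx = idx[:, 1:]  # drop self
    F = np.zeros((len(wells), len(wells)))
    counts = np.zeros(len(wells))
    for i in range(len(X)):
        g = owner[i]
        counts[g] += 1
        nb_wells = owner[idx[i]]
        for h in range(len(wells)):
            F[g, h] += np.mean(nb_wells == h)
    F /= np.maximum(counts[:, None], 1)
    M = (F + F.T) / 2.0
    return pd.DataFrame(M, index=wells, columns=wells)


def _mantel_spearman(
    A: pd.DataFrame, B: pd.DataFrame, n_perm: int, rng,
    exclude: Optional[set] = None,
) -> tuple[float, float, int]:
    """Spearman rho between two aligned distance-like matrices + Mantel p.

    ``exclude``: set of frozenset well pairs removed from the comparison.
    Two-sided permutation p over relabelings of B's wells.
    """
    wells = list(A.index)
    n = len(wells)
    iu = np.triu_indices(n, k=1)
    mask = np.ones(iu[0].size, dtype=bool)
    if exclude:
        for t, (i, j) in enumerate(zip(*iu)):
            if frozenset((wells[i], wells[j])) in exclude:
                mask[t] = False
    a = A.to_numpy()[iu][mask]
    Bm = B.loc[wells, wells].to_numpy()
    b = Bm[iu][mask]
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan"), int(a.size)
    rho = stats.spearmanr(a, b).statistic
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(n)
        bp = Bm[np.ix_(perm, perm)][iu][mask]
        null[t] = stats.spearmanr(a, bp).statistic
    p = (1 + np.sum(np.abs(null) >= abs(rho))) / (n_perm + 1)
    return float(rho), float(p), int(a.size)


@dataclass
class HeritabilityReport:
    """Founder-relatedness vs gastruloid-phenotype association summary."""

    nn_pairs: list = field(default_factory=list)
    nn_pearson: pd.DataFrame = None
    spearman_pseudobulk: tuple = (np.nan, np.nan)     # (rho, p)
    spearman_mixing: tuple = (np.nan, np.nan)
    spearman_pseudobulk_nonn: tuple = (np.nan, np.nan)
    spearman_mixing_nonn: tuple = (np.nan, np.nan)
    n_pairs: int = 0
    n_redundant_nn: int = 0


def founder_heritability(
    well_tree: LineageTree,
    pcs: pd.DataFrame,
    sc_embedding: Optional[pd.DataFrame] = None,
    well_of: Optional[pd.Series] = None,
    k: int = 15,
    n_perm: int = 999,
    seed: int = 0,
) -> HeritabilityReport:
    """Founder-tree relatedness versus gastruloid phenotype.

    (i) Pearson correlation of each pseudo-bulk PC between nearest-neighbor
    gastruloid pairs on the founder tree (co-minimal ties and redundant
    ordered pairs retained); (ii) Spearman correlation, across all well
    pairs, of patristic distance with pseudo-bulk PC-space Euclidean
    distance, and with the k-nearest-neighbor cross-gastruloid mixing
    fraction in single-cell embedding space; (iii) both repeated excluding
    nearest-neighbor pairs.  Permutation (Mantel-style) p-values throughout.
    """
    rng = np.random.default_rng(seed)
    wells = [w for w in well_tree.tip_names() if w in pcs.index]
    if set(well_tree.tip_names()) - set(wells):
        raise ValueError("well tree tips missing from the PC table")
    report = HeritabilityReport()
    pairs = well_tree.nearest_neighbor_pairs()
    report.nn_pairs = pairs
    report.n_redundant_nn = sum(
        1 for a, b in pairs if (b, a) in set(pairs)) // 2
    # (i) nearest-neighbor Pearson per PC
    rows = []
    if len(pairs) >= 3:
        for pc in pcs.columns:
            x = np.array([pcs.loc[a, pc] for a, _ in pairs])
            y = np.array([pcs.loc[b, pc] for _, b in pairs])
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"pc": pc, "r": np.nan, "p": np.nan})
                continue
            r = stats.pearsonr(x, y).statistic
            vals = pcs[pc]
            null = np.empty(n_perm)
            for t in range(n_perm):
                shuf = pd.Series(rng.permutation(vals.to_numpy()),
                                 index=vals.index)
                xs = np.array([shuf[a] for a, _ in pairs])
                ys = np.array([shuf[b] for _, b in pairs])
                null[t] = stats.pearsonr(xs, ys).statistic
            p = (1 + np.sum(np.abs(null) >= abs(r))) / (n_perm + 1)
            rows.append({"pc": pc, "r": float(r), "p": float(p)})
    else:
        logger.warning("founder_heritability: fewer than 3 NN pairs; "
                       "Pearson correlations undefined")
        rows = [{"pc": pc, "r": np.nan, "p": np.nan} for pc in pcs.columns]
    report.nn_pearson = pd.DataFrame(rows)
    # (ii) all-pair Spearman analyses
    D = well_tree.cophenetic_matrix(order=wells)
    Z = pcs.loc[wells].to_numpy()
    diff = Z[:, None, :] - Z[None, :, :]
    E = pd.DataFrame(np.sqrt((diff ** 2).sum(axis=2)),
                     index=wells, columns=wells)
    report.spearman_pseudobulk = _mantel_spearman(D, E, n_perm, rng)[:2]
    nn_set = {frozenset(p) for p in pairs}
    report.spearman_pseudobulk_nonn = _mantel_spearman(
        D, E, n_perm, rng, exclude=nn_set)[:2]
    n = len(wells)
    report.n_pairs = n * (n - 1) // 2
    if sc_embedding is not None and well_of is not None:
        M = knn_mixing_matrix(sc_embedding, well_of, k=k)
        M = M.loc[wells, wells]
        report.spearman_mixing = _mantel_spearman(D, M, n_perm, rng)[:2]
        report.spearman_mixing_nonn = _mantel_spearman(
            D, M, n_perm, rng, exclude=nn_set)[:2]
    return report
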
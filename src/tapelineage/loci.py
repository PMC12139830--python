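"""Resolving duplicated tape barcodes into genomic integration loci.

TapeBCs do not uniquely identify integration sites: transposon re-integration
duplicates them, so one TapeBC may report several independent tapes.  The
key observation is that a single cell carries exactly one edit pattern per
genomic locus, so two patterns of the same TapeBC that are co-expressed in a
cell must come from different loci, while patterns that are never
co-expressed may be alternative outcomes of the same locus.

Pipeline per TapeBC: pool identical full edit sequences into consensus
clusters (>100 UMIs), binarize the cell x pattern UMI matrix at the valley
between its modes, group cells by their binary pattern profiles (DBSCAN with
a KNN rescue for dropout cells), build a mutual-exclusivity graph of
patterns (intersected across cell clusters), and cover it with the fewest
cliques by greedy coloring of the complement graph; each clique is one
inferred locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .tape_io import SITE_COLUMNS, pattern_of_row

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Consensus patterns
# ---------------------------------------------------------------------------


def call_consensus_patterns(
    observations: pd.DataFrame, min_cluster_umis: int = 100
) -> tuple[pd.DataFrame, dict]:
    """Pool identical full edit sequences of one TapeBC into clusters.

    Pools whose total UMI count strictly exceeds ``min_cluster_umis`` become
    clusters; the rest are discarded as likely noise and counted.  Unedited
    (zero-edit) sequences are excluded: they carry no lineage information and
    cannot be attributed to a particular locus of a duplicated TapeBC.
    ``observations`` rows: cell_id, site1..site6, umi.
    """
    if observations.empty:
        logger.warning("call_consensus_patterns: no observations")
        return (
            pd.DataFrame(columns=["pattern", "total_umis", "n_cells"]),
            {"discarded_umis": 0, "unedited_umis": 0},
        )
    pats = [pattern_of_row(r) for _, r in observations.iterrows()]
    df = observations.assign(_pattern=pats)
    unedited = int(df.loc[[p == () for p in pats], "umi"].sum())
    df = df[[p != () for p in pats]]
    pooled = (
        df.groupby("_pattern")
        .agg(total_umis=("umi", "sum"), n_cells=("cell_id", "nunique"))
        .reset_index()
        .rename(columns={"_pattern": "pattern"})
    )
    kept = pooled[pooled["total_umis"] > min_cluster_umis].copy()
    discarded = int(pooled.loc[pooled["total_umis"] <= min_cluster_umis,
                               "total_umis"].sum())
    if kept.empty:
        logger.warning("call_consensus_patterns: no cluster above %d UMIs",
                       min_cluster_umis)
    kept = kept.sort_values("pattern").reset_index(drop=True)
    return kept, {"discarded_umis": discarded, "unedited_umis": unedited}


def pattern_umi_matrix(
    observations: pd.DataFrame, patterns: list[tuple]
) -> pd.DataFrame:
    """Cells x patterns UMI-count matrix for one TapeBC."""
    pats = [pattern_of_row(r) for _, r in observations.iterrows()]
    df = observations.assign(_pattern=pats)
    df = df[df["_pattern"].isin(set(patterns))]
    mat = df.pivot_table(
        index="cell_id", columns="_pattern", values="umi",
        aggfunc="sum", fill_value=0,
    )
    return mat.reindex(columns=patterns, fill_value=0)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------


def binarize_pattern_matrix(
    umi_matrix: pd.DataFrame, pseudocount_scale: float = 1e4
) -> tuple[pd.DataFrame, pd.DataFrame, float, bool]:
    """Row-normalize, log-transform, and threshold at the inter-mode valley.

    Returns (binary matrix, log-normalized matrix, threshold, fallback_flag).
    If the pooled nonzero value distribution is effectively unimodal, the
    threshold falls back to the 1st percentile of nonzero values (flagged).
    """
    X = umi_matrix.to_numpy(dtype=float)
    if X.size == 0 or not (X > 0).any():
        raise ValueError("binarize_pattern_matrix requires a nonzero row")
    rowsum = X.sum(axis=1, keepdims=True)
    norm = np.divide(X, rowsum, out=np.zeros_like(X), where=rowsum > 0)
    lognorm = np.log1p(norm * pseudocount_scale)
    vals = lognorm[X > 0]
    threshold, fallback = _valley_threshold(vals)
    binary = (lognorm > threshold) & (X > 0)
    return (
        pd.DataFrame(binary.astype(np.int8), index=umi_matrix.index,
                     columns=umi_matrix.columns),
        pd.DataFrame(lognorm, index=umi_matrix.index,
                     columns=umi_matrix.columns),
        float(threshold),
        fallback,
    )


def _valley_threshold(vals: np.ndarray) -> tuple[float, bool]:
    """Lowest density point between the two largest modes of ``vals``."""
    lo, hi = vals.min(), vals.max()
    fallback_t = float(np.percentile(vals, 1.0)) - 1e-9
    if hi - lo < 1e-12 or vals.size < 10:
        return fallback_t, True
    try:
        kde = gaussian_kde(vals)
    except np.linalg.LinAlgError:
        return fallback_t, True
    grid = np.linspace(lo, hi, 256)
    dens = kde(grid)
    peaks = [
        i for i in range(1, 255)
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
    ]
    if dens[0] > dens[1]:
        peaks.insert(0, 0)
    if dens[-1] >= dens[-2]:
        peaks.append(255)
    # guard against numerically flat ripples in the KDE tails
    peaks = [i for i in peaks if dens[i] >= 1e-4 * dens.max()]
    if len(peaks) < 2:
        return fallback_t, True
    # lowest density point between the outermost modes: the deepest valley
    # separating the noise mode from the signal modes
    a, b = peaks[0], peaks[-1]
    valley = a + int(np.argmin(dens[a:b + 1]))
    return float(grid[valley]), False


# ---------------------------------------------------------------------------
# Cell clustering with dropout rescue
# ---------------------------------------------------------------------------


def cluster_cells_by_patterns(
    binary: pd.DataFrame,
    lognorm: pd.DataFrame,
    hamming_radius: int = 0,
    min_samples: int = 5,
    k_rescue: int = 10,
) -> pd.Series:
    """Group cells by their binary pattern profiles; rescue unassigned cells.

    DBSCAN on binary rows under the Hamming metric (``hamming_radius`` = 0
    means exact profile match); cells left unclustered (typically dropout)
    are labeled by majority vote of their ``k_rescue`` nearest assigned
    neighbors in log-normalized UMI space.  Every cell ends labeled.
    """
    if not binary.index.equals(lognorm.index):
        raise ValueError("binary and lognorm matrices must be row-aligned")
    X = binary.to_numpy(dtype=float)
    n_cells, n_pat = X.shape
    eps = (hamming_radius + 0.5) / max(n_pat, 1)
    db = DBSCAN(eps=eps, min_samples=min_samples, metric="hamming").fit(X)
    labels = db.labels_.copy()
    unassigned = np.flatnonzero(labels == -1)
    assigned = np.flatnonzero(labels != -1)
    if assigned.size == 0:
        logger.warning("cluster_cells_by_patterns: no core cluster; "
                       "single-cluster fallback")
        return pd.Series(0, index=binary.index, name="cluster")
    if unassigned.size:
        L = lognorm.to_numpy(dtype=float)
        k = min(k_rescue, assigned.size)
        nn = NearestNeighbors(n_neighbors=k).fit(L[assigned])
        _, idx = nn.kneighbors(L[unassigned])
        for row, cell in zip(idx, unassigned):
            votes = pd.Series(labels[assigned[row]]).value_counts()
            best = votes.max()
            labels[cell] = min(votes[votes == best].index)
    return pd.Series(labels, index=binary.index, name="cluster")


# ---------------------------------------------------------------------------
# Mutual exclusivity graph and clique cover
# ---------------------------------------------------------------------------


def _lcp(a: tuple, b: tuple) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def build_exclusivity_graph(
    clusters: pd.Series,
    binary: pd.DataFrame,
    tolerance: float = 0.0,
) -> nx.Graph:
    """Graph over patterns; edges join mutually exclusive pattern pairs.

    Within each cell cluster, two patterns are exclusive iff the cosine
    similarity of their binary presence vectors over that cluster's cells is
    <= ``tolerance`` (0 = never co-expressed).  The final edge set is the
    intersection over all clusters in which both patterns are expressed at
    all; pairs sharing no cluster are exclusive vacuously.  Edge weight is
    the longest-common-prefix length of the two patterns (shared ancestral
    edits).
    """
    patterns = list(binary.columns)
    P = len(patterns)
    G = nx.Graph()
    G.add_nodes_from(patterns)
    veto = np.zeros((P, P), dtype=bool)  # co-expression seen in some cluster
    for cl in sorted(clusters.unique()):
        sub = binary.loc[clusters == cl].to_numpy(dtype=float)
        npat = sub.sum(axis=0)
        C = sub.T @ sub
        denom = np.sqrt(np.outer(npat, npat))
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(denom > 0, C / np.maximum(denom, 1e-300), 0.0)
        both = (npat[:, None] > 0) & (npat[None, :] > 0)
        veto |= both & (cos > tolerance)
    for i in range(P):
        for j in range(i + 1, P):
            if not veto[i, j]:
                G.add_edge(patterns[i], patterns[j],
                           weight=_lcp(patterns[i], patterns[j]))
    return G


@dataclass
class LocusAssignment:
    """One inferred integration locus: a clique of exclusive patterns."""

    tapebc: str
    locus_id: str
    patterns: list = field(default_factory=list)


def partition_into_loci(
    graph: nx.Graph,
    tapebc: str = "",
    n_restarts: int = 100,
    seed: int = 0,
) -> list[LocusAssignment]:
    """Minimum clique cover of the exclusivity graph by greedy coloring.

    Greedy coloring of the complement graph is run under ``n_restarts``
    random node orders plus one largest-first order; among solutions the one
    with the fewest cliques and then the highest sum of within-clique edge
    weights is kept.  Deterministic given ``seed``.
    """
    nodes = sorted(graph.nodes())
    if not nodes:
        return []
    H = nx.complement(graph)
    rng = np.random.default_rng(seed)
    orders = [sorted(nodes, key=lambda v: (-H.degree(v), v))]
    for _ in range(n_restarts):
        perm = list(nodes)
        rng.shuffle(perm)
        orders.append(perm)

    def greedy(order):
        color: dict = {}
        for v in order:
            used = {color[u] for u in H.neighbors(v) if u in color}
            c = 0
            while c in used:
                c += 1
            color[v] = c
        return color

    def score(color):
        n_colors = max(color.values()) + 1
        w = 0
        for u, v, data in graph.edges(data=True):
            if color[u] == color[v]:
                w += data.get("weight", 0)
        return (n_colors, -w)

    best_color, best_score = None, None
    for order in orders:
        color = greedy(order)
        s = score(color)
        if best_score is None or s < best_score:
            best_color, best_score = color, s
    cliques: dict[int, list] = {}
    for v, c in best_color.items():
        cliques.setdefault(c, []).append(v)
    out = []
    for i, members in enumerate(sorted(
            (sorted(m) for m in cliques.values()), key=lambda m: m[0])):
        out.append(LocusAssignment(
            tapebc=tapebc,
            locus_id=f"{tapebc}|L{i}" if tapebc else f"L{i}",
            patterns=members,
        ))
    return out


# ---------------------------------------------------------------------------
# Cell x locus matrix
# ---------------------------------------------------------------------------


def build_cell_locus_matrix(
    assignments: list[LocusAssignment],
    umi_matrix: pd.DataFrame,
    binary: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Entry (cell, locus) = the cell's expressed pattern among the clique.

    A cell expressing two patterns of one clique is a conflict: the
    higher-UMI pattern is kept and the conflict counted.
    """
    cells = list(binary.index)
    conflicts = 0
    data = {}
    for la in assignments:
        col = [None] * len(cells)
        sub_bin = binary[la.patterns].to_numpy()
        sub_umi = umi_matrix[la.patterns].to_numpy()
        for ci in range(len(cells)):
            expressed = np.flatnonzero(sub_bin[ci])
            if expressed.size == 0:
                continue
            if expressed.size > 1:
                conflicts += 1
                expressed = [expressed[np.argmax(sub_umi[ci, expressed])]]
            col[ci] = la.patterns[int(expressed[0])]
        data[la.locus_id] = col
    mat = pd.DataFrame(data, index=cells)
    return mat, conflicts


def infer_loci(
    observations: pd.DataFrame,
    min_cluster_umis: int = 100,
    hamming_radius: int = 0,
    min_samples: int = 5,
    k_rescue: int = 10,
    exclusivity_tolerance: float = 0.0,
    n_restarts: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Full locus inference across TapeBCs.

    ``observations`` rows: cell_id, tapebc, site1..site6, umi (the
    un-collapsed per-sequence table).  Returns the cell x locus matrix of
    edit-pattern tuples (None = not observed) and a diagnostics dict with
    per-TapeBC inferred locus counts, thresholds, discarded UMI fractions,
    and conflict counts.
    """
    diagnostics: dict = {"tapebcs": {}, "conflicts": 0}
    pieces = []
    for k, (tapebc, obs) in enumerate(sorted(observations.groupby("tapebc"))):
        clusters_df, stats = call_consensus_patterns(obs, min_cluster_umis)
        info = dict(stats)
        if clusters_df.empty:
            info["n_loci"] = 0
            diagnostics["tapebcs"][tapebc] = info
            continue
        patterns = list(clusters_df["pattern"])
        umi_mat = pattern_umi_matrix(obs, patterns)
        binary, lognorm, threshold, fb = binarize_pattern_matrix(umi_mat)
        cl = cluster_cells_by_patterns(
            binary, lognorm, hamming_radius, min_samples, k_rescue
        )
        G = build_exclusivity_graph(cl, binary, exclusivity_tolerance)
        assignments = partition_into_loci(
            G, tapebc=tapebc, n_restarts=n_restarts, seed=seed + k
        )
        mat, conflicts = build_cell_locus_matrix(assignments, umi_mat, binary)
        info.update(
            n_patterns=len(patterns), n_loci=len(assignments),
            threshold=threshold, threshold_fallback=fb, conflicts=conflicts,
        )
        diagnostics["tapebcs"][tapebc] = info
        diagnostics["conflicts"] += conflicts
        pieces.append(mat)
    if not pieces:
        return pd.DataFrame(), diagnostics
    out = pd.concat(pieces, axis=1)
    return out, diagnostics


def serialize_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Dash-join pattern tuples for TSV output.

    Observed-but-unedited entries (empty tuples) become ".", unobserved
    entries become empty cells; a missing tape is not an unedited tape.
    """
    def ser(v):
        if isinstance(v, tuple):
            return "-".join(v) if v else "."
        return ""

    return matrix.map(ser)


def deserialize_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`serialize_matrix`."""
    def deser(v):
        if not isinstance(v, str) or v == "":
            return None
        if v == ".":
            return ()
        return tuple(v.split("-"))

    return df.map(deser)
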
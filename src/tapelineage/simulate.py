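"""Forward simulator for sequential-insertion lineage-recording experiments.

Cells divide as a complete binary tree.  Each cell carries ``n_loci`` tape
integrations; at every division each daughter independently appends, with
probability ``edit_prob`` per tape, a uniformly drawn 3-base insert code to
the first unwritten site of that tape (at most one insertion per tape per
division, six sites per tape).  Tapes share 12-base TapeBCs: when
``n_tapebc < n_loci`` several genomic loci carry the same TapeBC, which the
downstream locus-inference step must disentangle.  A latent fate state
evolves as a Markov chain along branches; capture applies per-(cell, locus)
dropout and negative-binomial UMI noise; pooled "debris" amplicon reads are
sampled per well with an optional chimeric-read fraction.

Default parameters emulate the study conditions this pipeline targets: the
per-division editing rate is set so an edited tape carries ~3 insertions at
the simulated depth, capture drops ~30% of tapes per cell, and tape
amplicons are sequenced to saturation (tens of UMIs per retained tape).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .tape_io import (
    N_SITES, SITE_COLUMNS, TapeAllele, serialize_allele,
)
from .tree import LineageTree, TreeNode

logger = logging.getLogger(__name__)

BASES = "ACGT"
ALL_CODES = tuple("".join(p) for p in itertools.product(BASES, repeat=3))

MAX_GENERATIONS = 20


@dataclass
class SimConfig:
    """Parameters of one simulated recording experiment."""

    n_generations: int = 9
    n_loci: int = 24
    n_tapebc: int = 12
    edit_prob: float = 0.32
    insert_alphabet: tuple = ALL_CODES
    dropout_prob: float = 0.3
    umi_mean: float = 25.0
    umi_dispersion: float = 2.0
    ambient_noise_frac: float = 0.05
    fate_states: int = 4
    fate_switch_prob: float = 0.1
    debris_reads_per_well: int = 20000
    noise_read_frac: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("edit_prob", "dropout_prob", "fate_switch_prob",
                     "noise_read_frac", "ambient_noise_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.n_generations > MAX_GENERATIONS:
            raise ValueError(
                f"n_generations={self.n_generations} exceeds the "
                f"{MAX_GENERATIONS}-division tip-count guard"
            )
        if self.n_tapebc > self.n_loci:
            raise ValueError("n_tapebc must not exceed n_loci")
        if len(set(self.insert_alphabet)) != len(self.insert_alphabet):
            raise ValueError("insert codes must be unique")
        if len(self.insert_alphabet) > 64:
            raise ValueError("at most 64 distinct 3-base insert codes exist")
        if self.fate_states < 1:
            raise ValueError("fate_states must be >= 1")


@dataclass
class TrueLineage:
    """Ground truth of one simulated experiment."""

    tree: LineageTree
    cell_ids: list
    locus_alleles: dict            # cell_id -> tuple of edit tuples, one per locus
    fate_labels: dict              # cell_id -> int state
    well_of_origin: dict           # cell_id -> well id
    tapebcs: list                  # per-locus TapeBC (len == n_loci)
    config: SimConfig
    founder_tree: Optional[LineageTree] = None   # two-epoch: tree over wells
    founder_fate: dict = field(default_factory=dict)  # well -> epoch-1 state
    well_loci: dict = field(default_factory=dict)     # well -> locus index array

    @property
    def n_loci(self) -> int:
        return len(self.tapebcs)

    def loci_for(self, well_id: str) -> np.ndarray:
        """Locus indices present in a well (all, unless founders differ)."""
        if well_id in self.well_loci:
            return np.asarray(self.well_loci[well_id])
        return np.arange(self.n_loci)

    def duplication_groups(self) -> dict[str, list[int]]:
        """TapeBC -> locus indices sharing it."""
        groups: dict[str, list[int]] = {}
        for i, bc in enumerate(self.tapebcs):
            groups.setdefault(bc, []).append(i)
        return groups


# ---------------------------------------------------------------------------
# Core growth
# ---------------------------------------------------------------------------


def _random_tapebcs(n: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out = []
    while len(out) < n:
        chars = rng.choice(list(BASES), size=12)
        chars[5] = chars[6] = "A"
        bc = "".join(chars)
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _grow(
    rng: np.random.Generator,
    config: SimConfig,
    root_alleles: tuple,
    root_state: int,
    prefix: str,
    total_height: float,
) -> tuple[TreeNode, dict, dict]:
    """Grow one binary tree; returns (root node, alleles, states) for tips."""
    g = config.n_generations
    codes = list(config.insert_alphabet)
    n_codes = len(codes)
    root = TreeNode(name=None, height=total_height)
    frontier = [(root, root_alleles, root_state)]
    for depth in range(1, g + 1):
        nxt = []
        h = total_height - depth
        for node, alleles, state in frontier:
            for _ in range(2):
                new_alleles = list(alleles)
                if config.edit_prob > 0:
                    hits = np.flatnonzero(
                        rng.random(config.n_loci) < config.edit_prob
                    )
                    for li in hits:
                        a = new_alleles[li]
                        if len(a) < N_SITES:
                            new_alleles[li] = a + (codes[rng.integers(n_codes)],)
                new_state = state
                if (config.fate_states > 1
                        and rng.random() < config.fate_switch_prob):
                    others = [s for s in range(config.fate_states) if s != state]
                    new_state = others[rng.integers(len(others))]
                child = TreeNode(name=None, height=h)
                node.add_child(child)
                nxt.append((child, tuple(new_alleles), new_state))
        frontier = nxt
    alleles_out, states_out = {}, {}
    width = max(1, len(f"{2**g - 1:b}"))
    for i, (node, alleles, state) in enumerate(frontier):
        name = f"{prefix}{i:0{width}b}" if g > 0 else f"{prefix}0"
        node.name = name
        alleles_out[name] = alleles
        states_out[name] = state
    if g == 0:
        only = frontier[0][0]
        only.name = f"{prefix}0"
    return root, alleles_out, states_out


def simulate_lineage_recording(
    config: SimConfig, well_id: str = "W00"
) -> TrueLineage:
    """Simulate one complete binary division tree with tape recording.

    Deterministic given ``config.seed``.  Fate labels follow a ``fate_states``
    Markov chain with per-division switch probability ``fate_switch_prob``.
    """
    rng = np.random.default_rng(config.seed)
    tapebcs_unique = _random_tapebcs(config.n_tapebc, rng)
    tapebcs = [tapebcs_unique[i % config.n_tapebc] for i in range(config.n_loci)]
    root_alleles = tuple(() for _ in range(config.n_loci))
    root_state = int(rng.integers(config.fate_states))
    root, alleles, states = _grow(
        rng, config, root_alleles, root_state,
        prefix=f"{well_id}:", total_height=float(config.n_generations),
    )
    cells = sorted(alleles)
    return TrueLineage(
        tree=LineageTree(root),
        cell_ids=cells,
        locus_alleles=alleles,
        fate_labels=states,
        well_of_origin={c: well_id for c in cells},
        tapebcs=tapebcs,
        config=config,
    )


# ---------------------------------------------------------------------------
# Capture and sequencing noise
# ---------------------------------------------------------------------------


def _umi_draw(rng: np.random.Generator, n: int, mean: float, disp: float) -> np.ndarray:
    """Counts >= 1 with negative-binomial spread around ``mean``."""
    m = max(mean - 1.0, 1e-9)
    p = disp / (disp + m)
    return 1 + rng.negative_binomial(disp, p, size=n)


def simulate_capture(lineage: TrueLineage, config: SimConfig) -> pd.DataFrame:
    """Per-cell tape capture with dropout and UMI count noise.

    Each (cell, locus) is retained with probability 1 - dropout_prob and
    emitted under its locus's TapeBC (duplication is only resolvable
    downstream).  A small fraction ``ambient_noise_frac`` of spurious
    low-UMI rows (another cell's tape observed in the wrong cell, as ambient
    contamination or barcode-hopping produces) is appended; these are the
    noise UMIs the downstream >100-UMI cluster rule and binarization valley
    are designed to discard.  Returns rows: cell_id, well_id, tapebc,
    site1..site6, umi, reads, true_locus (-1 for ambient rows).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for cell in lineage.cell_ids:
        alleles = lineage.locus_alleles[cell]
        loci = lineage.loci_for(lineage.well_of_origin[cell])
        keep = rng.random(loci.size) >= config.dropout_prob
        kept = loci[keep]
        if kept.size == 0:
            continue
        umis = _umi_draw(rng, kept.size, config.umi_mean, config.umi_dispersion)
        for li, umi in zip(kept, umis):
            edits = alleles[li]
            row = {
                "cell_id": cell,
                "well_id": lineage.well_of_origin[cell],
                "tapebc": lineage.tapebcs[li],
                "umi": int(umi),
                "reads": int(umi) * 3,
                "true_locus": int(li),
            }
            for i in range(N_SITES):
                row[SITE_COLUMNS[i]] = edits[i] if i < len(edits) else ""
            rows.append(row)
    cols = ["cell_id", "well_id", "tapebc", *SITE_COLUMNS,
            "umi", "reads", "true_locus"]
    obs = pd.DataFrame(rows, columns=cols)
    n_ambient = int(round(config.ambient_noise_frac * len(obs)))
    if n_ambient and len(obs):
        donors = obs.iloc[rng.integers(len(obs), size=n_ambient)].copy()
        recipients = obs.iloc[rng.integers(len(obs), size=n_ambient)]
        donors["cell_id"] = recipients["cell_id"].to_numpy()
        donors["well_id"] = recipients["well_id"].to_numpy()
        donors["umi"] = 1 + rng.poisson(0.5, size=n_ambient)
        donors["reads"] = donors["umi"] * 2
        donors["true_locus"] = -1
        obs = pd.concat([obs, donors], ignore_index=True)
    return obs


def simulate_debris_reads(
    lineage: TrueLineage, config: SimConfig
) -> dict[str, list[str]]:
    """Pooled per-well amplicon reads sampled from the well's cells.

    ``debris_reads_per_well`` reads per well, each from a uniformly chosen
    (cell, locus); a ``noise_read_frac`` fraction are chimeras formed by
    splicing two random alleles at a random site boundary (mimicking PCR
    template switching).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 2)
    wells: dict[str, list[str]] = {}
    by_well: dict[str, list[str]] = {}
    for cell, w in lineage.well_of_origin.items():
        by_well.setdefault(w, []).append(cell)
    for well_id in sorted(by_well):
        cells = sorted(by_well[well_id])
        if not cells:
            logger.warning("well %s has no cells; empty read set", well_id)
            wells[well_id] = []
            continue
        n = config.debris_reads_per_well
        loci = lineage.loci_for(well_id)
        ci = rng.integers(len(cells), size=n)
        li = loci[rng.integers(loci.size, size=n)]
        chim = rng.random(n) < config.noise_read_frac
        reads = []
        for k in range(n):
            edits = lineage.locus_alleles[cells[ci[k]]][li[k]]
            bc = lineage.tapebcs[li[k]]
            if chim[k]:
                c2 = cells[rng.integers(len(cells))]
                l2 = loci[rng.integers(loci.size)]
                other = lineage.locus_alleles[c2][l2]
                cut = int(rng.integers(0, N_SITES + 1))
                edits = (edits[:cut] + other[cut:])[:N_SITES]
            reads.append(serialize_allele(TapeAllele(bc, tuple(edits))))
        wells[well_id] = reads
    return wells


# ---------------------------------------------------------------------------
# Two-epoch (founder-of-founders) design
# ---------------------------------------------------------------------------


def simulate_two_epoch(
    config_epoch1: SimConfig, config_epoch2: SimConfig
) -> TrueLineage:
    """Two-epoch design: epoch-1 tips found independent epoch-2 trees.

    A single founder expands for ``config_epoch1.n_generations`` divisions;
    each resulting cell founds one well (gastruloid) that expands under
    ``config_epoch2``.  Editing continues on the same tapes across epochs and
    each well inherits its founder's latent fate state, so fate composition
    bias is heritable along the epoch-1 (founder) tree, which is recorded as
    ``founder_tree`` with wells as tips.
    """
    g1, g2 = config_epoch1.n_generations, config_epoch2.n_generations
    if g1 + g2 > MAX_GENERATIONS:
        raise ValueError("combined epoch depth exceeds the tip-count guard")
    rng = np.random.default_rng(config_epoch1.seed)
    cfg1 = config_epoch1
    tapebcs_unique = _random_tapebcs(cfg1.n_tapebc, rng)
    tapebcs = [tapebcs_unique[i % cfg1.n_tapebc] for i in range(cfg1.n_loci)]
    root_alleles = tuple(() for _ in range(cfg1.n_loci))
    root_state = int(rng.integers(cfg1.fate_states))
    total_h = float(g1 + g2)
    e1_root, e1_alleles, e1_states = _grow(
        rng, cfg1, root_alleles, root_state, prefix="F", total_height=total_h,
    )
    founders = sorted(e1_alleles)
    wells = [f"W{i:02d}" for i in range(len(founders))]

    # founder tree over wells: copy of epoch-1 topology with well-named tips
    name_map = dict(zip(founders, wells))

    def copy_named(node: TreeNode) -> TreeNode:
        kids = [copy_named(c) for c in node.children]
        nm = name_map.get(node.name) if node.is_tip() else None
        return TreeNode(name=nm, children=kids,
                        height=node.height - g2 if not node.is_tip() else 0.0)

    founder_tree = LineageTree(copy_named(e1_root))

    cells: list[str] = []
    alleles: dict = {}
    states: dict = {}
    origin: dict = {}
    founder_fate: dict = {}
    all_roots = []
    for founder, well in zip(founders, wells):
        cfg_w = SimConfig(**{**asdict(config_epoch2),
                             "n_loci": cfg1.n_loci,
                             "n_tapebc": cfg1.n_tapebc,
                             "insert_alphabet": cfg1.insert_alphabet})
        root_w, a_w, s_w = _grow(
            rng, cfg_w, e1_alleles[founder], e1_states[founder],
            prefix=f"{well}:", total_height=float(g2),
        )
        founder_fate[well] = e1_states[founder]
        for c in sorted(a_w):
            cells.append(c)
            alleles[c] = a_w[c]
            states[c] = s_w[c]
            origin[c] = well
        all_roots.append((founder, root_w))

    # graft epoch-2 trees onto the epoch-1 tree at its tips
    root_of = dict(all_roots)
    for node in list(LineageTree(e1_root).preorder()):
        if node.is_tip() and node.name in root_of:
            sub = root_of[node.name]
            node.name = None
            node.children = sub.children
            for c in node.children:
                c.parent = node
    full_tree = LineageTree(e1_root)
    return TrueLineage(
        tree=full_tree,
        cell_ids=cells,
        locus_alleles=alleles,
        fate_labels=states,
        well_of_origin=origin,
        tapebcs=tapebcs,
        config=config_epoch2,
        founder_tree=founder_tree,
        founder_fate=founder_fate,
    )


def simulate_polyclonal_wells(n_wells: int, config: SimConfig) -> TrueLineage:
    """Independent founders per well, each with its own tape integrations.

    Emulates the polyclonal design where every well's gastruloid descends
    from a distinct founder drawn from a polyclonal recorder line, so wells
    share (essentially) no TapeBCs and debris profiles are well-specific.
    """
    master = np.random.default_rng(config.seed)
    cells, alleles, states, origin = [], {}, {}, {}
    tapebcs: list[str] = []
    well_loci: dict[str, np.ndarray] = {}
    roots = []
    for w in range(n_wells):
        well = f"W{w:02d}"
        cfg = SimConfig(**{**asdict(config),
                           "seed": int(master.integers(2**31 - 1))})
        lin = simulate_lineage_recording(cfg, well_id=well)
        offset = len(tapebcs)
        tapebcs.extend(lin.tapebcs)
        well_loci[well] = np.arange(offset, offset + lin.n_loci)
        for c in lin.cell_ids:
            cells.append(c)
            # pad alleles into the global locus coordinate system
            padded = tuple(() for _ in range(offset)) + lin.locus_alleles[c]
            alleles[c] = padded
            states[c] = lin.fate_labels[c]
            origin[c] = well
        roots.append(lin.tree.root)
    n_total = len(tapebcs)
    for c in cells:
        alleles[c] = alleles[c] + tuple(() for _ in range(n_total - len(alleles[c])))
    root = TreeNode(children=roots, height=float(config.n_generations) + 1.0)
    return TrueLineage(
        tree=LineageTree(root),
        cell_ids=cells,
        locus_alleles={c: alleles[c] for c in cells},
        fate_labels=states,
        well_of_origin=origin,
        tapebcs=tapebcs,
        config=config,
        well_loci=well_loci,
    )


# ---------------------------------------------------------------------------
# Phenotype emulation
# ---------------------------------------------------------------------------


def simulate_embedding(
    lineage: TrueLineage,
    dim: int = 30,
    state_sep: float = 3.0,
    within_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian low-dimensional expression embedding per latent fate state.

    Each fate state gets an isotropic Gaussian centroid (pairwise distance
    scale ``state_sep``); cells scatter around their state's centroid with
    standard deviation ``within_sd``.
    """
    rng = np.random.default_rng(seed)
    k = lineage.config.fate_states
    centroids = rng.normal(scale=state_sep / np.sqrt(2), size=(k, dim))
    X = np.empty((len(lineage.cell_ids), dim))
    for i, c in enumerate(lineage.cell_ids):
        X[i] = centroids[lineage.fate_labels[c]] + rng.normal(
            scale=within_sd, size=dim
        )
    return pd.DataFrame(
        X, index=lineage.cell_ids,
        columns=[f"PC{i+1}" for i in range(dim)],
    )


def simulate_heritable_shifts(
    tree, dim: int = 30, rate: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Brownian-motion phenotype shifts along a (founder) tree.

    Each node's value diffuses from its parent with per-dimension variance
    ``rate`` x branch length, the standard model of a fully heritable
    continuous trait.  Returns a tips x dim table of shifts; add them to the
    embedding of each well's cells to couple phenotype to founder
    relatedness.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {id(tree.root): np.zeros(dim)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        bl = max(node.parent.height - node.height, 0.0)
        values[id(node)] = values[id(node.parent)] + rng.normal(
            scale=np.sqrt(rate * bl), size=dim
        )
    tips = tree.tips()
    return pd.DataFrame(
        np.array([values[id(t)] for t in tips]),
        index=[t.name for t in tips],
        columns=[f"PC{i+1}" for i in range(dim)],
    )


def simulate_expression(
    lineage: TrueLineage,
    n_genes: int = 100,
    depth: float = 2000.0,
    state_effect: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson pseudo-count matrix whose gene means depend on fate state."""
    rng = np.random.default_rng(seed)
    k = lineage.config.fate_states
    base = rng.gamma(2.0, 1.0, size=n_genes)
    effects = rng.normal(scale=state_effect, size=(k, n_genes))
    rows = []
    for c in lineage.cell_ids:
        mean = base * np.exp(effects[lineage.fate_labels[c]])
        mean = depth * mean / mean.sum()
        rows.append(rng.poisson(mean))
    return pd.DataFrame(
        np.array(rows), index=lineage.cell_ids,
        columns=[f"g{i}" for i in range(n_genes)],
    )


def fate_table(lineage: TrueLineage, embedding: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Tidy per-cell fate labels (and embedding coordinates if given)."""
    df = pd.DataFrame({
        "cell_id": lineage.cell_ids,
        "fate": [f"state{lineage.fate_labels[c]}" for c in lineage.cell_ids],
        "well_id": [lineage.well_of_origin[c] for c in lineage.cell_ids],
    }).set_index("cell_id")
    if embedding is not None:
        df = df.join(embedding)
    return df


# ---------------------------------------------------------------------------
# Run directory output
# ---------------------------------------------------------------------------


def write_run(lineage: TrueLineage, outdir, config: Optional[SimConfig] = None) -> None:
    """Write ground truth, observations, and debris reads under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or lineage.config
    obs = simulate_capture(lineage, cfg)
    obs.to_csv(out / "observations.tsv", sep="\t", index=False)
    (out / "truth.nwk").write_text(lineage.tree.to_newick())
    if lineage.founder_tree is not None:
        (out / "founders.nwk").write_text(lineage.founder_tree.to_newick())
    fate_table(lineage).to_csv(out / "fates.tsv", sep="\t")
    debris = simulate_debris_reads(lineage, cfg)
    for well, reads in debris.items():
        (out / f"debris_{well}.txt").write_text("\n".join(reads) + "\n")
    cfg_dict = asdict(cfg)
    cfg_dict["insert_alphabet"] = list(cfg_dict["insert_alphabet"])
    (out / "config.json").write_text(json.dumps(cfg_dict, indent=2))
    manifest = {
        "observations": "observations.tsv",
        "truth_tree": "truth.nwk",
        "fates": "fates.tsv",
        "debris": sorted(f"debris_{w}.txt" for w in debris),
        "config": "config.json",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
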
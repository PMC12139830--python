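# Methods

This document describes the statistical model behind `tapelineage`, the
default parameters and why they were chosen, what the simulator does and
does not emulate, the numerical choices made in each module, and the known
limitations. All quantitative behavior asserted here is recomputed by the
test suite (`tests/`) or the acceptance script (`scripts/acceptance.py`);
no empirical claim is made beyond what those compute.

## Recording model

A tape is an array of six target sites edited strictly in order. Its state
is a **prefix-complete allele**: a tuple of 0–6 three-base insert codes
where site *k* is written only after sites 1..*k*−1. A tape is identified
by a 12-bp TapeBC matching `NNNNNAANNNNN`; TapeBCs need not be unique
across the genome, so a TapeBC can label several independent loci.

In sequence space an edited site consists of the 3-bp insert followed by
the `GGA` insertion key; an amplicon read is therefore
`TapeBC + (insert + GGA)* + unedited-tail`, where the unedited tail begins
with `T`. The parser scans 6-bp slots, accepting a slot as an edit when it
ends in `GGA` and is followed by either another complete slot or the
terminal `T` — the lookahead is needed because the first base of the next
insert is unconstrained.

### Tape edit distance

For alleles *a*, *b* with longest common prefix of length *L*:

    d(a, b) = (|a| − L) + (|b| − L)

This is the minimal number of append/remove-last operations converting one
allele into the other, so it is a true metric on prefix-complete alleles.
Worked example: d((A,C,D), (B)) = 3 + 1 = 4. On six-site tapes the maximum
is 12 (two disjoint full tapes); the acceptance suite verifies both by
exhaustive enumeration of all 127 prefix-complete alleles over a two-letter
alphabet, and by a breadth-first-search oracle over the operation graph.

## Module-by-module description

### tape_io — parsing and tabulation

- Amplicon parsing rejects malformed reads with a reason (bad TapeBC, read
  too short, missing terminal key) rather than guessing.
- Debris wells are summarized by allele read counts; alleles below a
  per-well read fraction (`min_frac = 0.002`, strict less-than) are
  dropped as noise/chimeras. Tabulation is order-invariant with a
  lexicographic tie rule.
- Single-cell tables are UMI-filtered, and TapeBCs are corrected to a
  whitelist at Hamming distance ≤ 1; ambiguous corrections (two whitelist
  hits) are dropped, with per-reason counts reported.

### loci — resolving TapeBC duplication

For each TapeBC: pool cells' identical full patterns (UMI evidence above a
strict >100 threshold per consensus; unedited tapes excluded), then

1. **Binarize** the per-cell log1p UMI dose matrix at the deepest valley of
   a kernel density estimate between the outermost density modes. Peaks
   below 1e-4 of the maximum density are ignored as numerical ripple; if
   the density is unimodal, the fallback threshold is the 1st percentile
   minus 1e-9 (everything nonzero is "present").
2. **Cluster** cells by binarized pattern profile (DBSCAN on Hamming
   distance, `eps = (radius + 0.5) / n_patterns`, `min_samples = 5`) with
   a k-nearest-neighbor rescue (k = 10) for unclustered cells.
3. **Mutual exclusivity**: two patterns are compatible with the same locus
   if their presence vectors are near-orthogonal (cosine ≤ tolerance) in
   every cluster where both occur; compatible pairs are weighted by their
   longest common prefix (shared edit history).
4. **Minimum clique cover** of the compatibility graph = number of loci
   behind that TapeBC. Computed as greedy coloring of the complement graph
   (largest-first plus random restarts), choosing fewest cliques, then
   maximal total weight. The test suite checks this against an exact
   chromatic-number backtracking oracle on random graphs up to 10 nodes.

Entry (cell, locus) of the resulting matrix is the cell's expressed pattern
among that locus's clique members; conflicts resolve to the higher-UMI
pattern and are counted in the diagnostics.

### tree — reconstruction and support

- Cell–cell distance is the summed tape edit distance over shared loci,
  averaged per shared locus; pairs sharing no locus are set to the maximum
  observed distance + 1 (and reported), keeping the matrix finite without
  inventing affinity.
- **UPGMA** (average linkage) with node height = half the merge distance
  and a deterministic lexicographic tie rule (minimum member label), so
  equal-distance merges never depend on iteration order. Verified against
  a brute-force average-linkage oracle comparing (tip set, height) node
  sets.
- **Robinson–Foulds** counts symmetric differences of non-trivial
  bipartitions, each canonicalized as the side not containing the minimum
  tip; verified against dendropy.
- **Transfer bootstrap expectation (TBE)**: trees are rebuilt on 100
  locus-column resamples; each reference clade's transfer distance δ is
  the minimum bipartition Hamming distance (both orientations) to any
  bootstrap bipartition, and TBE = 1 − mean(δ/(p−1)) clamped to [0, 1],
  where p is the smaller side size. Clades with p = 1 have support 1 by
  convention and are excluded from summaries. With resampling disabled the
  tree is compared with itself and all supports are exactly 1 (a
  self-consistency check in the acceptance suite).

### assign — wells, well trees, pseudo-ancestors

- The whitelist keeps debris alleles exclusive to one well; wells with no
  exclusive allele are dropped.
- A cell's tape matches a whitelist allele if the TapeBC is within Hamming
  distance 1, site 1 matches exactly, and sites 2–4 allow the *cell* side
  to be unwritten (dropout) but not mismatched.
- The margin rule assigns a cell to the top well when its match tally is
  at least 1.5× the runner-up, boundary inclusive ({6, 4} assigns; {6, 5}
  does not). Unassigned cells are rescued by a PCA/k-nearest-neighbor vote
  among assigned cells. Wells with < 100 final cells are dropped
  (`min_cells_per_well`, matching the study scale; the CLI exposes
  `--min-cells` for smaller runs), with a Jaccard QC score per well.
- The **tree of trees** clusters wells by dominant
  (TapeBC, site, edit) combos (≥20% of that TapeBC's reads in the well),
  with 1 − Jaccard distance and UPGMA. Pseudo-ancestral founder nodes are
  mapped onto the single-cell tree as the most-cells node whose
  clade-exclusive combo fold change exceeds 2× the best competitor (on
  log2(FC+1)).

### phenostats — lineage–fate coupling

- **Distance-binned state correlation**: mean embedding distance per tree
  distance bin (2, 3, …, 10+), summarized by Spearman rank correlation.
- **Nearest-neighbor pair enrichment**: log2 ratio of observed to
  permuted same/different-type nearest-neighbor pair frequencies, with a
  +0.5 pseudocount.
- **Phylogenetic Moran's I** on fate indicators with weights
  W = exp(−d/τ) (row-normalized, zero diagonal). Significance uses the
  Cliff–Ord analytic z under normality for auto-correlation and Monte
  Carlo permutation for cross-correlation. Closed forms used as tests:
  two tips give I = −1; a star tree gives I = −1/(n−1).
- **Daughter fate tests**: Fisher exact (verified against explicit
  hypergeometric summation) on fate counts of each internal node's two
  daughter clades (minimum clade size 10), Benjamini–Hochberg corrected.
- **Clade composition enrichment**: per (clade, fate type) permutation
  test shuffling well labels, p = (1 + #{perm ≥ obs})/(n_perm + 1), by
  default 5000 permutations via a shared permutation matrix. Calibration
  (uniform p under a Dirichlet null) is checked in the acceptance suite.
- **Founder heritability**: nearest-neighbor founder pairs are compared on
  pseudobulk principal components (Pearson), and Mantel-style Spearman
  statistics relate founder-tree distance to pseudobulk distance and to
  kNN mixing (k = 15, symmetrized), each with permutation p-values and a
  no-nearest-neighbor control.

## Simulator: what it does and does not emulate

`SimConfig` defaults are the study conditions under which every downstream
module is validated; they are fixed before any outcome is inspected and
are never tuned toward passing a criterion.

| Parameter | Default | Rationale |
|---|---|---|
| `n_generations` | 9 | 512 tips — large enough for stable locus inference, small enough for CI; a guard rejects > 20. |
| `n_loci` / `n_tapebc` | 24 / 12 | Every TapeBC duplicated ×2 on average, so duplication resolution is always exercised. |
| `edit_prob` | 0.32 | Per-tape, per-division edit probability giving ~3 inserts per edited tape at 9 generations (checked by a test). |
| `dropout_prob` | 0.3 | ~30% of (cell, locus) tapes lost at capture. |
| `umi_mean` / `umi_dispersion` | 25 / 2 | Negative-binomial UMI counts at amplicon saturation depth. |
| `ambient_noise_frac` | 0.05 | Fraction of captured rows that are ambient (wrong-cell) molecules, flagged in truth as `true_locus = -1`. |
| `fate_states` / `fate_switch_prob` | 4 / 0.1 | Latent fate Markov chain along branches; 0.1 per division yields clade-correlated but not frozen fates. |
| `debris_reads_per_well` | 20000 | Deep bulk profile per well. |
| `noise_read_frac` | 0.01 | Chimeric/noise debris reads. |

The simulator **does** emulate: sequential prefix-complete editing,
TapeBC duplication, capture dropout, NB UMI noise, ambient rows, bulk
debris reads with chimeras, polyclonal wells with disjoint loci, two-epoch
(founder-then-well) designs with a founder tree, latent fate states, state
embeddings, count-based expression, and Brownian heritable founder shifts
(`simulate_heritable_shifts`: trait variance proportional to branch
length, the fully-heritable alternative used for power analysis).

It does **not** emulate: asynchronous or unequal division (the tree is a
complete binary tree with unit branch lengths), cell death or selection,
tape silencing or excision, sequencing base-call errors inside inserts,
doublets, batch effects, or realistic transcriptome structure beyond a
low-dimensional state embedding.

## Numerical choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; no global seeding.
- KDE binarization operates on log1p(UMI) with a 256-point grid including
  the endpoints; the 1e-4 relative density floor removes ripple-induced
  spurious peaks without discarding genuinely small modes.
- Greedy clique cover uses deterministic largest-first ordering plus
  seeded random restarts; results are reproducible given
  (`n_restarts`, `seed`).
- Permutation p-values use the add-one estimator
  (1 + #{perm ≥ obs})/(n_perm + 1), which is valid (never zero) and
  calibrated.
- Fisher tests use `scipy.stats.fisher_exact`; BH correction uses
  `statsmodels`. DBSCAN, k-nearest neighbors, and PCA use scikit-learn;
  graph algorithms use networkx. These standard components are treated as
  trusted, but the non-standard ones (distance, UPGMA tie rule, TBE,
  clique cover, Moran's I adaptation) are each checked against an
  independent oracle in the tests.

## Limitations

- UPGMA assumes a molecular-clock-like distance; the tape edit distance
  only approximates one, and saturated tapes (all six sites written)
  stop recording, compressing deep distances.
- Cells sharing no inferred locus receive an imputed maximal distance;
  with sparse matrices this can distort deep branches.
- Locus inference requires enough cells per TapeBC for density estimation
  and clustering; at desk scale (≈64 cells) it falls back to
  single-cluster behavior and may merge or split loci.
- The margin assignment rule trades recall for precision; unassignable
  cells are rescued only if the embedding separates wells.
- Moran's I significance for auto mode relies on the Cliff–Ord normal
  approximation, which weakens for very small trees; permutation mode is
  available where that matters.
- The simulator's idealizations listed above mean performance numbers
  established on it (tree recovery, locus recovery, assignment accuracy,
  heritability power/size — all recomputed in `tests/test_acceptance.py`)
  are upper bounds on what comparably sized real experiments would give.
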
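"""Parsing of sequential-insertion tape amplicon reads and capture tables.

A tape record starts with a 12-base TapeBC (degenerate NNNNNAANNNNN, i.e.
positions 6-7 are ``AA``) followed by up to six 6-base insertion blocks.
Each block is a 3-base insert code plus the fixed ``GGA`` key; the base
immediately after the last written block is the unedited tape key ``T``
(or ``G`` when another block follows, the start of its ``GGA``).  Slots are
read at fixed positions, so frame-shifted reads are rejected rather than
rescued.

Two summarization rules from bulk ("Debris-seq") and single-cell capture are
implemented: per-well dominant-pattern retention with a 0.2% read-fraction
floor, and per-cell UMI filtering with single-mismatch TapeBC correction.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAPEBC_LEN = 12
N_SITES = 6
SLOT_LEN = 6
INSERT_KEY = "GGA"
# fixed unedited-tape stub appended after the last written block; begins with
# the terminal key "T" so the slot scan stops deterministically
UNEDITED_TAIL = "TCGTATGCACGTCAGTTAGC"

SITE_COLUMNS = [f"site{i}" for i in range(1, N_SITES + 1)]


class TapeParseError(ValueError):
    """Raised when an amplicon read cannot be interpreted as a tape record."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class TapeAllele:
    """One tape record: TapeBC plus an ordered, prefix-complete edit list."""

    tapebc: str
    edits: tuple[str, ...]

    def __post_init__(self):
        if len(self.edits) > N_SITES:
            raise ValueError("a tape holds at most six insertions")

    @property
    def insertbc1(self) -> str:
        return self.edits[0] if self.edits else ""


def serialize_allele(allele: TapeAllele, tail: str = UNEDITED_TAIL) -> str:
    """Serialize a tape allele the way it appears in an amplicon read.

    e.g. allele (TTTTTAAGCAAT, [CCT]) -> "TTTTTAAGCAAT" + "CCTGGA" + "T...".
    """
    blocks = "".join(code + INSERT_KEY for code in allele.edits)
    # the unedited remainder of the tape follows the last block and starts
    # with "T", completing the GGAT key of the final insertion
    return allele.tapebc + blocks + tail


def parse_amplicon_read(read: str, strict_tapebc: bool = False) -> TapeAllele:
    """Parse a raw amplicon read into a TapeAllele.

    The first 12 bases are the TapeBC; fixed 6-base slots are then scanned.
    Slot i holds an edit iff its bases 4-6 are ``GGA`` and what follows is
    either another complete insertion block (continuation) or the unedited
    tape key ``T`` (the GGAT check); scanning stops at the first non-edit
    slot.  Raises :class:`TapeParseError` on rejection.
    """
    if len(read) < TAPEBC_LEN + 1:
        raise TapeParseError("read too short for TapeBC")
    tapebc = read[:TAPEBC_LEN]
    if tapebc[5:7] != "AA":
        if strict_tapebc:
            raise TapeParseError("TapeBC does not match NNNNNAANNNNN")
        logger.debug("TapeBC %s does not match NNNNNAANNNNN", tapebc)

    def is_block(s: str) -> bool:
        return len(s) == SLOT_LEN and s[3:] == INSERT_KEY

    edits: list[str] = []
    pos = TAPEBC_LEN
    while len(edits) < N_SITES:
        slot = read[pos:pos + SLOT_LEN]
        if len(slot) < SLOT_LEN:
            # a partial slot whose visible tail matches the key prefix can
            # only be a truncated insertion block
            if len(slot) > 3 and slot[3:] == INSERT_KEY[:len(slot) - 3]:
                raise TapeParseError("read too short for a started slot")
            break
        if slot[3:] != INSERT_KEY:
            break
        if pos + SLOT_LEN >= len(read):
            raise TapeParseError("read too short for a started slot")
        nxt_slot = read[pos + SLOT_LEN:pos + 2 * SLOT_LEN]
        if not (is_block(nxt_slot) or read[pos + SLOT_LEN] == "T"):
            break
        edits.append(slot[:3])
        pos += SLOT_LEN
    if len(edits) < N_SITES and pos >= len(read):
        raise TapeParseError("read ends without a terminal tape key")
    return TapeAllele(tapebc=tapebc, edits=tuple(edits))


def parse_reads(
    reads: Iterable[str], strict_tapebc: bool = False
) -> tuple[list[TapeAllele], Counter]:
    """Parse many reads; returns (alleles, rejection-reason counts)."""
    alleles: list[TapeAllele] = []
    rejected: Counter = Counter()
    for r in reads:
        try:
            alleles.append(parse_amplicon_read(r.strip(), strict_tapebc))
        except TapeParseError as e:
            rejected[e.reason] += 1
    return alleles, rejected


# ---------------------------------------------------------------------------
# Debris-seq summarization
# ---------------------------------------------------------------------------


def tabulate_alleles(alleles: Iterable[TapeAllele]) -> pd.DataFrame:
    """Tabulate parsed alleles into (tapebc, site1..site6, reads) rows."""
    counts = Counter((a.tapebc, a.edits) for a in alleles)
    rows = []
    for (tapebc, edits), n in sorted(counts.items()):
        row = {"tapebc": tapebc, "reads": n}
        for i in range(N_SITES):
            row[SITE_COLUMNS[i]] = edits[i] if i < len(edits) else ""
        rows.append(row)
    cols = ["tapebc", *SITE_COLUMNS, "reads"]
    return pd.DataFrame(rows, columns=cols)


def pattern_of_row(row) -> tuple[str, ...]:
    """Prefix-complete edit tuple from site1..site6 fields of a table row."""
    edits = []
    for c in SITE_COLUMNS:
        v = row[c]
        if isinstance(v, str) and v:
            edits.append(v)
        else:
            break  # first unedited site ends the tape; later sites ignored
    return tuple(edits)


def summarize_debris_well(
    alleles: Iterable[TapeAllele], min_frac: float = 0.002
) -> pd.DataFrame:
    """Dominant-pattern summary of one well's parsed debris reads.

    Full (TapeBC, Site1-6) patterns are tabulated; patterns with read
    fraction strictly below ``min_frac`` of the well total are removed, and
    for each (TapeBC, InsertBC(1)) key only the highest-count full pattern is
    kept (ties broken lexicographically and logged).
    """
    counts = Counter((a.tapebc, a.edits) for a in alleles)
    total = sum(counts.values())
    if total == 0:
        logger.warning("summarize_debris_well: no parsed reads")
        return pd.DataFrame(
            columns=["tapebc", "insertbc1", *SITE_COLUMNS, "reads"]
        )
    best: dict[tuple[str, str], tuple[int, tuple[str, ...]]] = {}
    for (tapebc, edits), n in counts.items():
        if n / total < min_frac:
            continue
        key = (tapebc, edits[0] if edits else "")
        incumbent = best.get(key)
        # higher count wins; equal counts -> lexicographically smaller pattern
        cand = (-n, edits)
        if incumbent is None or cand < incumbent:
            if incumbent is not None and incumbent[0] == -n:
                logger.info(
                    "summarize_debris_well: tie at %d reads for %s/%s, "
                    "keeping lexicographically smaller pattern", n, *key,
                )
            best[key] = cand
    rows = []
    for (tapebc, ibc1), (negn, edits) in sorted(best.items()):
        row = {"tapebc": tapebc, "insertbc1": ibc1, "reads": -negn}
        for i in range(N_SITES):
            row[SITE_COLUMNS[i]] = edits[i] if i < len(edits) else ""
        rows.append(row)
    cols = ["tapebc", "insertbc1", *SITE_COLUMNS, "reads"]
    return pd.DataFrame(rows, columns=cols)


def summarize_debris_run(
    well_reads: dict[str, Sequence[str]],
    min_frac: float = 0.002,
    strict_tapebc: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse and summarize debris reads for every well.

    Returns (profiles, tabulated) where ``profiles`` is the 9-column
    dominant-pattern table (well_id first, read number last) and
    ``tabulated`` holds all parsed read counts per full pattern, used for
    per-site edit fractions downstream.
    """
    profiles, tables = [], []
    for well_id in sorted(well_reads):
        alleles, rejected = parse_reads(well_reads[well_id], strict_tapebc)
        if rejected:
            logger.info("well %s: rejected reads %s", well_id, dict(rejected))
        prof = summarize_debris_well(alleles, min_frac=min_frac)
        prof.insert(0, "well_id", well_id)
        profiles.append(prof)
        tab = tabulate_alleles(alleles)
        tab.insert(0, "well_id", well_id)
        tables.append(tab)
    empty_prof = pd.DataFrame(
        columns=["well_id", "tapebc", "insertbc1", *SITE_COLUMNS, "reads"]
    )
    empty_tab = pd.DataFrame(columns=["well_id", "tapebc", *SITE_COLUMNS, "reads"])
    return (
        pd.concat(profiles, ignore_index=True) if profiles else empty_prof,
        pd.concat(tables, ignore_index=True) if tables else empty_tab,
    )


# ---------------------------------------------------------------------------
# Single-cell tape capture
# ---------------------------------------------------------------------------


def _hamming1_corrector(known: Sequence[str]):
    """Return f(bc) -> (corrected bc or None, reason) for a known-TapeBC set.

    Correction succeeds when the barcode is known, or is within Hamming
    distance 1 of exactly one known barcode; ambiguous (equidistant to two
    known barcodes) and unmatched barcodes are dropped with a reason.
    """
    known_set = set(known)

    def correct(bc: str) -> tuple[Optional[str], str]:
        if bc in known_set:
            return bc, "exact"
        hits = []
        for k in known_set:
            d = sum(1 for x, y in zip(bc, k) if x != y)
            if d == 1:
                hits.append(k)
                if len(hits) > 1:
                    return None, "ambiguous"
        if len(hits) == 1:
            return hits[0], "corrected"
        return None, "unmatched"

    return correct


def parse_scrna_tapes(
    records: pd.DataFrame,
    known_tapebcs: Sequence[str],
    min_umi: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Filter and deduplicate single-cell tape capture rows.

    ``records`` columns: cell_id, tapebc, site1..site6, umi (and optionally
    reads).  Rows with umi < ``min_umi`` are dropped; TapeBCs are corrected
    to a known barcode within Hamming distance 1 when the match is unique
    (ambiguous or unmatched barcodes dropped and counted); then for each
    (cell, tapebc, insertbc1) key the single pattern with most UMIs is kept
    (ties: most reads, then lexicographically smallest pattern).
    """
    stats = {"input_rows": len(records)}
    df = records.copy()
    if "reads" not in df.columns:
        df["reads"] = df["umi"]
    kept = df[df["umi"] >= min_umi]
    stats["dropped_low_umi"] = len(df) - len(kept)
    df = kept

    correct = _hamming1_corrector(known_tapebcs)
    cache: dict[str, tuple[Optional[str], str]] = {}

    def corr(bc: str) -> tuple[Optional[str], str]:
        if bc not in cache:
            cache[bc] = correct(bc)
        return cache[bc]

    results = [corr(bc) for bc in df["tapebc"]]
    reasons = Counter(r for _, r in results)
    stats["dropped_unmatched_tapebc"] = reasons.get("unmatched", 0)
    stats["dropped_ambiguous_tapebc"] = reasons.get("ambiguous", 0)
    stats["corrected_tapebc"] = reasons.get("corrected", 0)
    df = df.assign(tapebc=[bc for bc, _ in results]).dropna(subset=["tapebc"])

    patterns = [pattern_of_row(r) for _, r in df.iterrows()]
    df = df.assign(
        _pattern=patterns,
        insertbc1=[p[0] if p else "" for p in patterns],
    )
    # aggregate duplicate (cell, tapebc, exact pattern) rows
    grouped = (
        df.groupby(["cell_id", "tapebc", "insertbc1", "_pattern"], sort=False)
        .agg(umi=("umi", "sum"), reads=("reads", "sum"))
        .reset_index()
    )
    # keep the best pattern per (cell, tapebc, insertbc1)
    order = grouped.assign(
        _rank=list(zip(-grouped["umi"], -grouped["reads"], grouped["_pattern"]))
    ).sort_values("_rank").drop(columns="_rank")
    dedup = order.drop_duplicates(
        subset=["cell_id", "tapebc", "insertbc1"], keep="first"
    )
    stats["deduplicated_rows"] = len(dedup)
    out_rows = []
    for _, r in dedup.iterrows():
        row = {
            "cell_id": r["cell_id"], "tapebc": r["tapebc"],
            "insertbc1": r["insertbc1"], "umi": int(r["umi"]),
            "reads": int(r["reads"]),
        }
        p = r["_pattern"]
        for i in range(N_SITES):
            row[SITE_COLUMNS[i]] = p[i] if i < len(p) else ""
        out_rows.append(row)
    cols = ["cell_id", "tapebc", "insertbc1", *SITE_COLUMNS, "umi", "reads"]
    out = pd.DataFrame(out_rows, columns=cols)
    return out.reset_index(drop=True), stats


# ---------------------------------------------------------------------------
# File IO helpers
# ---------------------------------------------------------------------------


def read_lines(path) -> list[str]:
    """Read one read per line from plain or gzipped text, or FASTA."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = [ln for ln in lines if not ln.startswith(">")]
    return lines


def write_profiles(profiles: pd.DataFrame, path) -> None:
    """Write the 9-column Debris profile table (TapeBC-InsertBC(1) merged)."""
    out = profiles.copy()
    out["dtt"] = out["tapebc"] + "-" + out["insertbc1"]
    cols = ["well_id", "dtt", *SITE_COLUMNS, "reads"]
    out[cols].to_csv(path, sep="\t", index=False)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in SITE_COLUMNS})
    for c in SITE_COLUMNS:
        df[c] = df[c].fillna("")
    return df
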
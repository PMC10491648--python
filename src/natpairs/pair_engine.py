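"""The core pair engine: signed offsets, the 8-type classifier, extraction.

All comparisons are strand-aware and gene-level (one representative
start/end per gene; no isoforms).  A pair is always ordered — (sense,
antisense) — and every qualifying pair is emitted in both orientations,
once per directional sweep (plus-sense then minus-sense), with no
deduplication.  Output order is deterministic: pairs are sorted by
(sense chromosome, sense start, sense gene_id, antisense gene_id) so runs
are byte-reproducible.

Offset convention
-----------------
``AS_TSS_position`` is the antisense TSS relative to the sense TSS,
measured in the sense gene's transcription direction: negative means the
antisense TSS lies upstream of the sense TSS, 0 means coincident.
``AS_TES_position`` is the same construction at the TES.  Extraction
windows are closed on both ends; with window (−500, −1) an offset of
exactly −500 is included and 0 (coincidence) is excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import CANONICAL_COLUMNS, GeneRecord, GeneTable, PairType

#: Gap (bp) at or below which a non-overlapping pair is "nearby" (nHH/nTT).
NEARBY_THRESHOLD = 5000

PAIR_COLUMNS = [
    "sense_gene_id", "sense_symbol", "sense_biotype", "sense_chr",
    "sense_strand", "sense_start", "sense_end",
    "as_gene_id", "as_symbol", "as_biotype", "as_strand", "as_start", "as_end",
    "Type", "AS_TSS_position", "AS_TES_position",
]


class Mode(enum.Enum):
    """Extraction mode: overlap sweep, TSS window, or TES window."""

    MODE1_OVERLAP = 1
    MODE2_TSS = 2
    MODE3_TES = 3


@dataclass(frozen=True)
class ExtractionSpec:
    """Mode plus the signed offset window (Modes 2/3 only).

    Offsets may be negative (upstream of the sense anchor), zero
    (coincident) or positive (downstream); ``window_min <= window_max``.
    """

    mode: Mode
    window_min: int | None = None
    window_max: int | None = None

    def __post_init__(self) -> None:
        if self.mode is not Mode.MODE1_OVERLAP:
            if self.window_min is None or self.window_max is None:
                raise ValueError(f"{self.mode.name} requires window_min and window_max")
            if self.window_min > self.window_max:
                raise ValueError(
                    f"window_min ({self.window_min}) > window_max ({self.window_max})"
                )


def tss(g: GeneRecord) -> int:
    """Transcription start site: ``start`` on the plus strand, ``end`` on minus."""
    return g.start if g.strand == "+" else g.end


def tes(g: GeneRecord) -> int:
    """Transcript end site: ``end`` on the plus strand, ``start`` on minus."""
    return g.end if g.strand == "+" else g.start


def _check_pairable(sense: GeneRecord, antisense: GeneRecord) -> None:
    if sense.strand == antisense.strand:
        raise ValueError(
            f"{sense.gene_id}/{antisense.gene_id}: genes are on the same strand"
        )
    if sense.chromosome != antisense.chromosome:
        raise ValueError(
            f"{sense.gene_id}/{antisense.gene_id}: genes are on different chromosomes"
        )


def as_tss_position(sense: GeneRecord, antisense: GeneRecord) -> int:
    """Signed antisense-TSS offset in the sense transcription direction."""
    _check_pairable(sense, antisense)
    if sense.strand == "+":
        return tss(antisense) - tss(sense)
    return tss(sense) - tss(antisense)


def as_tes_position(sense: GeneRecord, antisense: GeneRecord) -> int:
    """Signed antisense-TES offset in the sense transcription direction."""
    _check_pairable(sense, antisense)
    if sense.strand == "+":
        return tes(antisense) - tes(sense)
    return tes(sense) - tes(antisense)


def anchor_window(sense: GeneRecord, spec: ExtractionSpec) -> tuple[int, int]:
    """Closed plus-strand coordinate interval the antisense anchor must occupy.

    The anchor is the antisense TSS (Mode 2) or TES (Mode 3).  For a
    plus-strand sense gene the interval is [anchor+min, anchor+max]; for a
    minus-strand sense gene the offset axis is mirrored, giving
    [anchor−max, anchor−min].  Both ends inclusive.
    """
    if spec.mode is Mode.MODE1_OVERLAP:
        raise ValueError("Mode 1 has no anchor window")
    a = tss(sense) if spec.mode is Mode.MODE2_TSS else tes(sense)
    if sense.strand == "+":
        return (a + spec.window_min, a + spec.window_max)
    return (a - spec.window_max, a - spec.window_min)


# ---------------------------------------------------------------------------
# Classification

_TYPE_CODES = [
    PairType.EB, PairType.HH, PairType.TT, PairType.FO,
    PairType.nHH, PairType.fHH, PairType.nTT, PairType.fTT,
]
_TYPE_STRINGS = np.array([t.value for t in _TYPE_CODES])


def _classify_arrays(
    s_start: np.ndarray,
    s_end: np.ndarray,
    s_plus: np.ndarray,
    a_start: np.ndarray,
    a_end: np.ndarray,
    nearby_threshold: int = NEARBY_THRESHOLD,
) -> np.ndarray:
    """Vectorized classifier; returns integer codes into ``_TYPE_CODES``.

    The antisense strand is by definition opposite the sense strand, so
    its TSS is ``a_end`` when the sense gene is on plus, else ``a_start``.
    Membership of the antisense TSS/TES in the closed sense interval
    decides the overlap types; for disjoint pairs the side (sense-5' vs
    sense-3') and the nearest-end gap decide nearby vs faraway.
    """
    a_tss = np.where(s_plus, a_end, a_start)
    a_tes = np.where(s_plus, a_start, a_end)
    in_tss = (s_start <= a_tss) & (a_tss <= s_end)
    in_tes = (s_start <= a_tes) & (a_tes <= s_end)
    overlap = (a_start <= s_end) & (a_end >= s_start)

    # Disjoint side: upstream of sense = lower coords for plus-sense genes,
    # higher coords for minus-sense genes.  Gap = distance between facing
    # ends (adjacent genes have gap 1).
    left = a_end < s_start
    upstream = np.where(s_plus, left, ~left)
    gap = np.where(left, s_start - a_end, a_start - s_end)
    near = gap <= nearby_threshold

    code = np.full(s_start.shape, -1, dtype=np.int8)
    code[in_tss & in_tes] = 0                      # EB
    code[in_tss & ~in_tes] = 1                     # HH
    code[~in_tss & in_tes] = 2                     # TT
    code[~in_tss & ~in_tes & overlap] = 3          # FO
    code[~overlap & upstream & near] = 4           # nHH
    code[~overlap & upstream & ~near] = 5          # fHH
    code[~overlap & ~upstream & near] = 6          # nTT
    code[~overlap & ~upstream & ~near] = 7         # fTT
    return code


def classify_pair(
    sense: GeneRecord,
    antisense: GeneRecord,
    nearby_threshold: int = NEARBY_THRESHOLD,
) -> PairType:
    """Classify one sense/antisense pair into one of the eight types.

    Overlapping pairs are typed by membership of the antisense TSS/TES in
    the closed sense interval (both in → EB, TSS only → HH, TES only → TT,
    neither but overlapping → FO).  Disjoint pairs are head-to-head when
    the antisense lies on the sense gene's 5' side and tail-to-tail on the
    3' side, "nearby" when the nearest-end gap is ≤ ``nearby_threshold``
    (adjacent genes have gap 1), else "faraway".
    """
    _check_pairable(sense, antisense)
    code = _classify_arrays(
        np.array([sense.start]), np.array([sense.end]),
        np.array([sense.strand == "+"]),
        np.array([antisense.start]), np.array([antisense.end]),
        nearby_threshold,
    )
    return _TYPE_CODES[int(code[0])]


# ---------------------------------------------------------------------------
# Extraction

def _strand_indices(df: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
    """Row indices grouped by (chromosome, strand)."""
    groups: dict[tuple[str, str], np.ndarray] = {}
    for key, sub in df.groupby(["Chr", "Strand"], sort=False):
        groups[key] = sub.index.to_numpy()
    return groups


def _emit_pairs(
    table: GeneTable,
    sense_idx: np.ndarray,
    as_idx: np.ndarray,
    nearby_threshold: int,
) -> pd.DataFrame:
    """Assemble the annotated pair table for index pairs (sense, antisense)."""
    df = table.df
    s = df.iloc[sense_idx].reset_index(drop=True)
    a = df.iloc[as_idx].reset_index(drop=True)
    s_start = s["Start"].to_numpy()
    s_end = s["End"].to_numpy()
    s_plus = (s["Strand"] == "+").to_numpy()
    a_start = a["Start"].to_numpy()
    a_end = a["End"].to_numpy()

    a_tss = np.where((a["Strand"] == "+").to_numpy(), a_start, a_end)
    a_tes = np.where((a["Strand"] == "+").to_numpy(), a_end, a_start)
    s_tss = np.where(s_plus, s_start, s_end)
    s_tes = np.where(s_plus, s_end, s_start)
    sign = np.where(s_plus, 1, -1)
    tss_off = sign * (a_tss - s_tss)
    tes_off = sign * (a_tes - s_tes)
    codes = _classify_arrays(s_start, s_end, s_plus, a_start, a_end, nearby_threshold)

    out = pd.DataFrame(
        {
            "sense_gene_id": s["gene_id"].to_numpy(),
            "sense_symbol": s["GeneSymbol"].to_numpy(),
            "sense_biotype": s["Biotype"].to_numpy(),
            "sense_chr": s["Chr"].to_numpy(),
            "sense_strand": s["Strand"].to_numpy(),
            "sense_start": s_start,
            "sense_end": s_end,
            "as_gene_id": a["gene_id"].to_numpy(),
            "as_symbol": a["GeneSymbol"].to_numpy(),
            "as_biotype": a["Biotype"].to_numpy(),
            "as_strand": a["Strand"].to_numpy(),
            "as_start": a_start,
            "as_end": a_end,
            "Type": _TYPE_STRINGS[codes] if len(codes) else np.array([], dtype=object),
            "AS_TSS_position": tss_off.astype(np.int64),
            "AS_TES_position": tes_off.astype(np.int64),
        }
    )
    extra = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    for c in extra:
        out[f"sense_{c}"] = s[c].to_numpy()
    for c in extra:
        out[f"as_{c}"] = a[c].to_numpy()
    out = out.sort_values(
        ["sense_chr", "sense_start", "sense_gene_id", "as_gene_id"],
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def _empty_pairs(table: GeneTable) -> pd.DataFrame:
    return _emit_pairs(
        table, np.array([], dtype=np.int64), np.array([], dtype=np.int64),
        NEARBY_THRESHOLD,
    )


def extract_mode1(
    table: GeneTable, nearby_threshold: int = NEARBY_THRESHOLD
) -> pd.DataFrame:
    """All overlapping opposite-strand pairs (the four cis-NAT types).

    Two directional sweeps — every plus-strand gene as sense against
    minus-strand genes, then the reverse — are concatenated, so each
    qualifying gene pair appears twice, once per sense role.  Pair types
    are in {HH, EB, FO, TT} by construction.
    """
    df = table.df
    groups = _strand_indices(df)
    starts = df["Start"].to_numpy()
    ends = df["End"].to_numpy()
    sense_out: list[np.ndarray] = []
    as_out: list[np.ndarray] = []
    chroms = df["Chr"].unique()
    for chrom in chroms:
        plus = groups.get((chrom, "+"), np.array([], dtype=np.int64))
        minus = groups.get((chrom, "-"), np.array([], dtype=np.int64))
        if len(plus) == 0 or len(minus) == 0:
            continue
        for sense_ids, anti_ids in ((plus, minus), (minus, plus)):
            tree = IntervalTree()
            for i in anti_ids:
                tree.addi(int(starts[i]), int(ends[i]) + 1, int(i))  # half-open
            for i in sense_ids:
                hits = tree.overlap(int(starts[i]), int(ends[i]) + 1)
                if hits:
                    js = np.fromiter((h.data for h in hits), dtype=np.int64)
                    sense_out.append(np.full(len(js), i, dtype=np.int64))
                    as_out.append(js)
    if not sense_out:
        return _empty_pairs(table)
    return _emit_pairs(
        table, np.concatenate(sense_out), np.concatenate(as_out), nearby_threshold
    )


def _extract_window(
    table: GeneTable,
    mode: Mode,
    window_min: int,
    window_max: int,
    nearby_threshold: int,
) -> pd.DataFrame:
    spec = ExtractionSpec(mode, window_min, window_max)  # validates the window
    df = table.df
    groups = _strand_indices(df)
    starts = df["Start"].to_numpy()
    ends = df["End"].to_numpy()
    plus_strand = (df["Strand"] == "+").to_numpy()
    # Anchor coordinate of every gene in its potential antisense role.
    if mode is Mode.MODE2_TSS:
        anchors = np.where(plus_strand, starts, ends)
    else:
        anchors = np.where(plus_strand, ends, starts)

    sense_out: list[np.ndarray] = []
    as_out: list[np.ndarray] = []
    for chrom in df["Chr"].unique():
        for s_strand, a_strand in (("+", "-"), ("-", "+")):
            sense_ids = groups.get((chrom, s_strand), None)
            anti_ids = groups.get((chrom, a_strand), None)
            if sense_ids is None or anti_ids is None:
                continue
            order = np.argsort(anchors[anti_ids], kind="mergesort")
            anti_sorted = anti_ids[order]
            coords = anchors[anti_sorted]
            # Per-sense closed coordinate interval for the antisense anchor.
            base = np.where(
                plus_strand[sense_ids],
                starts[sense_ids] if mode is Mode.MODE2_TSS else ends[sense_ids],
                ends[sense_ids] if mode is Mode.MODE2_TSS else starts[sense_ids],
            )
            plus_sense = plus_strand[sense_ids]
            lo = np.where(plus_sense, base + window_min, base - window_max)
            hi = np.where(plus_sense, base + window_max, base - window_min)
            first = np.searchsorted(coords, lo, side="left")
            last = np.searchsorted(coords, hi, side="right")
            counts = last - first
            keep = counts > 0
            if not keep.any():
                continue
            reps = counts[keep]
            sense_rep = np.repeat(sense_ids[keep], reps)
            offsets = np.concatenate(
                [np.arange(f, l) for f, l in zip(first[keep], last[keep])]
            )
            sense_out.append(sense_rep)
            as_out.append(anti_sorted[offsets])
    if not sense_out:
        return _empty_pairs(table)
    return _emit_pairs(
        table, np.concatenate(sense_out), np.concatenate(as_out), nearby_threshold
    )


def extract_mode2(
    table: GeneTable,
    window_min: int,
    window_max: int,
    nearby_threshold: int = NEARBY_THRESHOLD,
) -> pd.DataFrame:
    """TSS-comparison extraction: pairs with AS_TSS_position in the window.

    Returns every ordered opposite-strand, same-chromosome pair whose
    antisense TSS offset lies in the closed window [window_min,
    window_max], annotated with its structural type and both offsets.
    """
    return _extract_window(table, Mode.MODE2_TSS, window_min, window_max,
                           nearby_threshold)


def extract_mode3(
    table: GeneTable,
    window_min: int,
    window_max: int,
    nearby_threshold: int = NEARBY_THRESHOLD,
) -> pd.DataFrame:
    """TES-comparison extraction: pairs with AS_TES_position in the window."""
    return _extract_window(table, Mode.MODE3_TES, window_min, window_max,
                           nearby_threshold)
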
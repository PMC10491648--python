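"""Binned divergent/convergent landscape profiles and biotype combo counts.

The landscape question: what fraction of genes has an antisense partner
whose TSS (divergent side) or TES (convergent side) falls in each 500-bp
bin of the ±5-kb neighbourhood of the gene's own TSS/TES?  Counting is
per distinct sense gene (a gene with two antisense anchors in one bin
counts once there) and the denominator is the full biotype-filtered gene
set, so bin values are directly comparable across species and biotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import GeneTable
from .pair_engine import NEARBY_THRESHOLD, extract_mode2, extract_mode3

#: Sentinel biotype filter meaning "keep all biotypes".
ALL_BIOTYPES = "all"


def make_bins(range_bp: int = 5000, width_bp: int = 500) -> list[tuple[int, int]]:
    """Closed signed-offset bins tiling [−range_bp, range_bp−1].

    Upstream bins end at −1 ([−5000, −4501] … [−500, −1]) and downstream
    bins start at 0 ([0, 499] … [4500, 4999]), so an antisense anchor
    coincident with the sense anchor (offset 0) lands in the first
    downstream bin.  With the defaults this yields the canonical 20
    sections of 500 bp.
    """
    if range_bp <= 0 or width_bp <= 0:
        raise ValueError("range_bp and width_bp must be positive")
    if range_bp % width_bp != 0:
        raise ValueError(
            f"range_bp ({range_bp}) must be divisible by width_bp ({width_bp})"
        )
    edges = range(-range_bp, range_bp, width_bp)
    return [(lo, lo + width_bp - 1) for lo in edges]


def _apply_biotype_filters(pairs: pd.DataFrame, sense_biotypes, antisense_biotypes):
    out = pairs
    if sense_biotypes != ALL_BIOTYPES:
        out = out[out["sense_biotype"].isin(set(sense_biotypes))]
    if antisense_biotypes != ALL_BIOTYPES:
        out = out[out["as_biotype"].isin(set(antisense_biotypes))]
    return out


@dataclass
class BinnedProfile:
    """Per-bin distinct-sense-gene counts and percentages.

    ``anchor`` is "TSS" (divergent side) or "TES" (convergent side);
    ``denominator`` is the number of genes passing the sense-biotype
    filter, whether or not they have any antisense partner.
    """

    anchor: str
    bins: list[tuple[int, int]]
    counts: list[int]
    denominator: int

    @property
    def percentages(self) -> list[float]:
        return [100.0 * c / self.denominator for c in self.counts]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lo": [b[0] for b in self.bins],
                "hi": [b[1] for b in self.bins],
                "count": self.counts,
                "denominator": self.denominator,
                "percentage": self.percentages,
            }
        )


def profile(
    table: GeneTable,
    anchor: str = "TSS",
    range_bp: int = 5000,
    width_bp: int = 500,
    sense_biotypes=ALL_BIOTYPES,
    antisense_biotypes=ALL_BIOTYPES,
    nearby_threshold: int = NEARBY_THRESHOLD,
) -> BinnedProfile:
    """Binned profile of antisense-anchor occupancy around sense anchors.

    Runs the TSS-window (anchor="TSS") or TES-window (anchor="TES")
    extraction over the closed offset window [−range_bp, range_bp−1],
    restricts pairs by biotype, and counts per bin the number of distinct
    sense genes with at least one qualifying antisense anchor.
    """
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be 'TSS' or 'TES'")
    bins = make_bins(range_bp, width_bp)
    extractor = extract_mode2 if anchor == "TSS" else extract_mode3
    pairs = extractor(table, -range_bp, range_bp - 1,
                      nearby_threshold=nearby_threshold)
    pairs = _apply_biotype_filters(pairs, sense_biotypes, antisense_biotypes)

    if sense_biotypes == ALL_BIOTYPES:
        denominator = len(table)
    else:
        denominator = int(table.df["Biotype"].isin(set(sense_biotypes)).sum())
    if denominator == 0:
        raise ValueError("no genes pass the sense-biotype filter (denominator 0)")

    offcol = "AS_TSS_position" if anchor == "TSS" else "AS_TES_position"
    counts = []
    for lo, hi in bins:
        in_bin = pairs[(pairs[offcol] >= lo) & (pairs[offcol] <= hi)]
        counts.append(int(in_bin["sense_gene_id"].nunique()))
    return BinnedProfile(anchor=anchor, bins=bins, counts=counts,
                         denominator=denominator)


def combo_counts(
    pairs: pd.DataFrame,
    bins: list[tuple[int, int]],
    anchor: str = "TSS",
) -> pd.DataFrame:
    """Distinct-sense-gene counts per (sense biotype, antisense biotype, bin).

    One row per occupied cell, columns ``sense_biotype, as_biotype, lo,
    hi, count``.  Ratios between cells (e.g. lncRNA-antisense vs
    coding-antisense at the divergent peak) are computed by the caller.
    """
    offcol = "AS_TSS_position" if anchor == "TSS" else "AS_TES_position"
    rows = []
    for lo, hi in bins:
        in_bin = pairs[(pairs[offcol] >= lo) & (pairs[offcol] <= hi)]
        if in_bin.empty:
            continue
        grouped = in_bin.groupby(["sense_biotype", "as_biotype"], sort=True)[
            "sense_gene_id"
        ].nunique()
        for (sb, ab), n in grouped.items():
            rows.append((sb, ab, lo, hi, int(n)))
    return pd.DataFrame(
        rows, columns=["sense_biotype", "as_biotype", "lo", "hi", "count"]
    )
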
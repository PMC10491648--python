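"""Core domain types: genes, gene tables, and pair-type vocabulary.

Coordinates are 1-based, closed intervals on the plus strand throughout
(the GTF convention); ``start <= end`` regardless of strand.  A gene's
transcription start site (TSS) is ``start`` on the plus strand and ``end``
on the minus strand; the transcript end site (TES) is the other end.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import pandas as pd

#: Canonical gene-table CSV columns, in order.
CANONICAL_COLUMNS = [
    "gene_id",
    "GeneSymbol",
    "Chr",
    "Strand",
    "Start",
    "End",
    "Biotype",
    "gene_source",
]


class Strand(str, enum.Enum):
    PLUS = "+"
    MINUS = "-"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class PairType(str, enum.Enum):
    """Structural classes of a sense/antisense gene pair.

    Overlapping (cis-NAT) types:

    - ``HH``: head-to-head, the genes overlap only at their 5' ends
      (the antisense TSS lies inside the sense gene).
    - ``EB``: embedded, the antisense gene lies entirely inside the sense.
    - ``FO``: fully overlapped, the antisense gene covers the sense.
    - ``TT``: tail-to-tail, overlap only at the 3' ends (the antisense
      TES lies inside the sense gene).

    Non-overlapping types, split at a 5-kb gap ("nearby" vs "faraway"):

    - ``nHH`` / ``fHH``: the antisense gene lies entirely upstream of the
      sense gene (divergent transcription, the 5' ends face each other).
    - ``nTT`` / ``fTT``: entirely downstream (convergent transcription).
    """

    HH = "HH"
    EB = "EB"
    FO = "FO"
    TT = "TT"
    fHH = "fHH"
    nHH = "nHH"
    fTT = "fTT"
    nTT = "nTT"


#: Overlapping (cis-NAT) subset.
OVERLAP_TYPES = frozenset({PairType.HH, PairType.EB, PairType.FO, PairType.TT})


class GeneRecord(NamedTuple):
    """One annotated gene, the unit of all pairwise comparisons."""

    gene_id: str
    symbol: str
    chromosome: str
    strand: str  # "+" or "-"
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    biotype: str
    gene_source: str

    def validate(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start ({self.start}) > end ({self.end})"
            )


@dataclass
class GeneTable:
    """An ordered collection of genes backed by a pandas DataFrame.

    ``df`` always carries the canonical columns (``gene_id``, ``GeneSymbol``,
    ``Chr``, ``Strand``, ``Start``, ``End``, ``Biotype``, ``gene_source``);
    extra columns (``TPM_*``, ``padj``) ride along opaquely.  ``provenance``
    records where the table came from (source file, genome build string).
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"gene table missing mandatory column(s): {missing}")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: list[GeneRecord], provenance: dict | None = None
    ) -> "GeneTable":
        df = pd.DataFrame(
            [
                (r.gene_id, r.symbol, r.chromosome, r.strand, r.start, r.end,
                 r.biotype, r.gene_source)
                for r in records
            ],
            columns=CANONICAL_COLUMNS,
        )
        if not records:
            df = df.astype({"Start": "int64", "End": "int64"})
        return cls(df, provenance or {})

    def records(self) -> Iterator[GeneRecord]:
        for row in self.df.itertuples(index=False):
            yield GeneRecord(
                gene_id=row.gene_id,
                symbol="" if pd.isna(row.GeneSymbol) else str(row.GeneSymbol),
                chromosome=str(row.Chr),
                strand=str(row.Strand),
                start=int(row.Start),
                end=int(row.End),
                biotype="" if pd.isna(row.Biotype) else str(row.Biotype),
                gene_source="" if pd.isna(row.gene_source) else str(row.gene_source),
            )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneTable):
            return NotImplemented
        return list(self.records()) == list(other.records())
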
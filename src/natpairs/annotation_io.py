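"""Reading, validating and writing gene annotation tables.

Input is either an Ensembl-style GTF (only ``feature == "gene"`` lines are
used; one representative start/end per gene) or the canonical gene-table
CSV with columns ``gene_id, GeneSymbol, Chr, Strand, Start, End, Biotype,
gene_source`` plus optional ``TPM_<sample>`` / ``padj`` pass-through
columns.  Per-sample TPM expression is attached by ``gene_id`` only —
symbols are not unique in real annotations and are never used as keys.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
import pandas as pd

from .types import CANONICAL_COLUMNS, GeneRecord, GeneTable

#: Sentinel for filter_gene_source meaning "keep every source".
ALL_SOURCES = "all"

_CSV_HEADER_COMMENT = (
    "# natpairs gene table: 1-based closed coordinates (GTF convention); "
    "Strand is '+' or '-'"
)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """A malformed GTF line (wrong column count, missing gene_id, bad strand)."""


def _open_text(source: Union[str, Path, IO]) -> IO:
    """Open a path (gzip-transparent) or pass a stream through."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, "rt", encoding="utf-8")
        return open(path, "rt", encoding="utf-8")
    return source


def parse_gtf_genes(source: Union[str, Path, IO, Iterable[str]]) -> GeneTable:
    """Parse ``feature == "gene"`` lines of a GTF into a :class:`GeneTable`.

    Accepts a path (optionally gzip-compressed), an open text stream, or an
    iterable of lines.  Start/end are taken verbatim (GTF is 1-based,
    inclusive).  The attributes ``gene_id`` (mandatory), ``gene_name``,
    ``gene_biotype`` and ``gene_source`` are extracted; a missing
    ``gene_name`` yields an empty symbol, never the gene_id.  Lines whose
    feature column is anything else (transcript, exon, CDS, ...) are
    ignored, as are ``#`` comment lines.

    Raises
    ------
    GtfParseError
        On a line with fewer than 9 tab-separated columns, a gene line
        without a ``gene_id`` attribute, or a gene line with strand other
        than ``+``/``-`` (antisense logic is undefined without strand).
    """
    stream = _open_text(source)  # iterables of lines iterate the same way
    records: list[GeneRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
            )
        seqname, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
        if feature != "gene":
            continue
        attr = dict(_ATTR_RE.findall(attrs))
        if "gene_id" not in attr or not attr["gene_id"]:
            raise GtfParseError(f"line {lineno}: gene feature without gene_id")
        if strand not in ("+", "-"):
            raise GtfParseError(
                f"line {lineno}: gene {attr['gene_id']} has strand {strand!r}; "
                "only '+'/'-' are supported"
            )
        records.append(
            GeneRecord(
                gene_id=attr["gene_id"],
                symbol=attr.get("gene_name", ""),
                chromosome=seqname,
                strand=strand,
                start=int(start),
                end=int(end),
                biotype=attr.get("gene_biotype", ""),
                gene_source=attr.get("gene_source", ""),
            )
        )
    name = getattr(source, "name", None) or (
        str(source) if isinstance(source, (str, Path)) else ""
    )
    return GeneTable.from_records(records, provenance={"source": name})


def filter_gene_source(table: GeneTable, allowed_sources) -> GeneTable:
    """Keep genes whose ``gene_source`` is in ``allowed_sources``.

    ``allowed_sources`` may be the sentinel ``"all"`` (identity) or a
    set/iterable of source strings.  Order is preserved; an empty result is
    permitted.  Used to deduplicate annotations that list the same gene
    under several sources (e.g. keeping only ENA or PomBase entries).
    """
    if allowed_sources == ALL_SOURCES:
        return GeneTable(table.df.copy(), dict(table.provenance))
    allowed = set(allowed_sources)
    if not allowed:
        raise ValueError("allowed_sources must be non-empty or the sentinel 'all'")
    out = table.df[table.df["gene_source"].isin(allowed)].reset_index(drop=True)
    return GeneTable(out, dict(table.provenance))


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_gene_table`.

    Duplicate gene_ids, malformed coordinates and unknown strands are
    violations (the table must not be used downstream); duplicate symbols
    are expected in real annotations and only warned about.
    """

    duplicate_ids: list = field(default_factory=list)
    coordinate_violations: list = field(default_factory=list)
    strand_violations: list = field(default_factory=list)
    duplicate_symbol_warnings: list = field(default_factory=list)

    @property
    def violations(self) -> list:
        return self.duplicate_ids + self.coordinate_violations + self.strand_violations

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_gene_table(table: GeneTable) -> ValidationReport:
    """Check gene_id uniqueness, coordinate sanity and strand codes."""
    df = table.df
    report = ValidationReport()
    dup_ids = df["gene_id"][df["gene_id"].duplicated(keep=False)].unique()
    report.duplicate_ids = sorted(dup_ids)
    bad_coord = df[(df["Start"] > df["End"]) | (df["Start"] < 1)]
    report.coordinate_violations = list(bad_coord["gene_id"])
    bad_strand = df[~df["Strand"].isin(["+", "-"])]
    report.strand_violations = list(bad_strand["gene_id"])
    symbols = df["GeneSymbol"].astype(str)
    nonempty = symbols != ""
    dup_syms = symbols[nonempty][symbols[nonempty].duplicated(keep=False)].unique()
    report.duplicate_symbol_warnings = sorted(dup_syms)
    return report


def read_gene_table_csv(source: Union[str, Path, IO]) -> GeneTable:
    """Read the canonical gene-table CSV (``#`` comment lines skipped).

    Extra columns (``TPM_*``, ``padj``, ...) are carried through opaquely.

    Raises
    ------
    ValueError
        Naming the column, if a mandatory column is missing; naming the
        row, if Start/End are not integers.
    """
    stream = _open_text(source)
    df = pd.read_csv(stream, comment="#", dtype={"gene_id": str})
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table CSV missing mandatory column(s): {missing}")
    for col in ("Start", "End"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise ValueError(f"non-integer {col} at CSV row {row}")
        df[col] = numeric.astype("int64")
    df["GeneSymbol"] = df["GeneSymbol"].fillna("").astype(str)
    name = getattr(source, "name", None) or (
        str(source) if isinstance(source, (str, Path)) else ""
    )
    return GeneTable(df, provenance={"source": name})


def write_gene_table_csv(table: GeneTable, dest: Union[str, Path, IO, None] = None):
    """Write the canonical CSV; returns the text when ``dest`` is None.

    The coordinate convention is recorded in a leading ``#`` comment that
    :func:`read_gene_table_csv` skips, so the round trip is lossless.
    """
    buf = io.StringIO()
    buf.write(_CSV_HEADER_COMMENT + "\n")
    table.df.to_csv(buf, index=False)
    text = buf.getvalue()
    if dest is None:
        return text
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)
    return None


@dataclass
class ExpressionMatrix:
    """Per-gene TPM values over ordered samples, keyed by gene_id.

    ``df`` is indexed by gene_id with one column per sample label
    (``<timepoint>_<replicate>``); ``padj`` (if present on input) is kept
    separately.  TPM values must be non-negative.
    """

    df: pd.DataFrame
    padj: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id in expression matrix: {dups}")
        if (self.df.to_numpy() < 0).any():
            raise ValueError("TPM values must be >= 0")

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def timepoint_means(self) -> pd.DataFrame:
        """Average replicate columns into per-time-point means.

        Sample labels are ``<timepoint>_<replicate>``; the time point is
        everything before the last underscore (a label without an
        underscore is its own time point).  Column order follows first
        appearance, preserving the recorded time course.
        """
        tps: list[str] = []
        for s in self.samples:
            tp = s.rsplit("_", 1)[0] if "_" in s else s
            if tp not in tps:
                tps.append(tp)
        cols = {
            tp: self.df[
                [s for s in self.samples
                 if (s.rsplit("_", 1)[0] if "_" in s else s) == tp]
            ].mean(axis=1)
            for tp in tps
        }
        return pd.DataFrame(cols, index=self.df.index)


def read_expression_csv(source: Union[str, Path, IO]) -> ExpressionMatrix:
    """Read a TPM matrix CSV/TSV: first column gene_id, one column per sample."""
    stream = _open_text(source)
    df = pd.read_csv(stream, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    padj = None
    if "padj" in df.columns:
        padj = df.pop("padj")
    return ExpressionMatrix(df.astype(float), padj)


def attach_expression(table: GeneTable, expr: ExpressionMatrix) -> GeneTable:
    """Left-join TPM columns (as ``TPM_<sample>``) onto the gene table.

    The join key is ``gene_id`` only.  Genes absent from ``expr`` get NaN;
    expression rows whose id is not in the table are ignored.
    """
    tpm = expr.df.add_prefix("TPM_")
    out = table.df.merge(tpm, left_on="gene_id", right_index=True, how="left")
    if expr.padj is not None:
        out = out.merge(
            expr.padj.rename("padj"), left_on="gene_id", right_index=True, how="left"
        )
    return GeneTable(out, dict(table.provenance))


def tpm_matrix_from_table(table: GeneTable) -> ExpressionMatrix:
    """Recover an :class:`ExpressionMatrix` from ``TPM_*`` columns of a table."""
    tpm_cols = [c for c in table.df.columns if c.startswith("TPM_")]
    if not tpm_cols:
        raise ValueError("gene table carries no TPM_* columns")
    df = table.df.set_index("gene_id")[tpm_cols]
    df.columns = [c[len("TPM_"):] for c in tpm_cols]
    padj = (
        table.df.set_index("gene_id")["padj"] if "padj" in table.df.columns else None
    )
    return ExpressionMatrix(df.astype(float).dropna(how="any"), padj)
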
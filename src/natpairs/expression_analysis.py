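"""Expression-correlation screen for functional sense/antisense pairs.

Given a TPM time course, the screen (i) keeps "expressing" genes — TPM
above a threshold at one or more time points and never zero, (ii)
computes the Spearman rank correlation of each pair's sense and antisense
trajectories, (iii) compares correlation across distance groups and
against a random same-chromosome pair null using the Dwass–Steel–
Critchlow–Fligner (DSCF, "Steel–Dwass") all-pairs rank test, and (iv)
selects candidates with strong positive (rho > 0.9) or negative
(rho < −0.7) correlation.

Replicate columns are averaged into per-time-point means before both the
expressing-gene filter and the correlations (a ``time_point_means=False``
switch uses raw sample columns instead).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import ExpressionMatrix
from .types import GeneTable

logger = logging.getLogger(__name__)


def select_expressing(
    expr: ExpressionMatrix,
    min_tpm: float = 1.0,
    time_point_means: bool = True,
) -> set[str]:
    """Gene ids whose trajectory exceeds ``min_tpm`` somewhere and is never 0.

    With ``time_point_means`` (default) replicate columns are first
    averaged per time point; the filter then requires a mean TPM >
    ``min_tpm`` at at least one time point and a nonzero mean at every
    time point.
    """
    prof = expr.timepoint_means() if time_point_means else expr.df
    vals = prof.to_numpy()
    keep = (vals > min_tpm).any(axis=1) & (vals != 0).all(axis=1)
    return set(prof.index[keep])


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average-ranked data.

    Ties receive average ranks.  A constant series has no rank ordering,
    so the correlation is undefined and NaN is returned (never 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 points for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def pair_correlations(
    pairs: pd.DataFrame,
    expr: ExpressionMatrix,
    time_point_means: bool = True,
) -> pd.DataFrame:
    """Spearman rho of sense vs antisense trajectories, one row per pair.

    Pairs with a gene absent from ``expr`` are skipped (logged); pairs
    with an undefined rho (a constant trajectory) keep a NaN ``rho`` and
    are dropped by downstream grouping.  Adds ``rho`` and ``n_points``
    columns to a copy of ``pairs``.
    """
    prof = expr.timepoint_means() if time_point_means else expr.df
    have = set(prof.index)
    present = pairs["sense_gene_id"].isin(have) & pairs["as_gene_id"].isin(have)
    n_skipped = int((~present).sum())
    if n_skipped:
        logger.info("pair_correlations: skipped %d pair(s) lacking expression",
                    n_skipped)
    kept = pairs[present].reset_index(drop=True)
    mat = prof.to_numpy()
    idx = {g: i for i, g in enumerate(prof.index)}
    rhos = np.empty(len(kept))
    for i, (sg, ag) in enumerate(zip(kept["sense_gene_id"], kept["as_gene_id"])):
        x = mat[idx[sg]]
        y = mat[idx[ag]]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rhos[i] = np.nan
        else:
            rhos[i] = stats.spearmanr(x, y)[0]
    out = kept.copy()
    out["rho"] = rhos
    out["n_points"] = prof.shape[1]
    return out


def bin_pairs_by_count(
    records: pd.DataFrame,
    offset_col: str = "AS_TSS_position",
    bin_size: int = 100,
) -> list[pd.DataFrame]:
    """Cut offset-sorted pairs into consecutive groups of ``bin_size``.

    Records are sorted by the signed offset and grouped 100 at a time
    (default); every record tied at a group's boundary offset joins that
    group, so groups may exceed ``bin_size`` at the edge of a region.
    Each returned frame carries its offset span in ``.attrs["span"]``.
    """
    if records.empty:
        return []
    srt = records.sort_values(offset_col, kind="mergesort").reset_index(drop=True)
    offs = srt[offset_col].to_numpy()
    groups = []
    i = 0
    n = len(srt)
    while i < n:
        j = min(i + bin_size, n)
        while j < n and offs[j] == offs[j - 1]:
            j += 1
        g = srt.iloc[i:j].reset_index(drop=True)
        g.attrs["span"] = (int(offs[i]), int(offs[j - 1]))
        groups.append(g)
        i = j
    return groups


def nearest_pairs(
    records: pd.DataFrame,
    n: int = 400,
    offset_col: str = "AS_TSS_position",
) -> pd.DataFrame:
    """The ``n`` pairs with smallest absolute offset (anchor-proximal set).

    Records tied at the n-th absolute offset are all included, so the
    result may exceed ``n``.  With fewer than ``n`` records the whole
    input is returned with a warning.
    """
    if len(records) < n:
        warnings.warn(
            f"nearest_pairs: only {len(records)} records available (< n={n})",
            stacklevel=2,
        )
        return records.reset_index(drop=True)
    absoff = records[offset_col].abs()
    srt = records.assign(_abs=absoff).sort_values(
        ["_abs", offset_col], kind="mergesort"
    )
    cutoff = srt["_abs"].iloc[n - 1]
    out = srt[srt["_abs"] <= cutoff].drop(columns="_abs")
    return out.reset_index(drop=True)


def random_chromosome_pairs(
    table: GeneTable,
    expr: ExpressionMatrix,
    n: int = 400,
    seed: int = 0,
    min_tpm: float = 1.0,
    time_point_means: bool = True,
) -> pd.DataFrame:
    """Null model: random same-chromosome, opposite-strand expressing pairs.

    Each of the ``n`` pairs draws one expressing gene uniformly (from
    chromosomes with at least one expressing gene on each strand) and a
    distinct partner uniformly from the opposite strand of the same
    chromosome; chromosomes lacking two eligible opposite-strand genes
    never contribute.  Fully reproducible from ``seed``.  Returns a frame
    with gene ids, chromosome and ``rho``.
    """
    rng = np.random.default_rng(seed)
    expressing = select_expressing(expr, min_tpm=min_tpm,
                                   time_point_means=time_point_means)
    df = table.df[table.df["gene_id"].isin(expressing)]
    eligible: dict[str, dict[str, list[str]]] = {}
    for chrom, sub in df.groupby("Chr", sort=True):
        plus = sorted(sub.loc[sub["Strand"] == "+", "gene_id"])
        minus = sorted(sub.loc[sub["Strand"] == "-", "gene_id"])
        if plus and minus:
            eligible[chrom] = {"+": plus, "-": minus}
    if not eligible:
        raise ValueError("no chromosome has expressing genes on both strands")
    # Uniform over genes on eligible chromosomes, then a uniform
    # opposite-strand partner from the same chromosome.
    pool = [
        (chrom, strand, g)
        for chrom in sorted(eligible)
        for strand in ("+", "-")
        for g in eligible[chrom][strand]
    ]
    prof = expr.timepoint_means() if time_point_means else expr.df
    rows = []
    for _ in range(n):
        chrom, strand, g1 = pool[rng.integers(len(pool))]
        partners = eligible[chrom]["-" if strand == "+" else "+"]
        g2 = partners[rng.integers(len(partners))]
        x = prof.loc[g1].to_numpy()
        y = prof.loc[g2].to_numpy()
        rho = (
            np.nan
            if np.ptp(x) == 0 or np.ptp(y) == 0
            else stats.spearmanr(x, y)[0]
        )
        rows.append((g1, g2, chrom, rho))
    return pd.DataFrame(rows, columns=["gene_id_1", "gene_id_2", "Chr", "rho"])


# ---------------------------------------------------------------------------
# Dwass–Steel–Critchlow–Fligner all-pairs comparison


@dataclass
class GroupComparison:
    """All-pairs DSCF result: symmetric statistic and p-value matrices."""

    labels: list[str]
    statistic: pd.DataFrame  # studentized-range-scale statistic q
    p_value: pd.DataFrame
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        sig = self.p_value < self.alpha
        np.fill_diagonal(sig.values, False)
        return sig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, gi in enumerate(self.labels):
            for gj in self.labels[i + 1:]:
                rows.append(
                    (gi, gj, self.statistic.loc[gi, gj], self.p_value.loc[gi, gj],
                     bool(self.p_value.loc[gi, gj] < self.alpha))
                )
        return pd.DataFrame(
            rows, columns=["group_i", "group_j", "statistic", "p", "significant"]
        )


def dscf_pairwise_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Studentized two-sample rank statistic of one group pair.

    The two samples are pooled and mid-ranked; the Mann–Whitney count of
    the smaller side is centred at its null mean (with a 0.5 continuity
    correction for the discreteness of ranks) and divided by the
    tie-corrected null standard deviation; the result is put on the
    studentized-range scale (×√2).  Identical groups give 0.
    """
    ni, nj = len(x), len(y)
    s = ni + nj
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_i = np.sum(ranks[:ni]) - ni * (ni + 1) / 2
    u_j = np.sum(ranks[ni:]) - nj * (nj + 1) / 2
    u_min = min(u_i, u_j)
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    ties = np.sum((counts**3 - counts) / 12.0)
    var = ni * nj / (s * (s - 1.0)) * ((s**3 - s) / 12.0 - ties)
    if var <= 0:
        return 0.0
    # u_min never exceeds the null mean; the correction shrinks toward 0.
    z = min(u_min + 0.5 - ni * nj / 2.0, 0.0) / np.sqrt(var)
    return float(np.sqrt(2.0) * abs(z))


def steel_dwass(
    groups: dict[str, Sequence[float]] | Sequence[Sequence[float]],
    alpha: float = 0.01,
) -> GroupComparison:
    """DSCF all-pairs comparison of k groups of (correlation) values.

    For every unordered pair of groups a two-sample rank statistic is
    computed on the pooled pair (average ranks, tie-corrected variance)
    and referred to the studentized range distribution over k groups
    (infinite degrees of freedom), which controls the family-wise error
    rate across all k(k−1)/2 comparisons.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        data = [np.asarray(groups[g], dtype=float) for g in labels]
    else:
        labels = [f"group{i}" for i in range(len(groups))]
        data = [np.asarray(g, dtype=float) for g in groups]
    k = len(data)
    if k < 2:
        raise ValueError("steel_dwass needs at least 2 groups")
    for lab, g in zip(labels, data):
        if len(g) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")
        if np.isnan(g).any():
            raise ValueError(f"group {lab!r} contains NaN")

    stat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = dscf_pairwise_statistic(data[i], data[j])
            stat[i, j] = stat[j, i] = q
    iu = np.triu_indices(k, 1)
    pvals = stats.studentized_range.sf(stat[iu], k, np.inf)
    p = np.ones((k, k))
    p[iu] = pvals
    p.T[iu] = pvals
    return GroupComparison(
        labels=labels,
        statistic=pd.DataFrame(stat, index=labels, columns=labels),
        p_value=pd.DataFrame(p, index=labels, columns=labels),
        alpha=alpha,
    )


class CorrelatedSelection(NamedTuple):
    positive: pd.DataFrame
    negative: pd.DataFrame
    export: pd.DataFrame


def select_correlated(
    records: pd.DataFrame,
    pos_cut: float = 0.9,
    neg_cut: float = -0.7,
    expr: ExpressionMatrix | None = None,
    time_point_means: bool = True,
) -> CorrelatedSelection:
    """Split pairs into strongly positive / negative candidates.

    Cutoffs are strict: a pair is positive iff ``rho > pos_cut`` and
    negative iff ``rho < neg_cut``; rho exactly at a cutoff is excluded,
    as are undefined (NaN) correlations.  The export table concatenates
    both lists sorted by rho (descending) and, when ``expr`` is given,
    appends the sense and antisense TPM trajectories — the matrix behind
    a candidate heatmap.
    """
    defined = records[records["rho"].notna()]
    positive = defined[defined["rho"] > pos_cut].sort_values(
        "rho", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    negative = defined[defined["rho"] < neg_cut].sort_values(
        "rho", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    export = pd.concat([positive, negative], ignore_index=True)
    if expr is not None and not export.empty:
        prof = expr.timepoint_means() if time_point_means else expr.df
        for side, col in (("sense", "sense_gene_id"), ("as", "as_gene_id")):
            traj = prof.reindex(export[col]).reset_index(drop=True)
            traj.columns = [f"{side}_TPM_{c}" for c in traj.columns]
            export = pd.concat([export, traj], axis=1)
    return CorrelatedSelection(positive, negative, export)
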
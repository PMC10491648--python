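"""Independent brute-force oracles used to cross-check the pair engine.

Everything here applies the definitions directly — scalar Python, double
loops over all gene pairs, exhaustive permutation enumeration — and
deliberately shares no code path with the package's vectorized /
tree-based implementations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from natpairs.types import GeneRecord, GeneTable


def classify_oracle(s: GeneRecord, a: GeneRecord, nearby: int = 5000) -> str:
    """Scalar restatement of the 8-type definition."""
    a_tss = a.start if a.strand == "+" else a.end
    a_tes = a.end if a.strand == "+" else a.start
    tss_in = s.start <= a_tss <= s.end
    tes_in = s.start <= a_tes <= s.end
    if tss_in and tes_in:
        return "EB"
    if tss_in:
        return "HH"
    if tes_in:
        return "TT"
    if a.start <= s.end and a.end >= s.start:
        return "FO"
    if a.end < s.start:
        gap, left = s.start - a.end, True
    else:
        gap, left = a.start - s.end, False
    upstream = left if s.strand == "+" else not left
    if upstream:
        return "nHH" if gap <= nearby else "fHH"
    return "nTT" if gap <= nearby else "fTT"


def offsets_oracle(s: GeneRecord, a: GeneRecord) -> tuple[int, int]:
    s_tss = s.start if s.strand == "+" else s.end
    s_tes = s.end if s.strand == "+" else s.start
    a_tss = a.start if a.strand == "+" else a.end
    a_tes = a.end if a.strand == "+" else a.start
    sign = 1 if s.strand == "+" else -1
    return sign * (a_tss - s_tss), sign * (a_tes - s_tes)


def brute_force_pairs(
    table: GeneTable,
    mode: int,
    window_min: int | None = None,
    window_max: int | None = None,
    nearby: int = 5000,
) -> set[tuple]:
    """O(n^2) enumeration of every qualifying ordered pair.

    Returns tuples (sense_id, as_id, type, tss_offset, tes_offset).
    """
    recs = list(table.records())
    out = set()
    for s in recs:
        for a in recs:
            if s.gene_id == a.gene_id:
                continue
            if s.chromosome != a.chromosome or s.strand == a.strand:
                continue
            tss_off, tes_off = offsets_oracle(s, a)
            if mode == 1:
                keep = a.start <= s.end and a.end >= s.start
            elif mode == 2:
                keep = window_min <= tss_off <= window_max
            else:
                keep = window_min <= tes_off <= window_max
            if keep:
                out.add(
                    (s.gene_id, a.gene_id, classify_oracle(s, a, nearby),
                     tss_off, tes_off)
                )
    return out


def pairs_frame_to_set(df) -> set[tuple]:
    return {
        (r.sense_gene_id, r.as_gene_id, r.Type,
         int(r.AS_TSS_position), int(r.AS_TES_position))
        for r in df.itertuples(index=False)
    }


def make_random_table(seed: int, n_genes: int, n_chrom: int = 2,
                      span: int = 60_000) -> GeneTable:
    """Dense random gene table: many overlaps and window hits by design."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_genes):
        start = int(rng.integers(1, span))
        length = int(rng.integers(1, 6000))
        recs.append(
            GeneRecord(
                gene_id=f"R{i:05d}",
                symbol=f"r{i}",
                chromosome=f"chr{int(rng.integers(1, n_chrom + 1))}",
                strand="+" if rng.random() < 0.5 else "-",
                start=start,
                end=start + length - 1,
                biotype=["protein_coding", "lncRNA", "pseudogene"][
                    int(rng.integers(3))
                ],
                gene_source="test",
            )
        )
    return GeneTable.from_records(recs)


def rank_sum_statistic_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Studentized rank statistic, written from the formula, scalar style."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    ni, nj = len(x), len(y)
    s = ni + nj
    u_i = sum(ranks[:ni]) - ni * (ni + 1) / 2
    u_j = sum(ranks[ni:]) - nj * (nj + 1) / 2
    tie_counts = {}
    for v in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    ties = sum((t**3 - t) / 12.0 for t in tie_counts.values())
    var = ni * nj / (s * (s - 1.0)) * ((s**3 - s) / 12.0 - ties)
    if var <= 0:
        return 0.0
    z = min(min(u_i, u_j) + 0.5 - ni * nj / 2.0, 0.0) / np.sqrt(var)
    return float(np.sqrt(2.0) * abs(z))


def dscf_exact_permutation_p(x, y) -> float:
    """Exact permutation p-value of the studentized rank statistic (k=2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    obs = rank_sum_statistic_oracle(x, y)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        q = rank_sum_statistic_oracle(pooled[mask], pooled[~mask])
        count += q >= obs - 1e-12
        total += 1
    return count / total
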
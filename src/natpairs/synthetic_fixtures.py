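"""Seeded generators for synthetic gene tables and expression matrices.

The gene-table generator plants sense/antisense pairs of every structural
type by construction (the constructive inverse of the classifier) on
synthetic chromosomes, separated widely enough that no unintended
opposite-strand relation arises, plus strand-balanced decoy genes far
from every plant.  The expression generator gives each planted pair a
shared smooth latent trajectory (rising then falling, like a gene
up-regulated and then down-regulated over a differentiation time course)
with the antisense partner mirrored for negative plants, so the planted
Spearman sign is exact at zero noise.  All generators are pure functions
of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .annotation_io import ExpressionMatrix
from .types import GeneRecord, GeneTable, PairType
from .pair_engine import NEARBY_THRESHOLD

_BIOTYPES = ["protein_coding", "lncRNA", "pseudogene"]
_BIOTYPE_WEIGHTS = [0.6, 0.3, 0.1]


class TruthLabel(NamedTuple):
    """Ground truth for one planted pair."""

    sense_gene_id: str
    as_gene_id: str
    pair_type: str
    as_tss_position: int
    as_tes_position: int


@dataclass
class FixtureSpec:
    """Parameters of the synthetic gene-table generator.

    ``pairs_per_type`` maps each structural type to a planted count;
    gap bounds must respect the nearby threshold on the correct side
    (nearby gaps in [1, 5000], faraway gaps > 5000).
    """

    pairs_per_type: dict[str, int] = field(
        default_factory=lambda: {t.value: 3 for t in PairType}
    )
    decoy_genes: int = 20
    n_chromosomes: int = 3
    chromosome_length: int = 5_000_000
    gene_length: tuple[int, int] = (200, 8000)
    nearby_gap: tuple[int, int] = (1, NEARBY_THRESHOLD)
    far_gap: tuple[int, int] = (NEARBY_THRESHOLD + 1, 30_000)
    seed: int = 0
    max_retries: int = 1000

    def validate(self) -> None:
        if any(v < 0 for v in self.pairs_per_type.values()) or self.decoy_genes < 0:
            raise ValueError("counts must be >= 0")
        if not (1 <= self.nearby_gap[0] <= self.nearby_gap[1] <= NEARBY_THRESHOLD):
            raise ValueError(
                f"nearby_gap must lie within [1, {NEARBY_THRESHOLD}]"
            )
        if self.far_gap[0] <= NEARBY_THRESHOLD:
            raise ValueError(
                f"far_gap must start above {NEARBY_THRESHOLD}"
            )
        if self.gene_length[0] < 3:
            raise ValueError("gene_length lower bound must be >= 3")


def _reflect(g: GeneRecord, pivot: int) -> GeneRecord:
    """Mirror a gene around ``pivot``: flips strand, preserves pair geometry."""
    return g._replace(
        strand="-" if g.strand == "+" else "+",
        start=pivot - g.end,
        end=pivot - g.start,
    )


def plant_pair(
    pair_type: PairType | str,
    sense_strand: str,
    params: FixtureSpec,
    rng: np.random.Generator,
    origin: int = 100_000,
    chromosome: str = "chrS",
    id_prefix: str = "P",
) -> tuple[GeneRecord, GeneRecord, TruthLabel]:
    """Construct a (sense, antisense) pair classified as ``pair_type``.

    The layout is built for a plus-strand sense gene and mirrored when
    ``sense_strand`` is minus, which preserves every structural type.

    Raises
    ------
    ValueError
        If the requested gap range is infeasible for the type (e.g. a
        nearby type with gaps above the threshold).
    """
    pair_type = PairType(pair_type)
    params.validate()
    lmin, lmax = params.gene_length
    ls = int(rng.integers(lmin, lmax + 1))
    ss, se = origin, origin + ls - 1
    ov_types = {PairType.HH, PairType.TT, PairType.EB, PairType.FO}

    if pair_type is PairType.EB:
        la = int(rng.integers(3, max(4, ls - 1))) if ls > 4 else 3
        a_start = ss + int(rng.integers(1, ls - la)) if ls - la > 1 else ss + 1
        a_end = a_start + la - 1
    elif pair_type is PairType.FO:
        la = int(rng.integers(ls + 2, ls + lmax + 2))
        a_start = ss - int(rng.integers(1, la - ls))
        a_end = a_start + la - 1
        assert a_end > se
    elif pair_type in (PairType.HH, PairType.TT):
        la = int(rng.integers(lmin, lmax + 1))
        ov = int(rng.integers(1, min(ls, la)))  # < both lengths
        if pair_type is PairType.HH:
            a_end = ss + ov - 1
            a_start = a_end - la + 1
        else:
            a_start = se - ov + 1
            a_end = a_start + la - 1
    else:
        la = int(rng.integers(lmin, lmax + 1))
        near = pair_type in (PairType.nHH, PairType.nTT)
        glo, ghi = params.nearby_gap if near else params.far_gap
        if near and glo > NEARBY_THRESHOLD:
            raise ValueError(f"{pair_type.value}: gap range starts above threshold")
        if not near and ghi <= NEARBY_THRESHOLD:
            raise ValueError(f"{pair_type.value}: gap range within nearby threshold")
        gap = int(rng.integers(glo, ghi + 1))
        if pair_type in (PairType.nHH, PairType.fHH):
            a_end = ss - gap
            a_start = a_end - la + 1
        else:
            a_start = se + gap
            a_end = a_start + la - 1

    assert pair_type in ov_types or (a_end < ss or a_start > se)
    sense = GeneRecord(f"{id_prefix}S", f"{id_prefix}S", chromosome, "+",
                       ss, se, _draw_biotype(rng), "synthetic")
    anti = GeneRecord(f"{id_prefix}A", f"{id_prefix}A", chromosome, "-",
                      a_start, a_end, _draw_biotype(rng), "synthetic")
    if sense_strand == "-":
        pivot = ss + se + a_start + a_end  # any pivot keeping coords positive
        sense, anti = _reflect(sense, pivot), _reflect(anti, pivot)

    # Truth offsets by direct arithmetic on the final coordinates.
    s_tss = sense.start if sense.strand == "+" else sense.end
    s_tes = sense.end if sense.strand == "+" else sense.start
    a_tss = anti.start if anti.strand == "+" else anti.end
    a_tes = anti.end if anti.strand == "+" else anti.start
    sign = 1 if sense.strand == "+" else -1
    label = TruthLabel(
        sense.gene_id, anti.gene_id, pair_type.value,
        sign * (a_tss - s_tss), sign * (a_tes - s_tes),
    )
    return sense, anti, label


def _draw_biotype(rng: np.random.Generator) -> str:
    return _BIOTYPES[rng.choice(len(_BIOTYPES), p=_BIOTYPE_WEIGHTS)]


def _shift(g: GeneRecord, delta: int, chromosome: str) -> GeneRecord:
    return g._replace(start=g.start + delta, end=g.end + delta,
                      chromosome=chromosome)


def generate_gene_table(spec: FixtureSpec) -> tuple[GeneTable, pd.DataFrame]:
    """Generate a gene table with planted pairs and decoys, plus truth labels.

    Each plant occupies a rejection-sampled territory (its span padded by
    twice the nearby threshold) disjoint from every other territory, so
    no unintended opposite-strand overlap or nearby relation exists
    between different plants or decoys.  Sense-strand assignment
    alternates so both orientations of every type are exercised.  The
    same spec (including seed) always yields the identical table.

    Returns the table and a truth DataFrame with columns
    ``sense_gene_id, as_gene_id, pair_type, as_tss_position,
    as_tes_position``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    margin = 2 * NEARBY_THRESHOLD + 1
    territories: dict[str, list[tuple[int, int]]] = {
        f"chr{i + 1}": [] for i in range(spec.n_chromosomes)
    }
    chrom_names = list(territories)

    def place(span: int) -> tuple[str, int]:
        for _ in range(spec.max_retries):
            chrom = chrom_names[rng.integers(len(chrom_names))]
            lo = int(rng.integers(1, spec.chromosome_length - span))
            hi = lo + span - 1
            if all(hi + margin < a or lo - margin > b
                   for a, b in territories[chrom]):
                territories[chrom].append((lo, hi))
                return chrom, lo
        raise RuntimeError(
            "could not place a gene without collisions; "
            "increase chromosome_length or n_chromosomes"
        )

    records: list[GeneRecord] = []
    labels: list[TruthLabel] = []
    plant_no = 0
    for ptype in [t.value for t in PairType]:
        for _ in range(spec.pairs_per_type.get(ptype, 0)):
            plant_no += 1
            strand = "+" if plant_no % 2 else "-"
            sense, anti, label = plant_pair(
                ptype, strand, spec, rng, id_prefix=f"P{plant_no:04d}"
            )
            lo = min(sense.start, anti.start)
            hi = max(sense.end, anti.end)
            chrom, new_lo = place(hi - lo + 1)
            delta = new_lo - lo
            sense = _shift(sense, delta, chrom)
            anti = _shift(anti, delta, chrom)
            records.extend([sense, anti])
            labels.append(label._replace())
    for d in range(spec.decoy_genes):
        length = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
        chrom, lo = place(length)
        strand = "+" if d % 2 else "-"
        records.append(
            GeneRecord(f"D{d + 1:04d}", f"D{d + 1:04d}", chrom, strand,
                       lo, lo + length - 1, _draw_biotype(rng), "synthetic")
        )
    table = GeneTable.from_records(
        records, provenance={"source": f"synthetic(seed={spec.seed})"}
    )
    truth = pd.DataFrame(labels, columns=TruthLabel._fields)
    return table, truth


def generate_expression(
    truth: pd.DataFrame,
    time_points: int = 6,
    replicates: int = 2,
    rho_signs: dict[str, int] | int | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    decoy_gene_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """TPM time course with planted per-pair correlation signs.

    Each planted pair gets a smooth latent trajectory — a unimodal
    sequence (rise to a peak, then decline) over an evenly spaced level
    grid on a positive baseline, so consecutive ranks are separated by a
    fixed fraction of the dynamic range — and both genes observe it with
    independent additive noise whose SD is ``noise_sd`` times the
    trajectory's dynamic range.  For a negative plant the antisense
    observes the vertically mirrored trajectory, so at zero noise the
    Spearman correlation is exactly +1 or −1.  Decoy genes carry no
    latent signal: independent noise around a flat baseline (at zero
    noise their trajectory is constant, hence their correlation with
    anything is undefined).  All values stay positive and exceed the
    expressing-gene threshold somewhere.

    ``rho_signs`` maps sense_gene_id → ±1 (or a single ±1 for all pairs);
    by default signs alternate (+, −, +, ...) over the truth rows.
    Returns the matrix and a sign table (sense_gene_id, planted_sign).
    """
    if time_points < 4:
        raise ValueError("need at least 4 time points")
    rng = np.random.default_rng(seed)

    def latent() -> np.ndarray:
        # Unimodal arrangement of evenly spaced levels: every value is
        # distinct and adjacent ranks differ by range/(T-1).
        amp = float(rng.uniform(5.0, 20.0))
        levels = 2.0 + amp * np.linspace(0.05, 1.0, time_points)
        left: list[float] = []
        right: list[float] = []
        for v in levels[:-1]:
            (left if rng.random() < 0.5 else right).append(float(v))
        return np.array(left + [float(levels[-1])] + right[::-1])

    def observe(traj: np.ndarray) -> np.ndarray:
        # One noisy observation per (time point, replicate), time-major.
        scale = np.ptp(traj)
        reps = np.repeat(traj, replicates)
        noisy = reps + noise_sd * scale * rng.standard_normal(reps.shape)
        return np.maximum(noisy, 0.01)

    samples = [f"t{t}_{r + 1}" for t in range(time_points)
               for r in range(replicates)]
    rows: dict[str, np.ndarray] = {}
    signs = []
    for i, rec in enumerate(truth.itertuples(index=False)):
        if isinstance(rho_signs, dict):
            sign = rho_signs.get(rec.sense_gene_id, 1)
        elif isinstance(rho_signs, int):
            sign = rho_signs
        else:
            sign = 1 if i % 2 == 0 else -1
        base = latent()
        anti = base if sign > 0 else (base.max() + base.min()) - base
        rows[rec.sense_gene_id] = observe(base)
        rows[rec.as_gene_id] = observe(anti)
        signs.append((rec.sense_gene_id, sign))
    for g in decoy_gene_ids or []:
        baseline = float(rng.uniform(2.0, 10.0))
        noise = noise_sd * baseline * rng.standard_normal(
            time_points * replicates
        )
        rows[g] = np.maximum(baseline + noise, 0.01)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    df.index.name = "gene_id"
    sign_table = pd.DataFrame(signs, columns=["sense_gene_id", "planted_sign"])
    return ExpressionMatrix(df), sign_table


def write_gtf(table: GeneTable) -> str:
    """Emit one ``gene`` feature line per record (round-trips via the parser)."""
    lines = []
    for g in table.records():
        attrs = [f'gene_id "{g.gene_id}";']
        if g.symbol:
            attrs.append(f'gene_name "{g.symbol}";')
        if g.biotype:
            attrs.append(f'gene_biotype "{g.biotype}";')
        if g.gene_source:
            attrs.append(f'gene_source "{g.gene_source}";')
        lines.append(
            "\t".join(
                [g.chromosome, g.gene_source or "natpairs", "gene",
                 str(g.start), str(g.end), ".", g.strand, ".", " ".join(attrs)]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
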
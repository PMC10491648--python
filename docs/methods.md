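# Methods

## Gene model and coordinate conventions

All analyses operate on one representative interval per gene — the
annotated `Start`/`End` of the `gene` feature — on 1-based closed
coordinates (the GTF convention). Isoforms, exon structure and
alternative TES choice are deliberately out of scope: a pair's overlap
is interval overlap of the gene bodies, whether or not exonic sequence
is shared. The transcription start site (TSS) of a gene is `Start` on
the plus strand and `End` on the minus strand; the transcript end site
(TES) is the opposite end. Strand is mandatory (`+`/`-`); unstranded
features are rejected at parse time because antisense relations are
undefined without strand. Chromosome names are compared as exact
strings; an optional CLI flag strips a `chr` prefix, but no silent
normalisation happens in the library.

Gene identity is `gene_id` throughout. Symbols are carried for
readability but are never join keys and may repeat; duplicate symbols
are a validation warning, duplicate `gene_id`s an error. Annotations
that list the same locus under several `gene_source` values can be
deduplicated with a source whitelist before pairing.

## Pair classification

For an ordered pair (sense *S*, antisense *A*) on the same chromosome
and opposite strands, let `[s1, s2]` be the closed sense interval.
Classification is by membership of the antisense TSS and TES in that
interval:

- both in → **EB** (embedded); TSS only → **HH**; TES only → **TT**;
  neither, but the intervals intersect → **FO** (fully overlapped);
- disjoint intervals: the antisense lies entirely on the sense gene's
  5′ side (head-to-head, divergent) or 3′ side (tail-to-tail,
  convergent); the pair is *nearby* (**nHH**/**nTT**) when the gap
  between the facing gene ends is ≤ 5,000 bp (adjacent genes have
  gap 1) and *faraway* (**fHH**/**fTT**) otherwise.

These five cases are mutually exclusive and exhaustive, so the
classifier is total, and single-base overlaps count as overlap (closed
intervals). The end-to-end gap definition makes "nearby head-to-head"
coincide exactly with a TSS offset in `[-5000, -1]` for disjoint
upstream pairs, which ties the type system to the Mode 2 window
semantics. Swapping the roles of the two genes maps HH↔HH, TT↔TT,
EB↔FO and fixes the four disjoint types — except in boundary layouts
where the genes share an interval endpoint (identical-extent genes are
EB from both roles; an embedded gene sharing the sense gene's 5′ end
swaps to HH). The membership rule, not the symmetry, is the definition.

The 5-kb nearby threshold is a parameter (`nearby_threshold`, bp) with
the conventional default.

## Signed offsets and window extraction

`AS_TSS_position = ±(TSS_A − TSS_S)` with the sign chosen so that the
offset is measured along the sense gene's transcription direction
(`+` strand: as written; `−` strand: negated). Negative offsets are
upstream, 0 is coincident anchors. `AS_TES_position` is analogous at
the TES.

Mode 2 (TSS window) and Mode 3 (TES window) return every ordered pair
whose offset lies in the closed window `[min, max]`; `max = -1`
therefore excludes coincident anchors. Internally the window is mapped,
per sense gene, to a closed coordinate interval for the antisense
anchor (`[t+min, t+max]` for plus-strand sense, `[t−max, t−min]` for
minus-strand), and candidates are found by binary search over the
per-chromosome, per-strand sorted anchor coordinates. Mode 1 (overlap)
queries an interval tree per chromosome and strand. Both directional
sweeps (plus-sense then minus-sense) are emitted without deduplication:
each qualifying unordered pair appears once per sense role. Output is
sorted by (sense chromosome, sense start, sense gene_id, antisense
gene_id), making runs byte-reproducible. The test suite checks all
three modes against an independent O(n²) enumeration by exact set
equality.

## Region profiles

The divergent/convergent landscape splits the signed-offset axis
`[-range, range-1]` (default ±5 kb) into bins of `width` bp (default
500, giving 20 sections): upstream bins end at −1 (`[-500, -1]` is the
promoter-proximal divergent bin), downstream bins start at 0, so
coincident anchors fall in the first downstream bin — a convention
choice, since only the upstream bin labels are canonical. Per bin the
profile counts *distinct sense genes* with at least one antisense
anchor in the bin (a gene with several partners in one bin counts
once), and the percentage uses the full biotype-filtered gene set as
denominator — genes without any antisense partner dilute the
percentage by design, so values are comparable across species and
biotype splits. Biotype-combination counts use the same distinct-gene
rule per (sense biotype, antisense biotype, bin) cell; ratio summaries
between cells are left to the caller.

## Expression screen

Replicate columns (`<timepoint>_<replicate>` labels) are averaged to
time-point means before both the expressing-gene filter and the
correlations; a flag switches to raw per-sample columns. The choice of
means as default reflects that replicate averages are the quantity the
trajectories represent; the alternative is exposed because either is
defensible.

- *Expressing genes*: mean TPM > 1 at one or more time points, and no
  time point with mean 0. The threshold is strict (`> min_tpm`).
- *Spearman ρ*: Pearson correlation of average-ranked series (standard
  mid-rank tie handling). A constant series has no rank ordering: the
  correlation is reported as undefined (NaN), never 0, and such pairs
  are excluded from grouping and candidate selection.
- *Distance groups*: pairs sorted by signed offset are cut into
  consecutive groups of 100; records tied at a group's boundary offset
  join that group, so edge groups may exceed 100. The anchor-proximal
  set takes the 400 pairs of smallest |offset| (ties at the cutoff all
  included) — the natural reading of "pairs generated around the
  anchor".
- *Null model*: random pairs of distinct expressing genes on the same
  chromosome and opposite strands (one gene uniform over eligible
  genes, the partner uniform over the opposite strand of its
  chromosome), fully reproducible from a seed. The opposite-strand
  constraint mirrors the sense/antisense structure of the real pairs.
- *Candidates*: ρ > 0.9 (positive) and ρ < −0.7 (negative), strict
  inequalities; the export table carries pair type, offsets and both
  TPM trajectories, sorted by ρ.

## Steel–Dwass (DSCF) all-pairs comparison

For each unordered pair of groups, the two samples are pooled and
mid-ranked; the Mann–Whitney count of the smaller side is centred at
its null mean and studentized with the tie-corrected null variance

  Var = n_i n_j / (N (N − 1)) · [ (N³ − N)/12 − Σ (t³ − t)/12 ],

then referred, on the √2-scaled statistic, to the studentized range
distribution with k groups and infinite degrees of freedom, which
controls the family-wise error over all k(k−1)/2 comparisons. A 0.5
continuity correction (clamped at the null mean) is applied to the
Mann–Whitney count: it brings the asymptotic p-value within ~0.05 of
the exact permutation p-value for pooled samples as small as a dozen
observations, and is negligible at the group sizes the screen uses
(n ≈ 100–400). Degenerate pairs (all pooled values tied) get statistic
0 and p = 1. Monte-Carlo calibration under the null (4 groups of 30,
2,000 repetitions) and small-sample permutation consistency are part of
the test suite.

## Synthetic fixtures

The gene-table generator is the constructive inverse of the
classifier: for each requested type it draws gene lengths (default
200–8,000 bp) and, where relevant, gaps (nearby from [1, 5,000],
faraway from [5,001, 30,000]), builds the layout for a plus-strand
sense gene and mirrors it for minus-strand plants, so both orientations
of every type are exercised. Plants and decoy genes are placed by
rejection sampling (bounded retries, default 1,000, with an explicit
error suggesting longer chromosomes) into territories padded by twice
the nearby threshold, so no unintended opposite-strand relation exists
— Mode 1 emptiness among the strand-balanced decoys is a meaningful
negative control.

The expression generator gives each planted pair a latent trajectory:
a unimodal arrangement (rise to a peak, then decline — the shape of a
gene transiently induced over a differentiation time course) of evenly
spaced levels on a positive baseline, with amplitude drawn from
[5, 20] TPM. Both genes observe it with independent additive noise of
SD `noise_sd` × (dynamic range); negative-sign partners observe the
vertically mirrored trajectory. Because levels are evenly spaced, rank
order is stable at small noise, and at zero noise the pair's Spearman
ρ is exactly ±1. Decoy genes carry no latent signal — independent
noise around a flat baseline — so at zero noise their trajectories are
constant and their correlations undefined, which makes decoy exclusion
from the candidate lists deterministic. Everything is a pure function
of (spec, seed).

What the fixtures do *not* emulate: realistic chromosome composition
(gene density, GC/CpG structure), biotype-specific length
distributions, isoform variability, count noise of real RNA-seq
quantification, or library-level correlation between unrelated genes.
Passing tests therefore demonstrate algorithmic correctness on the
defined gene model, not discovery performance on any particular
genome.

## Problem sizes and numerical choices

The brute-force equivalence checks run 50 random tables of 40–260
genes plus tables of 1,000 genes, against a pure-Python O(n²) oracle;
the classifier symmetry property uses 10⁵ random pairs; the screen
recovery uses 104 planted pairs at 5 % noise; the DSCF calibration
uses 2,000 Monte-Carlo repetitions. All randomness is
`numpy.random.default_rng` seeded explicitly; the acceptance script
derives independent sub-seeds from its `--seed` via `SeedSequence`.

## Known limitations

- Gene-body intervals only: a reported overlap need not involve exonic
  sequence, and multi-isoform TES variation is invisible.
- The nearby gap is measured end-to-end between gene bodies; for
  disjoint head-to-head pairs this equals the TSS-to-TSS reading, but
  other conventions exist.
- The Spearman implementation uses average ranks; spreadsheet-style
  minimum-rank compatibility is not provided.
- The DSCF p-values are asymptotic (with continuity correction); for
  very small groups an exact permutation test is preferable and is
  implemented only as a test oracle.
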
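# Methods

This note documents the statistics `halfsibkit` implements, the modelling
assumptions behind the synthetic data generators, the numerical and design
choices made where the procedure was genuinely open, and what the test
suite does and does not establish about real data.

## The study design being modelled

Two seasonal spawning lots of rainbow trout, each produced by crossing
three dams to a single sire, so that the six fish within a lot are paternal
half-sibs (full sibs within a dam). From each (lot, dam) family one LARGE
and one SMALL offspring is retained: 12 fish, genotyped on a biallelic SNP
array and RNA-sequenced in white muscle. Parental genotypes are treated as
unknown — every analysis consumes offspring only.

## CSSC: identity-by-state allele sharing

For two fish with biallelic dosages `d_a, d_b ∈ {0, 1, 2}` at a marker, the
number of alleles shared identical-by-state is `2 − |d_a − d_b|`. CSSC is
the mean of `shared/2` over all markers where *both* genotypes are observed
(pairwise-complete denominators: a marker failing in one fish removes only
that fish's pairs, not the marker globally). The distance is `1 − CSSC`.

This is IBS sharing, not an IBD kinship estimate: no allele-frequency
correction is applied, because the coefficient is defined frequency-free.
Expected values under the design make the seasonal lots separate: half-sibs
share a transmitted sire allele, so within-lot CSSC exceeds between-lot
CSSC on average, and the NJ tree of `1 − CSSC` groups each lot.

A pair with zero informative markers raises an error naming the pair; it is
never silently scored 0.

## PAD: median-ratio expression distance

Per transcript with median RPKM `m > 0` across the 12 fish, each fish's
value `v` is rescaled to a ratio in [0, 2]. Two transforms are provided:

- `capped` (default): `min(v/m, 2)`. A plain ratio is unbounded above, so
  a cap at 2 enforces the bounded range; the cap is recorded in output
  metadata.
- `rational`: `2v/(v + m)`, smooth and bounded by construction, equal to 1
  at the median.

Transcripts with zero median (expressed in fewer than half the fish) have
no defined ratio and are excluded and reported, rather than assigned an
arbitrary value that would inflate distances.

PAD between two fish is the **mean** absolute ratio difference over the
included transcript set — the mean rather than the sum so that values are
comparable between the full filtered set and the high-expression subset;
NJ topology is invariant to this positive rescaling. The transcript set is
global (not pairwise-varying), which keeps PAD a true metric (a scaled L1
distance) over a fixed coordinate space; the suite verifies symmetry,
range, and the triangle inequality.

## DI: the small-vs-large dissimilarity scan

Within a lot, every SMALL fish is compared to every LARGE fish (9 pairs in
the 3+3 design). A pair scores 1 if the genotypes are not identical
(dosage inequality — a heterozygote differs from either homozygote) and 0
otherwise; DI is the mean over pairs with both genotypes observed. A
marker passes the scan iff it meets the criterion in *both* lots with at
least `min_informative` (default 9) informative pairs — the denominator
guard prevents tiny-denominator artifacts when data are missing.

Two pass criteria are implemented because the conventional cutoff is
internally ambiguous: "DI > 0.89" strictly excludes 8/9 ≈ 0.8889, yet the
intent of "one allowed similarity match" would admit it. The default is
the strict inequality; `criterion="max_one_match"` (at most one identical
pair per lot) implements the other reading. Both are reported with the
threshold and criterion used.

The permutation null shuffles size-class labels among the six fish of each
lot independently (lot and family structure fixed — the contrast of
interest is size within lot), recomputes the passing count, and reports
`p = (1 + #{null ≥ observed}) / (n_perm + 1)`. Note that this null is not
degenerate: a neutral marker whose sire is heterozygous splits the lot into
two sire-allele groups, and some permuted partitions align with that split,
so the null carries real mass at small positive counts. Even a perfectly
confounded signal therefore cannot reach `1/(n_perm + 1)`; with only nine
pairs per lot the scan is intrinsically noisy, which is exactly why the
permutation calibration is part of the pipeline.

## Expression preparation

- CPM = `count × 1e6 / column total`; RPKM = `count / (length/1000) /
  (column total / 1e6)`. Denominators are the input table's column totals
  (post-alignment, pre-filter). All-zero libraries yield all-zero columns
  rather than division errors.
- Low-expression exclusion: a contig is kept iff detected (raw count > 0)
  in **more than 3** fish AND its CPM summed over fish exceeds 1. The two
  clauses are combined with AND-to-keep (exclusion on either failure), the
  stricter of the two readings the usual phrasing admits; both thresholds
  and a per-sample CPM variant are configurable. "Detectable" means raw
  count > 0, as no detection floor is defined. The filter is idempotent.
- High-expression subset: ≥ 5 RPKM — inclusive, "matching or higher" — in
  ≥ 2 fish. Used before PAD to focus on the most highly expressed
  transcripts.
- BH-FDR is the standard step-up procedure (delegated to statsmodels),
  exposed for consumers of per-contig p-values. Differential-expression
  modelling itself (dispersion estimation, GLM testing) is out of scope:
  the pipeline consumes significance lists.

## Category tests

- The shared-contig overlap is a 2×2 table (rows = size class of the
  sharing set, columns = season) tested with the **uncorrected** Pearson
  χ² on 1 df — no Yates correction, which is what reproduces the published
  statistic for counts (432, 68, 60, 562): χ² = 663.2.
- G-test of independence on 2×k tables: `G = 2 Σ o ln(o/e)` with `0·ln 0 ≡ 0`;
  all-zero categories are dropped with a warning. The optional Williams
  correction divides G by `q = 1 + (N Σ 1/row − 1)(N Σ 1/col − 1)/(6 N df)`
  (the general r×c form). P-values are right-tail χ² with k−1 df; no exact
  tests.
- Backward elimination: run the G-test; while p < α, remove the category
  whose two cells contribute the largest absolute summed G terms
  (ties: first index), recompute margins, repeat until the retained table
  is homogeneous or one category remains. Removed categories are the ones
  declared significantly different. Every step is logged with the full
  per-category contributions so alternative protocols can be audited — the
  elimination rule follows the Sokal–Rohlf simultaneous-test-procedure
  style, a documented stand-in since no canonical protocol exists.
- Replicated-G decomposition, in the replicated goodness-of-fit framing:
  for m replicate count vectors over k categories tested against common
  extrinsic proportions, `Σ G_individual = G_pooled + G_heterogeneity`
  holds exactly, with the heterogeneity term equal to the independence G of
  the stacked m×k table. Both routes are computed and compared (the
  internal consistency check for the heterogeneity framing). For
  independence-test replicates the identity is only asymptotic, which is
  why the goodness-of-fit framing is the one implemented.

## Neighbour joining

The standard Saitou–Nei procedure: minimise
`Q(i,j) = (n−2) d(i,j) − r_i − r_j`, join, compute limb lengths from net
divergences, reduce the matrix. Exact (topology and branch lengths) for
additive inputs. Determinism: Q ties break to the lowest (row, column)
index pair. Negative intermediate limb lengths — possible for non-additive
inputs — are clamped to 0 with the deficit logged, matching common viewer
behaviour and keeping all branch lengths non-negative. Trees are left
unrooted and serialised as Newick with a trifurcating base node; labels
containing whitespace or metacharacters are single-quoted.

## Synthetic data generators

The generators' defaults are the study conditions: 12 offspring in the
2-lot × 3-dam × {LARGE, SMALL} design, with 8 parents (2 sires, 6 dams)
emitted alongside but never consumed downstream.

**Genotypes.** Per marker, an alternate-allele frequency is drawn uniform
on [maf_low, maf_high] (default 0.1–0.5, the informative range of a
genotyping array after QC); parents are Hardy–Weinberg draws; each
offspring receives one uniformly sampled allele from its dam and one from
its lot's sire. Markers planted as size-confounded make both sires
heterozygous and all dams homozygous reference, with sire transmission
forced by size class — SMALL offspring carry dosage 0 and LARGE dosage 1,
so within-lot DI is exactly 1 with complete data regardless of the dam
draw (forcing sire transmission alone would not guarantee this, since dam
alleles could equalise the dosages). Missingness is independent per cell,
offspring only. Dams are assumed unrelated within and between lots.

**Counts.** Contig relative abundances are log-normal (σ = 1.5,
normalised); the mean for contig g in fish i is
`library_size_i × ρ_g × 2^(s·log2fc·x_i)` with `x_i = ±1/2` encoding the
fish's level of the contig's factor (lot or size class), so the two groups
differ by a full `2^log2fc`. Counts are negative-binomial with variance
`μ + φμ²`; the default `φ = 0.29² ≈ 0.084` corresponds to a biological
coefficient of variation of 0.29, a realistic value for sibling fish.
Default library size 2 × 10⁶ reads per fish; lengths uniform on
200–4000 bp. Season- and size-responsive contigs are disjoint random sets
with random effect signs, recorded in the ground truth.

**Determinism.** One global integer seed feeds named sub-streams
(parents, transmission, missingness, abundances, counts, lengths, planted
selection, DE assignment) via `SeedSequence(seed, spawn_key=...)`, so
changing the marker count cannot perturb the simulated counts, and
identical seed + parameters reproduce byte-identical tables.

**What the generators do not emulate:** linkage and recombination (markers
are independent), multi-allelic markers, genotyping error, GC/length bias,
sample-specific composition effects, or correlated expression modules.
Passing tests therefore demonstrate correctness of the statistics and
recovery of planted structure under the design's sampling noise — not
robustness to array artefacts or to expression covariance found in real
tissue.

## Problem sizes and numerical choices

Simulation-based checks use 2000 markers (genotypes) and up to 5000
contigs (counts), with 20 replicate seeds for structure-recovery and
calibration rates and 99–199 permutations for empirical p-values — sizes
at which the pedigree and count signals are well resolved while the whole
suite runs in seconds. Exact identities (CSSC oracle equivalence, G
additivity) are asserted to 1e-9 relative or better; NJ recovery of
additive matrices to 1e-6 on patristic distances; asymptotic equivalences
(G vs Pearson χ²) to 5% in the all-cells ≥ 50 regime where the local
equivalence holds. Degenerate inputs (all-zero libraries, zero-median
transcripts, uninformative pairs, empty categories, degenerate margins)
are either handled with a defined convention or rejected with a specific
error, never silently coerced.

## Known limitations

- The DI scan's power analysis is purely empirical (permutation); with 9
  pairs per lot its false-positive behaviour depends strongly on sire
  heterozygosity, and maternal variation is not separated out.
- The backward-elimination protocol is one defensible choice among
  several; traces expose every step so results can be re-derived under a
  different contribution measure.
- The capped median-ratio transform flattens genuine > 2-fold
  over-expression; the rational transform preserves ordering but changes
  the distance scale. Both are labelled in output.
- PAD and CSSC trees are descriptive clusterings; no uncertainty
  (bootstrap) is attached to their topologies.
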
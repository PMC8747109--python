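# Methods

## Scope and data model

The package operates on grid-scored root microscopy: one observation is a
10 × 10 grid of integer structure codes (0 empty, 1 hyphae, 2 arbuscule,
3 vesicle, 4 spore, 5 auxiliary cell, 6 entry point) identified by a
(replication, segment, field) triple. The reference sampling design is 4
replications × 15 one-centimetre root segments × 15 microscopic fields =
900 observations over 60 segments. Code 0 is a package convention —
scoring schemes code only structures 1–6, but absence needs a
representation, and colonization maps render it as white non-colonized
area. A cell holds exactly one code: the per-class abundances then
partition the occupied area, which is what makes the complement identity
below exact. Grid orientation is fixed with columns along the root axis,
because frequency is a presence-along-length measure.

## Index definitions

Let `occ` be the set of occupied (non-zero) cells.

- frequency `F = 10 · #{columns intersecting occ}` (%)
- intensity `I = #occ` (%; the grid has 100 cells)
- arbuscule and vesicle abundance: counts of codes 2 and 3, as % of **all**
  cells, not of colonized cells — under this convention an arbuscule
  conversion probability of p per hyphal cell appears directly as an
  I→Arb regression slope near p
- colonization degree `Cdeg = F · I / 100`
- non-mycorrhizal area `nonM = 100 − I` (exact)
- ratio `M/nonM = I / (100 − I)`; at I = 100 the ratio diverges and the
  package reports a documented saturation value of 99.0 with a logged
  warning

These definitions are anchored by two identities that published class and
cluster tables of grid-scored datasets satisfy row by row: `nonM + I =
100` exactly, and the ratio cell equals `I/(100−I)` after 2-decimal
rounding. `I ≤ F` holds for every grid (each occupied column contributes
at most 10 cells to I but 10 points to F).

Frequency classes M1–M5 are the five 20-point bins [0,20], (20,40],
(40,60], (60,80], (80,100]. Sources differ on whether the second class
starts at 20 or 21; half-open intervals make the five classes a true
partition of [0,100] for non-integer frequencies, with exact 20.0 → M1.
Reported tables round to 2 decimals at output; all internal computation
is full precision.

## Statistics

**Histograms.** Each index is summarized two ways: a best-fitted solution
using Sturges' rule on the observed range (≈11 bins for n = 900, i.e. the
familiar ~10%-wide bins over 0–100), and a class-restricted solution
forcing the five frequency-class bins, right-closed like the class
assignment.

**ANOVA and letters.** One-way ANOVA across frequency classes, per index,
on per-observation records. Post-hoc separation uses Fisher's **protected**
LSD: pairwise pooled-variance t tests (df = N − k) are carried out only
when the omnibus F test rejects at α (default 0.05). Protection keeps the
family-wise error at the nominal level under the complete null — with five
groups, unprotected LSD would flag some pair in roughly 29% of null
datasets. Letters come from the standard insert-and-absorb compact letter
display, with columns ordered by descending mean so that "a" always marks
the top group.

**Regressions.** Ordinary least squares via statsmodels for the five
canonical pairs F→I, F→Arb, I→Arb, Cdeg→Arb, Cdeg→ratio. A zero-variance
predictor is rejected (and skipped, with a note, by the pipeline).

**Ordination.** PCA operates on centered, unit-variance-scaled indices —
scaling is required because the ratio lives on a far smaller scale than
the percentages; constant variables are dropped with a warning. NMDS uses
Bray–Curtis dissimilarities on the raw non-negative indices, 2 dimensions,
20 seeded SMACOF restarts (sklearn, nonmetric), reporting Kruskal
stress-1. Bray–Curtis is undefined between two all-zero records; such
pairs are identical and their dissimilarity is set to 0 with a warning.
The pipeline runs PCA per observation and NMDS on the 60 segment means:
nonmetric scaling of 900 near-duplicate observations costs minutes without
changing the ordination's structure, and the segment level matches the
resolution at which strategies are defined.

**Strategy clustering.** Segment-level mean records are z-scored per index
and clustered with Ward linkage on Euclidean distances; the dendrogram is
cut into k = 9 groups (configurable). Ward is chosen because it yields
compact clusters whose centroids — reported as member means on the raw
index scale — are meaningful "middle points". Clusters are relabeled
C1…Ck by input order of their first member, which makes the partition
invariant to row shuffling up to that canonical relabeling. Each cluster's
representative map is the member observation nearest the centroid in
z-score space, rendered with the fixed palette (hyphae blue, arbuscules
red, vesicles green, entry points purple, spores orange and auxiliary
cells yellow as package conventions — the latter two have no canonical
map color).

## Synthetic data generator

Real grid-scored root datasets are rarely deposited, so the simulator
provides data with the statistical structure the analysis assumes. Per
grid: a Poisson number of entry points (mean `entry_rate`) lands uniformly
on distinct cells; from each entry a hyphal run walks down its column,
continuing with probability `extension_prob` per step and branching into
an adjacent column with probability `lateral_prob` per visited cell; each
hyphal (non-entry) cell then differentiates independently — arbuscule with
`p_arb`, else vesicle with `p_ves`. Entry points keep their own code and
are excluded from the conversion denominator (arbuscules form on hyphae).
Downward growth makes frequency first-order driven by entry points and
intensity by extension — root penetration and colonization success as two
separable knobs — and guarantees I ≤ F by construction.

Between-segment heterogeneity is modeled by an optional gamma multiplier
on `entry_rate` (mean 1, shape `segment_dispersion`), drawn once per
segment. Without it, frequency concentrates around its homogeneous-Poisson
expectation and cannot span all five classes in one dataset; with it, the
15 fields of a segment share a colonization level, which is also what
gives the segment-level strategy clustering its structure.

The `festuca_like` preset emulates a lightly colonized perennial-grass
root system: `entry_rate 3.6, extension_prob 0.8, lateral_prob 0.12,
p_arb 0.2, p_ves 0.1, segment_dispersion 0.9`. The values were fixed once
by a coarse grid search with three targets: about two thirds of
observations with intensity ≤ 20% (band 0.56–0.76), an I→Arb slope
consistent with one-in-five hyphal-cell arbuscule conversion, and
frequency spanning all five classes. Across ten seeds the preset yields a
low-intensity share of 0.63–0.74, slopes of 0.148–0.163, and 5/5 classes,
with mean F ≈ 39% and mean I ≈ 16%. `sparse` (entry_rate 0.5,
extension_prob 0.3) and `saturated` (every grid fully colonized) cover
the boundary regimes.

What the simulator does **not** emulate: real within-root spatial
autocorrelation beyond simple downward/lateral contiguity (no data
constrain `lateral_prob`; it is a free parameter), senescent-root
structure, arbuscule life-cycle stages, or any host–fungus physiology.
Passing tests therefore demonstrate that the analysis machinery recovers
the properties the generator encodes, not that those properties hold in
any particular field dataset.

## Numerical and degenerate-input choices

- All randomness flows from explicit integer seeds (numpy `default_rng`);
  a config reproduces its dataset exactly, and the pipeline writes no
  timestamps, so report bundles are byte-identical across runs.
- An all-empty grid has ratio 0, nonM 100; a fully colonized grid caps the
  ratio at 99.
- Sparse grid tables omit empty cells; an all-empty grid is persisted as a
  single explicit code-0 row so it survives the round trip.
- ANOVA with zero within-group variance reports F = 0 (all values equal)
  or F = ∞, p = 0 (group means differ exactly).
- On degenerate data (e.g. the saturated preset, where every index is
  constant) the pipeline skips regressions, PCA, and NMDS with logged
  notes instead of aborting; the class summary then falls back to plain
  means ± se.
- Four mutually equidistant points cannot embed in the plane; the NMDS
  test asserts the tie-constrained planar optimum (stress-1 ≈ 0.17 for
  the square configuration) rather than zero.

## Problem sizes

The test suite and the acceptance script use the full 900-observation
design for end-to-end checks (a few seconds per dataset), 10 seeds for
parameter-recovery bands, 200 simulated null datasets for the type-I rate
of the protected LSD, and 1,000 random grids for oracle equivalence of
the index computation.

## Known limitations

- The index formulas are reconstructions anchored to published table
  identities, not a transcription of any scoring tool's source.
- The ratio cap (99) is arbitrary beyond being large and finite.
- Compact letter displays are not unique for non-transitive significance
  patterns; the insert-and-absorb construction is the conventional choice.
- The simulator's calibration trades overall colonization level for the
  low-intensity share: its mean frequency (~39%) sits below the ~50%
  typical of heavily colonized grassland datasets.
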
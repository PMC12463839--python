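# Methods

## Scope and model of the data

The package reconstructs the computational chain of a PGPB screening
study: matching field ASVs to a sequenced culture collection, placing the
matched isolates on a distance phylogeny, phenotyping potted plants from
rotating-platform photographs, and testing genotype × isolate effects on
dry shoot weight in a randomized complete block design (RCBD). The
original study's sequences, images and plant weights are not deposited,
so every stage runs against a synthetic generator that plants the ground
truth it is later asked to recover. All quantitative claims made by the
test suite and the acceptance script are therefore statements about the
pipeline's correctness and calibration on data with known structure, not
re-measurements of the original biological material.

## Sequence matching

**Aligner.** `ungapped_local_align` returns the maximum-score contiguous
single-diagonal segment over both query strands: local alignment with
mismatches but no indels. The scan is exhaustive (every diagonal), which
is affordable at collection scale (hundreds of ~250 nt reads) and makes
the result provably optimal — the test suite checks exact agreement,
including tie-break order, with brute-force enumeration of every
(strand, diagonal, window) segment. Scoring defaults to reward +2,
penalty −3, the classic blastn defaults; both are explicit parameters.
Ties resolve by longer alignment, more matches, '+' strand, smaller
subject start, then smaller query start — a total order, so output never
depends on iteration order. Ambiguity codes (including N) always score
as mismatches: conservative and deterministic. A best score ≤ 0 is a
no-hit. The inner loop is a numba kernel (prefix-minimum variant of
Kadane's algorithm per diagonal, O(|q|·|s|) per pair).

**Collation.** Hits are filtered by the length rule
|alignment_length − query_length| ≤ 2 nt, reduced to the best hit per
(ASV, subject), and multi-region hits of one isolate resolve to the
highest-preference region (merged > 27F > 515F > 515R). The preference
is applied per isolate after per-subject best-hit selection; a
`one_per_asv` flag gives the alternative reading in which each ASV keeps
only its single preference-resolved winner. Collation is idempotent.
Percent identity is reported to 3 decimal places.

**Identity floor.** Isolate summaries use `min_identity = 95.0` by
default, the floor implied by the study regime in which reported matches
span roughly 95.2–100% identity.

## Synthetic 16S families

Each isolate receives an i.i.d. uniform random full-length gene
(default 1200 nt); the V4 window (253 nt, anchored at the canonical
position 515 where it fits) yields the merged and 515F regions, its
reverse complement the 515R region, and the first 250 nt the 27F read.
A fraction of ASVs (default 0.87, the study's reported match rate) is
derived from an isolate's V4 window by substituting exactly
`round(rate × length)` sites, the rate drawn uniformly from the
configured divergence range (default 0–0.048, spanning identities
~95.2–100%); the rest are unrelated uniform DNA whose best ungapped hits
fall far below the identity floor and are additionally removed by the
length rule.

Two non-obvious generator rules exist to keep the planted truth exactly
recoverable:

* substitutions only, never indels — an ungapped matcher can only see
  truth that stays on one diagonal;
* substitutions are planted ≥3 nt from the read ends and ≥3 nt apart
  (`MUTATION_MARGIN`, `MUTATION_SPACING`). A maximum-score local
  alignment clips a terminal run whenever its prefix scores negatively;
  with the margin and spacing above, every prefix through the m-th
  planted mismatch spans ≥ 3m+1 sites and scores positively, so the
  full-length diagonal is the strict optimum, the alignment length
  equals the ASV length, and the recovered identity equals the planted
  Hamming identity exactly.

Because the substitution count is exact, the truth table's
`expected_percent_identity = 100·(1 − k/L)` holds as an identity on the
emitted pair, not as an expectation.

## Phylogeny

`complete_deletion` removes every column containing `-` or `?`;
`p_distance` is the proportion of differing sites (ambiguity characters
count as differences unless equal, mirroring the matcher's convention).
`neighbor_joining` is the standard Saitou–Nei agglomeration on the Q
criterion with branch lengths from the usual formulas; negative lengths
are clamped to zero (standard practice in distance-tree software). Exact
Q ties resolve to the lexicographically smallest pair of cluster labels,
a cluster being labeled by its smallest leaf — NJ output is therefore a
deterministic function of the matrix. On additive matrices NJ provably
recovers the generating topology and branch lengths; the suite verifies
this to 1e-9 over random trees of 4–12 taxa.

`bootstrap_consensus` resamples alignment columns with replacement,
reruns deletion → p-distance → NJ per replicate (replicates whose
resampled columns are all deleted are redrawn, up to a cap), tallies
bipartitions (normalized to the side not containing the smallest taxon,
which makes them clades of the tree rooted there; two are compatible iff
nested or disjoint), and assembles a strict majority-rule consensus:
bipartitions with frequency ≥ the 0.5 threshold are added greedily in
order of decreasing frequency when compatible. Supports are integer
percentages; consensus branch lengths are replicate means (over the
replicates containing the bipartition for internal branches, over all
replicates for terminal ones). Input alignments must be pre-aligned;
the synthetic V4 families are alignment-free by construction
(equal-length, substitution-only).

## Image phenotyping

The view chain is: green channel → threshold → distance mask → traits.
Thresholding defaults to Otsu on the grayscale histogram (a constant
image is an error that points to fixed mode); foreground is
above-threshold, with an `invert` flag for light backgrounds, and
components smaller than `min_object_px` can be removed. The manual
cropping of the original workflow is replaced by a parameterized
center-anchored disk mask (default radius fraction 0.9 of the inscribed
radius) — reproducible and monotone: masking never increases foreground.
Traits per view: pixel biomass (foreground count), shoot width
(horizontal extent of the foreground boundary, in pixels), occupancy
ratio (foreground fraction of the full frame). Aggregation over the view
series is the mean for biomass and occupancy (a `sum` option exists,
since the combine rule is a modeling choice) and the maximum for width.
Calibration regresses dry weight on aggregated pixels and reports
Pearson r; it requires ≥3 plants, matched ids, and nonzero variance.

The image generator renders a stem plus two elliptical leaves, jittered
per view, confined to 85% of the inscribed radius, bright in the green
channel on a dark background; the exact rendered foreground count is the
truth. Clutter is placed strictly outside a stated radius (default 0.92
of the inscribed radius) from an independent RNG stream, so enabling it
does not perturb the silhouettes and the 0.9 mask provably excludes it.
It does not emulate leaf occlusion, specular highlights, color
calibration error, or soil texture — trait exactness results on this
generator validate the arithmetic of the chain, not robustness to real
segmentation noise. The calibration operating point
(`calibration_regime`) generates weights as `a·pixels + noise` with the
noise variance chosen from the realized pixel variance so the analytic
correlation `a·σ_pix/√(a²σ_pix² + σ²)` equals a target (0.937, the
regime reported for image-predicted vs dry biomass); the recovered r is
then a Monte-Carlo estimate whose mean the suite checks within ±0.03.

## Trial statistics

Model: `y = μ + genotype + isolate + genotype:isolate + block + e`,
block ~ N(0, σ²_b) random, e ~ N(0, σ²_e), fixed effects in sum-to-zero
coding. Because blocks partition the rows, with λ = σ²_b/σ²_e the
marginal covariance is σ²_e(I + λZZ') and Z'Z is diagonal, so V⁻¹,
log|V| and the REML criterion are closed-form in λ (Woodbury); REML
reduces to 1-D minimization of the profiled criterion, done on a
log-spaced λ grid (0 and 10⁻⁸–10⁶) refined by bounded scalar
minimization to xatol 1e-9, with the λ=0 boundary checked explicitly.
On balanced data these REML estimates coincide with the ANOVA
estimators, so the Type III F statistics equal the fixed-block two-way
ANOVA closed form exactly — a tested identity (to the optimizer's
tolerance ~1e-6 relative).

Denominator df use the containment (between-within) rule: all three
fixed terms are within-block, so ddf = n − rank(X) − (n_blocks − 1),
exact for balanced RCBD and deterministic under unbalance
(Kenward–Roger was deliberately not used: the published-style F tables
need a closed-form, reproducible rule). LS-means are fixed-part predictions
on the equally weighted genotype × isolate grid (margins average the
grid), with SEs from the GLS covariance. Tukey–Kramer comparisons use
q = |Δ|/(SE_Δ/√2) against the studentized-range distribution with k
groups and the containment df; unequal cell sizes enter through the GLS
SEs. The compact letter display uses insert-and-absorb with groups
ordered by descending mean; by construction two levels share a letter
iff their adjusted p ≥ α, and the suite asserts this equivalence on
random fits. High-N control rows are a benchmark condition, not a
treatment crossed with the factors, and are excluded from the factorial
fit by default (`include_high_n=True` retains them).

Known limitation: contrast SEs plug in the REML λ̂, ignoring its
sampling error, which can make post-hoc error rates deviate slightly
from nominal in very small designs; in the simulated settings used here
(4–9 blocks) the measured familywise error is ≈0.048, marginally
conservative. The independent cross-checks are statsmodels MixedLM
(variance components) and, on a balanced fixture, R lme4 + emmeans
(LS-means and Tukey-adjusted p values).

The trial generator draws one replicate per cell per block, adds the
declared additive effects (validated to sum to zero per factor and per
interaction row/column), and removes plots by independent Bernoulli
dropout (default 0.08 in the study-like configuration, producing the
uneven n = 4–9 cells the Tukey–Kramer path needs). Configurations whose
dropout empties a cell are rejected, and the power driver redraws them.
It does not model spatial gradients within blocks, dropout correlated
with treatment, or repeated measures over time.

## Problem sizes and numerical choices

Defaults mirror the study conditions: 63 isolates, 100 ASVs with 87%
matchable, 3×5 factorial with 9 blocks, 8 views per plant, 1000
bootstrap replicates in the tree driver. The bundled end-to-end runs
scale two knobs for interactive turnaround, as the package's own
defaults: the bootstrap phylogeny carries 16 matched isolates (the
consensus machinery is identical at any taxon count) and 24 plants are
imaged. Monte-Carlo checks use 2000 replicates for test calibration
(binomial sd ≈ 0.005 at α = 0.05) and 100 seeds for calibration-r
recovery. The familywise-error simulation decides each replicate by
comparing the maximum studentized-range statistic to the 0.95 quantile
computed once — identical to testing the smallest adjusted p against
0.05, since the survival function is monotone. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; the
image generator uses separate child streams for silhouette, clutter and
noise so that switching one feature off never shifts another's draws.
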
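# Methods

This note documents the statistical models implemented in `phyllodyn`, the
design choices behind them, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Similarity-scaled trees and the depth scan

An isolate phylogeny (Newick, internal-node labels read as percent support)
is first filtered by collapsing internal nodes below a support threshold
(default 30%) into polytomies.  It is then rescaled onto the **pairwise
nucleotide similarity (PS)** axis: PS(i, j) is the fraction of matching
aligned sites between isolates i and j, sites with a gap or ambiguity code
in either sequence excluded pairwise.  Each internal node's raw height is
the mean PS over tip pairs whose MRCA is that node (pairs spanning different
child subtrees).  Means are used rather than minima because they are stable
under unbalanced clades; when a node's raw mean exceeds a child's height the
node is clamped to the child (a postorder pass), which restores
monotonicity.  Tips sit at PS = 1, so the result is ultrametric and the
patristic distance between two tips is `2 (1 − PS(MRCA))`.

**Taxon slicing.**  At a threshold t ∈ [root height, 1], taxa are the
maximal clades whose subtending node height is ≥ t.  Partitions form a
refinement chain as t decreases (lowering t only merges taxa), which is
property-tested.

**Depth scan.**  For each grid value (default 0.926 to 1.000, step 0.001 —
the step is a package choice; only the range is inherent to the scale of
within-genus variation), isolates are classified into taxa, tabulated into
per-group absolute abundances (group = host tree × date × isolation
temperature, the finest observational unit an isolate table supports; the
key is configurable), Hellinger-transformed, converted to Bray-Curtis
distances, and partitioned by PERMANOVA.  The output is an R²(PS) profile
per factor.

## Node–trait association test

For a binary isolate trait (forest, or isolation temperature 20/30 °C), each
internal node is scored by the **count of its majority trait level**.  The
null permutes trait labels uniformly across all isolates; per node this
makes the level count hypergeometric, so the Monte-Carlo permutation is
implemented as per-node hypergeometric draws (distributionally identical to
permuting the full label vector, and much faster), with the +1 correction so
p > 0; an exact enumeration mode uses the hypergeometric tail directly and
is verified against hand-counted cases (a pure 5-of-5 clade in a balanced
10-isolate set has p = 1/252).  The one-sided tail on the observed majority
level was chosen because it is exact under enumeration; ties count as ≥
(conservative).  P-values are Bonferroni-adjusted across tested nodes.

A sizing caveat documented here because it shapes the power analysis: a
10-tip pure clade among 60 isolates with a balanced global split has an
exact p of about 4 × 10⁻³, so after Bonferroni over ~59 nodes such a clade
can never reach family-wise 0.05.  Power statements for clades of this size
therefore use the per-node p < 0.05 level; family-wise detection becomes
possible only for larger clades (as in real collections of 167+ isolates).

## PERMANOVA

Distances D are squared, Gower-centered (G = H(−½D²)H), and each model
term's sum of squares is tr(P G) for the projection P onto the orthonormal
directions that term adds beyond all earlier terms — **Type-I (sequential)**
partitioning, so the term order is part of the analysis and is logged.
Pseudo-F = (SS_t/df_t)/(SS_res/df_res); p-values from free row permutation
(no strata), with exhaustive enumeration available for n ≤ 8.  Aliased terms
(no new degrees of freedom) are reported as NaN with a warning.  The
implementation is tested to 1e-10 against an independent brute-force oracle
(explicit hat matrices via pseudo-inverse) and its exhaustive p against
direct enumeration of all row orders.  Tie handling uses a relative
tolerance of 1e-9 on F so that analytically equal permutation statistics
count as ties regardless of accumulation order.

## Spatial and temporal models

Within-forest sample pairs carry the Bray-Curtis dissimilarity of their
relative-abundance profiles.  Spatial pairs (same date) are regressed on the
Euclidean distance between trees (planar meters — at transect scale, ~1.2 km,
curvature is negligible); temporal pairs on the absolute day difference.
Estimates, standard errors and sequential-ANOVA p-values are ordinary least
squares, as is conventional for these descriptive models, although pairs
sharing a sample are positively correlated; for this reason the package's own
**recovery criterion is bias-based**: across replicate simulations the slope
estimate must sit within 2 *empirical* (replicate-wise) standard errors of
the planted value in ≥95% of replicates.  The naive per-fit OLS standard
error understates the sampling SD of the slope and cannot support a coverage
statement.

The homogenization trend (decline of mean within-date dissimilarity over the
season) is fitted on the pooled within-date pair BC values against the day
of year; per-date mean BC values are reported alongside.  Fitting on the
four per-date means alone would leave 2 residual degrees of freedom and
statistically meaningless standard errors.

## SES(MNTD)

MNTD is the mean, over taxa present in a sample, of the patristic distance
to the nearest co-occurring taxon; it is **unweighted** (presence-based),
matching the richness-preserving null: the null distribution draws the same
number of taxa uniformly without replacement from the pool of taxa observed
in at least one sample (999 draws by default).  SES = (obs − null mean)/null
SD, with a two-sided rank p.  Samples with < 2 taxa, or equal to the entire
pool (degenerate null), are reported as missing with a flag.  Abundance
weighting is available as an option but off by default.  An ANOVA of SES on
host, forest and date (categorical, sequential) summarizes how clustering
varies with the environment.

## Growth phenotyping

Plate photos (one grayscale frame per plate per day; the emulated design is
a 6×6 spot grid photographed on days 7, 13 and 24) are processed as:

1. **Background**: per image, a degree-2 polynomial surface is fitted by
   least squares to inter-spot pixels (spot discs dilated ×1.6 are masked)
   and subtracted; spot intensity is the pixel sum over the disc.
2. **Competition correction**: colonies suppress each other through the
   model `I_obs = I_true / (1 + c · N)` with neighbourhood load
   `N_i = Σ_j I_obs,j / dist(i, j)` over occupied spots on the plate
   (grid-cell distances).  Because the load is defined on observed
   intensities the inversion is exact given c; c itself is estimated by
   least squares on replicate consistency — replicates of an isolate ×
   treatment at different grid positions must recover equal true
   intensities — using absolute residuals so that high-intensity (low
   relative noise) groups dominate.  The generator uses the same functional
   form (solved as a fixed point), making the correction testable as an
   exact inverse at zero noise.  The model is pluggable; the inverse-linear
   form is a package choice.
3. **Logistic fits**: `I(t) = Y / (1 + exp(−k (t − t_mid)))`, anchored at
   I(0) = 0 (inoculation) so three photo time points identify three
   parameters; multi-start least squares with an initial-value grid.
   Derived: lag = t_mid − 2/k (tangent construction), time-to-yield
   t_Y = t_mid + ln 19/k (95%-of-Y convention, configurable), and
   **rate r = 1/t_Y** — the inverse of lag plus the exponential-phase
   duration.  With t_Y around 9–14 days this gives r ≈ 0.07–0.11 day⁻¹,
   the magnitude typical of slow-growing leaf bacteria.  Spots whose
   maximum intensity is below a detection threshold get Y = 0 and missing r.
   Replicates are averaged per isolate × treatment after spot-level fitting
   (joint fitting is an option).
4. **Variance partition**: sequential ANOVA of log Y and log r on forest,
   host, date, preconditioning/monitoring/isolation temperatures, clade and
   the listed two/three-way interactions; the remaining between-cell
   variation (cells = full factor crossing) is pooled as "other
   interactions", and the residual is within-cell.  Fractions are
   SS/SS_total and sum to 1 with the residual (tested to 1e-9 and against a
   hand-computed two-factor table).

## The synthetic-data generator

The generator's role is to give every analysis a recovery surface with
known truth; its defaults emulate the survey scale (2 forests × 4 plots ×
20 trees × 4 dates ≈ 160 samples; amplicon depth log-uniform in
[5 × 10³, 5 × 10⁴]; trees of 40–100 tips in 4–6 clades; 6×6 plates with 5
replicates per isolate × treatment, photographed on days 7/13/24).

- **Trees**: clade crowns at PS 0.955–0.975, between-clade joins at
  0.928–0.950, so within-clade similarity always exceeds between-clade;
  supports drawn in [40, 100] (no collapse under the default 30% filter).
  Average-linkage clustering of the implied similarity matrix recovers the
  planted clades exactly (tested).
- **Isolate traits** are drawn from clade-conditional level probabilities.
  In power analyses the background clades' probability compensates the
  planted clade's bias so the global level split stays balanced — as in the
  emulated design, where every sample is isolated at both temperatures.
- **Planted slopes** use a three-block mixture: two single-taxon gradient
  endmembers u, v (share φ = 0.3) and a sample-specific Dirichlet noise
  block q.  For disjoint blocks, BC between relative-abundance profiles is
  exactly φ|w_i − w_j| + (1 − φ)BC(q_i, q_j), so a mixture weight linear in
  the transect coordinate plants the BC-per-meter slope exactly, and a
  within-date weight spread shrinking linearly in time plants the
  mean-BC-per-day slope exactly.  Single-taxon endmembers keep the
  per-taxon signal far above multinomial counting noise: with diffuse
  endmembers the |·| kink washes out small weight differences and attenuates
  the recovered slope (measured ~4–10% at these depths); with the
  single-taxon design the residual attenuation is below 0.2 empirical SD of
  the slope estimator.  Equal tree allocation to plots (round-robin) keeps
  the replicate designs homogeneous; random allocation mixes leverages and
  fattens the estimator's tails.
- **Clustered assembly** ("subset" mode) picks a focal tip per sample and
  includes taxa with probability ∝ exp(−strength × patristic distance to
  the focal); strength 0 is uniform stochastic assembly, under which
  SES(MNTD) is calibrated (mean ≈ 0, SD ≈ 1) because the generator then
  coincides with the null.  Sample richness (6–14 of a 100-tip pool)
  deliberately stays below the clade size: with richness approaching clade
  size, samples are forced to span clades and clustering saturates.
- **Plates**: spot totals follow the logistic curve, mutually suppressed by
  the same competition model the correction inverts (fixed-point solution),
  over a per-plate degree-2 polynomial background plus Gaussian pixel noise
  (σ expressed as a fraction of the peak per-pixel spot signal).  Growth
  shapes are drawn with k·t_mid ≥ 5.5 (the inoculum, Y/(1 + e^{k·t_mid}),
  stays below ~0.4% of yield, consistent with the origin anchor) and
  k ≤ 0.7 day⁻¹ — faster curves saturate before the day-13 photo, leaving
  one informative time point and an unidentifiable shape.  This is a real
  limitation of the three-photo design, not of the fitting: outside this
  regime r is reported but cannot be pinned by any estimator.

What the generator does **not** emulate: sequencing error and chimeras,
taxonomic mis-assignment, phenology of real leaves, geodesic distances,
non-logistic growth, plate mis-registration, and replicate-level variation
in growth parameters (replicates share their isolate × treatment truth, so
replicate consistency identifies the competition coefficient).  Passing
recovery tests therefore demonstrates the correctness of the estimators
under the stated model, not robustness to those real-data complications.

## Numerical conventions

- All stochastic functions take an explicit seed; the pipeline expands one
  global seed into per-stage seeds via `SeedSequence(seed, spawn_key)`.
- Permutation p-values use the +1 correction (p ≥ 1/(n_perm + 1));
  exhaustive modes divide by the number of arrangements with no correction.
- Design matrices are orthonormalized sequentially with an SVD rank
  tolerance of 1e-9; aliased terms get 0 df and NaN statistics.
- Distance-based ties in permutation statistics use a 1e-9 relative
  tolerance and count as exceedances (conservative).
- Tables are UTF-8 TSV with headers; trees are Newick with supports as
  internal node labels; run manifests carry SHA-256 checksums and a schema
  version.

## Known limitations

- Per-taxon screening tests default to unadjusted p < 0.05 (matching the
  descriptive per-ASV style of such surveys); Benjamini–Hochberg adjustment
  is available and recommended for confirmatory use.
- The node test assumes a binary trait; multi-level factors must be
  dichotomized by the caller.
- OLS p-values on dissimilarity pairs inherit the non-independence caveat
  above; a Mantel-style permutation is the appropriate confirmatory check.
- MNTD abundance weighting, restricted permutation strata, UniFrac and
  rarefaction are out of scope.
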
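# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the design decisions taken where the
methodology is genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Abundance-class partitioning

Each taxon's statistic is, by default, the mean over samples of its
per-sample relative abundance; taxa above 0.1 % are *abundant*, below
0.01 % *rare*, otherwise *intermediate*. Values exactly at a threshold fall
to *intermediate* (strict inequalities on both sides). Two alternative
bases are provided (`pooled`: taxon total over grand total; `max`: maximum
per-sample relative abundance) because the literature is not uniform about
which is meant; the mean basis is the dominant convention in the
abundant/rare literature and is the default.

Classification is performed **within each treatment group**: a taxon can be
abundant among tilled sites and intermediate among untilled ones, matching
how per-group class percentages are conventionally reported. Taxa with zero
counts within a group are not members of that group's community and are
excluded from its sub-communities (this also keeps Levins breadth defined).
Cross-group analyses of one class (ordination, PERMANOVA/ANOSIM, dispersion)
use the union of the two groups' memberships for that class, so both groups'
samples can be embedded in one distance matrix; per-group analyses
(alpha diversity, niche breadth, distance decay, assembly) use each group's
own sub-tables. The partition is exhaustive and exclusive, and total counts
are conserved exactly across the three sub-tables.

## Alpha diversity

Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)), defined even
when no doubletons are observed (the classic F1²/(2F2) form is not). Shannon
is −Σ p ln p with natural logarithms over within-sample relative abundances.
No rarefaction is applied by default (the input's sequencing depth is taken
as given); a seeded hypergeometric `rarefy` is available for sensitivity
analysis. Group comparisons use the two-sided Wilcoxon rank-sum test with an
exact p-value when both groups have ≤ 8 observations and no ties, and the
normal approximation with midrank-tie and continuity corrections otherwise;
identical pooled values return p = 1 with a degenerate flag.

## Beta diversity

Bray–Curtis is Σ|x−y| / Σ(x+y) over taxa, computed on raw counts by default
and on within-sample relative abundances for ordination and group tests
(library sizes then do not contribute to dissimilarity; a flag switches to
raw counts). PCoA is the Gower-centred −½D² eigendecomposition with all axes
retained; negative-eigenvalue (imaginary) axes are flagged rather than
discarded, coordinates are scaled by √|λ|, and variance explained is
reported over positive eigenvalues.

PERMANOVA is the one-way distance-based pseudo-F
(SS_total = Σ_{i<j} d²ij/n, within-group sums analogous) with label
permutation; ANOSIM is the rank-based R = (mean between − mean within) /
(n(n−1)/4) with midranks. Dispersion homogeneity follows the betadisper
treatment: squared distance to the group centroid is the real-axis part
minus the imaginary-axis part, truncated at zero with a warning; the
statistic is the one-way ANOVA F on the distances, with the p-value obtained
by permuting distances among groups. Group centroids (not spatial medians)
are used, matching the reference implementation's default.

All permutation p-values use (1 + #{T_perm ≥ T_obs}) / (1 + n_perm), so
p = 0 is impossible and p ≥ 1/(n_perm+1). PERMANOVA defaults to 9999
permutations; all other permutation and null procedures default to 999.

## Niche breadth

Levins breadth B_j = 1/Σ_i P²ij with P_ij the share of taxon j's total found
in sample i: B = 1 for single-sample occupancy, B = N for perfectly even
occupancy. Generalists have B > 3, specialists B < 1.5; boundary values are
"neither", and proportions are reported over all taxa of the cell (the
"neither" share is explicit). Breadth is computed within each treatment
group by default, since occupancy pooled across habitats conflates breadth
with habitat preference; a pooled mode is available. The community-level
summary is the unweighted mean of B over taxa present.

## Spatial analysis

Geographic distances are great-circle (haversine) with Earth radius
6371.0088 km. Distance decay is an OLS regression of ln(similarity) on
ln(distance) over unordered pairs, with similarity = 1 − Bray–Curtis; the
log–log slope is a scale-free decay exponent, invariant to rescaling the
distances. Pairs with zero similarity or zero distance are excluded
(ln undefined) and counted in the output; `lnsim` and untransformed variants
are available. Significance is a Mantel-style permutation test on the same
pairs, one-sided in the decay direction.

The Mantel statistic is the Pearson (or midrank Spearman) correlation of the
matrices' upper triangles, with simultaneous row/column permutation of the
second matrix; one-sided "greater" is the default, as is conventional for
ecological distance–distance association. r is symmetric in its arguments;
the permutation p may differ slightly depending on which matrix is permuted.
For n ≤ 7 an exhaustive mode enumerates all n! permutations. Environmental
Mantel panels use the absolute difference of the z-scored single variable as
the environmental distance, plus a Spearman correlation matrix among
variables.

## Assembly null models

βMNTD between samples j and k is the abundance-weighted mean over the taxa
of each sample of the patristic distance to the nearest taxon in the other
sample (taxa shared by both samples contribute zero), averaged over both
directions. The βNTI null shuffles taxon identities across the tips of the
tree pruned to the analysed taxa ("taxa-labels" randomisation), implemented
as one shared row/column permutation of the precomputed patristic matrix per
null replicate; βNTI = (obs − null mean)/null sd with the sample standard
deviation (ddof 1). When the null sd is zero (identical supports, star
phylogenies) the pair is flagged undefined and excluded from process
fractions, with the count reported. βNTI is invariant to rescaling all
branch lengths.

RC_bray rebuilds each of the two communities per replicate preserving its
observed richness S and total reads N: S distinct taxa are drawn from the
pool weighted by occurrence frequency, each receives one individual, and the
remaining N − S individuals are distributed multinomially in proportion to
the drawn taxa's pool-wide relative abundances; RC = 2·[#(null < obs) +
½·#(null = obs)]/n_null − 1 ∈ [−1, 1]. The pool is the sample set of the
analysed sub-table (treatment group × abundance class in the pipeline), so
the null reflects the community actually being analysed; a global pool is a
caller option. RC is computed only for pairs with |βNTI| ≤ 2 (selection is
already decided otherwise) unless requested for all.

Process classification: βNTI > 2 variable selection; βNTI < −2 homogeneous
selection; otherwise RC > 0.95 dispersal limitation, RC < −0.95 homogenizing
dispersal, |RC| ≤ 0.95 undominated. The strict inequalities leave the
boundaries |βNTI| = 2 and |RC| = 0.95 unassigned in the source framework;
here they fall to the stochastic/undominated side, which is conservative
toward selection claims. Deterministic = the two selection classes;
stochastic = dispersal classes + undominated. βNTI nulls are evaluated
within treatment groups (between-group pairs are not classified), matching
per-treatment reporting; per-pair RC seeds are derived deterministically
from the stage seed and pair index, so results are independent of
evaluation order.

## Synthetic survey generator

The generator emulates a two-group regional soil survey: 19 "tilled" and 25
"untilled" sites by default, in a ~200 km box, with a skewed lognormal
species pool. Components:

- **Phylogeny** — Yule (pure-birth) tree, ultrametric, `n_taxa` tips.
- **Niche optima** — Brownian motion along the tree from root value 0 (tip
  variance = σ²_BM × root-to-tip length), giving phylogenetic niche
  conservatism; before use the optima are linearly rescaled to mean 0.5 and
  sd `niche_optimum_spread` (default 0.3) on the gradient axis, so optima
  and gradient overlap regardless of tree height while the phylogenetic
  correlation structure is untouched.
- **Environment** — one latent gradient E as a Gaussian process over the
  sites with exponential covariance (scale `env_spatial_corr_length`, km),
  min–max rescaled per group into `env_range[group]`; compressing the tilled
  range models environmental homogenization under management. Soil
  chemistry variables (pH, SOM, TN, TP, AP, TK, AK) are noisy linear
  functions of E, with a constant shift added to the tilled group's pH, TN,
  TP, AP and AK (nutrient accumulation under tillage).
- **Communities** — expected relative abundance of taxon s at site i ∝
  L_s · exp(−(E_i − μ_s)²/(2σ²)) · K(d_is), with lognormal pool abundance
  L_s, Gaussian niche filter (σ = ∞ is neutral), and an optional exponential
  dispersal kernel K from a random per-taxon origin site. With
  `drift_sdlog > 0` the expectation is multiplied by iid lognormal
  per-taxon-per-site noise — ecological drift/local patchiness, which makes
  taxon occupancy vary between samples. Counts are multinomial at a fixed
  `read_depth` per sample, so library size is controlled and
  compositionality explicit.

Named presets fix the regimes used in testing — `neutral`, `filtering`
(σ = 0.15), `dispersal_limited` (25 km kernel) and `homogenized` (σ = 0.10,
tilled range compressed to (0.40, 0.60), gradient correlation length
100 km). All presets set `drift_sdlog = 1.5`; the `SimulationConfig` default
is 0, which reproduces the pure sampling model exactly (identical per-site
expectations in the neutral limit). In the homogenized preset the distance
decay is carried by the spatially autocorrelated environment rather than a
dispersal kernel: when a kernel dominates, compressing the environmental
range *unmasks* the kernel signal and makes the homogenized group's decay
steeper, which is the opposite of the environmentally driven pattern the
regime represents.

Determinism: one master seed; per-stage child seeds derived with
`numpy.random.SeedSequence.spawn` (tree, traits, sites, communities), so
identical configurations give bit-identical outputs and stages can be
re-run independently. The tree stage feeds a derived integer seed to
dendropy's birth–death sampler.

What the generator does **not** emulate: sequencing-level artifacts
(chimeras, primer bias, OTU-clustering noise), temporal dynamics, soil-depth
structure, interactions between taxa, and realistic taxonomic richness
(hundreds of taxa, not thousands — analyses here run at desk scale). Tests
passing on these simulations therefore validate the statistical machinery
and the direction of regime contrasts, not field-scale effect sizes.

## Problem sizes and numerical conventions

Regime-recovery tests and the acceptance script run at 150 taxa,
19–20 + 24–25 samples, 199 null replicates and up to 9999 permutations —
sizes chosen so the full suite completes in minutes on one CPU while keeping
permutation granularity (p ≥ 1/200 for null models) adequate for the
directional claims being tested. Distance matrices are validated symmetric
within 1e-12 and symmetrised exactly; relative-abundance columns sum to 1
within 1e-9; Bray–Curtis ties in RC are detected with absolute tolerance
1e-10; PCoA eigenvalues within 1e-12 of zero are treated as zero. Alignment
of table/tree/metadata sorts all identifiers lexicographically so
permutation streams reproduce across platforms.

## Known limitations

- One-way designs only (two or more groups, single factor); no nested or
  multi-factor PERMANOVA.
- RC_bray follows the probabilistic occurrence+abundance null described
  above; other published variants (fixed row/column sums via swap
  algorithms) are not implemented.
- The βNTI null shuffles tips of the pruned per-class tree; shuffling
  against the full-community tree is not offered.
- Exhaustive Mantel is limited to n ≤ 7; exhaustive PERMANOVA enumerates
  only two-group splits.
- Distance decay drops zero-similarity pairs rather than modelling them; at
  high beta diversity (many disjoint pairs) the fitted slope describes the
  non-disjoint subset, and the excluded count should be inspected.
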
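# Methods

This note records the models implemented by `protcomm`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical conventions a user should know before
trusting a number.

## Table preparation

The pipeline starts from a denoised ASV table. Preparation follows the
standard order for soil 18S surveys:

1. **Taxon exclusion.** ASVs whose lineage contains any of
   {Fungi, Metazoa, Embryophyta} at any rank are dropped — general 18S
   primers co-amplify these groups, which are not protists. Matching is
   exact and case-sensitive on whole rank names; no substring matching,
   so an exclusion term can never silently remove a similarly named
   clade.
2. **Singleton removal.** An ASV whose total read count across all
   samples equals 1 is discarded.
3. **Rarefaction** to a common depth (default 18,907 reads) by
   multivariate-hypergeometric subsampling — uniform draws without
   replacement, a single seeded draw per sample. Samples below the
   depth are dropped (with a warning naming them) rather than kept
   unscaled, so all downstream row sums stay comparable. Averaging over
   multiple rarefaction draws is deliberately not done; one seeded draw
   keeps every downstream number bit-reproducible.

The counts-table orientation is declared by an explicit flag, never
guessed from the shape.

## Diversity

* **Shannon** uses the natural log on relative abundances of nonzero
  taxa; **Pielou's J** is Shannon / ln(richness), reported as missing
  (with a warning) when a sample has at most one taxon.
* **Chao1** uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)),
  which remains defined when no doubletons exist.
* **Faith PD** is root-inclusive: the total branch length of the
  minimal rooted subtree spanning the sample's taxa *and the root*.
  Unrooted conventions differ; the choice is stated here because it
  changes values on small trees.
* **Bray–Curtis** is computed on (rarefied) counts;
  **PCoA** Gower-centres −½d², takes the eigendecomposition, scales
  positive axes by √eigenvalue, reports negative eigenvalues (a sign of
  non-Euclidean input) but applies no Lingoes/Cailliez correction —
  their axes are simply omitted from the coordinates, with a warning.
* **PERMANOVA** is one-way per factor (cultivation mode and growth
  stage separately, matching the two reported effects; no interaction
  term), with unrestricted seeded label permutations and
  p = (1 + #{F* ≥ F}) / (1 + n_perm). R² is SS_among/SS_total from the
  same distance partition. Note that permutations occasionally
  reproduce the observed partition (probability 2·6!·6!/12! ≈ 0.2% for
  6+6 labels); such draws tie with the observed statistic, so the
  attainable minimum p can exceed 1/(n_perm+1) by a count of ties.
* **Tukey HSD** uses the Tukey–Kramer harmonic-mean correction for
  unbalanced groups. The fully degenerate case (zero within-group
  variance everywhere with equal means) is reported as p = 1 with a
  warning instead of NaN.

## Null-model assembly analysis

* **betaMNTD** is abundance-weighted by default (an unweighted variant
  is available by flag): each taxon contributes its relative abundance
  times the patristic distance to its nearest relative in the paired
  community; a shared taxon contributes zero.
* **betaNTI** standardizes betaMNTD against `n_null` shuffles of tip
  labels across the whole phylogeny, community matrix untouched — the
  standard null for phylogenetic turnover. The null sd uses ddof=1.
  Default `n_null` is 999; calibration experiments and the acceptance
  script use 199 for speed, which changes betaNTI values by Monte-Carlo
  noise of order 1/√199 relative to the null sd. Pairs with a null sd
  of 0 (e.g. on a star phylogeny, or when two samples share their
  entire taxon set so betaMNTD is 0 under every shuffle) are *undefined*:
  excluded from process fractions and counted in an `n_undefined`
  column, never silently dropped.
* **RCbray** assembles, per pair, `n_null` null sample pairs preserving
  each sample's observed richness and total count: taxa are drawn
  without replacement with probability proportional to occurrence
  frequency across samples; each drawn taxon is seeded with one
  individual (so richness is preserved exactly) and the remaining
  individuals are assigned multinomially with probability proportional
  to the taxa's total relative abundance. With
  RC_raw = (#{BC* < BC} + ½#{BC* = BC}) / n_null, the reported metric
  is RC = 2(RC_raw − ½) ∈ [−1, 1]; ties carry weight ½ symmetrically.
* **Partition.** Per pair: betaNTI > +2 → heterogeneous selection,
  betaNTI < −2 → homogeneous selection; otherwise RC > +0.95 →
  dispersal limitation, RC < −0.95 → homogenizing dispersal,
  |RC| ≤ 0.95 → drift. Fractions are computed over within-group pairs
  (mode × stage cells by default) because per-farmland-group
  percentages are the quantity of interest; both selection subtypes
  are always reported separately.

## Trophic traits

ASVs map to consumer / phototrophic / parasitic by taxonomic
affiliation. The packaged lookup table is a small curated subset keyed
mostly at higher ranks (ciliates, cercozoans → consumer; green algae,
diatoms → phototrophic; apicomplexans, oomycetes → parasitic) —
sufficient for common soil clades and the synthetic generator. A full
published matching table can replace it wholesale via a TSV with
columns `taxon, rank, trait`. When a lineage matches at several ranks,
the most specific rank wins; unmatched lineages are reported as
`unassigned`, and per-sample compositions (which sum to 1) always carry
the unassigned share explicitly.

## Production index

The composite fruit-quality index follows the multifunctionality-index
recipe: z-score each of the twelve measured parameters across samples
(sample sd, n−1 denominator), then average the z-scores within each
sample. All parameters enter with positive orientation by default —
no desirability flipping, since no orientation rule is established for
these parameters; a per-parameter sign vector allows flipping (e.g.
seed number, if fewer seeds are considered better). Zero-variance
parameters are excluded with a warning. Regressions of the index on
diversity or ordination axes are ordinary least squares with a
two-sided t-test on the slope.

## Environmental drivers

* **RDA** regresses the Hellinger-transformed relative-abundance table
  (square roots of proportions — the standard variance-stabilising
  choice for abundance RDA) on standardized soil variables, reporting
  the constrained proportion of variance and a permutation p-value from
  seeded row permutations of the predictor matrix. Rank-deficient
  predictor sets are rejected with the dependent columns named.
* **Random forest** ranks soil variables for a scalar community
  response — by default the first principal coordinate of the
  Bray–Curtis matrix, the axis that separates cultivation modes; any
  per-sample response can be supplied. The forest is a standard
  bootstrap regression forest; the fit score is out-of-bag R², and
  importances are classic out-of-bag permutation importances (mean OOB
  MSE increase per tree when one variable is permuted, floored at 0),
  implemented in-package on top of the fitted ensemble.

## Synthetic data

The generator emulates the survey's statistical structure, not its
sequences:

* A seeded pure-birth (Yule) tree with unit depth carries
  **niche optima** evolved under a Gaussian process along branches from
  a root value of 0. The default uses an early-burst variant — variance
  density σ²·e^(−12h) at height h — which concentrates niche divergence
  on deep splits and keeps close relatives tightly clustered (strong
  phylogenetic niche conservatism); plain Brownian motion is the
  `conservatism = 0` limit of the same routine. Optima are standardized
  to unit spread so gradient units mean the same thing across tree
  realizations. Early burst was adopted after plain Brownian motion at
  40 taxa proved unreliable: roughly a third of realizations carry too
  little clade-level niche separation for any environmental filtering
  to leave a detectable phylogenetic signature.
* Each mode × stage cell has a **nitrogen-like environmental value**:
  gradient_strength × (mode score + 0.5 × stage score) with mode scores
  −1/0/+1 (greenhouse < hilly < paddy, the direction observed in the
  field) plus per-sample noise of sd 1.5. The within-cell noise is
  deliberate: sampling points in one farmland differ in microhabitat,
  and it is what makes *heterogeneous* selection dominate within-group
  pairs, as observed in real surveys of this design.
* **Selection scenario:** sampling weights ∝ lognormal base abundance ×
  exp(−(optimum − E)²/(2σ²)) × per-sample lognormal drift
  (σ_niche = 0.4, drift sd 0.75, abundance log-sd 0.5). Filtering acts
  on weights (soft selection), so rarefaction and singleton filters
  still have work to do. **Neutral scenario:** the niche term is
  dropped; abundance log-sd rises to 3.0 and drift sd falls to 0.5.
  Both changes matter: with even abundances every taxon occurs in
  every sample and betaMNTD degenerates to zero for all pairs (no
  betaNTI defined), so sparsity must come from a strongly skewed
  abundance distribution that puts rare taxa at the detection edge;
  and drift noise must stay mild, because turnover much larger than
  the Raup–Crick null's own assembly variation reads as dispersal,
  not drift — the neutral regime should leave stochastic pairs inside
  the null envelope.
* Counts are multinomial at a Poisson(20,000) depth, above the 18,907
  rarefaction depth. Three **contaminant ASVs** (a fungus, a nematode,
  a land plant) are held at ~3% of reads outside the niche model, so
  taxon exclusion is exercised without dropping samples below depth.
* **Taxonomy**: protist tips are chunked over six clade templates in
  tree order and the chunks matched to templates by mean niche optimum,
  so phototrophs sit on the low-nitrogen (greenhouse) end and consumers
  on the high end — the trophic shift the design is meant to show.
* **Soil** (15 named variables) and **quality** (12 parameters) tables
  are Gaussian with mode- and stage-dependent means; the quality shift
  puts greenhouse one noise-sd below and the open-field modes half an
  sd above baseline.

What the generator does **not** emulate: realistic lineage strings
beyond what trait matching needs, read-level error, chimeras,
compositional correlations between soil variables beyond their shared
mode structure, thousands-of-ASV richness (it runs at tens of taxa), or
spatial autocorrelation between trees in one farmland. Passing tests
therefore show that the *methods* recover planted structure at desk
scale — not that any particular field result is correct.

## Problem sizes and determinism

Calibration and acceptance runs use 40 protist taxa, 6 samples per
mode × stage cell (36 samples), 199 null randomisations and 999
permutations — sizes at which the whole pipeline runs in minutes on one
CPU while leaving the null-model classification well resolved. Every
stochastic stage takes an explicit seed; the pipeline expands one
global seed into fixed per-stage streams (SeedSequence spawned by stage
index), so disabling one stage never shifts another's draws, and two
runs with the same config hash-match output for output.

## Known limitations

* betaNTI at 40 taxa has an intrinsically noisy null (sd over tip
  shuffles shrinks only as richness grows); per-pair classifications
  near the ±2 threshold are unstable at this scale and should be read
  in aggregate.
* High-overlap sample pairs (shared dominant taxa) are structurally
  difficult for the tip-shuffle null — shared taxa contribute zero
  under every shuffle — so homogeneous selection between near-identical
  communities is undetectable in principle; such pairs surface as
  undefined or low-|betaNTI|.
* The Raup–Crick null fixes richness and total count but not the
  species-abundance shape within a sample; its classification of
  dispersal processes inherits that choice.
* PCoA performs no correction for negative eigenvalues; ordinations of
  strongly non-Euclidean matrices under-represent total variance.
* The trait table ships as a minimal curated stand-in; real analyses
  should supply a complete published matching table.
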
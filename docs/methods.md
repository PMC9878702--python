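# Methods

This note documents the statistical machinery, the synthetic-data
generative model, the numerical choices, and the limitations of the
`mirweave` pipeline.

## Differential expression

Counts for feature *i* in sample *s* are modelled as negative binomial
with mean μ_is and dispersion α_i (variance μ + αμ²):

    log μ_is = log L_s + x_s' β_i

where L_s is the sample's library size (column sum) and x_s holds an
intercept, the case indicator, and the covariates Sex (0/1), Age, PMI,
pH and RIN, each continuous covariate quantile-scaled to normal scores
so that heavy-tailed or skewed covariates cannot dominate the fit.
Fitting is iteratively reweighted least squares, vectorised across
features (batched p×p normal equations), with a fixed dispersion per
feature.

Dispersion is estimated in two passes: an initial fit at α = 0.1, then
the Pearson method of moments on its residuals,
α̂_i = Σ_s[(y−μ̂)² − μ̂]/μ̂² divided by the residual degrees of freedom.
Raw estimates are shrunk toward the cohort median with a fixed prior
weight of 10 pseudo-degrees of freedom — a light-touch stabiliser for
small cohorts, far simpler than empirical-Bayes tagwise shrinkage but
serving the same purpose — and floored at 1e-4. Significance of the
group coefficient is a likelihood-ratio χ²₁ test against the
covariate-only model; q-values are Benjamini–Hochberg across tested
features. Features with mean count below 1 are excluded before
testing. On null simulations (no planted effects) the raw p < 0.05
fraction measures ≈ 0.06 over 2000 genes × 5 seeds: the plug-in
dispersion makes the LRT mildly liberal at n = 15 + 27, which the
acceptance band [0.03, 0.07] accommodates.

Thresholds mirror the study design the pipeline targets: genes at
strict |log2FC| > log2(1.5) and q < 0.05; miRNA candidates at
unadjusted p < 0.05 with no fold-change filter (screening, not
calling); an exactly zero fold change gets no direction. Library-size
offsets are used as-is — no TMM or upper-quartile factors — so
compositional shifts (many features changing in one direction) appear
as a small uniform offset in estimated fold changes, visibly so in the
20-feature miRNA universe.

## Target-set enrichment and network assembly

For one direction mode (e.g. up-miRNA/down-gene), the universe is the
genes measured in the DE analysis intersected with the compendium
universe; for each candidate miRNA of the mode's miRNA direction with
K ≥ 1 predicted targets in the universe, the statistic is the
hypergeometric upper tail P(X ≥ k) with n the DE genes of the mode's
gene direction and k the observed overlap. BH adjustment runs within
each mode across the miRNAs actually tested. Regulators at q < 0.05
contribute edges to their DE targets; the result is a strictly
bipartite graph. Cross-tissue overlap of target (or pathway) lists is
a fixed-list hypergeometric test over a declared universe — expected
overlap nK/N, p = P(X ≥ k) — not a ranked-list optimisation, so its
p-values are comparable across analyses but deliberately simple.

Fisher's two-sided p throughout is the point-probability rule (total
probability of tables, margins fixed, with point probability at most
the observed), and both exact tests are computed via log-gamma so
20 000-gene universes stay numerically safe. Both are checked
exhaustively against exact rational enumeration for every
parameterisation with N ≤ 30.

## Pathway and term enrichment

Pathway over-representation intersects every gene set with the
universe first (so unmeasured genes can never affect a p-value), tests
the hypergeometric upper tail, adjusts by BH across tested pathways,
and requires both q < 0.05 and at least two overlapping genes for a
call. Term meta-enrichment builds, per GO-style term, the 2×2 table of
[annotated vs not] × [significant vs not] pathways, takes the
two-sided Fisher p, BH across terms with at least one annotated
pathway, and flags *enriched* only when q < 0.05 and OR > 1 —
depletions are reported, never flagged.

## Coexpression modules, deconvolution, traits

The module core follows the weighted-correlation-network recipe with
an unsigned adjacency a_ij = |cor|^β (the conventional default when no
sign convention is declared). β is the smallest candidate power whose
scale-free fit R² — the squared correlation of log10 p(k) vs log10 k
over 10 connectivity bins — reaches 0.8, falling back to the best
fitting power. The topological overlap matrix is
TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with ℓ = A² off-diagonal;
it is verified against a brute-force triple loop to 1e-10. Clustering
is average linkage on 1 − TOM with a **static height cut** (default
0.995): a deliberate replacement for the dynamic hybrid tree cut,
trading adaptive branch detection for a fully specified, deterministic
and testable rule. Clusters below the minimum module size (default 5)
merge into `grey`; surviving modules take the conventional colour
palette in decreasing size order. On planted blocks of sizes 7–36 with
within-block correlation 0.8 plus 26 independent noise genes, the
default settings recover the partition with adjusted Rand index ≥ 0.95
and leave the noise genes grey. When target genes share a strong
common axis (e.g. all suppressed by the same amount), separating
sub-modules may need a harder power/cut than the defaults — both are
exposed.

Module eigengenes are the first principal component of
row-standardised member expression, unit variance, sign-oriented to
non-negative mean member correlation. Cell-type fractions come from
per-sample non-negative least squares of marker-gene expression on a
cell-type signature matrix, renormalised to sum to one — a
constrained-regression deconvolution that is exact on noiseless
mixtures and within 0.05 at 5% multiplicative noise; it stands in for
kernel-based methods (ν-SVR style) without their tuning surface.
Module–trait association is the Pearson correlation of each eigengene
with each numeric trait (deconvolved fractions + case status coded
0/1), significant at p < 0.05.

## Signature scores

A set's score in a corpus sample is the sum of its member genes'
z-scores, where each gene's log2(CPM + 1) is standardised across
corpus samples (sample sd, n−1). Standardising per gene across samples
is the only reading of "summed z-scores" that makes scores comparable
across sets of different baseline expression; a switch accepts
pre-normalised matrices. Constant genes are dropped before scoring;
sets left with a single scorable gene are flagged. Scores are
invariant to per-sample library rescaling. Set–set association is the
Pearson correlation of score vectors across the corpus, p < 0.05.

## Synthetic-data generative model

The generator produces every input the pipeline consumes, at the
scale of the motivating study: 15 control vs 27 case brain samples,
2000 genes, 20 miRNAs with 5 planted up-regulated regulators (+1 log2
in cases) each suppressing 40 disjoint target genes by −1 log2, NB
dispersion 0.1, a blood miRNA matrix for an 8 + 18 donor subset, a
425-sample reference corpus, 200 GOBP-like pathways and exactly 50
Hallmark-like sets. All are configurable; all randomness flows from
one seed through fixed per-component substreams, so outputs are
byte-reproducible and independent of call order.

Counts are NB(μ, α) (α = 0 handled as Poisson); library sizes are
log-normal with configured mean (2 × 10⁶) and CV (0.2). Effects are
additive on the log2 mean:

* **Covariate confounding.** Sample demographics mirror the motivating
  cohort (controls ≈ 87% male, 55 ± 14 y; cases ≈ 56% male, 39 ± 13 y;
  PMI, pH, RIN realistic), and per-gene Gaussian coefficients
  (sd 0.05–0.1 log2 per covariate SD) act on the standardised
  covariates — confounded with group through the demographic
  imbalance, hence removable only by the covariate-adjusted model.
* **Module coexpression.** Each planted module (one per regulator)
  shares a per-sample latent factor (sd 0.3 log2), *centred within
  each group* so residual coexpression stays orthogonal to the planted
  group effect — otherwise the factor would randomly shift each
  module's realised fold change and the planted −1 would not be the
  generative truth it claims to be. A separate block generator
  (`simulate_coexpression_blocks`) provides exact-correlation blocks
  for module-detection benchmarks.
* **Cell types.** Dirichlet per-sample fractions over 4 types
  (astrocytes, neurons, endothelial, microglia); 20 marker genes per
  type scale with the sample's fraction, and the matching signature
  matrix is derivable from the ground truth, so deconvolution has an
  exact generative target.
* **Cross-tissue coupling.** Each miRNA carries a per-donor latent
  value (sd 0.2 log2) expressed in brain and, scaled by a loading with
  extra noise, in blood — so a miRNA's brain–blood correlation across
  shared donors is planted and tunable. Regulator induction is
  systemic (same miRNAs shift in both tissues).
* **Corpus structure.** Hallmark-like set k loads on latent factor k
  (loading 1.0, noise sd 0.1 on log2 means); planted module m shares
  factor m, so module-vs-pathway score correlation over the corpus is
  a planted quantity (≈ 0.97 realised, vs ≈ 0.04 median |r| for
  independent pairs).

Miscellaneous scales chosen once: gene baseline abundances log-normal
(sd 1.5 log2); miRNA baselines tighter (sd 1.0 log2) because a
20-feature library is a scaled-down stand-in for a real miRNome of
hundreds of species — with heavier tails a single dominant regulator's
induction would swing total library mass enough to mask the screen
entirely, which is a property of the miniature universe, not of the
biology being emulated. Relative abundances are *not* renormalised
after planting effects, so suppressing 10% of the transcriptome
lightens case libraries by ≈ 5% and shifts estimated fold changes by
≈ +0.07 log2 — the usual compositional footprint, left visible on
purpose.

Decoy structure makes the enrichment null exact: non-regulator miRNAs
get uniformly random target sets, and true regulators' predicted sets
are their planted targets plus an equal number of random decoys.

### What the generator does not emulate

No sequence biology (seed matching, binding energies), no isoform or
length effects, no batch structure beyond the five covariates, no
unknown unwanted-variation factors (the model adjusts for *known*
covariates; the study's residual-factor approach is intentionally out
of scope), no overlap between target sets of different regulators, and
identical regulator identities in brain and blood (the motivating
study found disjoint miRNAs with overlapping targets; here the overlap
arises trivially). Passing recovery tests therefore demonstrates that
the statistical machinery is correct and calibrated under its stated
assumptions — not that those assumptions hold in any particular real
dataset.

## Pipeline, problem sizes, determinism

The driver runs nine stages (simulate → DE → integration in all four
modes for brain and blood candidates → pathway enrichment → term
meta-enrichment → modules → deconvolution + traits → signature scores
→ overlap statistics), writing TSV/GMT/SIF/JSON outputs with a
manifest of the seed and every threshold. All writers emit stable
formatting, and two runs with one seed are byte-identical. Default
problem sizes (2000 × 42 genes, 425 × 2000 corpus) complete in a few
seconds; the acceptance script's multi-seed recovery studies use 10
seeds for the integration recovery and 5 for null calibration, sizes
at which the measured quantities are stable to the reported precision.

## Known limitations

* The plug-in dispersion LRT is mildly anti-conservative at small n
  (measured ≈ 0.06 at nominal 0.05); an F-type correction or
  empirical-Bayes moderation would tighten it at the cost of departing
  from the plain method-of-moments contract.
* The static tree cut cannot split nested modules that merge below the
  cut height; strongly shared axes (all-DE gene panels) may need a
  higher power or lower cut than the defaults.
* Fixed-list overlap p-values ignore list acquisition (both lists come
  from thresholded screens on the same data), so they overstate
  certainty for overlapping pipelines; treat them as descriptive.
* NNLS deconvolution assumes the signature spans the bulk mixture;
  unmodelled cell types bias fractions toward the nearest modelled
  profile.
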
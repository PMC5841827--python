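# Methods

This note records the models behind `rhizochron`, the assumptions they
make, the defaults they ship with, and the boundaries of what the test
suite demonstrates.

## Data model and normalization

The unit of analysis is an OTU count table (OTUs × samples) with
per-sample design covariates: site, season, compartment (bulk soil,
rhizosphere, rhizoplane, endosphere — coded as spatial positions
0–3), plant age in days, genotype, developmental stage on a 1–27 scale
(panicle initiation = 18), watering treatment, soil, and sequencing
run. Counts are converted to per-mille relative abundance (count ÷
sample depth × 1000, so each sample column sums to 1000), and OTUs
observed in fewer than 5% of samples are removed before analysis
(removal is strictly-less-than; presence means count > 0; the filter is
idempotent). Taxonomy is parsed from Greengenes-style lineage strings;
rank aggregation conserves per-sample totals, with unassigned taxa
pooled into an explicit `unclassified_<rank>` row and an option to
replace the Proteobacteria phylum by its classes.

## Community structure

Bray-Curtis dissimilarity d(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) is computed on
per-mille profiles, by default after a log2(x + 1) transform — the
pseudocount of 1 per mille makes the log defined at zero; both the
transform and the pseudocount are caller options, and nothing downstream
assumes one choice. PCoA is classical metric scaling: double-center
−½d², eigendecompose; coordinates span the positive-eigenvalue axes,
negative eigenvalues are reported but not embedded, and proportion
explained is taken over the positive part of the spectrum.

PERMANOVA follows the adonis convention: sequential (Type-I) sums of
squares in the user's term order, computed as traces of projection
differences against the Gower-centered matrix; the p-value for each
term is (#{F_perm ≥ F_obs} + 1)/(n_perm + 1) under unrestricted row
permutations (no strata). Numeric covariates with many distinct values
enter as a single regression column; categorical terms as dummy blocks.

The time-point similarity matrix summarizes stabilization: cell
(t₁, t₂) is the mean of (1 − d) over cross-time-point sample pairs
within one compartment, z-scored by that compartment's overall cell
mean and standard deviation (grand mean 0 by construction).

## Taxon trends and colonizer classes

Proportions in (0, 1) are modeled with beta regression: y ~
Beta(μφ, (1−μ)φ), logit(μ) = β₀ + β₁x, constant precision φ, maximum
likelihood via `statsmodels`' Beta likelihood with a log link on φ,
Wald z-tests on coefficients. Exact 0/1 observations are compressed by
y′ = (y(n−1) + 0.5)/n before fitting. The spatial covariate is the
position code 0–3 treated as numeric (a single slope per taxon);
temporal fits run per compartment with age in days. Significance is
Bonferroni-adjusted within the set of taxa tested in one call. Seasons
are pooled by default.

Colonizer classification is deliberately simpler: per OTU, an OLS slope
of per-mille abundance on age with a two-sided t-test, Bonferroni over
the supplied OTU set; significantly negative → early, significantly
positive → late, otherwise complex. A constant profile is complex by
convention.

## The sparse random-forest maturity model

Training data are a stratified random half of the samples within each
time point × compartment cell (ceil(n/2) per cell to the training
side). A full random-forest regression (500 trees, features-per-split
= p/3, unlimited depth — the regression conventions; all exposed) maps
OTU abundances to plant age or developmental stage. OTU importance is
out-of-bag permutation importance: per tree, each feature used by that
tree is permuted among the tree's out-of-bag samples and the rise in
OOB mean squared error recorded; features a tree never splits on
contribute zero, which is also what makes the computation cheap at
thousands of OTUs.

Feature elimination evaluates the top-k ranked OTUs for k on a halving
schedule (p, p/2, …, 1) by 10-fold cross-validation, refitting a
(smaller, 100-tree) forest inside each fold using the global ranking.
The automatic subset choice is the smallest size whose CV error is
within 5% of the curve's minimum; fixed sizes (85 for age, 54 for
stage) are available as overrides and are the right choice when the
goal is a marker panel rather than a minimal predictor — with strongly
correlated successional taxa the CV curve is shallow and the automatic
rule may legitimately return a handful of OTUs. The sparse model is a
fresh forest on the selected OTUs only.

At prediction time, model OTUs absent from the incoming table are
imputed as 0 per mille with a warning; more than 50% missing aborts —
the model does not transfer to such data. Residuals (predicted −
actual) are the maturity signal; contrasts of predictions or residuals
across design factors use sequential ANOVA plus Tukey HSD pairwise
comparisons. Models serialize to JSON (selected OTUs, provenance, and
per-tree child/feature/threshold/value arrays), so a saved model is
portable and inspectable without unpickling anything.

## Site dynamics

Between-site convergence collects cross-site Bray-Curtis distances
within each common time point × compartment. The trend test regresses
the per-time-point *mean* distance on age: pairs inside one time point
share a sampling realization, and pair-level OLS overstates the degrees
of freedom badly enough to declare ±10⁻⁴ slopes significant under a
static-soil null.

Site-skewed OTUs are detected per time point × compartment with a
conditional negative-binomial exact test. Library sizes are equalized
by rescaling each sample to the family's median depth (rounded);
group sums are modeled as sums of i.i.d. NB counts with common mean and
a given dispersion φ (variance μ + φμ²). Conditioning on the total
makes the split distribution free of μ (negative hypergeometric;
conditional binomial at φ = 0), and the two-sided p-value sums the
probabilities of all splits no more probable than the observed one.
Dispersions are method-of-moments tagwise estimates moderated toward an
abundance trend φ(μ) = a + b/μ fitted across the family: rare taxa in
compositional count data are genuinely more dispersed, so a flat common
value is anti-conservative for them. Moderation is asymmetric —
below-trend tagwise values (mostly estimation noise at few replicates)
are raised to the trend, above-trend values keep half their tagwise
excess — which in null simulations holds the family-wise error at or
below α where symmetric 50/50 shrinkage measurably exceeded it. This
is an approximation to full empirical-Bayes dispersion machinery, not a
replication of it, and no claim is made of numerical agreement with any
particular differential-abundance package.

The site-specific fraction is the per-sample per-mille total over the
union of ever-significant OTUs, with an OLS age trend per compartment.
Genotype trajectories are compared on a principal-coordinate axis:
within each compartment and each season window (age ≤ 84 d, > 84 d),
`coordinate ~ age` is tested against `coordinate ~ age × genotype` with
a nested-model F-test, alongside per-genotype slopes. The axis is a
caller choice: in a multi-compartment, multi-site ordination the
developmental axis is typically the second coordinate, while in a
single-compartment single-site ordination it is the first.

## The synthetic community generator

Per OTU and sample, log abundance = baseline + affinity·position +
w(position)·curve(dev_time), where dev_time = age × the genotype's
development rate, and the archetype curve is a falling logistic
(early colonizers), rising logistic (late), Gaussian bump (complex), or
constant (static). Compositions are renormalized to the simplex,
optionally drought-perturbed, and sampled as Dirichlet-multinomial
counts at log-normal depths.

Defaults, and why:

* **Archetype mix** 15% early, 25% late, 10% complex, 50% static; 20%
  of early OTUs are site-specific, and 10% of static OTUs are
  bulk-soil-leaning site-specific taxa (persistent soil differences
  between fields, which decaying early taxa alone cannot produce).
* **Succession midpoints** are drawn with sd 25 d around the
  developmental time at which the 1–27 stage scale reaches 18
  (140·17/26 ≈ 91.5 dev-days), clipped to [30, 110] so every dynamic
  OTU actually transitions inside the sampled window. Tying the center
  of turnover to panicle initiation makes the aggregate early→late
  dominance switch track entry into reproductive growth for every
  genotype; the wide spread staggers turnover across the season so age
  signal is available everywhere, not only near the switch.
* **Succession weights by position** (0, 0.7, 0.9, 1.0): succession is
  plant-driven, so bulk soil does not track plant development and the
  endosphere tracks it most strongly.
* **Abundance**: static taxa draw baseline N(0, 1.2); successional
  colonizers N(1, 1) — they are moderately abundant, not incidental
  rare taxa; site-specific early colonizers N(2, 0.7) and root-enriched
  (affinity N(1.0, 0.3)), because site-specific taxa compose a large
  share of the early-season root community and the site signal is
  strongest inside the root. Amplitudes are uniform on [2, 4] log
  units (an order-of-magnitude seasonal swing).
* **Site-specific taxa come in niche-equivalent pairs**, one member per
  site with identical parameters (odd leftovers become shared taxa).
  Unbalanced site-specific loads would shift the renormalized share of
  *every* shared OTU between sites, and the exact test then correctly
  reports hundreds of shared taxa as site-skewed — a compositional
  spillover that would drown the planted signal.
* **Noise**: Dirichlet concentration 1000 (per-sample compositional
  overdispersion) plus per-OTU, per-sample lognormal jitter with
  σ = 0.5 (plant-to-plant heterogeneity). Together these make any
  single taxon a noisy age predictor (CV ≈ 0.7 for a median-abundance
  OTU) while the community-level signal stays strong — the regime in
  which a sparse *panel* of markers is meaningful. The two sources are
  deliberately moderate individually: pushing the Dirichlet
  concentration much lower gives rare taxa Beta-tailed marginals that
  no negative-binomial dispersion can match, and exact-test error
  control degrades for reasons unrelated to the code under test.
* **Drought** multiplies early-colonizer latent abundance by
  (1 + severity) and late by its inverse in drought-arm endospheres,
  attenuated by a configurable factor (default 0.25) in the
  rhizosphere, then renormalizes; severity defaults to 0.8.
* **Depth**: log-normal around 20,000 reads (σ = 0.3 on the log scale),
  floor 100.

What the generator does **not** emulate: phylogenetic correlation among
OTUs (taxonomy is assigned, not evolved), sequencing-run batch effects,
chimeras and contaminants, within-plot spatial autocorrelation,
interactions among taxa beyond compositional coupling, and
genotype-specific taxa (genotypes differ only in developmental rate).
Passing tests therefore demonstrate that the statistical machinery
recovers the structure this model plants at realistic noise levels —
not that field data meet the model's assumptions.

## Scenario configurations used by tests and the acceptance script

Problem sizes are chosen so the full suite runs in a couple of minutes
on one core while leaving each check statistically meaningful:

* *Sparse age pipeline*: one site, rhizosphere + endosphere, 10
  time points (7–133 d, 14-d spacing), 6 replicates — 60 endosphere
  samples, half for training; 1,000 OTUs of which 30 (15 early + 15
  late) carry signal; sparse size fixed at 85.
* *Structure/site stages*: two sites × four compartments × 10 time
  points × 3 replicates (240 samples), 300 OTUs, default archetypes.
* *Genotype comparison*: rates 1.0 vs 0.6 with succession midpoint 35
  dev-days (sd 3, logistic scale 4) and no complex taxa, so succession
  completes within the season for both genotypes: the slow genotype is
  still mid-transition at the day-84 split (ordered early-season
  slopes) but plateaued afterward (null late-season interaction). This
  mirrors the mid-season stabilization structure of real crop
  microbiota; with the default late midpoint the slow genotype would
  still be turning over after day 84 and no late-window null exists.
* *Drought*: severity 0.8 with zero rhizosphere attenuation (the
  endosphere-specific scenario), markers taken from ground truth,
  contrasts on residuals (age-adjusted maturity).
* *Calibration*: PERMANOVA null over 200 label-permuted simulations
  (199 permutations each); exact-test family-wise error over 40
  NB-null families of 80 OTUs × 8 replicates per site.

## Numerical conventions

Importance ties break lexicographically by OTU id. The halving schedule
uses integer floor division. The exact test treats splits within 10⁻¹⁰
relative log-probability of the observed split as ties (included in the
p-value). Zero-total exact tests return p = 1. Beta-regression
non-convergence is flagged on the fit object, never silently dropped.
Per-mille subcompositions (row subsets) intentionally skip the
column-sum invariant. All stochastic stages take explicit seeds; the
pipeline derives per-stage seeds from one master seed by hashing, and
its manifest records content digests but no timestamps, so a seed fully
determines the output bytes.
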
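# Methods

## Scope and model

`comethyl` implements the analysis path of a two-group methylation-array
cohort study: normalization → value-scale conversion → differential
screening → region aggregation → weighted co-methylation network → module
summaries → hub selection → gene-set over-representation. The groups are
labelled `case` (drug-hypersensitive) and `control` (drug-tolerant); group
sizes are configuration, not constants.

### Value scales

The methylation fraction at a CpG is

* β = M_int / (M_int + U_int + α), with methylated/unmethylated channel
  intensities and offset α (default 100, the array convention). With α > 0,
  β < 1 strictly; with α = 0 and both channels zero, β is defined as 0.
* M = log₂(β / (1 − β)), the logit. β is clipped to [ε, 1 − ε] (ε = 1e-6)
  before the logit so boundary values stay finite; the inverse is
  β = 2^M / (1 + 2^M). On typical intensities (most above 1000) the α offset
  is negligible and the logit form is treated as the operative M definition.

Statistics and network correlations use M (unbounded, closer to
variance-stable); effect sizes are reported as Δβ (interpretable as a
methylation-percentage difference).

### Normalization and QC

Raw-data (IDAT-level) normalization needs control probes this package never
sees; instead classic quantile normalization is applied at matrix level:
every sample's sorted values are replaced by the across-sample mean of
sorted values, mapped back through ranks (ties share interpolated targets).
When intensities are available, both channels are stacked per sample and
normalized jointly so they share one target distribution; otherwise β is
normalized directly. QC drops probes whose missing fraction exceeds 5%
(configurable) and median-imputes the remainder; pure drop-incomplete
behaviour is selectable. Published quality-check criteria for such arrays
are usually wet-lab-side, so this missingness policy is a package decision.

### Differential screening

Per feature, a two-sided two-sample t-test on M values (pooled variance by
default, Welch selectable). The paired test sometimes named in array
workflows cannot apply to independent groups of unequal size, so the
unpaired test is the operative p-value everywhere (including gene
significance below); a limma-style moderated test is out of scope.
Degenerate features: zero pooled variance with equal means → t = 0, p = 1;
with unequal means → p is set to the smallest positive normal double and the
feature is flagged. FDR is Benjamini–Hochberg, implemented as the step-up
q_(i) = min_{j≥i} p_(j)·n/j (clipped at 1) and cross-checked against an
independent oracle and statsmodels in the tests.

The *combined rank* orders features by reliability across three criteria:
ascending ranks of −|Δβ|, of p, and of q (ties broken by feature id so each
rank is a permutation of 1..n), combined as the maximum — a feature is only
as good as its worst criterion. Improving any one criterion can never worsen
the combined rank.

Regions (tiling window / gene / promoter / CpG island, ids taken from the
annotation) are summarized as the per-sample mean of member-probe M values
and screened with the identical test; a mean (rather than p-value
combination) keeps regions usable as network nodes. Promoter summaries use
only probes flagged as annotated protein-coding promoters, mirroring the
exclusion of ribosomal-RNA, pseudogene and unannotated promoters.

### Network construction

On promoter M profiles x_i (features × samples):

* unsigned adjacency a_ij = |cor(x_i, x_j)|^β′, diagonal 1. Zero-variance
  features are rejected by name before this step.
* soft power β′: for each candidate (1..20) the connectivity
  k_i = Σ_{j≠i} a_ij is binned into 10 equal-width bins on log₁₀ k (empty
  bins dropped), log₁₀ of the bin frequency is regressed on log₁₀ of the bin
  mean, and the signed fit is −sign(slope)·R². The chosen power is the
  smallest reaching 0.8, else the argmax; an explicit user power (the
  reference study used 14) always wins.
* topological overlap TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) /
  (min(k_i, k_j) + 1 − a_ij). Conventions that make the worked cases
  well-defined: adjacency diagonal 1, k excludes the diagonal, the cross-term
  excludes u ∈ {i, j}, TOM diagonal set to 1. Dissimilarity is 1 − TOM.
* modules: average-linkage hierarchical clustering on distTOM, static cut at
  height 0.97 (default), clusters below 30 features → grey, survivors
  labelled by descending size with the fixed turquoise/blue/brown/… palette.
  Modules whose eigengenes are closer than the merge height 0.15 are merged
  iteratively (closest pair first, eigengenes recomputed each round). The
  published "cut-off 0.15" is read as this eigengene-merge height — as a raw
  distTOM cut it would shatter realistic data into thousands of fragments —
  and both heights are exposed.
* eigengene ME: leading right-singular vector (over samples) of the
  standardized member profiles, rescaled to unit sample variance and
  sign-oriented so members correlate positively with it on average.
* gene significance GS_i = −log₂(p_i) from the region-level screen (base 2
  as the workflow defines it; a base-10 switch exists); p = 0 is capped at
  the zero-variance flag value. Module membership MM_i = cor(x_i, ME).
  Hubs: per module, the top-20 by MM, annotated with whether GS clears
  −log₂(0.05). Intramodular connectivity (kWithin) is also emitted, but MM
  is the operative hub axis. Edge export emits unordered feature pairs with
  weight ≥ a link-relevance threshold (default source TOM, |cor| selectable;
  which of the two a published threshold refers to is often ambiguous).

### Over-representation

For each (module, gene set): upper-tail hypergeometric p = P(X ≥ overlap)
with population = universe, successes = set ∩ universe, draws = module size —
equivalent to one-sided Fisher. The universe is the set of annotated
promoter genes that entered the network (not the genome), avoiding
background inflation. BH is applied within module across sets; GO-hierarchy
propagation is out of scope — sets are flat GMT.

## Synthetic cohort generator

Per sample s: module factors F_k(s) ~ N(0,1), standardized to exactly unit
sample variance. Promoter r in module k has the M-scale profile
m_r(s) = b_r + u_r F_k(s) + δ_r·1[s case] + e_r(s) with baseline
b_r ~ N(0, 1), loading u_r ~ U(0.5, 0.9) by default, noise e_r ~ N(0,
noise_sd); null promoters omit the factor term. Each promoter spans
1 + Poisson(16) CpG positions (mean 17, the array's per-gene density);
position j adds a fixed offset c_j and noise ε_rj, both N(0, 0.3). β is the
inverse logit of M; the total intensity T ~ LogNormal(median 5000, log-sd
0.3) splits into M_int = βT, U_int = (1 − β)T, so the α = 100 offset
produces a small visible shrinkage when β is recomputed. Group sizes default
to 15 cases vs 20 controls, echoing the motivating cohort; default module
layout is K equal modules jointly covering 60% of promoters. Everything is
deterministic given the seed.

Effects are planted on the M scale, not β: the network runs on M values, and
a β-scale shift would have variance-dependent magnitude after the logit.

What the generator emulates: module-driven co-methylation, group mean
shifts, realistic intensity magnitudes, per-position heterogeneity. What it
does not: Infinium I/II chemistry bias, batch effects, sex chromosomes,
cell-composition effects, spatial correlation along the genome. Passing
planted-recovery tests therefore demonstrates the machinery, not robustness
to those artefacts.

A second generator, `simulate_power_law_profiles`, plants scale-free
connectivity for exercising the soft-threshold scan: single-factor profiles
whose soft-powered communalities follow a truncated Pareto (exponent 2,
communality 0.3–0.95), drawn at a large sample count (5000) because the
planted law lives in population correlations — at cohort-scale n the
estimation noise of near-zero correlations dominates the low-connectivity
tail and hides the law. This dataset is a demonstration of the fit
machinery, not a cohort model.

## Numerical choices

* logit clip ε = 1e-6; zero-variance p stand-in = smallest positive normal
  double (so −log₂ caps near 1022).
* per-criterion and per-module ties always break deterministically (feature
  id lexicographic), making runs reproducible.
* quantile normalization uses average ranks with linear interpolation into
  the reference, so ties share their target mean.
* eigengene orientation uses the mean member correlation; a single-member
  module's eigengene is its standardized profile (with a warning).
* all written tables print floats at 10 significant digits; re-reading
  reproduces values to < 1e-9.
* the run-directory log deliberately contains no wall-clock information
  (timings go to stderr), so same-seed runs are byte-identical.

## Problem sizes used in the test and acceptance runs

The shipped validation uses a 300-promoter study (three 60-promoter modules
plus 120 null promoters, ≈5100 CpG positions, 35 samples), 200 replicate
500-position null cohorts for FDR calibration, 1000-feature power-law
networks, and 50 random 20-node networks for the topological-overlap oracle.
These sizes give stable Monte-Carlo margins while keeping the whole suite in
the tens of seconds; all are configuration, and the estimators scale to the
tens of thousands of promoters of a real array within ordinary memory
(the TOM for 21k promoters is ≈3.5 GB in doubles — block-wise decomposition
is a non-goal).

## Known limitations

* Hub identification by MM cannot distinguish members whose true eigengene
  correlations differ by less than the sampling noise of a correlation at
  the cohort's n. With loadings confined to [0.7, 0.9] and noise sd 0.2 at
  n = 35, true MM spans only ≈[0.96, 0.98] while the estimate's sd is ≈0.01,
  so the top-20-by-MM list recovers only ≈50–65% of the top-20-by-loading
  members. This is an identifiability limit of such study conditions, and
  the corresponding planted-recovery check is expected to fail at those
  settings; hub lists on real cohorts of this size should be read as "high
  MM", not as a faithful ordering within a tight MM band.
* The t-test (even Welch) is not a moderated/limma-style test; at very small
  n its p-values are noisier than shrinkage-based ones.
* Quantile normalization assumes comparable global methylation
  distributions across samples; strong global shifts would be flattened.
* The static-cut clustering is simpler than dynamic tree cutting; very
  unbalanced module structures may need a tuned cut height.
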
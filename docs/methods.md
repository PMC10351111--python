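# Methods

This note documents the statistical models behind `twinmeth`, the defaults
and why they were chosen, what the synthetic cohort generator does and does
not emulate, and the numerical choices that matter for reproducibility.

## The co-twin design

Monozygotic (MZ) twins share their genome and, largely, their rearing
environment. Within a pair, genetic and shared-environment influences are
statistically inseparable, so the generator and the inference both collapse
them into a single *familial factor* per pair. Two consequences drive the
design:

* association tests must account for the within-pair correlation of both
  trait and methylation — hence cluster-robust GEE with the pair as
  cluster; and
* the co-twin's exposure carries the familial part of the signal but not
  the individual causal part — the lever that ICE FALCON uses to separate
  causation from familial confounding.

## Preprocessing

* **Coverage capping** (`cap_coverage`, default q = 0.90): read depths above
  the 90% quantile of all non-missing cells are winsorized to that
  quantile. Capping, rather than removing high-coverage sites, keeps the
  best-measured CpGs; since downstream analysis uses β only, the cap is
  currently informational unless coverage-weighted options are added.
* **Site filters** (`filter_sites`): drop CpGs with mean non-missing
  β < 0.05 (essentially unmethylated; M-values there are noise-dominated)
  or with more than 10 missing observations out of the cohort's
  individuals. Boundaries are inclusive for keeping (mean β = 0.05 stays,
  exactly 10 missing stays), matching rules phrased as "< 0.05" and "more
  than ten". The missing-value count is per individual, not per pair.
* **Scale change**: M = log₂(β/(1−β)). β is clipped to [ε, 1−ε], ε = 10⁻⁶,
  before the log; unclipped β ∈ {0, 1} would produce infinities that poison
  regression. The inverse is β = 2ᴹ/(1+2ᴹ); the round trip is exact to
  < 10⁻⁹ over M ∈ [−10, 10].
* **Pair inclusion** (`select_discordant_pairs`): pairs with intra-pair
  |ΔFPG| < 0.1 mmol/L are removed as a whole (both members). The comparison
  tolerates float representation error at the boundary (10⁻⁹).
* **Outliers** (`remove_m_outliers`): optional per-site Tukey fence at
  3×IQR on the M scale; off by default. The fence choice is ours — it is a
  sensitivity-analysis knob, not a headline setting.

## Cell-type adjustment (ReFACTor-style)

Sites standardized across samples; rank-k SVD approximation; per-site
reconstruction distance; keep the t lowest-distance sites; return the first
d principal-component scores of the samples over those sites. Defaults
k = 5 assumed cell types, t = 500 informative sites, d = 5 components —
d is fixed by the analysis design (five composition covariates); k and t
follow common reference-free practice and are exposed as configuration.
Missing cells are imputed by the site mean (deterministic); constant sites
are excluded from selection with a warning; component signs are fixed by
making each component's largest-magnitude site loading positive.

## Association scan

Per CpG: M ~ FPG + age + sex + DBP (+ smoking, drinking in sensitivity
mode) + d composition scores, estimated by GEE with Gaussian family,
twin-pair clusters and robust sandwich covariance. Methylation is the
response and FPG the exposure; the reported coefficient is in M-units per
mmol/L. Working correlation is exchangeable by default (natural for twin
pairs); independence is offered — its point estimates equal ordinary least
squares exactly, and with robust errors both workings are asymptotically
valid. Sex is coded female = 0 / male = 1, smoking and drinking
never = 0 / ever = 1; zero-variance covariates are dropped with a warning
rather than crashing a sensitivity run. p-values use the two-sided normal
approximation to the robust z; no small-sample t correction is applied
(see Limitations). Sites failing preconditions (fewer than 10 complete
pairs, collinear design) get missing statistics with a logged reason.
q-values are Benjamini–Hochberg step-up, computed in-house and tested
against the brute-force definition q_i = min_{p_j ≥ p_i} m·p_j/rank_j.

Nearest-gene labels come from user-supplied intervals (BED input, 0-based
half-open, converted to 1-based closed internally): distance 0 inside a
gene, ties broken by distance then lexicographic symbol.

## DMR detection (combined p-values)

1. **Autocorrelation**: z_i = Φ⁻¹(1−p_i); Pearson correlation of z over all
   same-chromosome site pairs, binned by distance (bin width 50 bp, max lag
   500 bp); negative estimates clipped to 0, everything capped at 0.99.
2. **SLK smoothing**: each site is combined with neighbors within ±500 bp:
   z_comb = Σz_j / √(1ᵀΣ1), Σ_jk = acf(distance), Σ_jj = 1; adjusted
   p = 1−Φ(z_comb). An isolated site keeps its raw p. With identity Σ this
   reduces exactly to the classic unweighted Stouffer combination.
3. **Region growth**: maximal runs of sites with adjusted p < 0.05 where
   consecutive qualifying sites are ≤ 500 bp apart; singletons allowed.
4. **Scoring**: the region's *raw* p-values are SLK-combined (slk_p), then
   Šidák-corrected: sidak_p = 1−(1−slk_p)^(total_span/region_span), with
   region span = end−start+1 bp and total span the sum of per-chromosome
   extents of tested sites. sidak_p ≥ slk_p always.

All four parameters (seed p 0.05, join distance 500 bp, window 500 bp, bin
width 50 bp) are package defaults — the combined-p literature publishes no
single canonical setting — and are logged and configurable. Significance is
thresholded on sidak_p by default; `threshold_on="slk"` reproduces
reports whose significance column is the slk-corrected p.

Calibration on 10,000-site null tracks with mild autocorrelation: ≤ 1
falsely significant region per track on average (measured ≈ 0.2); an
implanted 20-site region with p ~ Beta(0.05, 1) is recovered in ≥ 90% of
runs (measured 100%).

When relating a top-site list to detected regions, `region_site_coverage`
reports positional overlap and, optionally, annotation-concordant overlap
(site and region must carry the same gene symbol). At gene-dense loci the
nearest-gene labels of a single CpG and of a region legitimately disagree,
and the concordant mode restricts the count to sites the region plausibly
annotates; both modes are reported by the acceptance script.

## ICE FALCON

For each CpG and direction, with every individual serving once as "self"
(making all results invariant to within-pair ordering), three models are
fitted with covariates carried along:

* Model 1: outcome on own exposure → β_self;
* Model 2: outcome on co-twin's exposure → β_cotwin;
* Model 3: outcome on both → β′_self, β′_cotwin.

Fits are GEE with independence working correlation (ordinary least-squares
point estimates with pair-cluster sandwich errors); this makes the
pair-level nonparametric bootstrap exact and fast, and the package's
internal fitter is cross-checked against an independent GEE implementation
in the tests. Under pure familial confounding both coefficients attenuate
proportionally between the marginal and joint fits; under a causal effect
of the exposure the co-twin coefficient collapses much more. The ratio
(β_cotwin−β′_cotwin)/(β_self−β′_self) is computed signed from the observed
fits (undefined when the self change is exactly zero), and a direction is
called causal when |ratio| > 1.5 **and** the co-twin change is significant
at α = 0.05. The significance rule is part of the operational definition:
a huge ratio with a noisy, non-significant co-twin change is not a causal
call. Change p-values come from a pair-bootstrap (B = 1000 by default,
minimum 100): pairs resampled with replacement, all three models refitted
per replicate (batched normal-equation solves from per-pair Gram blocks),
SE = the replicate standard deviation, p = two-sided normal. Runs with
more than 20% failed replicates abort.

Measured operating characteristics at 500 pairs with strong effects
(100 seeded cohorts): true-direction detection 100%, false causal calls on
purely confounded sites ≈ 2% per direction, null sites flagged at ≈ the
nominal 5% per direction. Note that a truly causal exposure-outcome pair
may legitimately produce calls in both directions (the reverse analysis
also departs from the pure-confounding pattern); directionality statements
therefore rest on the per-direction calls, not on exclusivity.

## Targeted validation

Group comparisons use the Wilcoxon rank-sum test (normal approximation with
tie and continuity corrections; default, robust to non-normal methylation
fractions) or Student's t test via a flag. The case-minus-control mean
difference is reported with its sign so replication-direction checks are
mechanical. Disease association uses binary logistic regression adjusted
for CHOL, TG and LDLC, reporting the odds ratio per unit (and per 0.01)
methylation fraction with Wald CI and p. Perfect separation and
zero-variance predictors are rejected explicitly rather than returning
divergent estimates.

## Synthetic cohort generator

Per pair p and twin i, with one familial factor F_p ~ N(0,1):

* latent FPG: l_i = β_age·age_std + β_sex·sex + √ρ·F_p + √(1−ρ)·ε_i, and
  FPG = 5.44·exp(0.15·l_i) mmol/L — median 5.44 with a right-skewed,
  strictly positive distribution. The published cohort reports only the
  median and 95% range, so the log-normal shape is a stand-in, not an
  estimate.
* ρ is *calibrated* (cached bisection against a 100,000-pair pilot with a
  fixed internal stream) so that the **realized** intra-pair correlation —
  after the |ΔFPG| ≥ 0.1 rejection step, which preferentially removes
  concordant pairs — equals `r_target`, default 0.68, the reported FPG
  heritability in the emulated population. Without calibration the
  realized correlation runs ≈ 0.03–0.06 below the latent one.
* scenarios per CpG: `null` (familially correlated methylation,
  M = γG_p + e, γ = 0.7), `confounded` (M loads on F_p itself),
  `causal_m_to_y` (standardized M adds b to the FPG latent, default
  b = 0.5; the cohort-level tests use the "strong" setting b = 0.8), and
  `causal_y_to_m` (M gains b·l_i). Effects act on the standardized latent
  scale.
* observed β: 20% of sites (always scenario-null) are *cell-informative*:
  β = Σ_k π_k·β_ref(k, s) + noise, with per-sample proportions π ~
  Dirichlet (K = 3 types by default) and Beta-distributed reference
  profiles; the rest are logistic⁻¹ of a site baseline plus the latent
  M signal. Values are clipped to [0, 1].
* coverage ~ shifted negative binomial (mean ≈ 30); missingness at rate
  0.02 applied jointly to β and coverage; sex assigned per pair at the
  reported 27/52 male-pair fraction; ages shared within a pair (N(52, 7²));
  DBP individual; smoking/drinking pair-level categories at the reported
  concordance frequencies (19/28/5 and 17/32/3 of 52).
* rejection sampling redraws a pair's FPG-determining randomness until
  |ΔFPG| ≥ 0.1; the marginal FPG distribution moves by no more than the
  removed truncation mass (property-tested against the unconstrained
  generator).

What the generator does **not** emulate: read-level bisulfite noise and
coverage-dependent β precision, genomic clustering of methylation states
beyond what the p-value-track simulator provides, batch effects, DZ twins,
and any real LD/annotation structure. Passing tests therefore demonstrate
the statistical machinery under the stated generative assumptions, not
performance on any particular real cohort.

The null p-value track simulator is a separate tool: positions from
exponential spacings, z-scores from the block-diagonal Gaussian covariance
implied by a user-supplied distance-to-correlation function (blocks split
wherever a gap exceeds the correlation support; marginally-PSD functions
are handled by clipping negative eigenvalues and renormalizing to unit
marginals), p = Φ(−z) — marginally uniform with controlled spatial
correlation, the right null bed for DMR calibration.

## Numerical choices

* p-values are clipped to [10⁻¹⁵, 1−10⁻¹⁵] before Φ⁻¹.
* All randomness flows from a single integer seed through numpy
  Generators; cohort generation is bit-reproducible per seed.
* The empirical power routine uses the independence working correlation
  (identical point estimates, ~30× faster), one causal site per replicate.
* Floats are written with 10 significant digits; table read→write→read is a
  fixed point to < 10⁻⁹.

## Known limitations

* GEE p-values use the normal approximation; with a skewed, familially
  correlated exposure the cluster-robust z test runs mildly hot (true
  type-I ≈ 0.055–0.065 at α = 0.05 across a wide range of cohort sizes in
  our Monte-Carlo). Distribution-level uniformity checks (KS) are
  insensitive to this; exact finite-sample corrections (t reference,
  CR2/CR3 adjustments) are out of scope.
* The Šidák span-ratio correction treats per-chromosome extents as the
  search space; sparse chromosomes with a single site contribute 1 bp.
* The bootstrap treats pairs as exchangeable units; covariate-conditional
  resampling is not implemented.
* `logistic_association` refuses separated designs instead of offering a
  penalized (Firth-type) fallback.
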
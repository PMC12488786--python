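# Methods

This note documents the statistical model behind `mrpath`, the choices made
where the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Causal model and estimators

All estimation operates on per-variant GWAS summary statistics under the
standard instrumental-variable assumptions: each instrument is associated
with its exposure (relevance), shares no confounder with the outcome
(exchangeability), and affects the outcome only through the exposure
(exclusion restriction). Binary-trait effects are log-odds per allele;
continuous traits are in SD units.

**Wald ratio.** β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order delta SE σ_yⱼ/|γ̂ⱼ| by
default. The second-order term (adding Γ̂ⱼ²σ_xⱼ²/γ̂ⱼ⁴) is available by
flag; it is never smaller than the first-order SE. A widely circulated
verbal description of this ratio inverts numerator and denominator
("exposure effect divided by outcome effect"); the package implements the
standard outcome-over-exposure form.

**IVW.** Weighted zero-intercept regression of Γ̂ on γ̂ with weights
1/σ_y², algebraically identical to the inverse-variance-weighted mean of
Wald ratios with weights γ̂²/σ_y² (asserted to 1e-10 in the tests via an
independent normal-equation solve). Heterogeneity is handled by
*multiplicative over-dispersion*: random-effects SEs are the fixed-effects
SEs times max(1, √(Q/df)). The factor never shrinks below one, and additive
random-effects models are out of scope. With a single instrument IVW
delegates to the Wald ratio.

**MR-Egger.** Same regression with an intercept, after orienting every
variant so the (first) exposure effect is non-negative; the orientation is
re-derived inside `fit`, so the estimate is invariant to the input allele
orientation. The intercept estimates the mean directional pleiotropy; its
two-sided test at α = 0.05 is the pleiotropy flag used in screening.
Dispersion scaling uses k−2 (univariable) degrees of freedom.

**Weighted median.** Wald ratios are ordered; with normalized weights
wⱼ = γ̂ⱼ²/σ_yⱼ² the cumulative weight of the j-th order statistic is
sⱼ = Σᵢ≤ⱼ wᵢ − wⱼ/2 and the estimate interpolates the ratios linearly at
s = 1/2. Standard errors come from a parametric bootstrap: per-variant
betas are redrawn from normal distributions centred on the observed values
with the reported SEs (both sides when exposure SEs are supplied); the SE
is the SD of the bootstrap estimates. Default 1,000 replicates; a seed is
mandatory in the CLI.

**Mode-based estimators.** A normal-kernel density over the Wald ratios,
weighted by inverse ratio variance (weighted mode) or equally (simple
mode). Bandwidth follows the normal-reference rule
φ·0.9·min(sd, iqr/1.349)·k^(−1/5) with φ = 1 by default; when the IQR
collapses to zero the positive member of {sd, iqr/1.349} is used, and fully
degenerate ratios return the common value. The density is evaluated on a
512-point grid spanning the ratios ± 3 bandwidths; exact ties between modes
break toward the smaller value with a warning. Bootstrap SEs as above.

**MVMR.** The same weighted regressions with a (k × m) exposure-effect
matrix: coefficients are direct effects conditional on the other columns.
Rank-deficient designs raise a collinearity error naming the offending
columns. The multivariable median is the weighted least-absolute-deviation
fit (weights 1/σ_y², no intercept), solved by iteratively reweighted least
squares with smoothing constant 1e-6 in the weight denominators and a 1e-8
tolerance on coefficient change. Because IRLS can drift along a flat valley
of the smoothed objective, the solver also stops — returning the
best-objective iterate — once the weighted-L1 objective has not improved by
a relative 1e-8 for 10 consecutive iterations; the iteration cap is 1,000.
Approximate conditional F statistics (each exposure's effects residualized
on the others, mean squared residual z) are available; they assume
independent exposure samples and are flagged as approximate.

Everywhere: 95% intervals use the normal 1.96 multiplier (a t option for
small-k Egger exists but is off by default), and two-sided p-values come
from the normal distribution of β̂/SE.

## Instrument QC cascade

Order: p < 5×10⁻⁸ (strict) → greedy LD clumping (r² > 0.001 within
10,000 kb removes a candidate against any already-accepted variant;
candidates ranked by p with (chrom, pos, id) tie-breaks for determinism) →
MAF > 1% on min(eaf, 1−eaf) → harmonization → proxy substitution →
F ≥ 10 → Steiger. The attrition table reports n_in/n_dropped/n_out per
stage and their sums are asserted consistent; an exhausted stage raises an
error carrying the stage name.

*LD is an input contract*: clumping and proxy lookup consume externally
supplied sparse tables; absent pairs count as r² = 0 by default (an
"error" policy exists). *F statistic*: (β/SE)² by default — it needs no
allele frequency; the r²-based form (n−2)r²/(1−r²) is available.
*Steiger*: variance explained r² = z²/(z²+n−2) in exposure and outcome;
direction is correct iff r²_x > r²_y strictly (ties drop), and the test
compares Fisher-transformed correlations with variances 1/(n−3). The
default `confirm` mode retains only variants with correct direction *and*
Steiger p < α — confidently oriented instruments; the alternative
`exclude_significant_wrong` drops only significantly wrong variants. For
binary traits the same z²-based r² is used on the log-odds scale (no
liability-scale conversion) — a documented approximation.

In MVMR unions, each variant's direction is tested against the exposure it
best instruments (largest variance explained across columns) rather than
the primary exposure alone: mediator-specific instruments legitimately
explain more outcome than primary-exposure variance, and testing them
against the primary exposure would delete exactly the strongest of them and
shrink the mediator's conditional coefficient toward zero.

## Harmonization

The first exposure's effect allele is the reference. Other datasets align
by allele-label match, swap (beta negated, frequency complemented) or, by
default, strand complement; pairs that match under no orientation are
dropped with an explicit flag — every input variant carries exactly one
flag, and retained + dropped counts add up to the input. Palindromic (A/T,
C/G) variants are oriented by which side of 0.5 the allele frequencies
fall on and are dropped when any dataset's frequency lies inside the
configurable window (0.42, 0.58) or is missing — a symmetric window around
0.5 where strand cannot be inferred from frequency. Variant identity is by
identifier string; positions serve only clumping windows.

## Mediation

Step 1 screens the panel: the exposure's instruments (selected once) are
harmonized to each mediator, Steiger-filtered (exclusions tallied
panel-wide), and IVW gives â per mediator; passing requires p below the
Bonferroni threshold α/(panel size) and a non-significant Egger intercept.
Note the intercept exclusion is a per-mediator 5% test, so on large panels
a handful of true mediators are expected to be excluded alongside any
genuinely pleiotropic one. Step 2 runs univariable mediator→outcome MR for
candidacy at nominal p < 0.05 (the panel-wide Bonferroni threshold for this
step is reported alongside, mirroring the convention of proceeding with
nominally significant mediators), then a two-exposure MVMR gives b̂ and the
exposure's conditional coefficient.

The decomposition uses the difference method: c′ = c − a·b, so
c′ + a·b = c up to floating-point round-off. The MVMR exposure coefficient
is reported next to c′ as an independent estimate of the direct effect but
is *not* forced equal. Sobel variance a²SE_b² + b²SE_a²; proportion
mediated a·b/c with delta-method variance
p²[(SE_a/a)² + (SE_b/b)² + (SE_c/c)²] treating numerator and denominator
as independent — in two-sample designs no covariance is estimable from
summary data, a stated limitation. Mediators whose indirect effect opposes
the total effect's sign are excluded (and logged); an exactly zero indirect
effect is retained with a warning. The Sobel test is conservative under
the joint null (a = b = 0); the suite asserts rejection ≤ 6% at α = 0.05.

## Synthetic-data generator

Summary statistics are simulated directly — no individual-level genotypes —
because every estimator consumes only summary data and direct simulation
gives exact control of the assumed linear structural model:

- allele frequency pⱼ ~ U(maf_range); SE = 1/√(2·n·p(1−p));
- instrument effects γⱼ with true per-variant F ~ U(f_true_range), random
  sign; observed betas are Normal(truth, SE²), independently per cohort, so
  the two-sample assumption holds by construction;
- mediator effects δᵢⱼ = aᵢγⱼ at exposure instruments plus each mediator's
  own specific instruments (needed for MVMR identifiability);
- outcome truth Γⱼ = c′γⱼ + Σᵢ bᵢδᵢⱼ + αⱼ, with pleiotropy αⱼ applied *in
  the orientation of the exposure effect* (directional pleiotropy defined
  against random allele orientations would cancel);
- outcome sampling noise optionally over-dispersed by a multiplicative
  heterogeneity scale;
- the chain constraint θ_total = c′ + Σ aᵢbᵢ is asserted at configuration
  time and the truth proportions aᵢbᵢ/θ_total are recorded for recovery
  tests.

The bundled default scenario emulates the shape of a realistic two-step
study: a protective binary exposure (θ = ln 0.956) instrumented by 36
variants, biobank-scale cohort sizes (≈441k exposure, ≈115k metabolite,
≈138k outcome), a 168-mediator panel with 95 truly exposure-associated
members of which one carries directional pleiotropy (to exercise the
Egger exclusion) and two carry genuine outcome paths with planted
proportions mediated of 0.244 and 0.133, 704 planted reverse-causality
(mediator, variant) instances for the Steiger filter to remove, and
modest outcome heterogeneity (scale 1.5). The second mediator's b is
scaled (0.0544) so the planted proportions are exact given a = (−0.06,
−0.11).

Two deliberate departures from field-typical magnitudes, both power
choices for desk-scale Monte Carlo: instrument strength defaults to true
F ~ U(300, 2500) — far stronger than the F ≈ 30–150 typical of real
instruments — so that 36 instruments resolve the total effect's sign and
the 168-mediator screen has near-unit power at its Bonferroni threshold
(real analyses obtain this power from much larger instrument sets); and
the F-parametrization anchors effect sizes to the analyzed sample size
unless `f_reference_n`/`mediator_f_reference_n` pin them to a reference
cohort, which is required for sample-size scaling laws (CI width ∝ 1/√n)
to manifest. What passing tests show, therefore, is correctness and
calibration of the estimators under the assumed model at high power — not
performance under weak instruments, LD misspecification, sample overlap,
or liability-scale effects, none of which the generator emulates.

Monte-Carlo problem sizes used by the verification suite and the
acceptance script: 500 replicates for IVW bias/coverage at k = 50,
1,000 for the Egger-intercept type-I error, 200 for the 40%-invalid
robustness comparison, 300 for mediation-proportion recovery (k = 100
instruments there, so the ratio estimator a·b/ĉ — whose relative bias is
≈ 1/z_c² — is negligibly biased at this scale), and 2,000 for the Sobel
null. The full 168-mediator end-to-end run takes well under a minute.

## Determinism

All randomness descends from one top-level seed through
`numpy.random.SeedSequence` spawning, one child per stage in fixed order,
so adding a stage does not perturb earlier stages' draws; bootstrap seeds
within the two-step report are spawned per mediator. Identical seed and
configuration reproduce byte-identical JSON summaries.

## Known limitations

- Binary-trait variance explained (Steiger, F in r² form) uses the
  log-odds z² approximation; no liability-scale conversion.
- The proportion-mediated CI ignores the a·b vs c covariance (none is
  estimable from two-sample summaries) and its delta interval can cross
  0 or 1 for weak chains.
- Conditional F statistics assume independent exposure samples.
- No MR-PRESSO/contamination-mixture variants; no LD computation from
  genotype panels; no rsID↔position resolution or genome-build handling.
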
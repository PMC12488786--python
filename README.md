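# mrpath

Two-sample, multivariable and two-step **mediation Mendelian randomization**
on GWAS summary statistics — with a synthetic summary-statistics generator so
the entire workflow is testable end-to-end without downloading consortium
data.

## Who this is for

Genetic epidemiologists asking three nested questions about an exposure *X*
(e.g. a metabolic disease), a panel of candidate mediators *M* (e.g.
circulating metabolite biomarkers) and an outcome *Y* (e.g. a
neurodegenerative disease), using only published per-variant association
summaries:

1. **Does X causally affect Y?** Two-sample MR with genetic variants as
   instruments.
2. **Does the effect survive adjustment for correlated exposures?**
   Multivariable MR (MVMR).
3. **Which mediators transmit the effect, and how much of it?** Two-step MR
   mediation with the Sobel test and a delta-method interval for the
   proportion mediated.

## The model

Per instrument *j* with exposure effect γ̂ⱼ (SE σ_xⱼ) and outcome effect Γ̂ⱼ
(SE σ_yⱼ), the Wald ratio β̂ⱼ = Γ̂ⱼ/γ̂ⱼ estimates the causal effect. The
inverse-variance-weighted (IVW) estimate pools them,

    β̂_IVW = Σⱼ wⱼ β̂ⱼ / Σⱼ wⱼ ,   wⱼ = γ̂ⱼ² / σ_yⱼ² ,

equivalently a weighted zero-intercept regression of Γ̂ on γ̂; heterogeneity
(Cochran's Q) inflates the SE multiplicatively under the random-effects
model. MR-Egger adds an intercept (directional pleiotropy), the weighted
median tolerates up to half invalid weight, and the mode-based estimators
follow the densest cluster of ratios. MVMR regresses Γ̂ on several columns
of exposure effects jointly, giving each exposure's *direct* effect.

Mediation decomposes the total effect *c* of X on Y into an indirect path
through a mediator, a×b (a: X→M from univariable MR; b: M→Y conditional on X
from two-exposure MVMR), and a direct remainder c′ = c − a·b. The Sobel
statistic is a·b / √(a²·SE_b² + b²·SE_a²), and the proportion mediated is
a·b/c with a delta-method CI.

Instrument QC before any estimation: genome-wide significance (p < 5×10⁻⁸),
LD clumping (r² < 0.001 in 10,000 kb), MAF > 1%, palindromic-variant
exclusion at intermediate allele frequency, proxy substitution (r² > 0.8),
per-variant F ≥ 10, and Steiger directionality filtering.

## Worked example

```python
from mrpath import SimulationConfig, simulate_pair, select_instruments, run_all

cfg = SimulationConfig(n_snv=36, n_null_snv=300)   # protective OR ~ 0.956
exposure, outcome, truth = simulate_pair(cfg, seed=7)

instruments, harmonized = select_instruments(exposure, outcome)
print(instruments.attrition.to_string(index=False))

res = run_all(harmonized, n_boot=1000, seed=7)
print(res.to_frame().round(4).to_string(index=False))
```

prints the stage-by-stage attrition of the QC cascade,

```
      stage  n_in  n_dropped  n_out
     pvalue   336        300     36
      clump    36          0     36
        maf    36          0     36
  harmonize    36          0     36
f_statistic    36          0     36
    steiger    36          0     36
```

(336 simulated variants; the 300 null background variants fall at the
significance filter, the 36 planted instruments survive every stage, mean
F = 1387.9) and the five-method causal-estimate table:

```
         method  n_snv    beta     se    or_  or_low  or_high  pvalue
     ivw_random     36 -0.0521 0.0081 0.9492  0.9343   0.9644  0.0000
       mr_egger     36 -0.0568 0.0311 0.9448  0.8889   1.0042  0.0678
weighted_median     36 -0.0671 0.0120 0.9351  0.9133   0.9574  0.0000
  weighted_mode     36 -0.0803 0.0253 0.9228  0.8781   0.9698  0.0015
    simple_mode     36 -0.0803 0.0252 0.9228  0.8784   0.9694  0.0014
```

All five point estimates recover the planted protective effect
(θ = ln 0.956 = −0.045; the IVW odds ratio 0.949 with 95% CI 0.934–0.964).
The attached diagnostics report Cochran's Q = 36.0 (df 35, p = 0.423) and an
Egger-intercept p = 0.874 — no horizontal pleiotropy, as simulated.

The full two-step mediation workflow runs from the shell:

```bash
mrpath run --out report/ --seed 7          # bundled 168-mediator scenario
mrpath simulate --out data/ --seed 7       # write the datasets as TSV
mrpath mr --exposure data/exposure.tsv --outcome data/outcome.tsv --seed 7
```

`report/` receives the method table, the mediator screen (Bonferroni
threshold 0.05/168 = 2.98×10⁻⁴), the per-mediator MVMR table, the mediation
decompositions with proportions mediated and their CIs, and a
machine-readable `summary.json` that is byte-identical under an identical
seed and configuration.

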
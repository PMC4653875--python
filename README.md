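# mafblup

Genomic heritability estimation and breeding-value prediction under
MAF-stratified QTL architectures.

## The problem

Genetic variance that markers fail to capture — "missing heritability" — is
largely a consequence of imperfect linkage disequilibrium (LD) between the
genotyped SNPs and the causal loci (QTLs).  Because two loci can only be in
strong LD when their allele frequencies agree, QTLs with a low minor allele
frequency (MAF) are poorly tagged by commercial SNP arrays, whose content is
biased towards common variants.  `mafblup` is a simulation laboratory for
quantifying that effect in a livestock setting: it simulates LD- and
family-structured genotype panels with nested marker arrays, plants QTLs in
chosen MAF strata, and measures how much heritability a genomic evaluation
recovers and how accurately it predicts breeding values, as a function of the
genetic architecture, the marker density, the relationship-matrix
construction, and the reference-population size.

## The model

Phenotypes are simulated as `y_i = Σ_j x_ij b_j + e_i`, where `x_ij ∈ {0,1,2}`
counts the second allele at causal locus `j`.  QTL frequencies follow the
U-shaped density `f(p) ∝ 1/(p(1−p))`; on `[0.01, 0.5]` the mass splits
0.36 : 0.64 between the low-MAF interval `[0.01, 0.05]` and the rest.  Effects
come from either a gamma model (`|b_j| ~ Gamma(0.4, 1.66)`, independent of
frequency) or an equal-variance model (`b_j = 1/√(2p_j(1−p_j))`, every locus
contributing equal variance, so rare alleles carry large effects).  Effects
are rescaled so Var(TBV) = 100·h² exactly, and residuals are drawn with
variance `σ_g²(1/h² − 1)`, giving total phenotypic variance 100.

Evaluation uses GBLUP/GREML.  With `Z` the column-centered dosage matrix and
`Z̄` its per-SNP standardized version, three genomic relationship matrices are
supported:

* VanRaden: `G_V = ZZ' / (2Σ p_j(1−p_j))`
* Yang: `G_Y = Z̄Z̄' / m`
* LD-weighted (Speed/LDAK-style): `G_S = WW' / Σk_j`, `w_ij = √k_j z̄_ij`,
  with non-negative weights `k_j` chosen so local sums of distance-decayed r²
  are ≈ 1.

The mixed model is `y = 1μ + u + e` with `u ~ N(0, G σ_u²)` (model 1), or
`y = 1μ + u_L + u_H + e` with separate low-/high-MAF GRMs (model 2).
Variance components are estimated by average-information REML with monotone
EM safeguards; heritability is `h₁² = σ_u²/(σ_u²+σ_e²)` or
`h₂² = (σ_uL²+σ_uH²)/(σ_uL²+σ_uH²+σ_e²)`, model fit is compared by
`AIC = 2v − 2 lnL`, and test-set GEBV are BLUP conditional expectations.
Prediction quality is the Pearson correlation between true and estimated
breeding values in a reference-test validation design, with the deterministic
benchmark `r = √(Nh²/(Nh²+q))` available for calibration.

## Worked example

```python
from mafblup import ScenarioConfig, run_scenario, simulate_study_population

panel = simulate_study_population(n_animals=500, n_snps=2000, seed=1)

for model, panel_name in [("m1_Y", "sparse50"), ("m2", "dense")]:
    cfg = ScenarioConfig(maf_category="low", h2=0.4, n_qtl=300,
                         effect_model="equal_variance", panel=panel_name,
                         model=model, seed=2)
    print(run_scenario(panel, cfg, n_replicates=20).summary())
```

prints

```
scenario: maf=low h2=0.4 n_qtl=300 effects=equal_variance panel=sparse50 model=m1_Y
  replicates: 20 (20 converged)
  h2_est    mean 0.068  sd 0.036
  accuracy  mean 0.190  sd 0.109
  AIC       mean 3334.4
scenario: maf=low h2=0.4 n_qtl=300 effects=equal_variance panel=dense model=m2
  replicates: 20 (20 converged)
  h2_est    mean 0.407  sd 0.069
  accuracy  mean 0.586  sd 0.113
  AIC       mean 3294.8
```

Low-MAF QTLs evaluated through a common-variant-biased sparse array recover
almost none of the simulated heritability of 0.4 (mean estimate 0.07,
accuracy 0.19): the markers are in weak LD with the rare causal alleles.  The
same traits evaluated on the dense panel with the two-component
(low/high-MAF-partitioned) model recover the full setting (0.41) and more
than triple the accuracy, at a lower (better) AIC — denser markers plus a
MAF-aware model close the gap.

The same pipeline is scriptable from the shell (`mafblup
simulate-population`, `simulate-trait`, `build-grm`, `fit`, `predict`,
`validate`, `ld-stats`); every command logs its seed and parameters.

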
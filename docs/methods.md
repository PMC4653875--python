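# Methods

This note documents the models implemented in `mafblup`, the assumptions and
defaults of the synthetic-data generator, and the numerical choices made
where the design was genuinely open.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Genotype simulator

**What it emulates.** A beef-cattle genotyping study: a dense autosomal SNP
panel with a U-shaped allele-frequency spectrum, two nested sparser marker
arrays whose content is biased towards common variants, LD that decays with
physical distance, and a shallow half-sib pedigree (many sires, few progeny
each).

**Haplotype model.** Haplotypes come from a latent-Gaussian copula: along
each chromosome a standard-normal AR(1) series with adjacent correlation
`ρ = exp(−gap_bp / ld_decay)` is thresholded at `Φ⁻¹(f_j)`, so the marginal
allele frequency equals the target `f_j` while neighboring loci remain
correlated.  Resulting dosage r² decays with distance and is attenuated when
the two loci have discordant MAFs — the property the study design turns on.
The model is stationary and seedable; it makes no attempt at coalescent
realism, recombination hotspots, or long-range admixture LD.

**Family structure.** Progeny counts per sire follow a geometric law on
{1..24} with the success parameter solved so the truncated mean is 3.1
(matching the study herd's mean/max of 3.1/24).  Each animal receives one
gamete from its sire — one of the sire's two haplotypes chosen independently
per chromosome (no within-chromosome recombination) — and one fresh
population haplotype, giving paternal half-sib additive relationships near
0.25.  Dams are unobserved and unrelated.

**Target frequencies.** Dense-panel frequencies are drawn from
`f(p) ∝ 1/(p(1−p))` on `[0.01, 0.5]` by inverse CDF (`logit`/`expit`
closed form).  Sparse arrays are sampled without replacement with probability
∝ MAF^bias (Gumbel top-k; bias 1 by default), reproducing the high-MAF skew
of commercial arrays; the 7K-like array is nested inside the 50K-like array.
All SNPs not on a sparse array form the candidate-QTL pool, so sparse
markers never coincide with causal loci while the dense panel contains them
— the "perfect LD" density.

**Default scale.** `simulate_study_population` defaults: 1000 animals,
5000 SNPs on 4 chromosomes at 5 kb spacing (the dense-array order of
spacing), `ld_decay = 100 kb` (flanking-marker r² ≈ 0.3 at sparse-array
spacing, the order observed in real cattle panels), sparse fractions
0.08/0.015 of the dense panel.  The test suite uses a 500-animal,
2000-SNP instance of the same recipe.

**Genotype error (imputed densities).** Array-to-sequence imputation is
represented by its end effect only: each observed call is replaced, with
probability `1 − ρ`, by a fresh draw from `Binomial(2, p̂_j)`, making the
expected per-SNP correlation between clean and observed dosages exactly `ρ`
(0.98 for the 50K-derived density, 0.93 for the 7K-derived one).  No
LD-informed imputation algorithm is implemented; the error process is
frequency-preserving but unstructured, so it cannot reproduce the real
pattern of imputation errors concentrating at rare alleles.

**QC.** SNPs are dropped for observed MAF < 0.01, call rate < 0.95, or a
1-df chi-square goodness-of-fit test of genotype counts against
Hardy–Weinberg proportions with p < 0.001 (the rules are checked in that
order and the first failure recorded).  The chi-square form was chosen over
an exact test because only a "HWE test < 0.001" rule was specified; at the
sample sizes involved the two agree except at the rarest genotypes.  Close
relatives are removed greedily against a GRM: the animal with the most
|off-diagonal| entries above 0.4 goes first, ties broken by id order, until
no violation remains.

## Trait simulator

QTLs are sampled uniformly without replacement from the candidate pool
within a MAF category — low `[0.01, 0.05]` (boundary inclusive), high
`(0.05, 0.5]`, or all.  For the all category the low/high composition is
deterministic: round-half-up of the exact U-shape share (0.3592…) times the
QTL count, i.e. 180/320 at 500 QTLs, rather than binomially resampled — this
keeps per-replicate composition reproducible.

Effects: gamma model `|b| ~ Gamma(shape 0.4, scale 1.66)` — the scale
parameterization, mean 0.664 — independent of frequency; equal-variance
model `|b| = 1/√(2p(1−p))`.  Signs are i.i.d. ±1 in both.  One scalar then
rescales all effects so the realized population variance (denominator n) of
TBV equals `100·h²` exactly — in-sample, not in HWE expectation — and
residuals are `N(0, σ_g²(1/h²−1))`, so phenotypic variance targets 100 at
every setting (0.2, 0.4, 0.8).

## Relationship matrices

Allele frequencies are always computed on the full analysis sample
(reference plus test), as a single GRM serves all splits.  Missing dosages
are mean-imputed before centering.  Monomorphic SNPs are excluded from GRM
subsets (they carry no information and break the Yang scaling); VanRaden's
builder additionally tolerates them as zero contributions.

The LD weights solve `min_w ‖A w − 1‖²`, `w ≥ 0`, where
`A_jk = exp(−ln2·d_jk/halflife) · r²_jk` within a 1 Mb same-chromosome
window (half-life 125 kb; both configurable).  This captures the published
objective — local decayed-r² sums near one, so redundant SNPs share weight —
without replicating any particular solver's internals.  A ridge
augmentation of 1e-8 picks the minimum-norm solution on ties (q duplicate
SNPs each get ≈ 1/q).  For dense-like panels the solve runs twice, the
second pass on columns scaled by the first-pass weights, returning the
product.  r² inside the weighting is the same squared dosage correlation
used by the LD-profile module.

Each GRM used in a model gets `1e-5` added to its diagonal, shifting every
eigenvalue by exactly that amount, to keep the mixed-model solves away from
singularity.

## REML

`GREML` maximizes the restricted likelihood of `y = 1μ + Σ u_c + e` by
average-information REML.  Safeguards: the first step is an EM update;
afterwards an AI proposal that would lower the likelihood is step-halved up
to 8 times and then replaced by the EM update, so the likelihood path is
non-decreasing by construction.  Components are clamped at `1e-8·Var(y)`;
convergence is `|Δ lnL| < 1e-6` or a parameter change below `1e-8·Var(y)`,
with a 100-iteration cap.  A fit pinned at the floor or facing a singular AI
matrix (condition number > 1e10, e.g. `G = I`, where only `σ_u² + σ_e²` is
identified) is flagged degenerate and a warning raised; it is still returned
with its likelihood and heritability.

The restricted log-likelihood uses the Harville constant including
`+½ ln|X'X|`, so it equals the exact density of an orthonormal error
contrast (verified against the closed form at n = 2) and `AIC = 2v − 2 lnL`
is comparable across models (1) and (2) on the same data.  No
information-matrix standard errors are reported; dispersion across
validation replicates serves that role.

Prediction is the BLUP conditional mean
`û_test = Σ_c σ̂_c² G_c[test,ref] V⁻¹ (y_ref − μ̂)` with
`V = Σ_c σ̂_c² G_c[ref,ref] + σ̂_e² I`, using components and mean estimated on
the reference only but cross-covariance blocks from the full-sample GRM.
On a VanRaden GRM this is algebraically identical to ridge SNP-BLUP with
penalty `σ_e²/(σ_u²/2Σp(1−p))`, which the test suite verifies.

## Validation design

A replicate = fresh QTL draw + effects + phenotypes (the trait is
regenerated each replicate, since fixing it would make replicate dispersion
understate the design's sampling variance), one random reference/test split
(one-tenth test by default, or a fixed reference size), REML on the
reference, GEBV for the test set, Pearson TBV–GEBV accuracy.  Replicate
seeds are spawned from the master seed by counter, so runs are bitwise
reproducible and any replicate can be re-run alone.  Genotype-error
injection for the imputed densities happens once per scenario — imputed
genotypes are fixed data, not per-replicate noise.  Failed replicates are
recorded and skipped; beyond 20 % the scenario aborts.  Summaries report
mean and SD (ddof = 1) over replicates, with and without non-converged fits.

Scenario grids: the categorical axes (MAF category, effect model, panel,
prediction model, split mode) are validated strictly; numeric axes (h²,
QTL count, reference sizes) accept any admissible value so the design can be
run at reduced scale.  The suite uses 500 animals × 2000 SNPs with 8–50
replicates per scenario — enough for the qualitative orderings (low < all <
high MAF on biased sparse panels; accuracy rising with h² and reference
size; accuracy flat in QTL count) and for the dense-panel two-component
recovery check to resolve a ±0.03 band around the 0.40 setting.

**What passing does not show.** The generator's LD is first-order and
family structure shallow, so absolute heritability-loss and accuracy values
on the sparse panels depend on the chosen decay scale and array bias; only
their orderings and the dense-panel recovery are design-calibrated.  Results
on real populations with strong relationship structure, selection, or
long-range admixture LD can differ.

## Known limitations

No dominance/epistasis, single trait, autosomes only, no phased output, no
real imputation, no pedigree (A-matrix) or single-step evaluation.  The
LD-weight solver is dense NNLS per chromosome — adequate to ~10⁴ SNPs, not
to sequence scale.
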
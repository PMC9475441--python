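# Methods

## The generative model

The synthetic cohort is the reference frame for every downstream analysis, so
its assumptions are stated first.

**Genotypes.** Each subject carries two haplotypes. Within an LD block the
haplotype allele indicators arise by thresholding an equicorrelated latent
Gaussian vector at `Φ⁻¹(p_j)` (alt-allele frequency `p_j`), so marginal
genotype frequencies are exactly Hardy-Weinberg while between-variant dosage
correlation is controlled by the block's latent correlation. The implied
dosage correlation is not the latent correlation itself; it is computed from
the bivariate normal orthant probability
(`synthetic_cohort.haplotype_indicator_correlation`), and the test suite
checks it against an independent 2-D numeric integration. Blocks are
independent, which is the usual block-diagonal idealization of LD; long-range
LD and allele-frequency-dependent LD decay are not modelled. That is
sufficient for what the clumping step has to demonstrate (removal of
window-local correlated variants); it says nothing about reference-panel
mismatch in real data.

**Liability model.** For disorders d ∈ {SCZ, BIP, MDD},

```
F = a·x̃ + e_F                    (common factor, unit variance)
liability_d = λ_d F + b_d·x̃ + s_d ε_d   (unit variance per disorder)
case_d  iff  liability_d > Φ⁻¹(1 − K_d)
```

where `x̃` are dosages standardized by their theoretical mean/SD. Variants
carrying factor effects (`a`) and disorder-specific effects (`b_d`) are drawn
from disjoint LD blocks, so the per-disorder variance budget decomposes
exactly as `λ_d² + b_dᵀR b_d + s_d² = 1` with `R` the theoretical dosage
correlation matrix; `make_liability_model` normalizes effect vectors against
`R` so the budget holds by construction, and `TrueLiabilityModel.validate`
raises with the per-disorder budget table when it does not.

Defaults, chosen once as the package's study conditions: prevalences
`K = (0.046, 0.077, 0.413)` — lifetime ≥2-code rates of schizophrenia,
bipolar disorder and major depression in a large veteran health system, which
are several-fold above general-population rates and are the regime the
pipeline is meant to emulate; loadings `λ = (0.8, 0.6, 0.4)` giving genetic
correlations dominated by the shared factor with SCZ loading highest;
`factor_h2 = 0.5` and `specific_h2 = 0.1` per disorder, which put total
liability-scale heritabilities (0.42, 0.28, 0.18) in the vicinity of
SNP-based estimates for these disorders at the upper end, deliberately, so
that desk-scale cohorts still contain signal.

**Summary statistics.** The true marginal effect of a variant is the
LD-convolution of joint effects, `β_marg = R(λ_d a + b_d)` — marginal effects
are inflated inside LD blocks, which is precisely why clumping exists — plus
Gaussian noise with `SE = 1/√(2p(1−p)·n_gwas)`, the standardized-scale
approximation. Effects are liability-scale; the scoring path treats them as
log-OR weights, which conflates two effect scales that differ by a
near-constant factor at these prevalences. Since every downstream use is
scale-invariant (scores are standardized before analysis), the conflation is
harmless here, but the summary-stats table should not be read as a calibrated
case-control GWAS.

**EHR coding process.** Encounters per subject are `max(1, min + Poisson(μ −
min))` with integer day offsets (only ordering matters downstream). Per
encounter, a true case emits a disorder-family code with probability
`sensitivity_d` (schizophrenia codes split 0.7/0.1/0.2 across phecodes
295.1/295.2/295.3); schizophrenia and bipolar cases emit each other's codes
with probability `cross_coding`; non-cases emit psychiatric codes at a small
background rate; every subject emits each of the ~50 non-psychiatric
phecodes' codes at a per-phecode rate drawn once from
`background_rate_range`. Inpatient probability rises with liability in
excess of the diagnostic threshold (`severity_inpatient_slope`), which is
what makes hospitalization counts PRS-associated. Cases receive
class-concordant prescriptions (antipsychotics/mood stabilizers/
antidepressants) with probability 0.9; controls at background rates (0.3 for
antidepressants, reflecting their high background prescription volume).

Defaults `sensitivity = 0.45`, `cross_coding = 0.11`, `μ = 10` were set so
that the implied ≥2-code sensitivity (~0.95) and the SCZ↔BIP multiple-coding
rate (~0.3–0.5, the latter inflated by genuine comorbidity under the
correlated liability model) are of the magnitude reported for real veteran
EHR data. Real encounter-frequency distributions are not public; the
distribution is config, not a claim of realism. The generator does not model
coding drift over time, ICD-9→10 transition effects, or care received outside
the system — so passing tests validate the pipeline's logic, not those
real-data pathologies.

## Analysis-stage choices

**Harmonization** matches variants by id, flips the weight sign when the
effect allele is the target ref, and drops strand-ambiguous (A/T, C/G) pairs
and allele-set mismatches, reporting counts per category.

**Clumping** is greedy best-p-first: ties in p broken by (chromosome,
position, variant id) for determinism; the window is ±500 kb around the
index variant; r² is the squared Pearson correlation of dosages in the
supplied reference genotypes; removal requires r² strictly greater than the
0.1 threshold. The MHC default exclusion is chr6:25–34 Mb (configurable) —
the span conventionally excluded in psychiatric PRS work. The p-threshold
grid defaults to {5×10⁻⁸, 10⁻⁶, 10⁻⁴, 10⁻³, 0.01, 0.05, 0.1, 0.5, 1}.

**Scoring** sums `dosage × weight` over variants passing each threshold;
missing dosages contribute `2 × frequency × weight` (mean imputation).
Standardization uses the population-SD convention (divide by n), per group;
zero within-group variance is an error naming the group and column, because a
constant score is an upstream defect, not something to paper over.

**Phenotyping.** "Entries" in the mode-of-5 prevailing-diagnosis rule are
individual dated code events, not distinct dates; with fewer than five
relevant entries the mode of all available is taken; ties are broken by the
most recent entry's family. Under an inpatient criterion, subjects with only
outpatient codes are excluded rather than controls, keeping controls strictly
code-free. Two codes on the same date in the same setting count as two
entries (billing convention is ambiguous; this choice is documented and easy
to change at the counting function).

**Penetrance.** Decile cut points come from the analyzable (case or control)
sample's empirical quantiles; scores equal to a cut point fall in the lower
decile. Odds ratios are Wald-based from `statsmodels` logistic fits with age,
age², sex and six PCs; complete separation raises with a message suggesting
exact/penalized alternatives rather than silently switching estimator. The
hospitalization model is OLS on the raw count by default — the reported
unitless β is consistent with a linear fit — with a Poisson log-link
alternative behind `family="poisson"`; outputs label the family. A 1-D
quadrature oracle (`liability_decile_prevalence_oracle`) gives the expected
decile curve `E[Φ((√r²·z − T)/√(1−r²))]` per decile for liability-model
checks.

**PheWAS.** Cases ≥2 codes, controls 0, one-coders excluded, per phecode;
`min_cases` defaults to 100 (tests and desk runs use lower floors, stated at
the call site). Significance is the fixed two-sided 10⁻⁵ threshold;
Bonferroni and Benjamini-Hochberg columns are informational only. Phecode
parent/child rollup is not applied — each phecode is tested as mapped — a
documented limitation relative to full phecode-hierarchy tooling. "Lifetime
diagnosis" for sensitivity exclusions means ≥1 code ever (maximally
conservative), configurable at the spec.

**Direction tests.** Loci are oriented to the source risk allele once
upstream, so "reversed" is well defined; a target coefficient of exactly zero
counts as convergent (tie rule, reachable only in degenerate toys). The
two-sided exact binomial p sums all outcome probabilities not exceeding the
observed outcome's probability (minimum-likelihood convention), with exact
Clopper-Pearson 95% intervals; this convention reproduces published worked
examples from their printed counts to the printed precision.

**Factor model.** With three indicators and one factor the model is
just-identified, so the closed form replaces iterative weighted least
squares: the fit is exact whenever it exists, and pathologies surface as
errors (zero off-diagonal covariance → divergent loading; sign-inconsistent
off-diagonals; Heywood case θ < 0) instead of as poorly converged estimates.
The factor sign is fixed by λ_SCZ > 0. The per-SNV sampling covariance V
defaults to diag(se²) with an optional uniform cross-trait overlap
correlation; full intercept-based overlap estimation, heterogeneity
Q-statistics, and estimating S itself from summary statistics (LD-score
regression) are out of scope — S is an input.

## Problem sizes

Test-suite simulations use 1 200–50 000 subjects and 20–1 000 variants, with
n = 200 000 for the liability-quadrature comparison (score and liability only,
no genotype matrix); the acceptance script runs 20 000 subjects × 160
variants with GWAS n = 500 000. These sizes were chosen so Monte-Carlo error
bands (3×SE) are tight enough to be meaningful for every asserted comparison
while the full suite stays fast to run.

## Known limitations

- Liability-scale effects are reused as log-OR weights (see above); fine for
  standardized scores, wrong for absolute-risk calibration from β values.
- No X chromosome, no dosage uncertainty, no imputation, no sequence-level
  simulation.
- The bundled ICD→phecode vocabulary is a miniature synthetic stand-in
  (57 phecodes, 2 ICD codes each); interfaces accept a user-supplied full
  map file.
- Ancestry enters only through covariate structure (PC offsets, per-group
  standardization); the generator does not model ancestry-dependent LD or
  effect sizes, so cross-ancestry portability questions are outside what
  these simulations can address.
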
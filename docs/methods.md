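# Methods

This note documents the statistical machinery of `lipidgi`: the models,
the decision rules, the synthetic-data generating processes, and the
numerical and design choices made where more than one defensible option
existed.

## The pairwise battery

Each (predictor pair, trait) unit is analysed by the nested regressions
M1 (`y ~ x_A`), M2 (`y ~ x_B`), M3 (`y ~ x_A + x_B`, the additive model)
and M4 (`y ~ x_A + x_B + x_A:x_B`, the interaction model), all with
intercept; the screen arm additionally fits the intercept-only M0 to
represent "no knockdown effect at all". Predictors are numeric: carrier
indicators (0/1) for PTV gene burden, additive dosage coding (0/1/2) for
SNPs, a weighted allele sum for the PRS, and siRNA-presence indicators in
the screen. No factor coding of genotype classes is used — the regression
formulas are linear in dosage.

### Robust fitting

Quantitative responses are fitted by Huber M-estimation via iteratively
reweighted least squares (statsmodels `RLM`): tuning constant c = 1.345
(95% efficiency under Gaussian errors), residual scale re-estimated each
iteration as the scaled median absolute deviation (factor 1.4826),
convergence when coefficients move less than 1e-8, at most 50 iterations.
All three defaults are arguments. Standard errors and t-statistics come
from the robust fit; an exactly noise-free response short-circuits to the
least-squares solution with the scale floored at 1e-10 (a zero MAD would
leave the weights undefined). Rank-deficient designs never raise: linearly
dependent columns are dropped and reported as inestimable terms (all-NaN
coefficient rows), mirroring how an untestable interaction is handled.

### Pseudo-BIC for robust fits

A Huber fit has no canonical likelihood, so model selection uses a
Gaussian pseudo-BIC evaluated at the robust estimates:

    BIC = n * log(sigma2_w) + k * log(n),
    sigma2_w = sum(w_i r_i^2) / sum(w_i)

with `w_i` the Huber weights at the optimum and `k` counting regression
coefficients plus one for the scale. When every weight is one this reduces
exactly to the textbook Gaussian `n log(RSS/n) + k log(n)` (a property the
test suite checks against a closed-form OLS oracle). The variance is
floored at 1e-20 so saturated fits keep a finite criterion. This is one
defensible convention, implemented in one function
(`regression.gaussian_pseudo_bic`) so it can be swapped.

Logistic (CAD) fits use the ordinary `-2 loglik + k log(n)`. Complete
separation is detected from the optimizer (warning, singular Hessian, or
divergent coefficients) and reported as an inestimable fit rather than as
huge estimates.

### Model choice and evidence

The best model is the lowest BIC among converged fits; exact ties go to
the model with fewer parameters, which keeps the AE/GI partition
deterministic and favours parsimony. `delta_bic` is the gap to the
runner-up; a gap above 2 counts as strong evidence (Raftery's convention),
reported in the screen arm as `evidence = strong | ambiguous`.

Single-term p-values are read from the *full* model — M3 or M4, whichever
has the lower BIC — while the interaction p-value always comes from M4
when the interaction is testable. Which full model supplied the
single-term values is recorded per unit (`full_model`). This resolves an
ambiguity the two-step rule leaves open; taking singles from the selected
full model keeps estimates and p-values mutually consistent.

### Testability

The interaction term of a pair is testable when at least `min_joint`
samples are exposed to both predictors (default 1 — informative human
double knock-outs are extraordinarily rare, and as few as three carriers
can carry a real signal) and the product column is not collinear with the
main effects. Untestable units skip M4, carry a missing interaction
p-value, and can still be classified AE through the "untestable" branch.

### FDR families and classification

Benjamini–Hochberg adjustment runs over one family per design: the pooled
set of the three per-term p-values of every (pair, trait) unit of that
design — pooled across traits within a design, never across designs.
Missing entries (inestimable terms) stay missing and do not count toward
the family size. The two-step classifier is:

* GI: adjusted interaction p < 0.005 and M4 selected;
* AE: adjusted interaction p > 0.01 or untestable, both single-term
  adjusted p < 0.005, and M3 selected;
* none: everything else. Interaction p-values between 0.005 and 0.01 are
  deliberately never classified — the gap between the two thresholds is
  part of the rule, not an oversight.

All thresholds (0.005 / 0.01 / 0.005, the validation 0.01, the
delta-BIC evidence 2, the taxonomy tolerance) are keyword arguments with
these defaults and are echoed into the run manifest by the CLI.

## Cohort arm specifics

Quantitative traits are residualized once per trait by OLS against the
full covariate set (age, sex, smoking, alcohol, BMI, lipid-medication use,
ten genetic PCs); residuals are the outcomes of every robust battery.
CAD is never residualized: the covariates enter each logistic model
directly. Zero-variance covariates are dropped with a warning; samples
with missing covariates are dropped with a logged count.

Burden encoding defaults to the carrier indicator (any qualifying variant
→ 1), with an additive count mode available. A variant exclusion set
supports conditioning: `condition_on_variant` re-runs a scan with one
allele removed from the encoding and reports before/after results side by
side — the sensitivity analysis for a signal suspected to be carried by a
single prevalent allele (e.g. a gain-of-function stop variant in *LPL*).

Design enumeration: burden×burden and SNP×SNP take unordered pairs;
SNP×burden takes every (SNP, gene) combination except a lead SNP against
the burden of a gene it is mapped to (the gene↔SNP map is an input table —
with 30 genes and 28 lead SNPs, one SNP per gene, this yields 810 pairs);
burden×PRS pairs every gene with the trait-matched score, the gene's own
region excluded from the score before summation.

## Screen arm specifics

Image-level QC removes frames failing cell count (default ≥ 20 cells),
sharpness (default: above the 5th percentile of negative-control frames)
or background (below the 95th control percentile); explicit absolute
thresholds override the percentile rules. Arrays whose positive-control
knockdown is not separated from the negative controls are flagged.

Robust Z-scores follow the plate-normalization convention: per biological
replicate of a treatment, the mean image intensity is centred by the
median and scaled by the MAD of the same physical array's negative-control
intensities. The scaled MAD (×1.4826) is the default; the raw-MAD
convention is available behind `scaled_mad=False` because screening
pipelines differ on this point. Replicates of a treatment are pooled
across all arrays carrying it. A zero control MAD excludes the array with
an error record.

The five-model battery fits the pooled replicate Z-scores with the
negative-control values included to anchor the baseline; for a balanced
design without outliers the fitted interaction coefficient equals the
cell-mean contrast `mean(z_AB) − mean(z_A) − mean(z_B) + mean(z_ctrl)`
exactly (a tested identity).

### Interaction taxonomy

With J = β0+βA+βB+βAB the joint effect, E = β0+βA+βB the additive
expectation, M the single effect of larger magnitude and severity
s(x) = x·sign(M):

* negative-aggravating: s(J) > max(s(E), s(M)) + τ;
* positive-alleviating: |s(J) − s(M)| ≤ τ;
* positive-suppressive: s(J) < s(M) − τ.

τ defaults to the standard error of the double-knockdown replicate mean
(per pair) and can be overridden by a constant; every report records the τ
used. Two boundary conventions make the taxonomy a total partition: a
joint effect falling between the dominant single and the additive
expectation (partial alleviation) is labelled alleviating; and when both
singles are within τ of zero the dominant direction is undefined and the
pair is labelled "emergent" and reported separately. "Severity" is
deviation magnitude from the control baseline in the direction of the
dominant single effect — an orientation convention, not a disease
direction.

Validation: a primary interaction call is confirmed when the replication
screen gives an FDR-adjusted interaction p below 0.01 *and* an Interaction
Value of the same sign. A sign flip never validates, regardless of p.

## Synthetic data

The cohort generator draws age ~ U(40, 69) (a mid-life recruitment
window), Bernoulli lifestyle/medication indicators, BMI ~ N(27, 4) and ten
standard-normal PCs; these confound the traits through documented linear
effects and are irrelevant to correctness because residualization removes
them. Trait scales are chosen to be readable in mg/dl: means 138.3 / 55 /
150 / 200 and noise SDs 33 / 15 / 55 / 40 for LDLc / HDLc / TG / TC;
values are floored at 1 mg/dl because lipid measurements are positive
(the floor trims a negligible Gaussian tail at these scales). Carriers are
Bernoulli per gene (default frequency 0.01; the per-gene variant pool is
skewed so a most-prevalent allele exists for conditioning tests), dosages
Binomial(2, MAF) with MAF ~ U(0.03, 0.35), and the PRS a weighted sum over
panel plus background SNPs, standardized before entering the trait.
Planted effects are expressed in trait-SD units (log-odds for CAD) and
exported as the truth table.

The screen generator emits log-normal per-image intensities —
fluorescence is positive and right-skewed — with planted effects living on
the robust-Z scale: negative-control images spread with unit SD on the Z
scale (their MAD *defines* one Z unit), and a treatment's images sit at
`e_A + e_B + e_AB` Z units plus replicate-level noise (default SD 0.5,
drawn once per treatment × biological replicate) and image-level noise
(default SD 0.25). The control log-scale (default 0.02) keeps the
exp-nonlinearity second-order, so planted and recovered values share
units. QC failures are injected at a configurable rate (default 13.65%)
as low-cell, blurred or high-background frames. Array layouts carry the
control blocks (negative, transfection and positive controls) plus two
single-knockdown spots per gene on every array design, with the pairwise
spots split across as many designs as capacity requires.

What the generators do *not* emulate — and hence what passing recovery
tests cannot show: linkage disequilibrium and haplotype structure,
population stratification beyond the PC covariates, genotype missingness,
non-Gaussian trait tails, siRNA off-target effects, spatial plate
gradients, or pixel-level imaging artefacts. Recovery results certify the
statistical machinery under its own assumptions, not robustness to these
real-data features.

## Reference configuration and problem sizes

Simulation-based checks run at a desk-scale reference configuration chosen
once: pairwise batteries at n = 5,000 samples with common predictors
(MAF 0.2–0.25) and effects of 0.3 / 0.3 / 0.8 trait-SD; screen fits at
8 replicates with replicate noise SD 0.5 and a planted Interaction Value
of 2. At these sizes the interaction battery has essentially full power,
additive truths select M3 in ≳90% of seeds (the remainder mostly prefer
M4 by small margins, as expected from the BIC's finite-sample behaviour),
and null batteries call interactions far below the nominal 0.005.

## Known limitations

* The pseudo-BIC is a convention, not the likelihood of the Huber fit;
  rankings of non-nested models with very different weight patterns should
  be read with care.
* The taxonomy's boundary tolerance τ is estimate-noise based; pairs whose
  joint effect sits within τ of a boundary can legitimately flip labels
  between replications.
* The FDR family excludes inestimable terms, so family size (and hence
  adjusted p-values) depends on testability patterns in the data.
* Logistic batteries with rare exposures can be quasi-separated; such
  fits are flagged inestimable rather than estimated, which removes the
  unit's terms from the family.
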
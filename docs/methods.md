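# Methods

This note documents the models, parameter choices and numerical decisions
behind `somaqtl`, and what the synthetic cohort generator does and does not
emulate.

## Synthetic cohort generator

The generator produces one study's worth of linked artifacts — genotypes,
sample metadata, a log2 proteome, clinical variables and outcome-GWAS
summary statistics — from a single `SimConfig` whose `seed` fully
determines every output (independent named substreams per stage, so
changing one stage's inputs never perturbs another's draws).

**Genotypes.** Biallelic dosages on one synthetic chromosome with uniform
inter-variant spacing (default 50 kb, so a ±1 Mb cis window holds ~40
variants).  LD comes from a Gaussian copula: within blocks of
`ld_block_size` variants the latent field is AR(1) with parameter
`ld_rho`; two independent haplotypes are thresholded at the allele
frequency (drawn uniformly from `maf_range ⊂ [0.05, 0.5]`) and summed.
Marginals are Hardy–Weinberg; blocks are independent.  Not emulated:
realistic human LD maps, sex chromosomes, relatedness, imputation
uncertainty, population stratification.

**Cohort structure.** Three subcohorts (idiopathic, GBA+, LRRK2+) with
patients and matched controls; genetic-subcohort patients carry a
medication flag (rate 0.9), idiopathic patients are drug-naïve.  The
composition fractions are configurable scenario parameters chosen to
mirror a cohort dominated by idiopathic patients with smaller genetic
subcohorts.

**Proteome.** Analyte value = baseline + age/sex/center effects + cis
dosage effect + module factor loadings + optional disease effect + plate
location/scale batch effect + Gaussian noise, all on the log2 scale.  A
fraction `prop_cis_regulated` (default 0.3) of analytes carries a cis
effect β ~ N(0, `cis_effect_sd`) at a variant inside its ±1 Mb window;
a fraction `prop_causal` of those proteins is causal for the outcome trait
with effect `theta_causal`.  Two co-expression modules (default 25% of
analytes each) load on latent factors f₁, f₂ = ±`endotype_shift`·1{endotype 2}
+ N(0,1) plus a module-specific nuisance factor (sd `module_nuisance`)
that carries endotype-independent covariation.  The endotype shift default
(4.0) with nuisance 0.3 was chosen so that the planted two-endotype
structure is as stable as the study design this emulates implies
(near-perfectly stable consensus clusters): at shifts ≤ 3 even an oracle
projection on the true module contrast cannot exceed ARI ≈ 0.8 against the
planted labels, so no clustering procedure could meet the package's
recovery guarantee there.

**Outcome GWAS.** The virtual outcome trait is
y = Σ_k θ_k β_k d(v_k) + Σ_v α_v d(v) + ε with unit environmental
variance, where v_k is the causal protein's cis variant (or, in the
distinct-variant scenario, a variant from a different LD block inside the
same window) and α are optional direct (pleiotropic) effects on a fraction
of instruments.  Marginal per-variant betas are computed analytically from
the genotype panel's empirical dosage covariance with the genetic score,
SE = √(var(y)/(N·var(d))), and sampling noise at the configured external
sample size N (default 500 000) is added — no outcome individuals are ever
simulated, which keeps N free.  Optional swapped-allele records
(sign-flipped beta, complemented EAF) and strand-ambiguous A/T–C/G allele
pairs exercise harmonization.

**Clinical variables.** Idiopathic patients carry a latent endotype label
(fraction `endotype_frac` = 0.47 in endotype 2).  CSF p-tau is drawn from
endotype-conditional normals with means 14 and 8.5 pg/mL (sd 2.2), i.e.
straddling the 11 pg/mL decision point; amyloid-beta, total tau,
alpha-synuclein, UPDRS I and MoCA get endotype-2 location shifts scaled by
`clinical_shift` (0 gives an exact clinical null).  Everything outside the
idiopathic-patient subset draws from the endotype-1 distributions.

Passing tests on these cohorts show that the pipeline recovers effects of
the planted kinds at the planted scales; they do not certify behavior
under features the generator omits (assay floor/ceiling effects, missing
values, non-Gaussian abundance tails, LD mismatch between exposure and
outcome panels, sample overlap between the two MR samples).

## Preprocessing

Median normalization equalizes per-sample medians within each dilution
group to the group's global median.  Batch (plate) correction implements
the parametric empirical-Bayes location/scale model: per-analyte
standardization against the batch-design fit, per-batch location and scale
estimates shrunk via a normal prior (moments across analytes) and a
moment-matched inverse-gamma prior, iterated to their joint conditional
posterior means (tolerance 1e-6, max 200 iterations), back-transformed
with covariate effects preserved.  It refuses singleton batches and
designs where a covariate is confounded with batch.  The test suite checks
the adjusted matrix against `sva::ComBat` (agreement limited only by sva's
1e-4 iteration tolerance).  Two properties worth stating precisely: the
shrinkage leaves a residual batch-mean gap of order delta²/(n_b·tau²) per
analyte, so near-exact removal requires batch effects that vary across
analytes (tau² well above the 1/n_b sampling floor) — which is how real
plate effects behave and what the generator injects; and a second
application of the correction is a strong contraction (changes < 0.01 and
< 1/20 of the first pass) rather than an exact identity.

Principal components are column-centered SVD scores with a deterministic
sign convention (largest-magnitude loading positive).  They are computed
on the batch-corrected, normalized matrix.  The inverse normal transform
uses Blom's offset, Φ⁻¹((r − 3/8)/(n + 1/4)), with average ranks for ties;
the offset is configurable.  BH FDR delegates to statsmodels and is
cross-checked against a brute-force step-up enumeration.

## cis-pQTL scan

Windows are [gene_start − 1 Mb, gene_end + 1 Mb], 1-based inclusive on
both boundaries, clamped at position 1; analytes mapping to several genes
take the union of windows; analytes without coordinates are excluded with
a warning.  The scan residualizes the analyte matrix and the dosage matrix
on the covariate design once and computes per-pair OLS slope, SE, t and
two-sided p with df = n − rank(design) − 1 — algebraically identical to
fitting each pair's full model, verified to 1e-8 relative against
per-pair OLS across random configurations.  Variants are filtered to
MAF > 0.05; monomorphic columns are skipped.  Significance is strict
p < 5×10⁻⁸.

## Mendelian randomization

Instrument selection, harmonization and clumping follow the conventional
two-sample workflow (defaults: palindromic ambiguity band 0.42–0.58 on the
EAF; in-sample LD from the simulated panel; greedy clumping by ascending
exposure p at r² < 0.3).  The Wald SE uses the first-order delta method
(exposure-side variance ignored — the standard two-sample default); a
``second_order`` flag adds the exposure-side term of the ratio expansion.  IVW uses fixed-effect weights with
multiplicative random-effects inflation max(1, √(Q/(k−1))); a
fixed-effect-only flag exists.  The pleiotropy test computes
RSS = Σ_j w_j (β_out,j − β̂₋ⱼ·β_exp,j)² with leave-one-out IVW predictions
and w_j = 1/SE_out,j², simulating both sides parametrically from their SEs
under the fitted model; p uses the add-one rule, and proteins with fewer
than three instruments report NA (the minimum-instrument rule is a
documented choice; published tables show NA cells without stating one).
Under the default generator conditions the test's type-I rate sits in
[0.03, 0.08] at α = 0.05 and its power against one gross outlier exceeds
0.9.

## Colocalization

All Bayes-factor arithmetic is in log space with log-sum-exp (z² values in
the thousands are routine).  Prior effect scales default to 0.15
(quantitative pQTL side) and 0.2 (case-control GWAS side), following the
documented defaults of the standard implementation; both are configurable,
and no sdY correction is attempted since the GWAS effect scale is an
explicit config.  The distinct-variant weight L3 is computed as
exp(ls1+ls2)−exp(ls12) in log space and clamped at zero when round-off
makes it negative (warning only beyond float noise).  The region is the
protein's cis window.  Multi-causal-variant colocalization (SuSiE-style)
is out of scope.

## Differential expression

One shared design decomposition per comparison; the contrast is the
disease coefficient (case − control, so positive log2FC means higher in
patients).  The empirical-Bayes moment matching follows the marginal
scaled-inverse-χ² model of residual variances: with z = log s²_g,
E[z] and Var[z] identities in digamma/trigamma give d₀ (Newton inversion
of the trigamma) and s₀²; non-positive moment estimates fall back to
complete pooling (d₀ = ∞) with a warning.  Moderated t and p use
d₀ + d_g df.  Agreement with `limma::eBayes` (hyperparameters, t, p,
posterior variances) is asserted to 1e-6 in the tests.  The comparison
battery: GBA+ and LRRK2+ vs their own controls (treatment covariate),
idiopathic vs healthy controls (no treatment column — drug-naïve), all
patients vs all controls (mutation status + treatment as extra
covariates), and the disease × mutation interaction model, each
FDR-adjusted within the comparison.  Centers are fixed effects; protein
PCs are global, not per-subcohort.

## Endotype discovery

Residualization (age, sex, center as a factor) precedes the network.  The
unsigned adjacency is |cor|^power with power 11 by default; the soft-
threshold diagnostic reports the scale-free fit R² from a regression of
log10 density on log10 connectivity over 10 equal-occupancy bins
(width-corrected density) — equal-width binning is degenerate for the
spread-out connectivity distributions that soft thresholding produces.
Note that only heterogeneous module structure (varied sizes and loadings)
is scale-free-like; equal blocks with uniform loadings are not, and the
diagnostic correctly scores them low.

TOM follows the standard unsigned formula with unit diagonal.  Module
detection cuts the average-linkage dendrogram of 1 − TOM at a static
height chosen automatically as the midpoint of the widest height interval
maximizing the number of clusters of at least the minimum module size
(the final all-merging cut excluded); a fixed cut height is configurable.
A quantile-based cut was found to be unusable because virtually all merge
heights concentrate just below 1 at power 11.  The minimum module size
defaults to max(30, 0.12·n_analytes): at full aptamer-panel scale
(~4800 analytes) that reproduces the conventional 500, while staying
meaningful on desk-scale syntheses.

Consensus clustering subsamples 80% of patients 100 times and clusters
with Ward linkage on Euclidean distance over the z-scored module analytes
(average linkage is available but chains badly on elongated Gaussian
structure); the consensus entry is co-clustered/co-sampled, final per-k
labels come from average-linkage clustering of 1 − consensus, and the
reported k maximizes the Δ-area of the consensus CDF — though k = 2 is
the default used downstream, matching the two-endotype design.  Clinical
characterization uses χ² for categorical variables (Fisher fallback for
expected counts < 1 in 2×2 tables), a Gaussian GLM adjusted for age and
sex for quantitative variables, and Mann–Whitney for age.

The clinical predictor is a Gini CART on clinical variables only, with a
stratified 70/30 split, cost-complexity pruning chosen by 10-fold CV with
the 1-SE rule by default (strict CV-minimum does not prune
label-independent predictors back to the root, because null CV curves are
flat with a chance minimum at the full tree), and test AUC computed from
leaf class-proportion scores.

## Problem sizes

Default test and acceptance runs use cohorts of 200–1200 samples, 10–300
variants and 30–200 analytes, 30–100 consensus replicates, and 300–500
pleiotropy-test simulations — sizes at which every stage's statistical
guarantee is measurable in seconds while leaving the algorithms identical
to full-scale runs.

## Known limitations

Single-causal-variant colocalization only; no trans-pQTLs or conditional
secondary signals; no MR-Egger/median/mode estimators or Steiger
filtering; in-sample LD only (a reference panel can be supplied as a
genotype table); the generator's Gaussian abundance model has no
missingness or detection limits; clinical variables are conditionally
Gaussian.  The pleiotropy test implements the global detection step only —
outlier removal and distortion testing are limited to the
``leave_worst_out`` re-estimate, which drops the instrument with the
largest weighted leave-one-out residual and refits.
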
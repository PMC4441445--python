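# Methods

## Phenotype model and study design

A subject is "bald" when his Norwood-Hamilton grade is III or higher.
Categories cross age with baldness: 1 = age <50 and grade ≥III, 2 = age ≥50
and grade ≤II, 3 = age <50 and grade ≤II, 4 = age ≥50 and grade ≥III. The
age-50 boundary is inclusive on the older side ("aged 50 or older") and
strict on the younger ("below 50"). Categories 1 and 4 carry label 1
(bald), 2 and 3 label 0. Association and model fitting use the category
1-vs-2 extremes (176 + 129 men); evaluation uses a disjoint 300-man test
set of 50/50/100/100 per category, mirroring the two-stage design the
analysis was built around.

## Genotype representation and coding

Genotypes are stored as minor-allele dosages: 0/1/2 for autosomal SNPs and
a single allele (0/1) for the male X chromosome — hemizygous calls are
never expanded to diploid pairs. Inheritance codings: additive = dosage
(male X mapped to 0/2, so a minor-allele hemizygote carries the full
two-unit effect); dominant = any minor allele; recessive = two minor
alleles (a minor hemizygote counts as the "homozygote" and codes 1 under
both dominant and recessive). Missing calls propagate and are excluded
pairwise in univariate scans, complete-case within any multivariate model;
samples missing a model SNP are excluded from that model's evaluation and
counted separately. Genotype tables accept both allele-string and coded
dialects, auto-detected per cell, because no single table layout is
canonical for candidate-SNP panels.

## Logistic fitting and inference

Fits use Newton-scored maximum likelihood (statsmodels) with convergence
tolerance 1e-10 and a 100-iteration budget; perfect or quasi-separation
(|β| > 15 or non-finite standard errors) raises a diagnostic rather than
returning a silent extreme estimate. Confidence intervals are Wald,
exp(β ± 1.96·se), matching the convention of mainstream statistical GUIs;
univariate p-values are Wald, with likelihood-ratio p-values used inside
stepwise selection. Nagelkerke R² = [1 − exp(2(L0−Lm)/n)] / [1 − exp(2·L0/n)].

Stepwise multivariate selection: forward entry at LR p < 0.05, backward
removal at LR p ≥ 0.10, additive coding, perfectly collinear candidates
reduced to one representative. `max_snps=5` reproduces the compact-model
design of keeping the five most significant independent predictors. The
extended model ranks all candidates (including univariately non-significant
ones) by additive univariate p with an rsID tie-break and admits each SNP
whose refit raises the in-sample AUC by ≥0.001. Training AUC is in-sample
on the discovery set; no cross-validation is applied, a documented
limitation of the original design.

## Risk score and quartiles

GRS = Σ |βⱼ|·rⱼ over the model SNPs, where rⱼ counts the risk allele —
the minor allele when βⱼ > 0, otherwise the major allele, so every term
acts in the risk-increasing direction; male X counts are 0/2. Weights come
from the multivariate five-SNP model (univariate weights selectable).
Quartiles are rank-based with tied scores pulled into the lower quartile;
quartile odds ratios come from a logistic regression on quartile indicator
variables against the lowest quartile, which reduces exactly to the 2×2
cross-product ratio for each contrasted pair.

## Prediction thresholds and evaluation

At threshold t ≥ 0.5 a sample is called bald when P ≥ t, non-bald when
P ≤ 1−t, inconclusive otherwise; the boundary is a conclusive call
("failed to exceed" read strictly), and t = 0.5 has no inconclusive zone.
Sensitivity, specificity, PPV, NPV and per-category correct rates are
computed over conclusive calls only, with integer numerator/denominator
pairs retained; the inconclusive rate is over all attempted calls; AUC
(Mann-Whitney, ties one half) is threshold-free. Age-stratified reports
split the test set at 50 years (categories 1+3 vs 2+4).

## MDR and interaction information

MDR labels a multi-locus genotype cell high-risk when its case:control
ratio is at least the cohort-wide ratio (ties high-risk; empty cells
low-risk), scores models by balanced accuracy, and searches k-SNP subsets
exhaustively. Ten-fold stratified cross-validation with an explicit seed
yields testing balanced accuracy (fold-held-out scoring of the winning
set) and CV consistency (folds whose own best set matches the overall
winner); the original software's exact CV scheme is not documented, so
these conventions are this package's own. Entropies are plug-in estimates
from observed cell frequencies; node and edge values are normalised by the
class entropy H(C), the reading consistent with describing a SNP as
removing a percentage of outcome "uncertainty". The pairwise multiplicative
interaction test adds a product term to the two main effects and reports
its OR/CI/p.

## Population-genetic QC

Hardy-Weinberg testing is the exact conditional test (full enumeration of
heterozygote counts given allele counts, two-sided by summing probabilities
≤ the observed configuration's); it refuses X-linked SNPs in an all-male
cohort, where genotypes carry no within-individual allele pairing. A χ²
alternative is deliberately not the default because small genotype classes
are common at low MAF. LD between autosomal SNPs uses EM-estimated
haplotype frequencies (deterministic linkage-equilibrium initialisation,
relative log-likelihood tolerance 1e-10, 1000-iteration cap) with
r² = D²/(p₁q₁p₂q₂); male X pairs use the directly observed haplotypes.
Blocks are connected components of the r² > 0.8 graph — no D′-based or
four-gamete block definitions. The minimal detectable OR solves the
two-proportion normal-approximation power equation on allele counts by
bracketed root finding.

## The synthetic cohort generator

The generator emulates the candidate-panel structure the analysis assumes:

* **Panel.** 50 biallelic SNPs, 17 X-linked. Literature-anchored members
  keep their real rsIDs and, where published, MAFs (e.g. rs5919324 minor C
  at 0.17); the remaining fillers are synthetic — plausible rsIDs,
  positions, and MAFs frozen in `simulate.DEFAULT_PANEL` for
  reproducibility, not measured values.
* **LD.** Haplotypes within a block follow a first-order Markov chain whose
  adjacent-pair conditional probabilities achieve the target r² (solving
  D = r·√(p₁q₁p₂q₂)); non-adjacent r² decays multiplicatively. Blocks:
  three Xq12 blocks of 7+5+5 SNPs at r²=0.85, a five-SNP 20p11 block at
  0.85, a 17q21 triplet at 0.92, a chr7 pair at 0.85, and a four-SNP chr1
  cluster at 0.70. Infeasible targets (MAF-limited) raise an error stating
  the attainable maximum. Autosomal genotypes sum two independent
  haplotypes (HWE); male X genotypes are one haplotype.
* **Effects.** The five principal predictors carry the published joint
  odds ratios (0.480, 0.482, 0.557, 0.493, 1.595); secondary loci carry
  small effects (|OR| 1.1–1.4) sized so they are at best univariately
  detectable at n≈305, matching the observation that they improved
  prediction only marginally and showed no independent multivariate
  effects. Because those ORs were estimated by contrasting early-bald
  cases (a low-prevalence age stratum) with old non-bald controls (a
  high-prevalence stratum), the case-control slope amplifies the
  within-age allelic effect by approximately (1 − p_bald|<50) +
  p_bald|≥50 ≈ 1.36 under the default age model; target effects are stated
  on that design scale and deflated by this factor at generation time, so
  that refitting the published design recovers the stated values. The
  factor is a first-order approximation; residual deviation is well inside
  sampling error at the study's n.
* **Age and grades.** Baldness probability is logit-linear in age,
  calibrated to reported prevalence anchors (~16% of men 18–29 with
  significant hair loss, rising to 43–50% before 50): intercept −3.886,
  slope 0.0828/year at the mean genotype, ages uniform on 18–79. Grades:
  non-bald men receive I or II (II more likely with age); bald men receive
  III–VII by a monotone quantile map of the liability with fixed severity
  proportions (0.35/0.30/0.20/0.10/0.05). The grade-by-age joint
  distribution is a stand-in — no published joint distribution exists to
  calibrate against — so grade-resolved quantities should not be
  over-interpreted.
* **Missingness** defaults to 0 and is set to 0.002 in the study scripts,
  consistent with per-marker completion rates above 99%.
* **Seeding.** One integer seed drives genotypes, phenotypes and the
  study-design subsampling; identical configurations are bit-reproducible.

What passing tests on this generator do **not** show: robustness to
population stratification, genotyping error, female X dosage, coalescent
LD patterns, or non-additive genetic architecture (the generator's
liability is purely additive, so interaction-information and
product-term quantities computed on simulated data hover around their
null values and will not reproduce redundancy or antagonism observed in
real cohorts unless such effects are added to the configuration).

## Problem sizes and known behaviour

The bundled scripts simulate a 20,000-man population and subsample the
published design (305 discovery / 300 test); at this discovery size,
selection-based quantities are intentionally noisy — stepwise sets can
include high-LD proxies of causal SNPs, the forward-AUC model admits
20–30 SNPs, and per-SNP odds ratios scatter widely around their targets,
as they would across real replications of a study of this size. The GRS
quartile-4 odds ratio on the discovery extremes is large (commonly ~10–30)
because the extreme-category contrast concentrates genetic risk; a model
with test AUC ≈ 0.75 mathematically implies a top-versus-bottom-quartile
OR well above 3.

## Interfaces

Genotype, sample and SNP-metadata tables are TSV; models are versioned
JSON (schema mismatches and corrupted fields raise named errors); the CLI
(`mpbpred`) wires the stages and stamps outputs with a configuration hash
and seed. VCF ingest and XLS conversion are intentionally out of the core
path: the TSV readers define the supported dialects.
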
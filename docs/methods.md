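# Methods

## Scope and design

`cispen` is organised as an analysis project: the library under
`src/cispen/` holds every computation (simulation, expression prediction,
QC, variant classification, association and penetrance statistics), and the
numbered scripts under `analysis/` are thin narrative drivers that chain
those computations over files in `results/`.  The tests and the acceptance
script import only the library.

## Generative model

The simulator (`cispen.synthdata`) produces the three datasets the analyses
need, from a single `SimulationConfig`:

* **Weight models.** Per gene, `snps_per_gene` cis-SNPs with MAF ~
  U(`maf_range`) and weights ~ N(0, `weight_sd`²); each gene receives a
  synthetic cross-validation p (Beta(0.3, 3), so most but not all genes pass
  a 0.05 filter).  Variant ids are unique genome-wide; ref/alt pairs are
  never palindromic (array QC would remove them anyway).
* **Trios.** Parental haplotypes are vectors of independent Bernoulli(MAF)
  alleles — there is deliberately no LD and no recombination, which keeps
  the haplotype-expression contrast interpretable and makes every oracle
  (allele-frequency recovery, Mendelian consistency, expression linearity)
  exact.  The child inherits one whole haplotype from each parent, chosen
  uniformly.  One rare damaging variant per candidate trio is placed on one
  haplotype of one parent in one uniformly chosen gene; it is represented as
  an annotation bound to that haplotype id, not as a genotype row, because
  weight models never contain such variants.
* **Affection.** Bernoulli with logit = α + β·(μ_E − E_wt) (+ optional
  N(0, `noise_sd`²) liability noise), where E_wt is the predicted expression
  of the individual's own wild-type (non-carrier) haplotype and μ_E the
  population mean per-haplotype expression of the variant gene.  Penetrance
  therefore acts only through the wild-type haplotype, the loss-of-function
  reading of the hypothesis; β = 0 recovers the null exactly.  The
  non-carrier parent's affection uses the baseline logit alone.
* **Ascertainment.** Candidate trios are simulated in vectorised batches
  until `n_trios_target` satisfy (child affected ∧ child inherited the
  variant ∧ transmitting parent unaffected).  A bound (default
  400·`n_trios_target` candidates) turns pathological configurations into an
  explicit `SimulationError` naming the bound.
* **Case/control.** Unrelated individuals with Binomial(2, MAF) genotypes;
  a configured subset of genes (default one) shifts the logit by γ per
  centred unit of predicted expression; covariates are standard-normal
  noise columns, giving the TWAS calibration tests a realistic design
  matrix with no confounding.

Randomness: one master seed; fixed `SeedSequence` spawn keys per component
(0 weights, 1 trios, 2 case/control), so a config+seed reproduces output
byte for byte.  `simulate_wt_expression_pairs` is a fast path running the
identical generative and ascertainment model but returning only the
per-trio expression summaries; replicate studies (null calibration, power
curves) use it to avoid rebuilding pedigree/VCF plumbing thousands of
times.

### Default conditions

Desk-scale defaults: 40 genes × 10 cis-SNPs, MAF ∈ (0.05, 0.5), weight sd
0.2 (per-haplotype expression sd ≈ 0.28 expression units), baseline logit
−1 (≈ 27% baseline penetrance on the ascertainment scale), liability noise
0, 500 target trios, 1000+1000 case/control, 10 covariates.  Replicate
studies in the tests use smaller sizes (30–40 pairs per replicate, 4 genes
× 4 SNPs; the 200-gene null TWAS uses 500+500 samples); these sizes are
stated where used and were chosen so that thousands of replicates remain a
routine desk computation while binomial error bands stay tight enough to
detect miscalibration.

## Expression prediction

`predict_expression` computes E = Σ w·dosage over the variants present in
both the weight table and the dosage data.  Missing model variants are
dropped, not mean-imputed — the per-gene coverage fraction is reported and
an optional threshold can exclude low-coverage genes (default keeps all).
Allele handling: dosages count the weight table's alt allele; a ref/alt
swap is a hard error unless flipping is explicitly allowed (dosage → 2 − d,
or 1 − d per haplotype), and any other allele disagreement is always an
error.  Strand flips for palindromic SNPs are not attempted; those markers
are removed upstream by QC.  Predicted values are used raw (no
re-normalisation): both downstream tests are difference- or rank-based, so
any monotone rescaling is irrelevant (a property the tests verify).

## QC

Sample filters run before SNP filters, mirroring standard array-QC
practice: missingness ≥ 5% first (so an all-missing sample never reaches
the undefined het-rate computation), then heterozygosity outside
[0.158, 0.17] (bounds exclusive for removal; boundary inclusivity is a
convention choice documented here).  SNP filters run in fixed order —
palindromic, duplicated position+alleles, multiallelic position, indel,
missingness > 5%, MAF < 1%, HWE exact p < 10⁻⁶ (founders only when a
pedigree is supplied), Mendelian errors in > 1% of trios, then two-batch
checks (differential missingness by Fisher's exact at p < 10⁻⁵⁰, allele
frequency difference > 0.05; both are convention choices since no specific
statistic is standard).  Each removal carries exactly one primary reason
code and reports reconcile (input = kept + removed); every filter is
idempotent on its own output.

The HWE exact test is the standard conditional test (two-sided by
probability mass, not mid-p), implemented in log space over all
heterozygote counts of the observed parity; a tiny relative tolerance
(10⁻¹²) guards the ≤-comparison against floating-point ties.  The
Mendelian-error counter flags unphased-impossible child genotypes and skips
any site with a missing call in the trio.  The post-imputation filter keeps
r² ≥ 0.8 (inclusive) — note that one variant of the upstream description
inverts this direction; keeping high-r² variants is the only reading
consistent with the case/control preparation.

## Variant classification and triage

Putatively damaging = heterozygous, parentally inherited, gnomAD AF
strictly < 10⁻⁵ and cohort AF ≤ 10⁻⁴ (a lenient preset applies MAF < 0.1%
to both sources), in one of three gene contexts: dominant DDG2P
(confirmed/probable, LoF mechanism), recessive DDG2P (same), or constrained
(pLI > 0.9).  MPC ≥ 2 is required for missense variants only in the
constrained category by default; a switch extends it to the DDG2P
categories.  A missing MPC fails the gate (conservative) with a logged
warning rather than an error.  PTV-only sub-labels are always derivable
alongside PTV+missense.

The multi-indel filter removes all indels of any (proband, gene) pair with
two or more, since clustered indels usually reflect one complex event that
cannot be resolved without haplotype-aware annotation.  PPVs per clinical
filter class are the fraction of clinician-rated variants rated
(definitely/likely) pathogenic; unrated variants count in neither numerator
nor denominator, and a class with no rated variants has undefined PPV.
Diagnosis triage applies, in order: reanalysis membership, any rated
pathogenic/likely-pathogenic variant, any unrated variant in a class with
PPV > 50% (classes can be marked pair-only, in which case a trans
compound-het pair — one maternal plus one paternal variant in the same
gene — is required), and a de novo PTV in a pLI > 0.9 gene.  NDD cohort
membership is exact HPO-id intersection with the ten-term
neurodevelopmental list; no ontology traversal.

Pair sampling draws at most one (parent, gene) candidate per proband per
category, uniformly and deterministically given a seed, with candidate
order canonicalised so input row order cannot bias the draw.

## Statistics

* **TWAS**: statsmodels maximum-likelihood logistic fit per gene; Wald p on
  the expression coefficient (an LRT is available behind a flag).
  Constant-expression genes, separation and non-convergence are flagged
  with p absent rather than dropped silently.
* **Outlier enrichment**: control-only mean/sd, strict |E − mean| > k·sd
  with k = 3 by default, two-sided Fisher's exact per gene (SciPy's
  minimum-likelihood convention), Bonferroni threshold over genes actually
  tested.
* **Family test**: one-sided paired t (H1: parent > child), two-sided p and
  a two-sided 95% t-interval reported alongside so reversed effects remain
  visible.  Degenerate inputs (n < 2, all differences equal) are errors.
* **Rank test**: percentiles 100·(rank − ½)/N with mean-rank ties, pooled
  across genes; each control contributes one rank per gene (pooled N =
  carriers + genes × controls).  No within-control dependence correction is
  applied — a known limitation of the pooled design, inherited from the
  study it models.  Mann–Whitney is exact for pooled n ≤ 20 without ties,
  else a tie-corrected normal approximation with continuity correction; the
  method used is recorded.
* **Power**: exact noncentral-t (one- or two-sided); sample size by
  doubling bracket plus integer bisection, returning the minimal n.

## Validation strategy

Every statistical primitive has a dual route in the tests: the
implementation (library call or hand-written routine) against an
independent brute-force oracle — per-term accumulation loops for
prediction, exact rational enumeration for HWE and Fisher, 27-case gamete
enumeration for Mendelian errors, quadrature of the t density, full
rank-assignment enumeration for Mann–Whitney, from-scratch IRLS for the
logistic fit, and Monte Carlo for power.  Calibration tests check the
family, rank and TWAS tests at the nominal 5% level under the β = γ = 0
generative null within 3 binomial SEs, and a parameter-recovery test
verifies that family-test power rises monotonically in β and agrees with
the noncentral-t calculation evaluated at the Monte-Carlo effect size.

## What the simulations do and do not show

The generator emulates the mechanism and the ascertainment, not the data's
nuisance structure: no LD or recombination, no population stratification,
no genotyping or imputation error, no phenotypic heterogeneity, one variant
per trio, and expression that is exactly its genetic component.  Passing
tests therefore demonstrate that the statistics are implemented correctly,
calibrated under the model's null, and able to recover the embedded effect
— not that the real study's power or robustness to confounding is
reproduced.  Real-data analogues (specific genes, published p values)
require controlled-access genotypes and are out of scope.
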
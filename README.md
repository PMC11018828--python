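# cispen

Do common *cis*-regulatory variants modify the risk of neurodevelopmental
disorders (NDDs), and the penetrance of rare, inherited, putatively damaging
coding variants?  `cispen` implements the full analysis framework for that
question — weight-based expression imputation, a transcriptome-wide
association study (TWAS), rare-variant classification, within-family and
case/control penetrance-modification tests, power analysis and the
supporting genotype/trio QC — together with a generative simulator that
embeds the hypothesized mechanism with known ground truth, so every test can
be validated for calibration and parameter recovery without access to any
controlled patient data.

## The model

**Predicted expression.** For gene *g* with cis-eQTL weights
*w<sub>gv</sub>* (UTMOST/PrediXcan-style), the genetic component of
expression of individual *i* is the linear predictor
*E<sub>ig</sub>* = Σ<sub>v</sub> *w<sub>gv</sub>* · *d<sub>iv</sub>*, where
*d<sub>iv</sub>* ∈ [0, 2] is the alt-allele dosage.  Applied to one phased
haplotype (alleles in {0, 1}) the same form gives per-haplotype expression,
and E(hap1) + E(hap2) = E(diploid).  Genes are used only when their
cross-validation adjusted *p* < 0.05.

**TWAS.** Per gene, logistic regression of case status on *E* plus 10
covariates; Wald test on the expression coefficient; Bonferroni control
*α*/*m* across the *m* genes tested.

**Penetrance modification.** For a rare heterozygous variant inherited by an
affected child from an unaffected parent, both individuals share the variant
and its haplotype; they may differ in the *wild-type* haplotype.  If low
wild-type expression increases penetrance (a second, regulatory "hit" in a
loss-of-function gene), then under ascertainment (affected child, unaffected
transmitting parent):

* the parent's wild-type-haplotype expression should exceed the child's —
  one-sided paired *t*-test on *d<sub>i</sub>* = parent − child;
* variant-carrying probands should rank low in predicted expression of the
  variant gene relative to population controls — per-gene percentile ranks
  (100·(rank − ½)/N, mean rank for ties) pooled across genes, one-sided
  Wilcoxon test.

**Power.** The paired test's power at Cohen's *d* with *n* pairs is
P(T′ > t<sub>1−α,n−1</sub>) for T′ noncentral *t* with noncentrality
*d*·√*n* (as in R's `pwr.t.test`), with a bracketed search for the smallest
*n* reaching a target power.

**Simulator.** Independent Bernoulli(MAF) cis-SNP haplotypes; child inherits
one haplotype per parent; one rare damaging variant placed on a parental
haplotype; affection is Bernoulli with
logit = α + β·(μ<sub>E</sub> − E<sub>wt</sub>), so β = 0 is the exact null;
trios are ascertained on the study design.  A case/control generator adds a
known TWAS effect gene (logit shift γ per expression unit).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (each accepts `--seed`):

```bash
python analysis/01_simulate_cohort.py --seed 1     # trios + case/control panel
python analysis/02_predict_expression.py           # haplotype & diploid expression
python analysis/03_twas_scan.py                    # TWAS + outlier enrichment
python analysis/04_penetrance_tests.py --seed 1    # family + rank tests
python analysis/05_power_analysis.py --seed 1      # beta -> power map
```

With seed 1 the pipeline prints, among other lines:

```
trios: ascertained 500 families (3000 haplotypes x 300 variants)
TWAS: 30 genes, Bonferroni threshold 1.67e-03
top gene GENE0009 (beta=+1.008, p=3.10e-42); true effect gene(s): GENE0009 -> RECOVERED
family test: n=500 pairs, mean(parent - child) = +0.0853 [+0.0536, +0.1170], one-sided p = 9.38e-08
rank test: 500 carrier ranks vs 60000 pooled control ranks (30 genes); mean case rank 45.28 vs control 50.04; one-sided p = 0.000122 (normal)
```

Reading this: the scan recovers the generative effect gene with a
coefficient estimate (+1.008) matching the simulated γ = 1.0; transmitting
parents' wild-type haplotypes are expressed +0.085 units above their
affected children's (95% CI excludes 0, one-sided p ≈ 10⁻⁷); and carrier
probands' per-gene expression percentile sits below the control mean of 50,
both signatures of the simulated penetrance modification (β = 1.5).  The
power map in `results/power/power_curve.tsv` shows how quickly these
signatures fade at smaller β — at β = 0.5, ~1600 pairs would be needed for
80% power at α = 0.05.

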
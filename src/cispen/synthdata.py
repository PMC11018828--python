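"""Synthetic cohorts in which cis-regulatory haplotypes modify penetrance.

The generative model mirrors the study design under test:

* Per gene, a handful of independent cis-SNPs with MAFs drawn uniformly from
  a configured range and additive expression weights drawn from N(0, w_sd^2).
  There is no LD between cis-SNPs: each parental haplotype is a vector of
  independent Bernoulli(MAF) alleles, which keeps the haplotype-expression
  contrast interpretable and the Monte-Carlo oracles tractable.
* Trios: each parent has two haplotypes; the child inherits one uniformly
  chosen haplotype from each parent (no recombination).  One rare, putatively
  damaging variant is placed on one haplotype of one parent, in one randomly
  chosen gene; rare variants are annotations bound to a named haplotype, not
  rows of the genotype matrix (weight models never include them).
* Penetrance acts through the predicted expression of the NON-carrier
  (wild-type) haplotype: affection is Bernoulli with

      logit = baseline_logit + penetrance_effect * (mu_E - E_wt) [+ noise]

  where mu_E is the population mean per-haplotype expression of the variant
  gene, E_wt is the individual's wild-type-haplotype prediction, and noise is
  optional N(0, noise_sd^2) liability noise.  penetrance_effect = 0 recovers
  the null exactly.
* Ascertainment: candidate trios are simulated until the target number
  satisfy (child affected) AND (child inherited the variant) AND
  (transmitting parent unaffected) — the affected-child / unaffected-
  transmitting-parent design.  Under ascertainment with a positive effect,
  transmitting parents are enriched for high wild-type expression and
  children for low, the signature the family paired test looks for.
* Case/control cohorts: unrelated individuals under Hardy-Weinberg; a
  configured subset of genes shifts the affection logit by
  twas_effect * (centred predicted expression), giving the TWAS scan a known
  true-effect gene.

All randomness flows from a single master seed; per-component streams are
derived with fixed ``numpy.random.SeedSequence`` spawn keys (0 = weights,
1 = trios, 2 = case/control), so the same config + seed is byte-reproducible
stream by stream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigurationError, SimulationError
from .expression import DosageMatrix, EQTLWeightSet

log = logging.getLogger(__name__)

_STREAMS = {"weights": 0, "trios": 1, "case_control": 2}

_BASES = np.array(["A", "C", "G", "T"])
# non-palindromic ref/alt pairs only (palindromic SNPs are removed by QC)
_ALLELE_PAIRS = [(r, a) for r in _BASES for a in _BASES
                 if r != a and {r, a} not in ({"A", "T"}, {"C", "G"})]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for the synthetic study.

    Expression is in model units (weights ~ N(0, weight_sd^2) per alt allele);
    ``baseline_logit`` sets the un-modified penetrance scale and
    ``penetrance_effect`` (per expression unit of wild-type-haplotype
    deficit) and ``twas_effect`` (per expression unit, case/control genes)
    set the signal sizes.
    """

    n_genes: int = 40
    snps_per_gene: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    weight_sd: float = 0.2
    noise_sd: float = 0.0
    n_trios_target: int = 500
    n_cases: int = 1000
    n_controls: int = 1000
    baseline_logit: float = -1.0
    penetrance_effect: float = 1.0
    twas_effect: float = 0.5
    n_effect_genes: int = 1
    n_covariates: int = 10
    seed: int = 0
    max_candidates: int | None = None  # default: 400 * n_trios_target

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.snps_per_gene < 1:
            raise ConfigurationError("snps_per_gene must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.weight_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("weight_sd and noise_sd must be >= 0")
        if self.n_covariates < 0:
            raise ConfigurationError("n_covariates must be >= 0")

    def candidate_bound(self) -> int:
        return self.max_candidates or 400 * self.n_trios_target

    def rng(self, component: str) -> np.random.Generator:
        """Deterministic per-component stream derived from the master seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[component],))
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery checks."""

    weights: pd.DataFrame
    trios: pd.DataFrame = field(default_factory=pd.DataFrame)
    liability: pd.DataFrame = field(default_factory=pd.DataFrame)
    twas_effect_genes: list[str] = field(default_factory=list)


@dataclass
class TrioCohort:
    """Ascertained trios: pedigree, phased haplotypes and variant placements."""

    pedigree: pd.DataFrame          # fid iid father mother sex phenotype
    haplotypes: DosageMatrix        # phased; rows <iid>_h1 / <iid>_h2
    rare_variants: pd.DataFrame     # proband, parent, gene, carrier haplotype ids

    @property
    def n_trios(self) -> int:
        return int((self.pedigree["father"] != "0").sum())


def simulate_eqtl_models(config: SimulationConfig, tissue_label: str = "blood") -> EQTLWeightSet:
    """Fabricate a per-gene cis-SNP weight set with synthetic cv p values."""
    rng = config.rng("weights")
    G, S = config.n_genes, config.snps_per_gene
    genes = [f"GENE{g:04d}" for g in range(G)]
    rows = []
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), G * S)
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], G * S)
    w = rng.normal(0.0, config.weight_sd, G * S) if config.weight_sd > 0 else np.zeros(G * S)
    for g in range(G):
        for s in range(S):
            k = g * S + s
            ref, alt = _ALLELE_PAIRS[pair_idx[k]]
            rows.append(
                {
                    "gene": genes[g],
                    "variant_id": f"var_g{g:04d}_s{s:02d}",
                    "chrom": str(g % 22 + 1),
                    "pos": 10_000 + (g // 22) * 1_000_000 + s * 1_000 + 1,
                    "ref": ref,
                    "alt": alt,
                    "weight": w[k],
                    "maf": mafs[k],
                }
            )
    cv_p = pd.Series(rng.beta(0.3, 3.0, G), index=pd.Index(genes, name="gene"), name="cv_p")
    return EQTLWeightSet(tissue=tissue_label, weights=pd.DataFrame(rows), cv_p=cv_p)


def _weight_arrays(weights: EQTLWeightSet):
    """(variant table, maf vector, V x G weight matrix, gene list)."""
    wt = weights.weights.reset_index(drop=True)
    if "maf" not in wt.columns:
        raise ConfigurationError("weight table needs a 'maf' column to simulate from")
    genes = list(dict.fromkeys(wt["gene"]))
    gidx = {g: j for j, g in enumerate(genes)}
    W = np.zeros((len(wt), len(genes)))
    W[np.arange(len(wt)), [gidx[g] for g in wt["gene"]]] = wt["weight"].to_numpy(float)
    return wt, wt["maf"].to_numpy(float), W, genes


def simulate_wt_expression_pairs(
    config: SimulationConfig, weights: EQTLWeightSet, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Fast path: ascertained trios as (parent, child) wild-type expression pairs.

    Runs the identical generative and ascertainment model as
    :func:`simulate_trio_cohort` but returns only what the penetrance tests
    consume — per ascertained trio, the gene, the transmitting parent's and
    the child's wild-type-haplotype predicted expression, and the child's
    total (diploid) predicted expression for the variant gene.  Used by
    replicate studies (null calibration, power curves) where building the
    full pedigree/VCF plumbing thousands of times would be waste.
    """
    if weights.n_variants == 0:
        raise ConfigurationError("weight set is empty")
    rng = rng or config.rng("trios")
    wt, maf, W, genes = _weight_arrays(weights)
    mu_hap = maf @ W  # population mean per-haplotype expression per gene
    V, G = W.shape
    target, bound = config.n_trios_target, config.candidate_bound()
    out: list[pd.DataFrame] = []
    n_acc, attempts = 0, 0
    batch = max(256, 4 * target)
    while n_acc < target:
        if attempts >= bound:
            raise SimulationError(
                f"ascertained only {n_acc}/{target} trios after {attempts} candidate "
                f"trios (bound {bound}); raise baseline_logit or max_candidates"
            )
        M = min(batch, bound - attempts)
        attempts += M
        mother = rng.random((M, 2, V)) < maf          # two haplotypes each
        father = rng.random((M, 2, V)) < maf
        m_choice = rng.integers(0, 2, M)              # which maternal hap the child gets
        f_choice = rng.integers(0, 2, M)
        gene = rng.integers(0, G, M)
        par_is_father = rng.integers(0, 2, M).astype(bool)
        par_hap = rng.integers(0, 2, M)               # carrier haplotype within parent

        mE = mother.reshape(M * 2, V) @ W             # (2M, G) haplotype expression
        fE = father.reshape(M * 2, V) @ W
        idx = np.arange(M)
        gcol = gene
        mE = mE.reshape(M, 2, G)
        fE = fE.reshape(M, 2, G)

        carrier_choice = np.where(par_is_father, f_choice, m_choice)
        inherited = carrier_choice == par_hap

        # child wild-type hap = the hap transmitted by the *other* parent
        child_wt = np.where(
            par_is_father, mE[idx, m_choice, gcol], fE[idx, f_choice, gcol]
        )
        child_carrier_expr = np.where(
            par_is_father, fE[idx, f_choice, gcol], mE[idx, m_choice, gcol]
        )
        parent_E = np.where(par_is_father[:, None], fE[idx, :, gcol], mE[idx, :, gcol])
        parent_wt = parent_E[idx, 1 - par_hap]

        noise = (
            rng.normal(0.0, config.noise_sd, (2, M)) if config.noise_sd > 0 else np.zeros((2, M))
        )
        beta, alpha = config.penetrance_effect, config.baseline_logit
        p_child = expit(alpha + beta * (mu_hap[gcol] - child_wt) + noise[0])
        p_parent = expit(alpha + beta * (mu_hap[gcol] - parent_wt) + noise[1])
        child_aff = rng.random(M) < p_child
        parent_aff = rng.random(M) < p_parent

        keep = inherited & child_aff & ~parent_aff
        if keep.any():
            out.append(
                pd.DataFrame(
                    {
                        "gene": [genes[j] for j in gene[keep]],
                        "parent_is_father": par_is_father[keep],
                        "parent_carrier_hap": par_hap[keep] + 1,
                        "child_from_mother": m_choice[keep] + 1,
                        "child_from_father": f_choice[keep] + 1,
                        "parent_wt_expr": parent_wt[keep],
                        "child_wt_expr": child_wt[keep],
                        "child_total_expr": child_wt[keep] + child_carrier_expr[keep],
                    }
                )
            )
            n_acc += int(keep.sum())
    pairs = pd.concat(out, ignore_index=True).iloc[: target].reset_index(drop=True)
    return pairs


def simulate_trio_cohort(
    config: SimulationConfig, weights: EQTLWeightSet
) -> tuple[TrioCohort, GroundTruth]:
    """Simulate ascertained trios with full phased genotypes and pedigree.

    See the module docstring for the generative model.  The rare damaging
    variant of trio *t* sits on haplotype ``parent_carrier_hap`` of the
    transmitting parent and (by ascertainment) was transmitted to the child.
    """
    if weights.n_variants == 0:
        raise ConfigurationError("weight set is empty")
    rng = config.rng("trios")
    wt, maf, W, genes = _weight_arrays(weights)
    mu_hap = maf @ W
    V, G = W.shape
    target, bound = config.n_trios_target, config.candidate_bound()

    hap_rows, ped_rows, rv_rows, truth_rows, liab_rows = [], [], [], [], []
    n_acc, attempts = 0, 0
    batch = max(256, 4 * target)
    alpha, beta = config.baseline_logit, config.penetrance_effect
    while n_acc < target:
        if attempts >= bound:
            raise SimulationError(
                f"ascertained only {n_acc}/{target} trios after {attempts} candidate "
                f"trios (bound {bound}); raise baseline_logit or max_candidates"
            )
        M = min(batch, bound - attempts)
        attempts += M
        mother = (rng.random((M, 2, V)) < maf).astype(np.int8)
        father = (rng.random((M, 2, V)) < maf).astype(np.int8)
        m_choice = rng.integers(0, 2, M)
        f_choice = rng.integers(0, 2, M)
        gene = rng.integers(0, G, M)
        par_is_father = rng.integers(0, 2, M).astype(bool)
        par_hap = rng.integers(0, 2, M)

        mE = (mother.reshape(M * 2, V) @ W).reshape(M, 2, G)
        fE = (father.reshape(M * 2, V) @ W).reshape(M, 2, G)
        idx = np.arange(M)
        carrier_choice = np.where(par_is_father, f_choice, m_choice)
        inherited = carrier_choice == par_hap
        child_wt = np.where(par_is_father, mE[idx, m_choice, gene], fE[idx, f_choice, gene])
        parent_E = np.where(par_is_father[:, None], fE[idx, :, gene], mE[idx, :, gene])
        parent_wt = parent_E[idx, 1 - par_hap]
        other_logit = np.full(M, alpha)

        noise = (
            rng.normal(0.0, config.noise_sd, (3, M)) if config.noise_sd > 0 else np.zeros((3, M))
        )
        child_logit = alpha + beta * (mu_hap[gene] - child_wt) + noise[0]
        parent_logit = alpha + beta * (mu_hap[gene] - parent_wt) + noise[1]
        other_logit = other_logit + noise[2]
        child_aff = rng.random(M) < expit(child_logit)
        parent_aff = rng.random(M) < expit(parent_logit)
        other_aff = rng.random(M) < expit(other_logit)

        keep = np.flatnonzero(inherited & child_aff & ~parent_aff)
        for k in keep:
            if n_acc >= target:
                break
            t = n_acc
            fid = f"F{t:05d}"
            cid, mid, pid = f"{fid}_C", f"{fid}_M", f"{fid}_F"
            child_h = np.stack([mother[k, m_choice[k]], father[k, f_choice[k]]])
            for iid, haps in ((cid, child_h), (mid, mother[k]), (pid, father[k])):
                hap_rows.append((f"{iid}_h1", haps[0]))
                hap_rows.append((f"{iid}_h2", haps[1]))
            carrier_parent = pid if par_is_father[k] else mid
            # child carries the variant on the hap from the carrier parent:
            # hap1 = maternal, hap2 = paternal by construction above
            child_hap = 2 if par_is_father[k] else 1
            ped_rows += [
                (fid, cid, pid, mid, 0, 2 if child_aff[k] else 1),
                (fid, mid, "0", "0", 2,
                 2 if (not par_is_father[k] and parent_aff[k]) or
                      (par_is_father[k] and other_aff[k]) else 1),
                (fid, pid, "0", "0", 1,
                 2 if (par_is_father[k] and parent_aff[k]) or
                      (not par_is_father[k] and other_aff[k]) else 1),
            ]
            rv_rows.append(
                {
                    "trio": fid,
                    "proband": cid,
                    "parent": carrier_parent,
                    "gene": genes[gene[k]],
                    "parent_carrier_hap": f"{carrier_parent}_h{par_hap[k] + 1}",
                    "child_carrier_hap": f"{cid}_h{child_hap}",
                }
            )
            truth_rows.append(
                {
                    "trio": fid,
                    "transmitting_parent": carrier_parent,
                    "carrier_hap": f"{carrier_parent}_h{par_hap[k] + 1}",
                    "gene": genes[gene[k]],
                    "parent_wt_expr": parent_wt[k],
                    "child_wt_expr": child_wt[k],
                }
            )
            liab_rows += [
                {"iid": cid, "logit": child_logit[k], "affected": bool(child_aff[k])},
                {"iid": carrier_parent, "logit": parent_logit[k],
                 "affected": bool(parent_aff[k])},
                {"iid": mid if par_is_father[k] else pid, "logit": other_logit[k],
                 "affected": bool(other_aff[k])},
            ]
            n_acc += 1

    hap_ids = [h for h, _ in hap_rows]
    hap_mat = np.asarray([v for _, v in hap_rows], dtype=float)
    variants = wt[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    variants["maf"] = maf
    cohort = TrioCohort(
        pedigree=pd.DataFrame(
            ped_rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"]
        ),
        haplotypes=DosageMatrix(
            samples=hap_ids, variants=variants, dosages=hap_mat, phased=True
        ),
        rare_variants=pd.DataFrame(rv_rows),
    )
    truth = GroundTruth(
        weights=wt.copy(),
        trios=pd.DataFrame(truth_rows),
        liability=pd.DataFrame(liab_rows).sort_values("iid", kind="stable").reset_index(drop=True),
    )
    log.info("ascertained %d trios from %d candidates (%.1f%%)",
             target, attempts, 100 * target / attempts)
    return cohort, truth


def simulate_case_control(
    config: SimulationConfig, weights: EQTLWeightSet
) -> tuple[DosageMatrix, np.ndarray, np.ndarray, GroundTruth]:
    """Simulate an unrelated case/control panel with optional TWAS effect genes.

    Returns (dosages, status 0/1, covariate matrix, ground truth).  Genotypes
    are Binomial(2, MAF) per variant (Hardy-Weinberg, no LD); the first
    ``n_effect_genes`` genes (chosen at random) shift the affection logit by
    ``twas_effect`` per centred unit of their predicted expression.
    """
    if config.n_cases < 1 or config.n_controls < 1:
        raise ConfigurationError("n_cases and n_controls must be >= 1")
    if weights.n_variants == 0:
        raise ConfigurationError("weight set is empty")
    rng = config.rng("case_control")
    wt, maf, W, genes = _weight_arrays(weights)
    V, G = W.shape
    n_eff = min(config.n_effect_genes, G) if config.twas_effect != 0 else 0
    eff_idx = np.sort(rng.choice(G, size=n_eff, replace=False)) if n_eff else np.array([], int)
    mu_ind = 2 * (maf @ W)  # mean diploid expression per gene

    need_case, need_ctrl = config.n_cases, config.n_controls
    geno_rows, status = [], []
    bound = 400 * (need_case + need_ctrl)
    attempts = 0
    got_case = got_ctrl = 0
    batch = max(512, 2 * (need_case + need_ctrl))
    while got_case < need_case or got_ctrl < need_ctrl:
        if attempts >= bound:
            raise SimulationError(
                f"collected {got_case}/{need_case} cases and {got_ctrl}/{need_ctrl} "
                f"controls after {attempts} individuals (bound {bound})"
            )
        M = min(batch, bound - attempts)
        attempts += M
        geno = rng.binomial(2, maf, (M, V)).astype(float)
        logit = np.full(M, config.baseline_logit)
        if n_eff:
            E = geno @ W[:, eff_idx]
            logit = logit + config.twas_effect * (E - mu_ind[eff_idx]).sum(axis=1)
        if config.noise_sd > 0:
            logit = logit + rng.normal(0.0, config.noise_sd, M)
        aff = rng.random(M) < expit(logit)
        for m in range(M):
            if aff[m] and got_case < need_case:
                geno_rows.append(geno[m])
                status.append(1)
                got_case += 1
            elif not aff[m] and got_ctrl < need_ctrl:
                geno_rows.append(geno[m])
                status.append(0)
                got_ctrl += 1

    covariates = rng.normal(0.0, 1.0, (len(status), config.n_covariates))
    variants = wt[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    variants["maf"] = maf
    dosages = DosageMatrix(
        samples=[f"S{i:05d}" for i in range(len(status))],
        variants=variants,
        dosages=np.asarray(geno_rows),
    )
    truth = GroundTruth(weights=wt.copy(), twas_effect_genes=[genes[j] for j in eff_idx])
    return dosages, np.asarray(status), covariates, truth


# ---------------------------------------------------------------------------
# Emission: phased VCF 4.2, 6-column PED, TSV tables
# ---------------------------------------------------------------------------

def write_vcf(haplotypes: DosageMatrix, path: str | Path, phased: bool | None = None) -> None:
    """Write a (phased) haplotype or genotype matrix as VCF 4.2 text.

    For phased input, sample ids must come in ``X_h1``/``X_h2`` pairs; the two
    rows of a pair become one ``a|b`` genotype column.
    """
    phased = haplotypes.phased if phased is None else phased
    v = haplotypes.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=cispen\n")
        for chrom in dict.fromkeys(v["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if phased:
            if len(haplotypes.samples) % 2:
                raise ConfigurationError("phased output needs paired haplotype rows")
            samples = [s[:-3] for s in haplotypes.samples[::2]]
            a = haplotypes.dosages[0::2].astype(int)
            b = haplotypes.dosages[1::2].astype(int)
            gt = np.char.add(np.char.add(a.astype(str), "|"), b.astype(str))
        else:
            samples = list(haplotypes.samples)
            code = {0: "0/0", 1: "0/1", 2: "1/1"}
            gt = np.vectorize(lambda d: code[int(round(d))])(haplotypes.dosages)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = np.lexsort((v["pos"].to_numpy(), v["chrom"].astype(str).to_numpy()))
        for j in order:
            row = v.iloc[j]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gt[:, j]) + "\n"
            )


def write_ped(pedigree: pd.DataFrame, path: str | Path) -> None:
    """Write a 6-column PED/FAM file (fid iid father mother sex phenotype)."""
    pedigree[["fid", "iid", "father", "mother", "sex", "phenotype"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_ped(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(
        path, sep="\t", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    return ped
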
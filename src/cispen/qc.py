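"""Genotype-array and trio quality control.

Implements the standard pre-imputation QC ladder for trio array data:
sample-level missingness and heterozygosity filters, per-trio Mendelian-error
counts, then per-SNP filters (palindromic / duplicated / multiallelic /
indel removal, missingness, MAF, Hardy-Weinberg exact test on founders,
per-SNP Mendelian error rate across trios, batch differential missingness
and allele-frequency checks), and a post-imputation r-squared filter.

Filter order is fixed — samples first, then SNPs, each reason applied in the
order listed above — and every removal carries exactly one primary reason
code, so reports reconcile (input = kept + removed).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .exceptions import ConfigurationError

log = logging.getLogger(__name__)

MISSING = -1

_PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GenotypeCalls:
    """Hard genotype calls in {0, 1, 2, missing(-1)}, samples x variants."""

    samples: list[str]
    variants: pd.DataFrame  # variant_id, chrom, pos, ref, alt [, is_indel]
    calls: np.ndarray
    batch: pd.Series | None = None  # per-sample batch label

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ConfigurationError("calls shape does not match samples x variants")
        if not np.isin(self.calls, (MISSING, 0, 1, 2)).all():
            raise ConfigurationError("calls must be in {0, 1, 2, missing}")
        if self.variants["variant_id"].duplicated().any():
            raise ConfigurationError("variant ids must be unique")
        v = self.variants
        if "is_indel" not in v.columns:
            v = v.assign(is_indel=(v["ref"].str.len() != 1) | (v["alt"].str.len() != 1))
        if "is_palindromic" not in v.columns:
            v = v.assign(
                is_palindromic=[(r, a) in _PALINDROMES for r, a in zip(v["ref"], v["alt"])]
            )
        self.variants = v.reset_index(drop=True)

    def drop_samples(self, ids: set[str]) -> "GenotypeCalls":
        keep = [i for i, s in enumerate(self.samples) if s not in ids]
        return GenotypeCalls(
            samples=[self.samples[i] for i in keep],
            variants=self.variants,
            calls=self.calls[keep],
            batch=None if self.batch is None else self.batch.drop(index=list(ids), errors="ignore"),
        )

    def drop_variants(self, ids: set[str]) -> "GenotypeCalls":
        keep = ~self.variants["variant_id"].isin(ids).to_numpy()
        return GenotypeCalls(
            samples=self.samples,
            variants=self.variants[keep].reset_index(drop=True),
            calls=self.calls[:, keep],
            batch=self.batch,
        )


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults follow common array-QC practice for trios."""

    sample_missing_max: float = 0.05
    het_rate_min: float = 0.158
    het_rate_max: float = 0.17
    trio_mendel_max: int = 200
    snp_missing_max: float = 0.05
    snp_maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    snp_mendel_trio_frac_max: float = 0.01
    batch_diff_p_min: float = 1e-50
    batch_af_diff_max: float = 0.05
    impute_r2_min: float = 0.8

    def __post_init__(self) -> None:
        for name in ("sample_missing_max", "snp_missing_max", "snp_maf_min",
                     "snp_mendel_trio_frac_max"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not self.het_rate_min < self.het_rate_max:
            raise ConfigurationError("het_rate_min must be < het_rate_max")


@dataclass
class QCReport:
    """Removals with one primary reason code each, plus reconciliation counts."""

    removed_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample", "reason"])
    )
    removed_variants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )
    trio_mendel_counts: pd.Series | None = None
    n_input_samples: int = 0
    n_input_variants: int = 0

    @property
    def summary(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for reason, n in self.removed_samples.groupby("reason").size().items():
            out[f"sample:{reason}"] = int(n)
        for reason, n in self.removed_variants.groupby("reason").size().items():
            out[f"variant:{reason}"] = int(n)
        return out

    def reconciles(self, kept_samples: int, kept_variants: int) -> bool:
        return (
            kept_samples + len(self.removed_samples) == self.n_input_samples
            and kept_variants + len(self.removed_variants) == self.n_input_variants
        )

    def to_tsv(self, prefix: str) -> None:
        self.removed_samples.to_csv(f"{prefix}samples_removed.tsv", sep="\t", index=False)
        self.removed_variants.to_csv(f"{prefix}variants_removed.tsv", sep="\t", index=False)


def sample_qc(calls: GenotypeCalls, thresholds: QCThresholds = QCThresholds()) -> QCReport:
    """Remove samples by missingness, then by heterozygosity rate.

    A sample is removed if its missing fraction is >= ``sample_missing_max``;
    among the remainder, if its het rate (het calls / non-missing calls) is
    strictly below ``het_rate_min`` or strictly above ``het_rate_max``.
    Missingness is evaluated first, so a fully missing sample never reaches
    the (undefined) het-rate check.
    """
    if len(calls.variants) == 0:
        raise ConfigurationError("sample QC needs at least one variant")
    miss = (calls.calls == MISSING).mean(axis=1)
    removed = []
    for i, s in enumerate(calls.samples):
        if miss[i] >= thresholds.sample_missing_max:
            removed.append((s, "missingness"))
            continue
        nonmiss = (calls.calls[i] != MISSING).sum()
        het = (calls.calls[i] == 1).sum() / nonmiss
        if het < thresholds.het_rate_min or het > thresholds.het_rate_max:
            removed.append((s, "heterozygosity"))
    return QCReport(
        removed_samples=pd.DataFrame(removed, columns=["sample", "reason"]),
        n_input_samples=len(calls.samples),
        n_input_variants=len(calls.variants),
    )


def mendelian_error_flags(
    child: np.ndarray, mother: np.ndarray, father: np.ndarray
) -> np.ndarray:
    """Per-variant flags: the unphased child genotype is Mendelian-impossible.

    Sites with any missing call in the trio are never flagged.
    """
    child, mother, father = (np.asarray(a, dtype=int) for a in (child, mother, father))
    if not (child.shape == mother.shape == father.shape):
        raise ConfigurationError("child/mother/father call vectors must be aligned")
    complete = (child != MISSING) & (mother != MISSING) & (father != MISSING)
    err = np.zeros(child.shape, dtype=bool)
    err |= (child == 0) & ((mother == 2) | (father == 2))
    err |= (child == 2) & ((mother == 0) | (father == 0))
    err |= (child == 1) & (((mother == 0) & (father == 0)) | ((mother == 2) & (father == 2)))
    return err & complete


def mendelian_error_count(
    child: np.ndarray, mother: np.ndarray, father: np.ndarray
) -> int:
    """Count Mendelian-impossible sites in a trio (missing sites skipped)."""
    return int(mendelian_error_flags(child, mother, father).sum())


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p value (Wigginton-style, not mid-p).

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts (same parity) whose probability does not exceed that
    of the observed configuration.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ConfigurationError("genotype counts must be >= 0")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ConfigurationError("need at least one genotype")
    n_alt = 2 * n_hom_alt + n_het  # alt allele count; symmetric in ref/alt
    rare = min(n_alt, 2 * n - n_alt)
    # log P(h hets | allele counts) up to a constant: -log h! -log hom_a! -log hom_b! + h log 2
    hs = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hs) // 2
    hom_common = n - hs - hom_rare
    logp = (
        hs * math.log(2.0)
        - np.array([math.lgamma(h + 1) for h in hs])
        - np.array([math.lgamma(h + 1) for h in hom_rare])
        - np.array([math.lgamma(h + 1) for h in hom_common])
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hs == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _trio_indices(calls: GenotypeCalls, pedigree: pd.DataFrame):
    """(child, mother, father) sample-row index triples for complete trios."""
    pos = {s: i for i, s in enumerate(calls.samples)}
    trios = []
    for _, row in pedigree.iterrows():
        if row["father"] != "0" and row["mother"] != "0":
            if row["iid"] in pos and row["father"] in pos and row["mother"] in pos:
                trios.append((row["iid"], pos[row["iid"]], pos[row["mother"]], pos[row["father"]]))
    return trios


def trio_mendel_counts(calls: GenotypeCalls, pedigree: pd.DataFrame) -> pd.Series:
    """Per-trio Mendelian-error counts, indexed by child id."""
    out = {}
    for cid, ci, mi, fi in _trio_indices(calls, pedigree):
        out[cid] = mendelian_error_count(calls.calls[ci], calls.calls[mi], calls.calls[fi])
    return pd.Series(out, dtype=int, name="mendel_errors")


def snp_qc(
    calls: GenotypeCalls,
    pedigree: pd.DataFrame | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Per-SNP filters applied in fixed order; first failing reason wins.

    Order: palindromic, duplicated, multiallelic, indel, missingness, MAF,
    HWE (founders when a pedigree is supplied), per-SNP Mendelian error rate
    across trios, batch differential missingness (Fisher exact) and batch
    allele-frequency difference.
    """
    v = calls.variants
    n_var = len(v)
    reason = np.array([""] * n_var, dtype=object)

    def mark(mask: np.ndarray, label: str) -> None:
        mask = np.asarray(mask, dtype=bool) & (reason == "")
        reason[mask] = label

    mark(v["is_palindromic"].to_numpy(), "palindromic")
    dup = v.duplicated(["chrom", "pos", "ref", "alt"], keep=False).to_numpy()
    mark(dup, "duplicated")
    multi = v.duplicated(["chrom", "pos"], keep=False).to_numpy() & ~dup
    mark(multi, "multiallelic")
    mark(v["is_indel"].to_numpy(), "indel")

    miss = (calls.calls == MISSING).mean(axis=0)
    mark(miss > thresholds.snp_missing_max, "missingness")

    founders = np.arange(len(calls.samples))
    if pedigree is not None:
        children = set(pedigree.loc[pedigree["father"] != "0", "iid"])
        founders = np.array(
            [i for i, s in enumerate(calls.samples) if s not in children], dtype=int
        )
    fcalls = calls.calls[founders]
    nonmiss = (fcalls != MISSING).sum(axis=0)
    alt = np.where(fcalls == MISSING, 0, fcalls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(nonmiss > 0, alt / (2 * np.maximum(nonmiss, 1)), 0.0)
    maf = np.minimum(af, 1 - af)
    mark(maf < thresholds.snp_maf_min, "maf")

    hwe_fail = np.zeros(n_var, dtype=bool)
    for j in range(n_var):
        if reason[j]:
            continue
        col = fcalls[:, j]
        counts = [(col == g).sum() for g in (0, 1, 2)]
        if sum(counts) >= 1:
            hwe_fail[j] = hwe_exact_test(*counts) < thresholds.hwe_p_min
    mark(hwe_fail, "hwe")

    if pedigree is not None:
        trios = _trio_indices(calls, pedigree)
        if trios:
            errs = np.zeros(n_var, dtype=int)
            for _, ci, mi, fi in trios:
                errs += mendelian_error_flags(calls.calls[ci], calls.calls[mi], calls.calls[fi])
            mark(errs / len(trios) > thresholds.snp_mendel_trio_frac_max, "mendel")

    if calls.batch is not None:
        labels = pd.Series(calls.batch).reindex(calls.samples)
        groups = labels.dropna().unique()
        if len(groups) != 2:
            raise ConfigurationError("batch checks require exactly two batch labels")
        in_a = (labels == groups[0]).to_numpy()
        in_b = (labels == groups[1]).to_numpy()
        for j in range(n_var):
            if reason[j]:
                continue
            ca, cb = calls.calls[in_a, j], calls.calls[in_b, j]
            table = [
                [(ca == MISSING).sum(), (ca != MISSING).sum()],
                [(cb == MISSING).sum(), (cb != MISSING).sum()],
            ]
            if fisher_exact(table)[1] < thresholds.batch_diff_p_min:
                reason[j] = "batch_missingness"
                continue
            afs = []
            for c in (ca, cb):
                nm = (c != MISSING).sum()
                afs.append(np.where(c == MISSING, 0, c).sum() / (2 * nm) if nm else np.nan)
            if np.isfinite(afs).all() and abs(afs[0] - afs[1]) > thresholds.batch_af_diff_max:
                reason[j] = "batch_af"

    removed = pd.DataFrame(
        {"variant_id": v.loc[reason != "", "variant_id"], "reason": reason[reason != ""]}
    ).reset_index(drop=True)
    report = QCReport(
        removed_variants=removed,
        n_input_samples=len(calls.samples),
        n_input_variants=n_var,
    )
    if pedigree is not None:
        report.trio_mendel_counts = trio_mendel_counts(calls, pedigree)
    return report


def imputation_filter(
    variants: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
    require_maf: bool = False,
) -> list[str]:
    """Keep variant ids with imputation r2 >= ``impute_r2_min`` (inclusive).

    With ``require_maf``, additionally require MAF > ``snp_maf_min``.  A
    missing r2 is an error naming the variant.
    """
    if len(variants) == 0:
        return []
    if "r2" not in variants.columns:
        raise ConfigurationError("imputation filter requires an 'r2' column")
    bad = variants["r2"].isna()
    if bad.any():
        vid = variants.loc[bad, "variant_id"].iloc[0]
        raise ConfigurationError(f"variant {vid} has no imputation r2")
    keep = variants["r2"] >= thresholds.impute_r2_min
    if require_maf:
        keep &= variants["maf"] > thresholds.snp_maf_min
    return list(variants.loc[keep, "variant_id"])
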
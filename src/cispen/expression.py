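"""Genetically-predicted gene expression from per-gene cis-eQTL weight models.

A weight model is a sparse linear predictor per gene and tissue: predicted
expression is the weighted sum of alt-allele dosages over the model's cis-SNPs,

    E[i, g] = sum_v w(g, v) * dosage(i, v),

the standard weight-based imputation used by UTMOST/PrediXcan-style methods.
Applied to a phased haplotype (alleles in {0, 1}) the same form yields
per-haplotype expression, and by linearity the two haplotype values of an
individual sum to the individual's diploid prediction.

Genes are used only if their cross-validation (FDR-adjusted) p value passes a
threshold, reflecting that poorly predicted genes carry no usable signal.
Model variants missing from the dosage data are dropped (not mean-imputed);
the per-gene fraction of model variants actually found is reported as a
coverage fraction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AlleleMismatchError, ConfigurationError, UnphasedInputError

log = logging.getLogger(__name__)

#: canonical column order of a weight-table TSV
WEIGHT_COLUMNS = ["gene", "variant_id", "chrom", "pos", "ref", "alt", "weight", "cv_p", "tissue"]


@dataclass
class EQTLWeightSet:
    """Per-gene, per-tissue sparse linear expression models.

    Parameters
    ----------
    tissue:
        Tissue label the weights were trained in (opaque string).
    weights:
        One row per (gene, variant): columns ``gene, variant_id, chrom, pos,
        ref, alt, weight`` (extra columns such as a generative ``maf`` are
        preserved).
    cv_p:
        Per-gene cross-validation adjusted p value, indexed by gene id.
    """

    tissue: str
    weights: pd.DataFrame
    cv_p: pd.Series

    def __post_init__(self) -> None:
        required = {"gene", "variant_id", "chrom", "pos", "ref", "alt", "weight"}
        missing = required - set(self.weights.columns)
        if missing:
            raise ConfigurationError(f"weight table missing columns: {sorted(missing)}")
        if not np.isfinite(self.weights["weight"].to_numpy(dtype=float)).all():
            raise ConfigurationError("weights must be finite")
        if self.weights.duplicated(["gene", "variant_id"]).any():
            raise ConfigurationError("(gene, variant_id) pairs must be unique")
        cv = self.cv_p.to_numpy(dtype=float)
        if ((cv < 0) | (cv > 1)).any() or not np.isfinite(cv).all():
            raise ConfigurationError("cv_p values must lie in [0, 1]")
        self.cv_p = self.cv_p.rename("cv_p")
        self.cv_p.index.name = "gene"

    @property
    def genes(self) -> list[str]:
        return list(self.cv_p.index)

    @property
    def n_genes(self) -> int:
        return len(self.cv_p)

    @property
    def n_variants(self) -> int:
        return len(self.weights)

    def to_tsv(self, path: str | Path) -> None:
        """Write the canonical weight-table TSV (lossless round trip)."""
        out = self.weights.merge(self.cv_p.reset_index(), on="gene", how="left")
        out["tissue"] = self.tissue
        extra = [c for c in self.weights.columns if c not in WEIGHT_COLUMNS]
        out[WEIGHT_COLUMNS + extra].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EQTLWeightSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str, "variant_id": str})
        tissues = df["tissue"].unique()
        if len(tissues) != 1:
            raise ConfigurationError(f"expected a single tissue per table, got {list(tissues)}")
        cv_p = df.drop_duplicates("gene").set_index("gene")["cv_p"]
        weights = df.drop(columns=["cv_p", "tissue"])
        return cls(tissue=str(tissues[0]), weights=weights.reset_index(drop=True), cv_p=cv_p)


@dataclass
class DosageMatrix:
    """Alt-allele dosages (individuals) or alleles (phased haplotypes).

    ``dosages`` is samples x variants with values in [0, 2]; phased haplotype
    data use one row per haplotype with values in {0, 1} and ``phased=True``.
    ``variants`` carries ``variant_id, chrom, pos, ref, alt`` and optionally
    per-variant imputation ``r2`` and ``maf``.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    phased: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ConfigurationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ConfigurationError("sample ids must be unique")
        if self.variants["variant_id"].duplicated().any():
            raise ConfigurationError("variant ids must be unique")
        if self.dosages.size and (
            (self.dosages < 0).any() or (self.dosages > 2 + 1e-9).any()
        ):
            raise ConfigurationError("dosages must lie in [0, 2]")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])


@dataclass
class ExpressionMatrix:
    """Predicted expression, samples (or haplotypes) x genes, plus coverage.

    ``coverage`` is the per-gene share of model weight-variants that were
    found in the dosage data.
    """

    values: pd.DataFrame
    coverage: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ConfigurationError("expression values must be finite")
        cov = self.coverage.to_numpy(dtype=float)
        if cov.size and (((cov < 0) | (cov > 1)).any()):
            raise ConfigurationError("coverage fractions must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename_axis("sample").to_csv(path, sep="\t")

    def coverage_report(self, path: str | Path) -> None:
        self.coverage.rename("coverage").rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=values, coverage=pd.Series(1.0, index=values.columns))


def filter_models(weights: EQTLWeightSet, cv_p_max: float = 0.05) -> EQTLWeightSet:
    """Keep genes whose cross-validation p value is strictly below ``cv_p_max``."""
    if not (0 < cv_p_max <= 1):
        raise ConfigurationError("cv_p_max must lie in (0, 1]")
    cv_p = weights.cv_p[weights.cv_p < cv_p_max]
    kept = weights.weights[weights.weights["gene"].isin(cv_p.index)].reset_index(drop=True)
    if cv_p.empty:
        log.warning("cv_p filter at %g retained no genes", cv_p_max)
    log.info("cv_p < %g: retained %d of %d genes", cv_p_max, len(cv_p), weights.n_genes)
    return EQTLWeightSet(tissue=weights.tissue, weights=kept, cv_p=cv_p)


def _match_and_orient(
    dosages: DosageMatrix, weights: EQTLWeightSet, allow_flip: bool, ploidy: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Intersect weight variants with dosage variants, checking alleles.

    Returns the matched weight rows and the (samples x matched-variants)
    dosage sub-matrix oriented to the weight table's alt allele.  A ref/alt
    swap is a hard error unless ``allow_flip``, in which case dosage becomes
    ``ploidy - dosage``.
    """
    dv = dosages.variants[["variant_id", "ref", "alt"]]
    merged = weights.weights.merge(dv, on="variant_id", how="inner", suffixes=("", "_dos"))
    if merged.empty:
        return merged, np.empty((len(dosages.samples), 0))
    same = (merged["ref"] == merged["ref_dos"]) & (merged["alt"] == merged["alt_dos"])
    flipped = (merged["ref"] == merged["alt_dos"]) & (merged["alt"] == merged["ref_dos"])
    bad = ~(same | flipped)
    if bad.any():
        vid = merged.loc[bad, "variant_id"].iloc[0]
        raise AlleleMismatchError(f"alleles for {vid} do not match the weight table")
    if flipped.any() and not allow_flip:
        vid = merged.loc[flipped, "variant_id"].iloc[0]
        raise AlleleMismatchError(
            f"ref/alt swapped for {vid} relative to the weight table; pass allow_flip=True"
        )

    vids = merged["variant_id"].drop_duplicates()
    col_of = {v: i for i, v in enumerate(dosages.variants["variant_id"])}
    sub = dosages.dosages[:, [col_of[v] for v in vids]].copy()
    flip_ids = set(merged.loc[flipped, "variant_id"])
    if flip_ids:
        log.info("flipping %d variants to the weight table's alt allele", len(flip_ids))
        for j, v in enumerate(vids):
            if v in flip_ids:
                sub[:, j] = ploidy - sub[:, j]
    pos_of = {v: j for j, v in enumerate(vids)}
    merged = merged.assign(_col=[pos_of[v] for v in merged["variant_id"]])
    return merged, sub


def _predict(
    dosages: DosageMatrix,
    weights: EQTLWeightSet,
    allow_flip: bool,
    ploidy: int,
    min_coverage: float,
) -> ExpressionMatrix:
    matched, sub = _match_and_orient(dosages, weights, allow_flip, ploidy)
    model_sizes = weights.weights.groupby("gene").size()
    if matched.empty:
        raise ConfigurationError("no weight-model variant is present in the dosage data")
    genes = list(matched["gene"].drop_duplicates())
    gidx = {g: j for j, g in enumerate(genes)}
    W = np.zeros((sub.shape[1], len(genes)))
    W[matched["_col"].to_numpy(), [gidx[g] for g in matched["gene"]]] = matched[
        "weight"
    ].to_numpy(dtype=float)
    E = sub @ W

    coverage = (matched.groupby("gene").size() / model_sizes.loc[genes]).reindex(genes)
    dropped = model_sizes.index.difference(genes)
    if len(dropped):
        log.info("%d genes had no model variants in the dosage data: %s",
                 len(dropped), ", ".join(list(dropped)[:5]))
    if min_coverage > 0:
        keep = [g for g in genes if coverage[g] >= min_coverage]
        E = E[:, [gidx[g] for g in keep]]
        genes, coverage = keep, coverage.loc[keep]
    values = pd.DataFrame(E, index=pd.Index(dosages.samples, name="sample"), columns=genes)
    return ExpressionMatrix(values=values, coverage=coverage.rename("coverage"))


def predict_expression(
    dosages: DosageMatrix,
    weights: EQTLWeightSet,
    allow_flip: bool = False,
    min_coverage: float = 0.0,
) -> ExpressionMatrix:
    """Predict per-individual expression: E = sum of weight x dosage per gene."""
    return _predict(dosages, weights, allow_flip, ploidy=2, min_coverage=min_coverage)


def predict_haplotype_expression(
    haplotypes: DosageMatrix,
    weights: EQTLWeightSet,
    allow_flip: bool = False,
    min_coverage: float = 0.0,
) -> ExpressionMatrix:
    """Predict per-haplotype expression from phased alleles in {0, 1}."""
    if not haplotypes.phased:
        raise UnphasedInputError("haplotype prediction requires phased input")
    vals = haplotypes.dosages
    if vals.size and not np.isin(vals, (0.0, 1.0)).all():
        raise UnphasedInputError("phased haplotype values must be 0 or 1")
    return _predict(haplotypes, weights, allow_flip, ploidy=1, min_coverage=min_coverage)


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def load_vcf_dosages(path: str | Path, dosage_field: str = "GT") -> DosageMatrix:
    """Read a VCF into a per-individual DosageMatrix.

    ``dosage_field="GT"`` counts alt alleles from hard genotype calls;
    ``"DS"`` uses the imputed-dosage FORMAT field.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for v in vcf:
        if dosage_field == "DS":
            d = np.asarray(v.format("DS"), dtype=float).reshape(-1)
        else:
            g = np.asarray(v.genotypes, dtype=object)
            d = np.array([a[0] + a[1] for a in g], dtype=float)
        rows.append(d)
        meta.append(_vcf_meta(v))
    vcf.close()
    variants = pd.DataFrame(meta)
    dos = np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return DosageMatrix(samples=samples, variants=variants, dosages=dos)


def load_vcf_haplotypes(path: str | Path) -> DosageMatrix:
    """Read a fully phased VCF into a haplotype-level DosageMatrix.

    Sample ``S`` expands to haplotype rows ``S_h1`` and ``S_h2``.  Any
    unphased genotype is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    hap_ids = [f"{s}_h{k}" for s in samples for k in (1, 2)]
    rows, meta = [], []
    for v in vcf:
        alleles = np.empty(2 * len(samples))
        for i, (a1, a2, phased) in enumerate(v.genotypes):
            if not phased:
                raise UnphasedInputError(
                    f"unphased genotype for sample {samples[i]} at {v.CHROM}:{v.POS}"
                )
            alleles[2 * i] = a1
            alleles[2 * i + 1] = a2
        rows.append(alleles)
        meta.append(_vcf_meta(v))
    vcf.close()
    variants = pd.DataFrame(meta)
    dos = np.asarray(rows, dtype=float).T if rows else np.empty((len(hap_ids), 0))
    return DosageMatrix(samples=hap_ids, variants=variants, dosages=dos, phased=True)


def _vcf_meta(v) -> dict:
    return {
        "variant_id": v.ID or f"{v.CHROM}_{v.POS}_{v.REF}_{v.ALT[0]}",
        "chrom": str(v.CHROM),
        "pos": int(v.POS),
        "ref": v.REF,
        "alt": v.ALT[0] if v.ALT else ".",
    }
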
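"""Classification of rare inherited coding variants and proband triage.

Putatively damaging variants are rare (gnomAD MAF strictly below 1e-5,
cohort MAF at most 1e-4 by default), inherited, heterozygous coding variants
falling into three penetrance-relevant categories:

* ``dominant_LoF``  — PTV or missense in a confirmed/probable dominant
  developmental-disorder gene with a loss-of-function mechanism;
* ``recessive_LoF`` — the same for recessive LoF-mechanism genes;
* ``constrained``   — PTV, or missense with MPC >= 2, in a constrained gene
  (pLI > 0.9).

Each category carries a PTV-only sub-label alongside the PTV+missense one.
The module also applies the exome multi-indel filter (a sample with more
than one indel in a gene loses all of them — nearby indels usually signal a
single complex event that cannot be resolved without haplotype-aware
annotation), estimates clinician-rating positive predictive values per
clinical variant class, flags diagnosed vs undiagnosed probands, restricts a
cohort to neurodevelopmental phenotypes by exact HPO-term membership, and
samples one proband-parent-gene combination per proband per category
analysis, uniformly at random.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

log = logging.getLogger(__name__)

PTV = "PTV"
MISSENSE = "missense"

DOMINANT_LOF = "dominant_LoF"
RECESSIVE_LOF = "recessive_LoF"
CONSTRAINED = "constrained"

SUB_PTV = "PTV"
SUB_PTV_MISSENSE = "PTV_or_missense"

PATHOGENIC_RATINGS = frozenset({"definitely_pathogenic", "likely_pathogenic"})
RATED = frozenset(
    {"definitely_pathogenic", "likely_pathogenic", "uncertain", "likely_benign", "benign"}
)

#: neurodevelopmental-disorder HPO terms (exact membership, no ontology walk)
DEFAULT_NDD_TERMS = frozenset(
    {
        "HP:0012705",  # abnormal metabolic brain imaging by MRS
        "HP:0012657",  # abnormal brain positron emission tomography
        "HP:0012535",  # abnormal synaptic transmission
        "HP:0001311",  # abnormal nervous system electrophysiology
        "HP:0000708",  # behavioural abnormality
        "HP:0001250",  # seizures
        "HP:0001298",  # encephalopathy
        "HP:0011446",  # abnormality of higher mental function
        "HP:0012759",  # neurodevelopmental abnormality
        "HP:0012639",  # abnormality of the nervous system morphology
    }
)


@dataclass(frozen=True)
class VariantRecord:
    proband: str
    gene: str
    chrom: str = "1"
    pos: int = 1
    ref: str = "A"
    alt: str = "G"
    consequence: str = "other"       # PTV | missense | other
    is_indel: bool = False
    mpc: float | None = None
    gnomad_af: float = 0.0
    cohort_af: float = 0.0
    heterozygous: bool = True
    inheritance: str = "unknown"     # maternal | paternal | de_novo | unknown
    clinician_rating: str = "unrated"
    clinical_filter_class: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.gnomad_af <= 1 and 0 <= self.cohort_af <= 1):
            raise ConfigurationError("allele frequencies must lie in [0, 1]")
        if self.pos < 1:
            raise ConfigurationError("pos must be >= 1")


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    pli: float = 0.0
    ddg2p_inheritance: str = "none"  # dominant | recessive | other | none
    ddg2p_mechanism: str = "none"    # LoF | other | none
    ddg2p_confidence: str = "other"  # confirmed | probable | other

    def __post_init__(self) -> None:
        if not (0 <= self.pli <= 1):
            raise ConfigurationError("pLI must lie in [0, 1]")
        if (self.ddg2p_mechanism == "none") != (self.ddg2p_inheritance == "none"):
            raise ConfigurationError("DDG2P mechanism is 'none' iff inheritance is 'none'")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Rarity and deleteriousness gates for the damaging-variant categories.

    ``lenient()`` gives the MAF < 0.1% sensitivity preset applied to both
    frequency sources.  ``mpc_all_categories`` extends the MPC >= 2 missense
    gate from the constrained category to the DDG2P ones.
    """

    gnomad_af_max: float = 1e-5   # strict: af < max
    cohort_af_max: float = 1e-4   # inclusive: af <= max
    mpc_min: float = 2.0
    pli_min: float = 0.9
    mpc_all_categories: bool = False

    @classmethod
    def lenient(cls) -> "ClassificationThresholds":
        return cls(gnomad_af_max=1e-3, cohort_af_max=1e-3)


def classify_putatively_damaging(
    v: VariantRecord,
    g: GeneAnnotation,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> set[tuple[str, str]]:
    """Category set for one variant: subset of {category} x {sub-label}.

    Empty unless the variant is heterozygous, parentally inherited and passes
    both frequency gates.  A qualifying PTV yields both the PTV-only and the
    PTV+missense sub-label; a qualifying missense only the latter.
    """
    if v.gene != g.gene:
        raise ConfigurationError(f"variant gene {v.gene} does not match annotation {g.gene}")
    if not v.heterozygous or v.inheritance not in ("maternal", "paternal"):
        return set()
    if not (v.gnomad_af < thresholds.gnomad_af_max and v.cohort_af <= thresholds.cohort_af_max):
        return set()
    if v.consequence not in (PTV, MISSENSE):
        return set()

    mpc_ok = v.mpc is not None and not pd.isna(v.mpc) and v.mpc >= thresholds.mpc_min
    out: set[tuple[str, str]] = set()

    def add(category: str, require_mpc_for_missense: bool) -> None:
        if v.consequence == MISSENSE and require_mpc_for_missense and not mpc_ok:
            if v.mpc is None or pd.isna(v.mpc):
                log.warning(
                    "missense %s:%d in %s lacks an MPC score; excluded from %s",
                    v.chrom, v.pos, v.gene, category,
                )
            return
        out.add((category, SUB_PTV_MISSENSE))
        if v.consequence == PTV:
            out.add((category, SUB_PTV))

    ddg2p_ok = g.ddg2p_confidence in ("confirmed", "probable") and g.ddg2p_mechanism == "LoF"
    if ddg2p_ok and g.ddg2p_inheritance == "dominant":
        add(DOMINANT_LOF, thresholds.mpc_all_categories)
    if ddg2p_ok and g.ddg2p_inheritance == "recessive":
        add(RECESSIVE_LOF, thresholds.mpc_all_categories)
    if g.pli > thresholds.pli_min:
        add(CONSTRAINED, True)
    return out


def classify_table(
    variants: Iterable[VariantRecord],
    annotations: Mapping[str, GeneAnnotation],
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Long-format classified table: one row per (variant, category, sub-label)."""
    rows = []
    for v in variants:
        ann = annotations.get(v.gene, GeneAnnotation(gene=v.gene))
        for category, sub in sorted(classify_putatively_damaging(v, ann, thresholds)):
            rows.append(
                {
                    "proband": v.proband,
                    "gene": v.gene,
                    "inheritance": v.inheritance,
                    "consequence": v.consequence,
                    "category": category,
                    "variant_class": sub,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["proband", "gene", "inheritance", "consequence", "category", "variant_class"],
    )


def indel_dedup_filter(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Drop ALL indels of any (proband, gene) pair that has two or more."""
    counts: dict[tuple[str, str], int] = {}
    for r in records:
        if r.is_indel:
            counts[(r.proband, r.gene)] = counts.get((r.proband, r.gene), 0) + 1
    multi = {k for k, n in counts.items() if n >= 2}
    kept = [r for r in records if not (r.is_indel and (r.proband, r.gene) in multi)]
    n_removed = len(records) - len(kept)
    if n_removed:
        log.info("multi-indel filter removed %d of %d records", n_removed, len(records))
    return kept


def estimate_ppv(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Positive predictive value per clinical filter class from clinician ratings.

    PPV = rated pathogenic-or-likely / rated total; unrated variants count in
    neither.  Classes with no rated variant get PPV NaN and are flagged.
    """
    rows = []
    by_class: dict[str, list[VariantRecord]] = {}
    for r in records:
        by_class.setdefault(r.clinical_filter_class, []).append(r)
    for cls, recs in sorted(by_class.items()):
        rated = [r for r in recs if r.clinician_rating in RATED]
        n_path = sum(r.clinician_rating in PATHOGENIC_RATINGS for r in rated)
        ppv = n_path / len(rated) if rated else float("nan")
        if not rated:
            log.warning("class %r has no rated variants; PPV undefined", cls)
        rows.append(
            {
                "clinical_filter_class": cls,
                "n_pathogenic_or_likely": n_path,
                "n_rated": len(rated),
                "ppv": ppv,
            }
        )
    return pd.DataFrame(
        rows, columns=["clinical_filter_class", "n_pathogenic_or_likely", "n_rated", "ppv"]
    )


def compound_het_pairs(records: Sequence[VariantRecord]) -> list[tuple[int, int]]:
    """Index pairs of same-proband, same-gene variants in trans by inheritance.

    Phase is approximated by parental origin: one maternal plus one paternal
    variant in the same gene of the same proband forms a candidate pair.
    """
    out = []
    for i, a in enumerate(records):
        for j in range(i + 1, len(records)):
            b = records[j]
            if (
                a.proband == b.proband
                and a.gene == b.gene
                and {a.inheritance, b.inheritance} == {"maternal", "paternal"}
            ):
                out.append((i, j))
    return out


def flag_undiagnosed(
    records: Sequence[VariantRecord],
    ppv_table: pd.DataFrame,
    annotations: Mapping[str, GeneAnnotation] | None = None,
    reanalysis_diagnosed: set[str] = frozenset(),
    ppv_threshold: float = 0.5,
    pair_only_classes: set[str] = frozenset(),
) -> pd.DataFrame:
    """Diagnosed/undiagnosed status per proband.

    A proband is DIAGNOSED iff any of:
      (i)   it is in the reanalysis-diagnosed id set;
      (ii)  it has a variant rated pathogenic or likely pathogenic;
      (iii) it has an unrated variant in a clinical class with PPV above
            ``ppv_threshold`` (classes in ``pair_only_classes`` count only
            when two such variants form a trans compound-het pair);
      (iv)  it has a de novo PTV in a gene with pLI > 0.9.
    Everyone else is UNDIAGNOSED.  An unrated variant naming a class absent
    from ``ppv_table`` is an error.
    """
    annotations = annotations or {}
    ppv = ppv_table.set_index("clinical_filter_class")["ppv"]
    by_proband: dict[str, list[VariantRecord]] = {}
    for r in records:
        by_proband.setdefault(r.proband, []).append(r)
    probands = sorted(set(by_proband) | set(reanalysis_diagnosed))
    pair_idx = compound_het_pairs(list(records))
    paired = {(records[i].proband, records[i].gene) for i, _ in pair_idx} | {
        (records[j].proband, records[j].gene) for _, j in pair_idx
    }

    rows = []
    for p in probands:
        recs = by_proband.get(p, [])
        criterion = ""
        if p in reanalysis_diagnosed:
            criterion = "reanalysis"
        if not criterion and any(r.clinician_rating in PATHOGENIC_RATINGS for r in recs):
            criterion = "rated_pathogenic"
        if not criterion:
            for r in recs:
                if r.clinician_rating in RATED or not r.clinical_filter_class:
                    continue
                if r.clinical_filter_class not in ppv.index:
                    raise ConfigurationError(
                        f"variant in {r.gene} references unknown class "
                        f"{r.clinical_filter_class!r}"
                    )
                high = ppv[r.clinical_filter_class] > ppv_threshold
                needs_pair = r.clinical_filter_class in pair_only_classes
                if high and (not needs_pair or (p, r.gene) in paired):
                    criterion = "high_ppv_class"
                    break
        if not criterion:
            for r in recs:
                ann = annotations.get(r.gene)
                if (
                    r.inheritance == "de_novo"
                    and r.consequence == PTV
                    and ann is not None
                    and ann.pli > 0.9
                ):
                    criterion = "de_novo_ptv_constrained"
                    break
        rows.append({"proband": p, "diagnosed": bool(criterion), "criterion": criterion})
    return pd.DataFrame(rows, columns=["proband", "diagnosed", "criterion"])


def ndd_phenotype_filter(
    term_sets: Mapping[str, set[str]],
    ndd_terms: frozenset[str] | set[str] = DEFAULT_NDD_TERMS,
) -> list[str]:
    """Probands whose HPO term set intersects the NDD term list (exact ids)."""
    if not ndd_terms:
        raise ConfigurationError("the NDD term list must be non-empty")
    return sorted(p for p, terms in term_sets.items() if set(terms) & set(ndd_terms))


def select_unique_pairs(classified: pd.DataFrame, seed: int) -> pd.DataFrame:
    """One (proband, parent, gene) tuple per proband per category, uniformly.

    ``classified`` needs columns proband, parent, gene, category (an
    ``inheritance`` column, if present, must not contain 'unknown').
    Deterministic given ``seed``; candidate order is canonicalised before
    drawing so input row order does not matter.
    """
    required = {"proband", "parent", "gene", "category"}
    if missing := required - set(classified.columns):
        raise ConfigurationError(f"classified table missing columns: {sorted(missing)}")
    if "inheritance" in classified.columns and (classified["inheritance"] == "unknown").any():
        raise ConfigurationError("records with unknown inheritance cannot be pair-sampled")
    if classified["parent"].isna().any():
        raise ConfigurationError("every record needs a resolvable transmitting parent")
    rng = np.random.default_rng(seed)
    out = []
    ordered = classified.sort_values(["category", "proband", "parent", "gene"], kind="stable")
    for (category, proband), group in ordered.groupby(["category", "proband"], sort=True):
        cands = group[["parent", "gene"]].drop_duplicates().reset_index(drop=True)
        pick = cands.iloc[int(rng.integers(0, len(cands)))]
        out.append(
            {
                "proband": proband,
                "parent": pick["parent"],
                "gene": pick["gene"],
                "category": category,
            }
        )
    return pd.DataFrame(out, columns=["proband", "parent", "gene", "category"])
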
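"""Rare-variant classification, PPV estimation, diagnosis triage, phenotype
filtering and uniform proband-parent-gene sampling."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cispen import variants as va
from cispen.exceptions import ConfigurationError


DOM_LOF_GENE = va.GeneAnnotation(
    gene="EBF3", pli=0.99, ddg2p_inheritance="dominant",
    ddg2p_mechanism="LoF", ddg2p_confidence="confirmed",
)
PLAIN_GENE = va.GeneAnnotation(gene="G2", pli=0.95)


def record(**kw):
    base = dict(
        proband="p1", gene="EBF3", consequence=va.PTV, gnomad_af=0.0,
        cohort_af=0.0, inheritance="maternal",
    )
    base.update(kw)
    return va.VariantRecord(**base)


def test_inherited_ptv_in_dominant_lof_gene():
    """A stop-gained variant inherited in a confirmed dominant LoF gene lands
    in the dominant category with both sub-labels (cf. the EBF3 p.Arg303*
    class of incompletely penetrant diagnoses)."""
    v = record(chrom="10", pos=131665510, ref="G", alt="A")
    cats = va.classify_putatively_damaging(v, DOM_LOF_GENE)
    # pLI 0.99 also qualifies the constrained category for a PTV
    assert (va.DOMINANT_LOF, va.SUB_PTV) in cats
    assert (va.DOMINANT_LOF, va.SUB_PTV_MISSENSE) in cats
    assert (va.CONSTRAINED, va.SUB_PTV) in cats


def test_missense_with_high_mpc_in_constrained_gene():
    v = record(gene="G2", consequence=va.MISSENSE, mpc=2.5)
    cats = va.classify_putatively_damaging(v, PLAIN_GENE)
    assert cats == {(va.CONSTRAINED, va.SUB_PTV_MISSENSE)}  # never PTV-only


def test_common_variant_never_classified():
    v = record(gnomad_af=1e-3)
    assert va.classify_putatively_damaging(v, DOM_LOF_GENE) == set()


def test_frequency_gate_boundaries():
    # gnomAD gate strict, cohort gate inclusive
    assert va.classify_putatively_damaging(record(gnomad_af=1e-5), DOM_LOF_GENE) == set()
    assert va.classify_putatively_damaging(record(cohort_af=1e-4), DOM_LOF_GENE) != set()
    assert va.classify_putatively_damaging(record(cohort_af=1.01e-4), DOM_LOF_GENE) == set()


def test_non_inherited_or_hom_variants_excluded():
    assert va.classify_putatively_damaging(record(inheritance="de_novo"), DOM_LOF_GENE) == set()
    assert va.classify_putatively_damaging(record(heterozygous=False), DOM_LOF_GENE) == set()


def test_missing_mpc_excludes_constrained_missense_only():
    v = record(gene="G2", consequence=va.MISSENSE, mpc=None)
    assert va.classify_putatively_damaging(v, PLAIN_GENE) == set()
    v2 = record(consequence=va.MISSENSE, mpc=None)
    # DDG2P categories do not require MPC by default...
    assert va.classify_putatively_damaging(v2, DOM_LOF_GENE) == {
        (va.DOMINANT_LOF, va.SUB_PTV_MISSENSE)
    }
    # ...unless the switch extends the gate to all categories
    thr = va.ClassificationThresholds(mpc_all_categories=True)
    assert va.classify_putatively_damaging(v2, DOM_LOF_GENE, thr) == set()


@settings(deadline=None, max_examples=80, derandomize=True)
@given(
    gnomad=st.floats(0, 1e-4),
    cohort=st.floats(0, 1e-3),
    mpc=st.one_of(st.none(), st.floats(0, 5)),
    consequence=st.sampled_from([va.PTV, va.MISSENSE, "other"]),
    pli=st.floats(0, 1),
)
def test_tightening_maf_thresholds_never_adds_categories(gnomad, cohort, mpc, consequence, pli):
    g = va.GeneAnnotation(gene="X", pli=pli, ddg2p_inheritance="dominant",
                          ddg2p_mechanism="LoF", ddg2p_confidence="probable")
    v = record(gene="X", consequence=consequence, mpc=mpc,
               gnomad_af=gnomad, cohort_af=cohort)
    loose = va.ClassificationThresholds(gnomad_af_max=1e-4, cohort_af_max=1e-3)
    tight = va.ClassificationThresholds(gnomad_af_max=1e-5, cohort_af_max=1e-4)
    assert va.classify_putatively_damaging(v, g, tight) <= va.classify_putatively_damaging(
        v, g, loose
    )


def test_classification_is_pure_and_rederivable():
    v = record(consequence=va.MISSENSE, mpc=3.0)
    first = va.classify_putatively_damaging(v, DOM_LOF_GENE)
    assert va.classify_putatively_damaging(v, DOM_LOF_GENE) == first


def test_multi_indel_filter_drops_whole_gene_pairs():
    recs = [
        record(is_indel=True, pos=10),
        record(is_indel=True, pos=20),
        record(gene="G2", is_indel=True, pos=30),
        record(gene="G2", pos=40),  # SNV untouched
    ]
    kept = va.indel_dedup_filter(recs)
    assert [r.pos for r in kept] == [30, 40]
    assert va.indel_dedup_filter([]) == []
    snvs = [record(pos=1), record(pos=2)]
    assert va.indel_dedup_filter(snvs) == snvs


def test_ppv_counts_rated_variants_only():
    recs = [
        record(clinical_filter_class="c1", clinician_rating=r)
        for r in ("definitely_pathogenic", "likely_pathogenic", "benign", "uncertain",
                  "unrated")
    ]
    tab = va.estimate_ppv(recs)
    row = tab.set_index("clinical_filter_class").loc["c1"]
    assert row["n_rated"] == 4 and row["ppv"] == pytest.approx(0.5)


def test_ppv_undefined_without_rated_records():
    tab = va.estimate_ppv([record(clinical_filter_class="c2", clinician_rating="unrated")])
    assert np.isnan(tab.set_index("clinical_filter_class").loc["c2", "ppv"])
    tab3 = va.estimate_ppv(
        [record(clinical_filter_class="c3", clinician_rating="definitely_pathogenic")] * 3
    )
    assert tab3.set_index("clinical_filter_class").loc["c3", "ppv"] == 1.0


def _ppv_table():
    return pd.DataFrame(
        {
            "clinical_filter_class": ["high", "low"],
            "n_pathogenic_or_likely": [8, 1],
            "n_rated": [10, 10],
            "ppv": [0.8, 0.1],
        }
    )


def test_rated_pathogenic_variant_diagnoses_proband():
    recs = [record(clinician_rating="likely_pathogenic")]
    out = va.flag_undiagnosed(recs, _ppv_table())
    assert out.set_index("proband").loc["p1", "criterion"] == "rated_pathogenic"


def test_de_novo_ptv_in_constrained_gene_diagnoses_proband():
    recs = [record(inheritance="de_novo", consequence=va.PTV)]
    out = va.flag_undiagnosed(recs, _ppv_table(), annotations={"EBF3": DOM_LOF_GENE})
    assert out.set_index("proband").loc["p1", "criterion"] == "de_novo_ptv_constrained"


def test_high_ppv_unrated_class_diagnoses_proband():
    recs = [record(clinician_rating="unrated", clinical_filter_class="high")]
    out = va.flag_undiagnosed(recs, _ppv_table())
    assert out.set_index("proband").loc["p1", "criterion"] == "high_ppv_class"


def test_benign_rated_low_ppv_proband_stays_undiagnosed():
    recs = [record(clinician_rating="benign", clinical_filter_class="low")]
    out = va.flag_undiagnosed(recs, _ppv_table())
    assert not out.set_index("proband").loc["p1", "diagnosed"]


def test_unknown_clinical_class_is_an_error():
    recs = [record(clinician_rating="unrated", clinical_filter_class="mystery")]
    with pytest.raises(ConfigurationError, match="mystery"):
        va.flag_undiagnosed(recs, _ppv_table())


def test_empty_criteria_mark_everyone_undiagnosed():
    recs = [record(proband=p, clinician_rating="uncertain") for p in ("a", "b", "c")]
    out = va.flag_undiagnosed(recs, _ppv_table())
    assert (~out["diagnosed"]).all()


def test_reanalysis_set_diagnoses_without_variants():
    out = va.flag_undiagnosed([], _ppv_table(), reanalysis_diagnosed={"pX"})
    assert out.set_index("proband").loc["pX", "criterion"] == "reanalysis"


def test_compound_het_pairs_require_trans_inheritance():
    recs = [
        record(pos=1, inheritance="maternal"),
        record(pos=2, inheritance="paternal"),
        record(pos=3, inheritance="maternal"),
        record(proband="p2", pos=4, inheritance="paternal"),
    ]
    pairs = va.compound_het_pairs(recs)
    assert (0, 1) in pairs and (1, 2) in pairs
    assert all(recs[i].proband == recs[j].proband for i, j in pairs)
    assert (0, 2) not in pairs  # both maternal: cis by inheritance


def test_pair_only_class_needs_a_trans_pair():
    one = [record(pos=1, clinician_rating="unrated", clinical_filter_class="high")]
    out = va.flag_undiagnosed(one, _ppv_table(), pair_only_classes={"high"})
    assert not out["diagnosed"].iloc[0]
    two = one + [record(pos=2, inheritance="paternal", clinician_rating="unrated",
                        clinical_filter_class="high")]
    out2 = va.flag_undiagnosed(two, _ppv_table(), pair_only_classes={"high"})
    assert out2["diagnosed"].iloc[0]


def test_ndd_phenotype_membership_is_exact():
    kept = va.ndd_phenotype_filter(
        {"p1": {"HP:0001250"}, "p2": {"HP:9999999"}, "p3": set()}
    )
    assert kept == ["p1"]
    with pytest.raises(ConfigurationError):
        va.ndd_phenotype_filter({"p1": {"HP:0001250"}}, ndd_terms=set())


def test_single_candidate_pair_is_returned():
    df = pd.DataFrame(
        [{"proband": "p1", "parent": "m1", "gene": "g1", "category": va.CONSTRAINED}]
    )
    out = va.select_unique_pairs(df, seed=0)
    assert out.iloc[0].tolist() == ["p1", "m1", "g1", va.CONSTRAINED]


def test_pair_selection_uniform_over_candidates():
    df = pd.DataFrame(
        [
            {"proband": "p1", "parent": par, "gene": g, "category": va.CONSTRAINED}
            for par, g in (("m1", "g1"), ("m1", "g2"), ("f1", "g3"))
        ]
    )
    counts = {}
    for seed in range(12000):
        pick = va.select_unique_pairs(df, seed=seed).iloc[0]
        counts[(pick["parent"], pick["gene"])] = counts.get((pick["parent"], pick["gene"]), 0) + 1
    se = np.sqrt((1 / 3) * (2 / 3) / 12000)
    for k, n in counts.items():
        assert abs(n / 12000 - 1 / 3) <= 4 * se, (k, n)


def test_pair_selection_is_per_proband_and_deterministic():
    df = pd.DataFrame(
        [
            {"proband": "p1", "parent": "m1", "gene": "g1", "category": va.CONSTRAINED},
            {"proband": "p1", "parent": "f1", "gene": "g2", "category": va.CONSTRAINED},
            {"proband": "p2", "parent": "m2", "gene": "g1", "category": va.CONSTRAINED},
            {"proband": "p1", "parent": "m1", "gene": "g1", "category": va.DOMINANT_LOF},
        ]
    )
    out = va.select_unique_pairs(df, seed=42)
    per_cat = out.groupby("category")["proband"].nunique()
    assert out.groupby(["category", "proband"]).size().eq(1).all()
    assert per_cat[va.CONSTRAINED] == 2 and per_cat[va.DOMINANT_LOF] == 1
    pd.testing.assert_frame_equal(out, va.select_unique_pairs(df, seed=42))


def test_unknown_inheritance_blocks_pair_selection():
    df = pd.DataFrame(
        [{"proband": "p1", "parent": "m1", "gene": "g1", "category": va.CONSTRAINED,
          "inheritance": "unknown"}]
    )
    with pytest.raises(ConfigurationError):
        va.select_unique_pairs(df, seed=0)


def test_classify_table_long_format():
    recs = [record(), record(proband="p2", gene="G2", consequence=va.MISSENSE, mpc=2.5)]
    tab = va.classify_table(recs, {"EBF3": DOM_LOF_GENE, "G2": PLAIN_GENE})
    assert set(tab["proband"]) == {"p1", "p2"}
    assert set(tab["category"]) == {va.DOMINANT_LOF, va.CONSTRAINED}
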
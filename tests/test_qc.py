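"""Sample/SNP QC filters, Mendelian-error counting and the HWE exact test,
validated against exhaustive enumeration oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest

from cispen import qc
from cispen.exceptions import ConfigurationError

from oracles import hwe_enum, mendel_possible


def make_calls(calls, batch=None, **variant_cols):
    calls = np.asarray(calls, dtype=np.int8)
    n_var = calls.shape[1]
    base = {
        "variant_id": [f"v{i}" for i in range(n_var)],
        "chrom": ["1"] * n_var,
        "pos": list(range(100, 100 + n_var)),
        "ref": ["A"] * n_var,
        "alt": ["G"] * n_var,
    }
    base.update(variant_cols)
    samples = [f"s{i}" for i in range(calls.shape[0])]
    return qc.GenotypeCalls(
        samples=samples,
        variants=pd.DataFrame(base),
        calls=calls,
        batch=None if batch is None else pd.Series(batch, index=samples),
    )


# ---------------------------------------------------------------------- samples

def test_sample_missingness_threshold():
    g = np.ones((2, 100), dtype=np.int8)  # het rate 1.0: would fail het filter
    g[0, :6] = qc.MISSING  # 6% missing
    report = qc.sample_qc(make_calls(g))
    assert ("s0", "missingness") in list(map(tuple, report.removed_samples.values))


def test_het_rate_inside_bounds_is_kept():
    g = np.zeros((1, 1000), dtype=np.int8)
    g[0, :165] = 1  # het rate 0.165, 0% missing
    report = qc.sample_qc(make_calls(g))
    assert report.removed_samples.empty


@pytest.mark.parametrize("n_het, removed", [(100, True), (158, False), (170, False), (200, True)])
def test_het_rate_bounds_are_open(n_het, removed):
    g = np.zeros((1, 1000), dtype=np.int8)
    g[0, :n_het] = 1
    report = qc.sample_qc(make_calls(g))
    assert (len(report.removed_samples) == 1) == removed


def test_fully_missing_sample_fails_on_missingness_not_het_rate():
    g = np.full((1, 50), qc.MISSING, dtype=np.int8)
    report = qc.sample_qc(make_calls(g))
    assert list(report.removed_samples["reason"]) == ["missingness"]


# ------------------------------------------------------------------- mendelian

def test_mendelian_counter_on_forced_cases():
    assert qc.mendelian_error_count([2], [0], [0]) == 1
    assert qc.mendelian_error_count([1], [0], [2]) == 0
    assert qc.mendelian_error_count([1], [qc.MISSING], [2]) == 0  # missing skipped


def test_mendelian_counter_matches_exhaustive_oracle():
    """All 27 (child, mother, father) genotype combinations versus gamete
    enumeration."""
    for c, m, f in itertools.product((0, 1, 2), repeat=3):
        expected = 0 if mendel_possible(c, m, f) else 1
        assert qc.mendelian_error_count([c], [m], [f]) == expected, (c, m, f)


def test_mendelian_counter_rejects_misaligned_input():
    with pytest.raises(ConfigurationError):
        qc.mendelian_error_count([0, 1], [0], [0])


# ------------------------------------------------------------------------- hwe

def test_hwe_monomorphic_site_has_p_one():
    assert qc.hwe_exact_test(0, 0, 7) == 1.0
    assert qc.hwe_exact_test(7, 0, 0) == 1.0


@pytest.mark.parametrize(
    "counts", [(1, 0, 1), (50, 21, 29), (10, 55, 35), (3, 4, 3), (0, 2, 0), (100, 5, 0)]
)
def test_hwe_matches_enumeration_oracle(counts):
    assert qc.hwe_exact_test(*counts) == pytest.approx(hwe_enum(*counts), abs=1e-12)


def test_hwe_p_super_uniform_under_null(rng):
    """Genotypes simulated under HWE: the exact test rejects at no more than
    the nominal rate (discreteness makes it conservative)."""
    n, reps = 100, 2000
    ps = np.empty(reps)
    for k in range(reps):
        g = rng.binomial(2, 0.3, n)
        ps[k] = qc.hwe_exact_test((g == 0).sum(), (g == 1).sum(), (g == 2).sum())
    frac = (ps < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / reps)
    assert frac <= 0.05 + 3 * se


# ---------------------------------------------------------------------- snp qc

def test_snp_filters_reasons_in_order(rng):
    n = 200
    hets = rng.binomial(1, 0.45, (n, 7)).astype(np.int8)  # common, HWE-ish fodder
    g = hets + rng.binomial(1, 0.45, (n, 7)).astype(np.int8)
    g[:, 4] = 0
    g[:5, 4] = 1  # MAF 0.0125 > 0.01? 5/(2*200)=0.0125 kept; make it rarer
    g[:, 4] = 0
    g[:3, 4] = 1  # MAF 3/400 = 0.0075 < 1%
    g[:, 5] = 1   # all het: gross HWE violation
    calls = make_calls(
        g,
        ref=["A", "A", "A", "AT", "A", "A", "A"],
        alt=["T", "G", "C", "A", "G", "G", "G"],  # v1/v2 share pos, differ in alt
        pos=[100, 101, 101, 103, 104, 105, 106],
    )
    report = qc.snp_qc(calls)
    reasons = dict(report.removed_variants.values)
    assert reasons["v0"] == "palindromic"
    assert reasons["v1"] == "multiallelic" and reasons["v2"] == "multiallelic"
    assert reasons["v3"] == "indel"
    assert reasons["v4"] == "maf"
    assert reasons["v5"] == "hwe"
    assert "v6" not in reasons
    assert report.reconciles(kept_samples=len(calls.samples), kept_variants=1)


def test_duplicated_markers_removed():
    g = np.tile([0, 1, 2, 1], (4, 1)).T.astype(np.int8)
    calls = make_calls(g, pos=[100, 100, 102, 103])  # v0/v1 same pos, same alleles
    report = qc.snp_qc(calls, thresholds=qc.QCThresholds(snp_maf_min=0.0, hwe_p_min=0.0))
    reasons = dict(report.removed_variants.values)
    assert reasons["v0"] == "duplicated" and reasons["v1"] == "duplicated"


def test_snp_mendel_error_rate_filter(rng):
    n_trio = 100
    # children s0..s99, mothers s100.., fathers s200..; children are built by
    # proper gamete transmission so only injected errors exist
    mom_h = rng.binomial(1, 0.4, (n_trio, 2, 2))
    dad_h = rng.binomial(1, 0.4, (n_trio, 2, 2))
    child = mom_h[:, 0, :] + dad_h[:, 0, :]
    g = np.vstack([child, mom_h.sum(axis=1), dad_h.sum(axis=1)]).astype(np.int8)
    # inject Mendelian errors at v0 in 2% of trios: child hom-alt, parents hom-ref
    for t in range(2):
        g[t, 0], g[100 + t, 0], g[200 + t, 0] = 2, 0, 0
    calls = make_calls(g)
    ped = pd.DataFrame(
        {
            "fid": [f"f{t}" for t in range(n_trio)],
            "iid": [f"s{t}" for t in range(n_trio)],
            "father": [f"s{200 + t}" for t in range(n_trio)],
            "mother": [f"s{100 + t}" for t in range(n_trio)],
            "sex": 0,
            "phenotype": 0,
        }
    )
    report = qc.snp_qc(calls, pedigree=ped,
                       thresholds=qc.QCThresholds(snp_maf_min=0.0, hwe_p_min=0.0))
    reasons = dict(report.removed_variants.values)
    assert reasons.get("v0") == "mendel"
    assert "v1" not in reasons
    assert report.trio_mendel_counts is not None and report.trio_mendel_counts.sum() >= 2


def test_batch_differential_missingness(rng):
    n = 600
    g = (rng.binomial(1, 0.4, (n, 2)) + rng.binomial(1, 0.4, (n, 2))).astype(np.int8)
    g[: n // 2, 0] = qc.MISSING  # v0 entirely missing in batch A
    batch = ["A"] * (n // 2) + ["B"] * (n // 2)
    calls = make_calls(g, batch=batch)
    # disable the plain missingness filter to reach the batch test
    thr = qc.QCThresholds(snp_maf_min=0.0, hwe_p_min=0.0, snp_missing_max=1.0)
    report = qc.snp_qc(calls, thresholds=thr)
    reasons = dict(report.removed_variants.values)
    assert reasons.get("v0") == "batch_missingness"
    assert "v1" not in reasons


def test_batch_allele_frequency_difference():
    g = np.zeros((400, 1), dtype=np.int8)
    g[:200] = 2  # AF 1.0 in batch A, 0.0 in batch B
    g[200:210] = 1  # keep batch B polymorphic so MAF passes
    calls = make_calls(g, batch=["A"] * 200 + ["B"] * 200)
    thr = qc.QCThresholds(snp_maf_min=0.0, hwe_p_min=0.0, batch_diff_p_min=0.0)
    report = qc.snp_qc(calls, thresholds=thr)
    assert dict(report.removed_variants.values).get("v0") == "batch_af"


def test_snp_qc_is_idempotent(rng):
    g = (rng.binomial(1, 0.3, (150, 8)) + rng.binomial(1, 0.3, (150, 8))).astype(np.int8)
    calls = make_calls(g, ref=["A"] * 7 + ["A"], alt=["G"] * 7 + ["T"])
    first = qc.snp_qc(calls)
    kept = calls.drop_variants(set(first.removed_variants["variant_id"]))
    second = qc.snp_qc(kept)
    assert second.removed_variants.empty
    rep_s = qc.sample_qc(calls)
    kept_s = calls.drop_samples(set(rep_s.removed_samples["sample"]))
    if kept_s.samples:
        assert qc.sample_qc(kept_s).removed_samples.empty


def test_report_reconciliation_on_random_input(rng):
    g = rng.integers(-1, 3, (40, 12)).astype(np.int8)
    calls = make_calls(g)
    rep = qc.snp_qc(calls)
    kept = calls.drop_variants(set(rep.removed_variants["variant_id"]))
    assert rep.reconciles(len(calls.samples), len(kept.variants))
    assert rep.removed_variants["variant_id"].is_unique  # one primary reason each


# ------------------------------------------------------------------ imputation

def test_imputation_r2_bound_is_inclusive():
    variants = pd.DataFrame(
        {"variant_id": ["a", "b", "c"], "r2": [0.8, 0.79, 0.95], "maf": [0.2, 0.2, 0.005]}
    )
    assert qc.imputation_filter(variants) == ["a", "c"]
    assert qc.imputation_filter(variants, require_maf=True) == ["a"]


def test_imputation_filter_empty_and_missing_r2():
    assert qc.imputation_filter(pd.DataFrame(columns=["variant_id", "r2"])) == []
    bad = pd.DataFrame({"variant_id": ["x"], "r2": [np.nan]})
    with pytest.raises(ConfigurationError, match="x"):
        qc.imputation_filter(bad)
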
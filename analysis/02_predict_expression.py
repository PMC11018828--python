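#!/usr/bin/env python
"""Predict genetically-determined expression for the simulated cohorts.

Reads the emitted weight tables and the phased trio VCF, applies the
cross-validation p < 0.05 gene filter where requested, and writes:
per-haplotype expression for trio members (the penetrance tests need the
wild-type haplotype), per-individual expression for the case/control panel,
and per-gene model coverage reports.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cispen import expression as ex


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/expr"))
    ap.add_argument("--cvp", type=float, default=1.0,
                    help="cv-p filter; 1.0 keeps every simulated gene")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    weights = ex.EQTLWeightSet.from_tsv(args.sim / "weights_blood.tsv")
    kept = ex.filter_models(weights, cv_p_max=args.cvp)
    print(f"trio weight models: {kept.n_genes}/{weights.n_genes} genes pass "
          f"cv p < {args.cvp}")

    haps = ex.load_vcf_haplotypes(args.sim / "trios.vcf")
    hap_expr = ex.predict_haplotype_expression(haps, kept)
    hap_expr.to_tsv(args.out / "trio_haplotype_expression.tsv")
    hap_expr.coverage_report(args.out / "trio_coverage.tsv")
    print(f"haplotype expression: {hap_expr.values.shape[0]} haplotypes x "
          f"{len(hap_expr.genes)} genes "
          f"(mean coverage {hap_expr.coverage.mean():.2f})")

    cc_weights = ex.EQTLWeightSet.from_tsv(args.sim / "weights_cc.tsv")
    dos_df = pd.read_csv(args.sim / "cc_dosages.tsv", sep="\t", index_col=0)
    dosages = ex.DosageMatrix(
        samples=list(dos_df.index),
        variants=cc_weights.weights[["variant_id", "chrom", "pos", "ref", "alt"]],
        dosages=dos_df.to_numpy(),
    )
    cc_expr = ex.predict_expression(dosages, cc_weights)
    cc_expr.to_tsv(args.out / "cc_expression.tsv")
    print(f"case/control expression: {cc_expr.values.shape[0]} individuals x "
          f"{len(cc_expr.genes)} genes")


if __name__ == "__main__":
    main()
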
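#!/usr/bin/env python
"""Simulate the study's two synthetic datasets and write them to disk.

1. An ascertained trio cohort (affected child, unaffected transmitting
   parent) in which low wild-type-haplotype predicted expression raises
   penetrance of a rare damaging variant (effect beta = 1.5 on the logit).
2. An unrelated case/control panel with one gene whose predicted expression
   shifts disease risk (gamma = 1.0), for the TWAS scan.

Outputs under results/sim/: eQTL weight TSVs (blood tissue label), phased
trio VCF + PED + rare-variant annotations + ground truth, case/control
dosage, status and covariate TSVs.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cispen import synthdata as sd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    trio_cfg = sd.SimulationConfig(
        n_genes=30, snps_per_gene=10, n_trios_target=500,
        penetrance_effect=1.5, seed=args.seed,
    )
    weights = sd.simulate_eqtl_models(trio_cfg, tissue_label="blood")
    weights.to_tsv(args.out / "weights_blood.tsv")
    cohort, truth = sd.simulate_trio_cohort(trio_cfg, weights)
    sd.write_vcf(cohort.haplotypes, args.out / "trios.vcf")
    sd.write_ped(cohort.pedigree, args.out / "trios.ped")
    cohort.rare_variants.to_csv(args.out / "rare_variants.tsv", sep="\t", index=False)
    truth.trios.to_csv(args.out / "trio_ground_truth.tsv", sep="\t", index=False)
    print(f"trios: ascertained {cohort.n_trios} families "
          f"({len(cohort.haplotypes.samples)} haplotypes x "
          f"{len(cohort.haplotypes.variants)} variants)")

    cc_cfg = sd.SimulationConfig(
        n_genes=30, snps_per_gene=10, n_cases=2000, n_controls=2000,
        twas_effect=1.0, seed=args.seed + 1,
    )
    cc_weights = sd.simulate_eqtl_models(cc_cfg, tissue_label="blood")
    dosages, status, covariates, cc_truth = sd.simulate_case_control(cc_cfg, cc_weights)
    cc_weights.to_tsv(args.out / "weights_cc.tsv")
    pd.DataFrame(dosages.dosages, index=dosages.samples,
                 columns=dosages.variant_ids).rename_axis("sample").to_csv(
        args.out / "cc_dosages.tsv", sep="\t")
    pd.DataFrame({"sample": dosages.samples, "status": status}).to_csv(
        args.out / "cc_status.tsv", sep="\t", index=False)
    pd.DataFrame(covariates, index=dosages.samples).rename_axis("sample").to_csv(
        args.out / "cc_covariates.tsv", sep="\t")
    pd.Series(cc_truth.twas_effect_genes, name="gene").to_csv(
        args.out / "cc_effect_genes.tsv", sep="\t", index=False)
    print(f"case/control: {status.sum()} cases + {(status == 0).sum()} controls; "
          f"true effect gene(s): {', '.join(cc_truth.twas_effect_genes)}")


if __name__ == "__main__":
    main()
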
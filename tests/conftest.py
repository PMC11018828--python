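import numpy as np
import pandas as pd
import pytest

from cispen import synthdata as sd
from cispen.expression import DosageMatrix, EQTLWeightSet


@pytest.fixture
def small_config():
    return sd.SimulationConfig(
        n_genes=4, snps_per_gene=4, n_trios_target=50, n_cases=200, n_controls=200,
        penetrance_effect=1.0, seed=11,
    )


@pytest.fixture
def small_weights(small_config):
    return sd.simulate_eqtl_models(small_config, tissue_label="blood")


@pytest.fixture
def rng():
    return np.random.default_rng(20240415)


def toy_weight_set(weights_rows, cv_p=None, tissue="blood"):
    """Build an EQTLWeightSet from (gene, variant_id, weight[, maf]) tuples."""
    rows = []
    for k, item in enumerate(weights_rows):
        gene, vid, weight = item[:3]
        maf = item[3] if len(item) > 3 else 0.2
        rows.append(
            {
                "gene": gene, "variant_id": vid, "chrom": "1", "pos": 100 + k,
                "ref": "A", "alt": "G", "weight": weight, "maf": maf,
            }
        )
    df = pd.DataFrame(rows)
    genes = list(dict.fromkeys(df["gene"]))
    cv = pd.Series(
        cv_p if cv_p is not None else [0.01] * len(genes),
        index=pd.Index(genes, name="gene"),
    )
    return EQTLWeightSet(tissue=tissue, weights=df, cv_p=cv)


def toy_dosages(samples, variant_ids, dosages, phased=False, ref="A", alt="G"):
    variants = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": "1",
            "pos": np.arange(100, 100 + len(variant_ids)),
            "ref": ref,
            "alt": alt,
        }
    )
    return DosageMatrix(
        samples=list(samples), variants=variants, dosages=np.asarray(dosages, float),
        phased=phased,
    )
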
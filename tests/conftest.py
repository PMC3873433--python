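import numpy as np
import pandas as pd
import pytest

from gwaskit.containers import GenotypeMatrix
from gwaskit.syndata import SimConfig, simulate_study


def make_gm(calls, chrom=None, pos=None, ref="A", alt="G"):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    meta = pd.DataFrame({
        "snp_id": [f"snp{j+1}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["chr1"] * m,
        "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
        "ref": ref, "alt": alt,
    })
    return GenotypeMatrix(calls, meta, [f"s{i+1}" for i in range(n)])


@pytest.fixture(scope="session")
def small_study():
    """Small two-cohort study with real causal structure, reused across tests."""
    cfg = SimConfig(
        n_cases_per_cohort=150, n_controls_per_cohort=300, n_snps=400,
        n_causal_binary=8, or_causal=2.0, n_causal_quant=4, beta_quant=0.4,
        ld_r=0.0, n_gene_sets=20, genes_per_set=5, esnps_per_gene=3,
        enriched_set_fraction=0.1, gxe_snp_count=2, gxe_beta=0.8,
        missing_rate=0.01, seed=42,
    )
    return cfg, simulate_study(cfg)
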
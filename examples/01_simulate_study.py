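"""Simulate a two-cohort nested case-control study and look at its truth.

Builds a small synthetic study (two sex-stratified cohorts, 1:2
case:control, LD blocks, causal SNPs for the binary endpoint and the
biomarkers, gene sets with enriched eSNPs) and prints its shape.
"""

from gwaskit.syndata import SimConfig, simulate_study

cfg = SimConfig(n_cases_per_cohort=150, n_controls_per_cohort=300,
                n_snps=500, n_causal_binary=8, seed=1)
study = simulate_study(cfg)

for name, cohort in study.cohorts.items():
    gm = cohort.genotypes
    n_cases = int(cohort.phenotypes["status"].sum())
    print(f"{name}: {gm.n_samples} subjects ({n_cases} cases) x {gm.n_snps} SNPs")

print(f"gene sets: {len(study.gene_sets)}, eSNP records: {len(study.esnp_map)}")
print("truly enriched sets:", study.truth["enriched_sets"])
print("first causal SNPs for the endpoint:", study.truth["causal_binary"][:4])
# Each cohort has the exact configured case/control counts; the truth
# record names the SNPs and sets that downstream stages should recover.
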
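"""Generator: HWE proportions, LD control, determinism, effect recovery."""

import numpy as np
import pytest

from gwaskit import assoc, meta
from gwaskit.containers import MISSING
from gwaskit.syndata import (
    SimConfig,
    sample_case_control,
    simulate_binary_trait,
    simulate_quantitative_traits,
    simulate_study,
    tune_intercept,
    _simulate_genotypes_n,
)


def _corr_sweep(calls, block_size):
    """Brute-force mean within-block |r| over all pairs (the oracle)."""
    vals = []
    m = calls.shape[1]
    for b in range(m // block_size):
        cols = calls[:, b * block_size:(b + 1) * block_size].astype(float)
        cols[cols == MISSING] = np.nan
        for i in range(block_size):
            for j in range(i + 1, block_size):
                ok = ~np.isnan(cols[:, i]) & ~np.isnan(cols[:, j])
                r = np.corrcoef(cols[ok, i], cols[ok, j])[0, 1]
                vals.append(abs(r))
    return float(np.mean(vals))


def test_hwe_proportions_at_half():
    cfg = SimConfig(n_snps=10, maf_range=(0.5, 0.5), ld_r=0.0, missing_rate=0.0, seed=1)
    gm = _simulate_genotypes_n(cfg, np.random.default_rng(1), 20000)
    freqs = [(gm.calls == g).mean() for g in (0, 1, 2)]
    np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.01)


def test_independent_snps_when_ld_zero():
    cfg = SimConfig(n_snps=100, ld_block_size=10, ld_r=0.0, missing_rate=0.0, seed=2)
    gm = _simulate_genotypes_n(cfg, np.random.default_rng(2), 2000)
    # median |r| between neighbors ~ 0 (sampling noise ~ 1/sqrt(n))
    d = gm.calls.astype(float)
    rs = [abs(np.corrcoef(d[:, j], d[:, j + 1])[0, 1]) for j in range(99)]
    assert np.median(rs) < 0.05


def test_block_correlation_hits_target():
    cfg = SimConfig(n_snps=200, ld_block_size=10, ld_r=0.8, missing_rate=0.0, seed=7)
    gm = _simulate_genotypes_n(cfg, np.random.default_rng(7), 3000)
    mean_abs_r = _corr_sweep(gm.calls, 10)
    assert abs(mean_abs_r - 0.8) < 0.1


def test_positions_fixed_spacing_and_block_span():
    cfg = SimConfig(n_snps=50, ld_block_size=10, seed=0)
    gm = _simulate_genotypes_n(cfg, np.random.default_rng(0), 10)
    pos = gm.snp_meta["pos"].to_numpy()
    assert np.all(np.diff(pos[:50]) == 25_000)
    # a 10-SNP block spans 9 * 25 kb > 100 kb, so distance pruning bites
    assert pos[9] - pos[0] > 100_000


def test_determinism_same_seed():
    cfg = SimConfig(n_snps=50, n_cases_per_cohort=40, n_controls_per_cohort=80,
                    n_causal_binary=4, n_causal_quant=2, gxe_snp_count=1, seed=5)
    s1, s2 = simulate_study(cfg), simulate_study(cfg)
    for name in s1.cohorts:
        np.testing.assert_array_equal(s1.cohorts[name].genotypes.calls,
                                      s2.cohorts[name].genotypes.calls)
        assert s1.cohorts[name].phenotypes.equals(s2.cohorts[name].phenotypes)
    assert s1.gene_sets == s2.gene_sets
    assert s1.truth == s2.truth


def test_intercept_tuning_hits_case_fraction():
    rng = np.random.default_rng(3)
    eta = rng.standard_normal(50000)
    c = tune_intercept(eta, 1 / 3)
    realized = np.mean(1 / (1 + np.exp(-(c + eta))))
    assert abs(realized - 1 / 3) < 1e-8


def test_unattainable_case_fraction_errors():
    with pytest.raises(ValueError):
        tune_intercept(np.zeros(10), 1.0)


def test_exact_case_control_counts():
    rng = np.random.default_rng(0)
    labels = (rng.random(2000) < 0.4).astype(int)
    idx = sample_case_control(labels, 100, 200, rng)
    assert labels[idx].sum() == 100 and len(idx) == 300
    with pytest.raises(ValueError):
        sample_case_control(labels, 1900, 200, rng)


def test_logistic_refit_recovers_or():
    """Single causal SNP, OR=2, MAF=0.3, n=2000: refit within 3 SE."""
    cfg = SimConfig(n_snps=1, maf_range=(0.3, 0.3), n_causal_binary=1, or_causal=2.0,
                    n_cases_per_cohort=667, n_controls_per_cohort=1333,
                    ld_r=0.0, missing_rate=0.0, seed=9, ld_block_size=1)
    rng = np.random.default_rng(9)
    gm = _simulate_genotypes_n(cfg, rng, 2000)
    labels = simulate_binary_trait(gm, cfg, np.array([0]), rng)
    res = assoc.logistic_scan(gm, labels)
    assert abs(res["effect"].iloc[0] - np.log(2.0)) < 3 * res["se"].iloc[0]


def test_quant_refit_recovers_beta():
    cfg = SimConfig(n_snps=1, maf_range=(0.25, 0.25), beta_quant=0.3, ld_block_size=1,
                    ld_r=0.0, missing_rate=0.0, seed=4)
    rng = np.random.default_rng(4)
    gm = _simulate_genotypes_n(cfg, rng, 1400)
    traits = simulate_quantitative_traits(
        gm, cfg, {"ldl": np.array([0])}, {"ldl": np.array([1])}, rng)
    res = assoc.linear_scan(gm, traits["ldl"].to_numpy())
    # the trait is re-standardized, so the recovered slope shrinks by the trait SD
    sd_scale = np.sqrt(1 + 0.3**2 * 2 * 0.25 * 0.75)
    assert abs(res["effect"].iloc[0] - 0.3 / sd_scale) < 3 * res["se"].iloc[0]


def test_null_scan_pvalues_uniform_on_truth_snps():
    cfg = SimConfig(n_snps=100, n_causal_binary=10, or_causal=1.0, ld_r=0.0,
                    n_cases_per_cohort=150, n_controls_per_cohort=300, seed=12)
    study = simulate_study(cfg)
    c = study.cohorts["cohort_f"]
    res = assoc.logistic_scan(c.genotypes, c.phenotypes["status"].to_numpy())
    truth_p = res.set_index("snp_id").loc[study.truth["causal_binary"], "p"]
    from scipy import stats
    assert stats.kstest(truth_p.dropna(), "uniform").pvalue > 0.01


def test_meta_z_beats_single_cohort_on_causal(small_study):
    """Two cohorts of the same architecture: combined |Z| should beat the
    single-cohort |z| on most truly causal SNPs."""
    cfg, study = small_study
    zs = {}
    for name, c in study.cohorts.items():
        res = assoc.logistic_scan(c.genotypes, c.phenotypes["status"].to_numpy())
        zs[name] = res.set_index("snp_id")["z"]
    causal = study.truth["causal_binary"]
    wins = 0
    for s in causal:
        z1, z2 = zs["cohort_f"][s], zs["cohort_m"][s]
        zm = meta.sample_size_z_meta(z1, 450, z2, 450)["z_meta"]
        wins += abs(zm) > min(abs(z1), abs(z2))
    assert wins >= 0.8 * len(causal)


def test_gene_sets_reference_known_snps(small_study):
    cfg, study = small_study
    snp_ids = set(study.cohorts["cohort_f"].genotypes.snp_meta["snp_id"])
    assert set(study.esnp_map["snp_id"]) <= snp_ids
    assert len(study.truth["enriched_sets"]) == 2  # 10% of 20 sets
    assert set(study.gene_sets) >= set(study.truth["enriched_sets"])


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimConfig(maf_range=(0.0, 0.5)).validate()
    with pytest.raises(ValueError):
        SimConfig(n_causal_binary=10, n_snps=5).validate()
    with pytest.raises(ValueError):
        SimConfig(ld_r=1.0).validate()
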
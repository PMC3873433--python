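"""QC filters, PCA ancestry rule and genomic control."""

import numpy as np
import pytest
from scipy import stats

from gwaskit import qc
from gwaskit.containers import MISSING
from gwaskit.qc import QCThresholds, gc_adjust, genomic_control, hwe_test

from conftest import make_gm


# ---------------------------------------------------------------------------
# HWE

def test_hwe_exact_equilibrium():
    assert hwe_test((25, 50, 25)) == pytest.approx(1.0)


def test_hwe_hand_computed_chi_square():
    # expected (25, 50, 25) at p=0.5 -> chi2 = 1 + 2 + 1 = 4
    p = hwe_test((30, 40, 30))
    assert p == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-12)
    assert p == pytest.approx(0.0455, abs=2e-4)


def test_hwe_monomorphic_is_one():
    assert hwe_test((100, 0, 0)) == pytest.approx(1.0)


def test_hwe_all_zero_errors():
    with pytest.raises(ValueError):
        hwe_test((0, 0, 0))


# ---------------------------------------------------------------------------
# SNP filters

def test_missingness_rule():
    calls = np.ones((100, 1), dtype=np.int8)
    calls[:50, 0] = 0
    calls[:3, 0] = MISSING  # 3% missing
    rep = qc.snp_filters(make_gm(calls))
    assert "call_rate" in rep.snp_table["fail_reasons"].iloc[0]


def test_all_het_snp_fails_hwe_but_not_maf():
    calls = np.ones((100, 1), dtype=np.int8)  # all heterozygous: maf 0.5, chi2 = n
    rep = qc.snp_filters(make_gm(calls))
    row = rep.snp_table.iloc[0]
    assert row["maf"] == pytest.approx(0.5)
    assert "hwe" in row["fail_reasons"] and "maf" not in row["fail_reasons"]
    assert row["hwe_p"] == pytest.approx(stats.chi2.sf(100.0, 1))
    assert not row["kept"]


def test_monomorphic_excluded_despite_hwe_one():
    calls = np.zeros((50, 1), dtype=np.int8)
    rep = qc.snp_filters(make_gm(calls))
    row = rep.snp_table.iloc[0]
    assert "monomorphic" in row["fail_reasons"]
    assert row["hwe_p"] == pytest.approx(1.0)
    assert not row["kept"]


def test_kept_iff_no_fail_reasons():
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, size=(200, 30)).astype(np.int8)
    rep = qc.snp_filters(make_gm(calls))
    assert (rep.snp_table["kept"] == (rep.snp_table["fail_reasons"] == "")).all()


def test_filters_order_independent():
    """Each rule is a pure per-SNP predicate, so the kept set must not
    depend on evaluation order; check against rules applied one at a time."""
    rng = np.random.default_rng(1)
    calls = rng.integers(0, 3, size=(300, 50)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.03] = MISSING
    gm = make_gm(calls)
    rep = qc.snp_filters(gm)
    th = QCThresholds()
    keep = np.ones(gm.n_snps, dtype=bool)
    for rule in ("maf", "hwe", "call_rate", "monomorphic"):  # arbitrary order
        keep &= ~rep.snp_table["fail_reasons"].str.contains(rule).to_numpy()
    assert (keep == rep.snp_table["kept"].to_numpy()).all()


# ---------------------------------------------------------------------------
# sample filters

def test_low_call_rate_sample_excluded():
    rng = np.random.default_rng(11)
    calls = rng.integers(0, 3, size=(4, 100)).astype(np.int8)
    calls[0, :3] = MISSING  # 97% call rate
    rep = qc.sample_filters(make_gm(calls))
    assert not rep.sample_table["kept"].iloc[0]
    assert "call_rate" in rep.sample_table["fail_reasons"].iloc[0]


def test_duplicate_pair_flags_exactly_one():
    rng = np.random.default_rng(2)
    calls = rng.integers(0, 3, size=(5, 200)).astype(np.int8)
    calls[1] = calls[0]  # identical pair
    rep = qc.sample_filters(make_gm(calls))
    dup_flags = rep.sample_table["fail_reasons"].str.contains("duplicate")
    assert dup_flags.sum() == 1 and dup_flags.iloc[:2].sum() == 1


def test_clean_samples_all_kept():
    rng = np.random.default_rng(3)
    calls = rng.integers(0, 3, size=(6, 300)).astype(np.int8)
    rep = qc.sample_filters(make_gm(calls))
    assert rep.sample_table["kept"].all()


# ---------------------------------------------------------------------------
# PCA ancestry

def test_homogeneous_population_few_flagged():
    rng = np.random.default_rng(4)
    p = rng.uniform(0.1, 0.5, 300)
    calls = rng.binomial(2, p, size=(500, 300)).astype(np.int8)
    keep, scores = qc.pca_ancestry(make_gm(calls))
    # 3-SD rule on near-Gaussian scores flags ~0.3% per axis; allow up to 2%
    assert (~keep).mean() <= 0.02
    assert scores.shape == (500, 2)


def test_divergent_minority_population_flagged():
    rng = np.random.default_rng(5)
    n_major, n_minor, m = 475, 25, 400
    p_major = rng.uniform(0.1, 0.5, m)
    # strongly divergent allele frequencies for the minority cluster
    p_minor = np.clip(p_major + rng.choice([-0.35, 0.35], m), 0.02, 0.98)
    calls = np.vstack([
        rng.binomial(2, p_major, size=(n_major, m)),
        rng.binomial(2, p_minor, size=(n_minor, m)),
    ]).astype(np.int8)
    keep, _ = qc.pca_ancestry(make_gm(calls))
    assert (~keep[n_major:]).mean() > 0.8   # minority cluster flagged
    assert (~keep[:n_major]).mean() < 0.05


def test_infinite_threshold_keeps_everyone():
    rng = np.random.default_rng(6)
    calls = rng.integers(0, 3, size=(50, 60)).astype(np.int8)
    keep, _ = qc.pca_ancestry(make_gm(calls), sd_threshold=np.inf)
    assert keep.all()


def test_too_few_samples_errors():
    with pytest.raises(ValueError):
        qc.pca_ancestry(make_gm(np.ones((1, 10), dtype=np.int8)), n_components=2)


def test_thin_by_distance():
    import pandas as pd
    meta = pd.DataFrame({
        "snp_id": list("abcd"), "chrom": ["chr1"] * 3 + ["chr2"],
        "pos": [100_000, 150_000, 250_000, 1000], "ref": "A", "alt": "G",
    })
    keep = qc.thin_by_distance(meta, 100_000)
    assert list(keep) == [True, False, True, True]


# ---------------------------------------------------------------------------
# genomic control

def test_lambda_null_calibration():
    rng = np.random.default_rng(7)
    lam = genomic_control(rng.standard_normal(100_000))
    assert lam == pytest.approx(1.0, abs=0.02)


def test_lambda_median_arithmetic():
    z = np.sqrt(0.9098728) * np.ones(200)
    lam = genomic_control(z)
    assert lam == pytest.approx(2.0, abs=1e-4)
    np.testing.assert_allclose(gc_adjust(z, lam), z / np.sqrt(lam))


def test_gc_never_inflates():
    z = np.array([1.0, -2.0, 0.5])
    np.testing.assert_array_equal(gc_adjust(z, 0.9), z)


def test_gc_monotone_and_sign_preserving():
    rng = np.random.default_rng(8)
    z = np.sort(rng.standard_normal(1000))
    adj = gc_adjust(z, 1.7)
    assert np.all(np.diff(adj) >= 0)
    assert np.all(np.sign(adj) == np.sign(z))


def test_gc_empty_errors_and_warns_when_few():
    with pytest.raises(ValueError):
        genomic_control(np.array([]))
    with pytest.warns(UserWarning):
        genomic_control(np.ones(10))
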
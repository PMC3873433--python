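"""Genotype and sample quality control, PCA ancestry screening and
genomic control.

Default thresholds are the conventional array-QC set: drop SNPs that are
monomorphic, have missing call rate >= 2%, HWE p < 1e-4 or MAF < 2%;
drop samples with call rate < 98% or flagged as accidental duplicates;
flag samples beyond 3 SD on the first two genetic principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix, genotype_counts

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class QCThresholds:
    max_snp_missing: float = 0.02    # exclusive lower bound on call rate deficit: miss >= 2% fails
    min_maf: float = 0.02
    min_hwe_p: float = 1e-4
    min_sample_call_rate: float = 0.98
    duplicate_concordance: float = 0.95


@dataclass
class QCReport:
    snp_table: pd.DataFrame | None = None       # snp_id, call_rate, maf, hwe_p, kept, fail_reasons
    sample_table: pd.DataFrame | None = None    # sample_id, call_rate, kept, fail_reasons
    lambda_gc: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Hardy-Weinberg

def hwe_test(counts: tuple[int, int, int]) -> float:
    """1-df chi-square goodness-of-fit p-value for HWE.

    ``counts`` are genotype counts (n_AA, n_Aa, n_aa). The expected
    proportions are computed at the observed allele frequency; no
    continuity correction. A monomorphic site fits HWE exactly (p = 1);
    the monomorphic exclusion is a separate rule.
    """
    n_aa_, n_ab, n_bb = counts
    n = n_aa_ + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_aa_ + n_ab) / (2 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa_, n_ab, n_bb], dtype=float)
    nz = exp > 0
    chi2 = float(((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum())
    return float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# SNP / sample filters

def snp_filters(gm: GenotypeMatrix, thresholds: QCThresholds | None = None) -> QCReport:
    """Annotate every SNP with every failing rule (not short-circuited)."""
    th = thresholds or QCThresholds()
    if gm.n_snps == 0:
        raise ValueError("empty genotype matrix")
    call_rate = gm.snp_call_rate()
    maf = gm.maf()
    d = gm.dosages()
    rows = []
    for j in range(gm.n_snps):
        counts = genotype_counts(d[:, j])
        n_nonmiss = sum(counts)
        mono = n_nonmiss == 0 or counts[1] == 0 and (counts[0] == 0 or counts[2] == 0)
        hwe_p = hwe_test(counts) if n_nonmiss > 0 else np.nan
        reasons = []
        if 1.0 - call_rate[j] >= th.max_snp_missing:
            reasons.append("call_rate")
        if mono:
            reasons.append("monomorphic")
        if not mono and not np.isnan(hwe_p) and hwe_p < th.min_hwe_p:
            reasons.append("hwe")
        if not mono and maf[j] < th.min_maf:
            reasons.append("maf")
        rows.append((gm.snp_meta["snp_id"].iloc[j], call_rate[j],
                     maf[j] if n_nonmiss else np.nan, hwe_p, not reasons,
                     ",".join(reasons)))
    table = pd.DataFrame(rows, columns=["snp_id", "call_rate", "maf", "hwe_p", "kept", "fail_reasons"])
    return QCReport(snp_table=table)


def sample_filters(gm: GenotypeMatrix, thresholds: QCThresholds | None = None) -> QCReport:
    """Flag low-call-rate samples and accidental duplicates.

    Duplicates are found by pairwise genotype concordance over the
    non-missing overlap (a proxy for identity-by-descent); of a
    concordant pair the member with the lower call rate is flagged.
    """
    th = thresholds or QCThresholds()
    if gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    call_rate = gm.sample_call_rate()
    reasons: list[list[str]] = [[] for _ in range(gm.n_samples)]
    for i in np.flatnonzero(call_rate < th.min_sample_call_rate):
        reasons[i].append("call_rate")

    # pairwise concordance via per-genotype indicator matrix products
    calls = gm.calls
    obs = (calls != MISSING).astype(np.float32)
    matches = np.zeros((gm.n_samples, gm.n_samples), dtype=np.float32)
    for g in (0, 1, 2):
        ind = (calls == g).astype(np.float32)
        matches += ind @ ind.T
    n_both = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(n_both > 0, matches / n_both, 0.0)
    ii, jj = np.where(np.triu(conc > th.duplicate_concordance, k=1))
    for i, j in zip(ii, jj):
        drop = i if call_rate[i] <= call_rate[j] else j
        if "duplicate" not in reasons[drop]:
            reasons[drop].append("duplicate")
    table = pd.DataFrame({
        "sample_id": gm.sample_ids,
        "call_rate": call_rate,
        "kept": [not r for r in reasons],
        "fail_reasons": [",".join(r) for r in reasons],
    })
    return QCReport(sample_table=table)


def apply_qc(gm: GenotypeMatrix, thresholds: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Sample filters then SNP filters; returns the filtered matrix and a
    combined report. (The kept set is order-independent: each rule is a
    pure per-row predicate.)"""
    srep = sample_filters(gm, thresholds)
    gm2 = gm.subset_samples(srep.sample_table["kept"].to_numpy())
    vrep = snp_filters(gm2, thresholds)
    gm3 = gm2.subset_snps(vrep.snp_table["kept"].to_numpy())
    return gm3, QCReport(snp_table=vrep.snp_table, sample_table=srep.sample_table)


# ---------------------------------------------------------------------------
# PCA ancestry

def thin_by_distance(snp_meta: pd.DataFrame, min_bp: int = 100_000) -> np.ndarray:
    """Boolean keep-mask thinning SNPs so consecutive kept SNPs on a
    chromosome are >= min_bp apart (a cheap low-LD subset for PCA)."""
    keep = np.zeros(len(snp_meta), dtype=bool)
    last: dict[str, int] = {}
    order = snp_meta.sort_values(["chrom", "pos"]).index
    for i in order:
        c, p = snp_meta.loc[i, "chrom"], int(snp_meta.loc[i, "pos"])
        if c not in last or p - last[c] >= min_bp:
            keep[i] = True
            last[c] = p
    return keep


def pca_ancestry(
    gm: GenotypeMatrix,
    n_components: int = 2,
    sd_threshold: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Genetic PCA with the outlier rule used for ancestry screening.

    Genotypes are mean-imputed per SNP and standardized by sqrt(2p(1-p));
    samples farther than ``sd_threshold`` SDs from the mean on component
    1 or 2 are flagged for exclusion. Returns (keep_flags, scores).
    The caller is expected to pass a low-LD SNP subset (see
    :func:`thin_by_distance`).
    """
    if gm.n_samples < n_components:
        raise ValueError("fewer samples than components")
    d = gm.dosages()
    p = np.nanmean(d, axis=0) / 2.0
    inds = np.where(np.isnan(d))
    d[inds] = 2.0 * np.take(p, inds[1])
    denom = np.sqrt(2.0 * p * (1.0 - p))
    ok = denom > 0
    x = (d[:, ok] - 2.0 * p[ok]) / denom[ok]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    keep = np.ones(gm.n_samples, dtype=bool)
    for c in range(min(2, n_components)):
        col = scores[:, c]
        sd = col.std()
        if sd > 0 and np.isfinite(sd_threshold):
            keep &= np.abs(col - col.mean()) <= sd_threshold * sd
    return keep, scores


# ---------------------------------------------------------------------------
# genomic control

def genomic_control(z_scores: np.ndarray) -> float:
    """Inflation factor lambda = median(z^2) / median(chi^2_1)."""
    z = np.asarray(z_scores, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("no z-scores provided")
    if z.size < 100:
        warnings.warn("genomic control estimated from fewer than 100 z-scores", stacklevel=2)
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def gc_adjust(z_scores: np.ndarray, lambda_gc: float) -> np.ndarray:
    """Divide z by sqrt(lambda), flooring lambda at 1 so deflation
    (lambda < 1) never inflates the statistics."""
    if lambda_gc < 0:
        raise ValueError("lambda must be nonnegative")
    return np.asarray(z_scores, dtype=float) / np.sqrt(max(lambda_gc, 1.0))
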
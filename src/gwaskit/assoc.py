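"""Per-SNP association scans under the additive genetic model.

Binary endpoints are fit by unconditional logistic regression of status
on allele dosage plus covariates; quantitative biomarkers by OLS. Each
SNP is analyzed complete-case (samples missing that SNP's call are
dropped for that SNP only) and reported with a Wald z and a two-sided
normal p-value, the bookkeeping downstream meta-analysis expects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import check_full_rank, fit_logistic, fit_ols
from .containers import ASSOC_COLUMNS, GenotypeMatrix

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 5e-6


def _covariate_matrix(covariates: pd.DataFrame | None, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((n, 0)), []
    check_full_rank({c: covariates[c].to_numpy() for c in covariates.columns})
    return covariates.to_numpy(dtype=float), list(covariates.columns)


def _scan(
    gm: GenotypeMatrix,
    y: np.ndarray,
    covariates: pd.DataFrame | None,
    trait: str,
    cohort: str,
    binary: bool,
) -> pd.DataFrame:
    y = np.asarray(y, dtype=float)
    if len(y) != gm.n_samples:
        raise ValueError("response length must match sample count")
    if binary:
        classes = np.unique(y[~np.isnan(y)])
        if not np.all(np.isin(classes, (0.0, 1.0))) or len(classes) < 2:
            raise ValueError("binary status must contain both classes (0 and 1)")
    else:
        if np.nanstd(y) == 0:
            raise ValueError("quantitative trait is constant")

    cov, _ = _covariate_matrix(covariates, gm.n_samples)
    d = gm.dosages()
    maf = gm.maf()
    y_ok = ~np.isnan(y)
    if cov.shape[1]:
        y_ok &= ~np.isnan(cov).any(axis=1)

    rows = []
    meta = gm.snp_meta
    for j in range(gm.n_snps):
        dose = d[:, j]
        mask = y_ok & ~np.isnan(dose)
        n_used = int(mask.sum())
        flag = ""
        effect = se = z = p = np.nan
        if n_used > cov.shape[1] + 2 and np.nanstd(dose[mask]) > 0:
            X = np.column_stack([np.ones(n_used), dose[mask]] + ([cov[mask]] if cov.shape[1] else []))
            if binary and (y[mask].min() == y[mask].max()):
                flag = "one_class"
            else:
                fit = fit_logistic(X, y[mask]) if binary else fit_ols(X, y[mask])
                if binary and fit.separation:
                    flag = "separation"
                elif not fit.converged:
                    flag = "nonconverged"
                else:
                    effect = float(fit.params[1])
                    se = float(fit.bse[1])
                    z = effect / se if se > 0 else np.nan
                    p = 2.0 * float(stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        else:
            flag = "degenerate"
        rows.append((
            meta["snp_id"].iloc[j], meta["chrom"].iloc[j], int(meta["pos"].iloc[j]),
            meta["alt"].iloc[j], float(maf[j]), trait, cohort,
            effect, se, z, p, n_used, flag,
        ))
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def logistic_scan(
    gm: GenotypeMatrix,
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
    trait: str = "mi",
    cohort: str = "",
) -> pd.DataFrame:
    """Additive-model logistic regression of case status on each SNP.

    Returns one row per SNP with the per-allele log-odds (``effect``),
    its SE, signed Wald z, two-sided p and the complete-case n. SNPs
    with separation or non-convergence get a flag and missing p rather
    than raising.
    """
    return _scan(gm, status, covariates, trait, cohort, binary=True)


def linear_scan(
    gm: GenotypeMatrix,
    trait_values: np.ndarray,
    covariates: pd.DataFrame | None = None,
    trait: str = "trait",
    cohort: str = "",
) -> pd.DataFrame:
    """Additive-model OLS of a quantitative biomarker on each SNP;
    z = effect/se against a normal reference (cohort n is large)."""
    return _scan(gm, trait_values, covariates, trait, cohort, binary=False)


def classify_hits(
    results: pd.DataFrame,
    genome_wide: float = GENOME_WIDE_P,
    suggestive: float = SUGGESTIVE_P,
) -> pd.DataFrame:
    """Tier results as genome-wide / suggestive / none and sort by p."""
    out = results.copy()
    p = out["p"].to_numpy(dtype=float)
    tier = np.where(p < genome_wide, "genome-wide", np.where(p < suggestive, "suggestive", "none"))
    tier = np.where(np.isnan(p), "none", tier)
    out["tier"] = tier
    return out.sort_values("p", kind="mergesort", na_position="last").reset_index(drop=True)
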
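"""Two-cohort fixed-effects meta-analysis.

Two combiners are provided:

* inverse-variance: pool per-allele effects on the log-odds (or trait)
  scale, weighting each cohort by 1/se^2;
* sample-size-weighted signed z: combine the cohorts' signed z-scores
  with weights w_i = sqrt(n_i / (n_1 + n_2)), so the squared weights sum
  to one and each weight is proportional to the square root of the
  cohort's effective number of individuals.

Both assume the two results count the same allele; a harmonization
helper flips ref/alt-swapped records by negating effect and z.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def effective_n(n_cases: int, n_controls: int, convention: str = "total") -> float:
    """Per-cohort effective sample size.

    ``total`` (default) is the number of analyzed subjects; ``binary``
    uses n_eff = 4 / (1/n_cases + 1/n_controls), the equal-information
    convention for unbalanced case-control designs.
    """
    if convention == "total":
        return float(n_cases + n_controls)
    if convention == "binary":
        return 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    raise ValueError(f"unknown effective-n convention: {convention}")


def sample_size_z_meta(z1: float, n1: float, z2: float, n2: float) -> dict:
    """Sample-size-weighted signed-z combination of two cohorts.

    w_i = sqrt(n_i/(n_1+n_2)) (squared weights sum to 1);
    Z = w_1 z_1 + w_2 z_2; p = 2(1 - Phi(|Z|)).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("cohort sizes must be positive")
    w1 = np.sqrt(n1 / (n1 + n2))
    w2 = np.sqrt(n2 / (n1 + n2))
    z = w1 * z1 + w2 * z2
    return {
        "z_meta": float(z),
        "p_meta": 2.0 * float(stats.norm.sf(abs(z))),
        "w1": float(w1),
        "w2": float(w2),
        "n1": float(n1),
        "n2": float(n2),
    }


def inverse_variance_meta(effect1: float, se1: float, effect2: float, se2: float) -> dict:
    """Fixed-effects inverse-variance pooling of two harmonized effects."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    w1, w2 = 1.0 / se1**2, 1.0 / se2**2
    effect = (effect1 * w1 + effect2 * w2) / (w1 + w2)
    se = (w1 + w2) ** -0.5
    z = effect / se
    return {
        "effect_meta": float(effect),
        "se_meta": float(se),
        "z_meta": float(z),
        "p_meta": 2.0 * float(stats.norm.sf(abs(z))),
    }


def harmonize(r1: pd.Series, r2: pd.Series) -> pd.Series:
    """Align cohort-2's record to cohort-1's counted allele.

    If ref/alt are swapped the dosage is complemented, so effect and z
    negate. Strand flips are not attempted. Raises on mismatched SNP ids
    or non-matching allele pairs.
    """
    if r1["snp_id"] != r2["snp_id"]:
        raise ValueError(f"SNP id mismatch: {r1['snp_id']} vs {r2['snp_id']}")
    a1 = (r1.get("ref"), r1.get("allele"))
    a2 = (r2.get("ref"), r2.get("allele"))
    if a1 == a2 or a1[0] is None or a2[0] is None:
        return r2
    if a1 == (a2[1], a2[0]):
        out = r2.copy()
        out["ref"], out["allele"] = r2["allele"], r2["ref"]
        for col in ("effect", "z"):
            if col in out:
                out[col] = -out[col]
        return out
    raise ValueError(f"alleles for {r1['snp_id']} cannot be harmonized: {a1} vs {a2}")


def meta_analyze(
    results1: pd.DataFrame,
    results2: pd.DataFrame,
    n1: float | None = None,
    n2: float | None = None,
) -> pd.DataFrame:
    """Combine two per-SNP association tables by both methods.

    Tables are joined on (snp_id, trait); each merged row gets the
    sample-size-weighted Z (``z_meta``, ``p_meta``) and, where both SEs
    are available, the inverse-variance pooled effect. Cohort sizes
    default to each row's ``n_used``.
    """
    m = results1.merge(results2, on=["snp_id", "trait"], suffixes=("_1", "_2"))
    if m.empty:
        raise ValueError("no overlapping (snp_id, trait) rows to meta-analyze")
    nn1 = np.full(len(m), float(n1)) if n1 is not None else m["n_used_1"].to_numpy(float)
    nn2 = np.full(len(m), float(n2)) if n2 is not None else m["n_used_2"].to_numpy(float)
    if np.any(nn1 <= 0) or np.any(nn2 <= 0):
        raise ValueError("cohort sizes must be positive")
    z1 = m["z_1"].to_numpy(float)
    z2 = m["z_2"].to_numpy(float)
    w1 = np.sqrt(nn1 / (nn1 + nn2))
    w2 = np.sqrt(nn2 / (nn1 + nn2))
    z_meta = w1 * z1 + w2 * z2
    out = pd.DataFrame({
        "snp_id": m["snp_id"], "trait": m["trait"],
        "chrom": m.get("chrom_1"), "pos": m.get("pos_1"),
        "z1": z1, "z2": z2, "n1": nn1, "n2": nn2, "w1": w1, "w2": w2,
        "z_meta": z_meta, "p_meta": 2.0 * stats.norm.sf(np.abs(z_meta)),
    })
    se1 = m["se_1"].to_numpy(float) if "se_1" in m else np.full(len(m), np.nan)
    se2 = m["se_2"].to_numpy(float) if "se_2" in m else np.full(len(m), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        iw1, iw2 = 1.0 / se1**2, 1.0 / se2**2
        effect = (m.get("effect_1", np.nan) * iw1 + m.get("effect_2", np.nan) * iw2) / (iw1 + iw2)
        se = (iw1 + iw2) ** -0.5
        z_iv = effect / se
    ok = np.isfinite(se1) & np.isfinite(se2) & (se1 > 0) & (se2 > 0)
    out["effect_meta"] = np.where(ok, effect, np.nan)
    out["se_meta"] = np.where(ok, se, np.nan)
    out["z_meta_iv"] = np.where(ok, z_iv, np.nan)
    out["p_meta_iv"] = np.where(ok, 2.0 * stats.norm.sf(np.abs(z_iv)), np.nan)
    return out.sort_values("p_meta", kind="mergesort", na_position="last").reset_index(drop=True)
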
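"""Gene-environment interaction screen for a binary endpoint.

For each SNP, nested logistic models are compared with likelihood-ratio
tests under four model sets: the environment enters either linearly or
through a natural cubic spline with 3 degrees of freedom, and the test
is either interaction-only (full: main effects + SNPxE products vs
null: main effects) or joint (full vs a null without the SNP at all,
the Kraft-style combined main+interaction screen). Degrees of freedom
are 1/2 for the linear coding and 3/4 for the spline coding. Reported
alongside is each SNP's marginal main-effect p, so screens can surface
interaction loci that carry no main effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import fit_logistic
from .containers import GenotypeMatrix

BONFERRONI_GENOME_WIDE = 1e-9

#: default mapping of printed model ids 1-4 to (environment coding, test)
DEFAULT_MODEL_IDS: dict[int, tuple[str, str]] = {
    1: ("linear", "interaction_only"),
    2: ("linear", "joint"),
    3: ("spline3", "interaction_only"),
    4: ("spline3", "joint"),
}


@dataclass
class GxEModelSpec:
    env: str
    coding: str = "linear"            # linear | spline3
    test: str = "interaction_only"    # interaction_only | joint
    covariates: tuple[str, ...] = ("age", "smoke", "pc1", "pc2", "pc3")

    def __post_init__(self) -> None:
        if self.coding not in ("linear", "spline3"):
            raise ValueError(f"unknown environment coding: {self.coding}")
        if self.test not in ("interaction_only", "joint"):
            raise ValueError(f"unknown test: {self.test}")

    @property
    def df(self) -> int:
        k = 1 if self.coding == "linear" else 3
        return k if self.test == "interaction_only" else k + 1


def default_specs(env: str, covariates: tuple[str, ...] | None = None,
                  model_ids: dict[int, tuple[str, str]] | None = None) -> dict[int, GxEModelSpec]:
    ids = model_ids or DEFAULT_MODEL_IDS
    kw = {} if covariates is None else {"covariates": tuple(covariates)}
    return {i: GxEModelSpec(env, coding, test, **kw) for i, (coding, test) in ids.items()}


# ---------------------------------------------------------------------------
# spline basis

def spline_basis(env_values: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns, centered.

    Interior knots sit at the tertiles (equally spaced quantiles) of
    the observed distribution and boundary knots at min/max, the
    conventional reading of "3-df polynomial spline". The construction
    is the truncated-power natural-spline basis: N_1 = x and, for each
    interior knot k, d_k(x) - d_{K-1}(x) with
    d_k(x) = [(x - t_k)_+^3 - (x - t_K)_+^3] / (t_K - t_k).
    """
    x = np.asarray(env_values, dtype=float)
    if df != 3:
        raise ValueError("only the 3-df natural cubic basis is supported")
    if len(np.unique(x[~np.isnan(x)])) < df + 2:
        raise ValueError("too few distinct environment values for a 3-df spline")
    interior = np.quantile(x[~np.isnan(x)], [1 / 3, 2 / 3])
    knots = np.concatenate([[np.nanmin(x)], interior, [np.nanmax(x)]])
    t_last = knots[-1]

    def d(tk: float) -> np.ndarray:
        return (np.clip(x - tk, 0, None) ** 3 - np.clip(x - t_last, 0, None) ** 3) / (t_last - tk)

    d_pen = d(knots[-2])
    # [x, d(t0)-d(t2), d(t1)-d(t2)] -> exactly 3 columns spanning the
    # natural cubic splines (up to intercept) on these 4 knots
    basis = np.column_stack([x, d(knots[0]) - d_pen, d(knots[1]) - d_pen])
    return basis - np.nanmean(basis, axis=0)


def _env_columns(env: np.ndarray, coding: str) -> np.ndarray:
    if coding == "linear":
        e = np.asarray(env, dtype=float)
        return (e - np.nanmean(e)).reshape(-1, 1)
    return spline_basis(env)


# ---------------------------------------------------------------------------
# nested LRT

def lrt_nested(X_full: np.ndarray, X_null: np.ndarray, y: np.ndarray,
               full_cols: list[str] | None = None, null_cols: list[str] | None = None) -> dict:
    """LRT of two nested logistic models.

    statistic = 2(l_full - l_null), floored at 0 against numerical
    noise; p from chi-square with df = column-count difference. If
    column names are given, the null's names must be a subset of the
    full's. Separation in either fit yields a flagged missing result.
    """
    if full_cols is not None and null_cols is not None:
        if not set(null_cols) <= set(full_cols):
            raise ValueError("models are not nested: null terms not a subset of full terms")
    if X_null.shape[1] >= X_full.shape[1]:
        if X_null.shape[1] > X_full.shape[1]:
            raise ValueError("null model has more terms than full model")
        # identical term counts: statistic is 0 by construction
    fit_full = fit_logistic(X_full, y)
    fit_null = fit_logistic(X_null, y)
    df = X_full.shape[1] - X_null.shape[1]
    if fit_full.separation or fit_null.separation:
        return {"statistic": np.nan, "df": df, "p": np.nan, "flag": "separation"}
    statistic = max(0.0, 2.0 * (fit_full.llf - fit_null.llf))
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return {"statistic": statistic, "df": df, "p": p, "flag": ""}


# ---------------------------------------------------------------------------
# the scan

def gxe_scan(
    gm: GenotypeMatrix,
    status: np.ndarray,
    phenotypes: pd.DataFrame,
    specs: dict[int, GxEModelSpec],
    threshold: float = BONFERRONI_GENOME_WIDE,
) -> pd.DataFrame:
    """Four-model SNPxE interaction screen over all SNPs.

    Returns one row per SNP with ``p_model<i>`` for each spec id, the
    marginal main-effect p, and ``significant_any`` = (min model p <
    threshold). Complete-case per SNP over status, environment and
    covariates.
    """
    for spec in specs.values():
        missing = [c for c in (spec.env, *spec.covariates) if c not in phenotypes.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing} needed by a model spec")

    y_all = np.asarray(status, dtype=float)
    d = gm.dosages()
    envs = {spec.env for spec in specs.values()}
    covs = {c for spec in specs.values() for c in spec.covariates}
    base_cols = sorted(envs | covs)
    base = phenotypes[base_cols].to_numpy(dtype=float)
    base_ok = ~np.isnan(base).any(axis=1) & ~np.isnan(y_all)

    # environment codings are computed once on the analysis sample
    rows = []
    meta = gm.snp_meta
    for j in range(gm.n_snps):
        dose = d[:, j]
        mask = base_ok & ~np.isnan(dose)
        y = y_all[mask]
        rec = {"snp_id": meta["snp_id"].iloc[j], "chrom": meta["chrom"].iloc[j],
               "pos": int(meta["pos"].iloc[j])}
        if y.size == 0 or y.min() == y.max() or np.std(dose[mask]) == 0:
            for i in specs:
                rec[f"p_model{i}"] = np.nan
            rec.update(main_effect_p=np.nan, significant_any=False, flag="degenerate")
            rows.append(rec)
            continue
        g = dose[mask].reshape(-1, 1)
        one = np.ones((y.size, 1))
        pvals = []
        flag = ""
        for i, spec in sorted(specs.items()):
            ecols = _env_columns(phenotypes[spec.env].to_numpy(dtype=float)[mask], spec.coding)
            cv = phenotypes[list(spec.covariates)].to_numpy(dtype=float)[mask]
            inter = g * ecols
            X_base = np.column_stack([one, cv, ecols])
            X_main = np.column_stack([X_base, g])
            X_full = np.column_stack([X_main, inter])
            X_null = X_main if spec.test == "interaction_only" else X_base
            res = lrt_nested(X_full, X_null, y)
            rec[f"p_model{i}"] = res["p"]
            if res["flag"]:
                flag = res["flag"]
            if np.isfinite(res["p"]):
                pvals.append(res["p"])
        # marginal main-effect scan p (dosage + covariates, no environment terms)
        cv0 = phenotypes[sorted(covs)].to_numpy(dtype=float)[mask]
        fit = fit_logistic(np.column_stack([one, g, cv0]), y)
        if fit.separation:
            rec["main_effect_p"] = np.nan
        else:
            z = fit.params[1] / fit.bse[1]
            rec["main_effect_p"] = 2.0 * float(stats.norm.sf(abs(z)))
        rec["significant_any"] = bool(pvals and min(pvals) < threshold)
        rec["flag"] = flag
        rows.append(rec)
    return pd.DataFrame(rows)
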
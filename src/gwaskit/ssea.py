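"""SNP-set enrichment analysis (SSEA).

Gene sets are converted to SNP sets through an eSNP map (each gene is
represented by the expression SNPs mapped to it); each set's
association p-values are then tested *as a group* for enrichment toward
small values with a one-sided Kolmogorov-Smirnov test. The default
reference is two-sample — the set's eSNP p-values against all mapped
eSNPs outside the set, which controls for eSNP-ascertainment bias — with
a one-sample Uniform(0,1) mode as an alternative. For small sets the
asymptotic KS p-value is replaced by a permutation p-value obtained by
resampling same-size SNP sets from the background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_SET_SIZE = 5
PERMUTATION_BELOW = 30
N_PERMUTATIONS = 10_000


@dataclass
class SSEAConfig:
    mode: str = "two_sample"          # or "uniform"
    min_set_size: int = MIN_SET_SIZE
    permutation_below: int = PERMUTATION_BELOW
    n_permutations: int = N_PERMUTATIONS
    ld_thin_distance: int | None = None
    seed: int = 0


def map_set_to_snps(
    genes: list[str],
    esnp_map: pd.DataFrame,
    available_snps: set[str] | None = None,
    ld_thin_distance: int | None = None,
    assoc: pd.DataFrame | None = None,
) -> list[str]:
    """Union of eSNPs over a gene set, restricted to SNPs with results.

    Optional distance thinning keeps the smallest-p SNP within each
    ``ld_thin_distance`` window (requires ``assoc`` with chrom/pos/p) to
    damp LD-driven dependence among nearby eSNPs.
    """
    sub = esnp_map[esnp_map["gene_id"].isin(genes)]
    snps = list(dict.fromkeys(sub["snp_id"]))  # union, insertion-ordered
    if available_snps is not None:
        snps = [s for s in snps if s in available_snps]
    if ld_thin_distance and assoc is not None and snps:
        info = assoc.set_index("snp_id").loc[[s for s in snps if s in assoc["snp_id"].values]]
        info = info.sort_values("p")
        kept: list[tuple[str, int]] = []
        kept_ids = []
        for snp_id, row in info.iterrows():
            c, p_ = row["chrom"], int(row["pos"])
            if all(cc != c or abs(pp - p_) >= ld_thin_distance for cc, pp in kept):
                kept.append((c, p_))
                kept_ids.append(snp_id)
        snps = kept_ids
    return snps


def _ks_one_sided_d(set_p: np.ndarray, background: np.ndarray | None) -> float:
    """One-sided D toward stochastically smaller set p-values:
    sup_x [ F_set(x) - F_ref(x) ]."""
    x = np.sort(set_p)
    n = len(x)
    if background is None:
        # reference CDF is Uniform(0,1): sup at the jump points
        return float(np.max(np.arange(1, n + 1) / n - x))
    bg = np.sort(background)
    m = len(bg)
    grid = np.concatenate([x, bg])
    f_set = np.searchsorted(x, grid, side="right") / n
    f_bg = np.searchsorted(bg, grid, side="right") / m
    return float(np.max(f_set - f_bg))


def ks_enrichment(
    set_pvalues: np.ndarray,
    background_pvalues: np.ndarray | None = None,
    config: SSEAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """One-sided KS test for enrichment of a SNP set toward small p.

    Two-sample mode compares the set against a background sample; the
    uniform mode (``background_pvalues=None``) compares against the
    Uniform(0,1) CDF. When the set is smaller than
    ``config.permutation_below`` and a background is available, the
    asymptotic p is replaced by a permutation p from resampled
    equal-size sets.
    """
    cfg = config or SSEAConfig()
    set_p = np.asarray(set_pvalues, dtype=float)
    if set_p.size == 0:
        raise ValueError("empty set of p-values")
    if np.any((set_p <= 0) | (set_p > 1)):
        raise ValueError("p-values must lie in (0, 1]")

    if background_pvalues is None:
        d = _ks_one_sided_d(set_p, None)
        res = stats.kstest(set_p, "uniform", alternative="greater")
        return {"D": d, "p": float(res.pvalue), "mode": "uniform", "n_set": set_p.size}

    bg = np.asarray(background_pvalues, dtype=float)
    if bg.size < set_p.size:
        raise ValueError("background smaller than the set in two-sample mode")
    d = _ks_one_sided_d(set_p, bg)
    res = stats.ks_2samp(set_p, bg, alternative="greater")
    p_val = float(res.pvalue)
    method = "asymptotic"
    if set_p.size < cfg.permutation_below:
        r = rng or np.random.default_rng(cfg.seed)
        draws = cfg.n_permutations
        n, m = set_p.size, bg.size
        bg_sorted = np.sort(bg)
        # the sup of F_set - F_bg is attained at set observations, so each
        # resampled D reduces to max_i(i/n - F_bg(x_(i)))
        exceed = 0
        ranks = np.arange(1, n + 1) / n
        for _ in range(draws):
            x = np.sort(r.choice(bg, size=n, replace=False))
            f_bg = np.searchsorted(bg_sorted, x, side="right") / m
            if np.max(ranks - f_bg) >= d - 1e-12:
                exceed += 1
        p_val = (1 + exceed) / (1 + draws)
        method = "permutation"
    return {"D": float(d), "p": p_val, "mode": "two_sample", "method": method, "n_set": int(set_p.size)}


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = n - rank_from_end
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


def run_ssea(
    gene_sets: dict[str, list[str]],
    esnp_map: pd.DataFrame,
    assoc_results: pd.DataFrame,
    config: SSEAConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Test every eligible gene set; returns (results, QQ data).

    The background universe for each set is all mapped eSNPs outside the
    set (two-sample mode) or the uniform distribution. Results carry the
    KS D, p, a Benjamini-Hochberg q and are sorted ascending p. QQ data
    per set is the sorted observed -log10 p against expected uniform
    quantiles, ready for plotting.
    """
    cfg = config or SSEAConfig()
    if not gene_sets:
        raise ValueError("empty gene-set collection")
    pmap = assoc_results.dropna(subset=["p"]).set_index("snp_id")["p"]
    available = set(pmap.index)
    rng = np.random.default_rng(cfg.seed)

    # deduplicate (gene, snp) pairs once, with a logged count
    n_dup = int(esnp_map.duplicated(["gene_id", "snp_id"]).sum())
    if n_dup:
        logger.info("collapsed %d duplicate (gene, snp) eSNP-map records", n_dup)
        esnp_map = esnp_map.drop_duplicates(["gene_id", "snp_id"])

    set_snps: dict[str, list[str]] = {}
    for name in sorted(gene_sets):
        snps = map_set_to_snps(gene_sets[name], esnp_map, available,
                               cfg.ld_thin_distance, assoc_results)
        if len(snps) < cfg.min_set_size:
            logger.info("set %s skipped: %d mapped SNPs < min %d", name, len(snps), cfg.min_set_size)
            continue
        set_snps[name] = snps

    universe = sorted(set().union(*set_snps.values())) if set_snps else []
    rows = []
    qq: dict[str, pd.DataFrame] = {}
    for name, snps in set_snps.items():
        sp = pmap.loc[snps].to_numpy()
        if cfg.mode == "uniform":
            res = ks_enrichment(sp, None, cfg, rng)
        else:
            bg_ids = [s for s in universe if s not in set(snps)]
            res = ks_enrichment(sp, pmap.loc[bg_ids].to_numpy(), cfg, rng)
        rows.append({
            "set": name,
            "n_genes": len(gene_sets[name]),
            "n_snps": len(snps),
            "D": res["D"],
            "p": res["p"],
            "direction": "small_p",
        })
        obs = np.sort(sp)  # i-th smallest p pairs with the (i-0.5)/n uniform quantile
        n = len(obs)
        qq[name] = pd.DataFrame({
            "expected_neglog10p": -np.log10((np.arange(1, n + 1) - 0.5) / n),
            "observed_neglog10p": -np.log10(obs),
        })
    table = pd.DataFrame(rows)
    if table.empty:
        return table, qq
    table["q"] = _bh_qvalues(table["p"].to_numpy())
    return table.sort_values("p", kind="mergesort").reset_index(drop=True), qq
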
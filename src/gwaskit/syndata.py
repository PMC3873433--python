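"""Synthetic two-cohort nested case-control study generator.

The generator emulates the statistical structure every downstream stage
assumes: biallelic hard calls at Hardy-Weinberg proportions, block LD
with a controllable genotype correlation, a binary endpoint driven by an
additive logistic model, standardized quantitative biomarkers with their
own causal SNPs, a continuous environment with pure (no-main-effect)
SNPxE interactions, and gene sets whose eSNPs are preferentially drawn
from causal SNPs. Everything is deterministic under a fixed seed.

LD model
--------
Within an LD block all SNPs share one MAF and each haplotype is drawn by
thresholding an exchangeable multivariate normal (Gaussian copula).
Thresholding attenuates correlation, so the latent correlation is
calibrated by root-finding on the bivariate normal orthant probability
until the *genotype* correlation matches the requested ``ld_r``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MISSING, GenotypeMatrix

QUANT_TRAITS = ["ldl", "hdl", "apob", "tg", "adiponectin", "crp", "tc"]
#: traits whose high values are protective; risk-score signs flip for these
PROTECTIVE_TRAITS = ("hdl", "adiponectin")

SNP_SPACING_BP = 25_000  # fixed spacing so a 10-SNP block spans >100 kb
SNPS_PER_CHROM = 400


@dataclass
class SimConfig:
    """Full parameterization of the synthetic two-cohort study.

    Defaults mirror the shape of a pair of nested myocardial-infarction
    case-control studies drawn from large prospective cohorts: roughly
    450 incident cases with 2 matched controls each per cohort, one
    female-only and one male-only cohort, modest per-allele odds ratios
    and biomarker effects.
    """

    n_cases_per_cohort: int = 450
    n_controls_per_cohort: int = 900
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_binary: int = 20
    or_causal: float = 1.6
    n_causal_quant: int = 10
    beta_quant: float = 0.3
    ld_block_size: int = 10
    ld_r: float = 0.6
    n_gene_sets: int = 100
    genes_per_set: int = 7
    esnps_per_gene: int = 3
    enriched_set_fraction: float = 0.03
    enriched_causal_fraction: float = 0.5
    gxe_snp_count: int = 2
    gxe_beta: float = 0.5
    missing_rate: float = 0.01
    seed: int = 0
    pool_factor: float = 2.0
    n_pcs: int = 3

    def validate(self) -> None:
        counts = {
            "n_cases_per_cohort": self.n_cases_per_cohort,
            "n_controls_per_cohort": self.n_controls_per_cohort,
            "n_snps": self.n_snps,
            "n_causal_binary": self.n_causal_binary,
            "n_causal_quant": self.n_causal_quant,
            "ld_block_size": self.ld_block_size,
            "n_gene_sets": self.n_gene_sets,
            "genes_per_set": self.genes_per_set,
            "esnps_per_gene": self.esnps_per_gene,
            "gxe_snp_count": self.gxe_snp_count,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.ld_block_size == 0:
            raise ValueError("ld_block_size must be >= 1")
        if self.n_causal_binary > self.n_snps or self.n_causal_quant > self.n_snps:
            raise ValueError("causal SNP counts cannot exceed n_snps")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_r < 1):
            raise ValueError("ld_r must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.or_causal <= 0:
            raise ValueError("or_causal must be positive")
        if not (0 <= self.enriched_set_fraction <= 1):
            raise ValueError("enriched_set_fraction must be in [0, 1]")
        if not (0 <= self.enriched_causal_fraction <= 1):
            raise ValueError("enriched_causal_fraction must be in [0, 1]")


@dataclass
class CohortDataset:
    """One cohort's genotypes, phenotype table and generating truth."""

    name: str
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame  # keyed by sample_id; status, traits, env, covariates
    truth: dict = field(default_factory=dict)


@dataclass
class StudyData:
    """A full two-cohort synthetic study plus shared set annotations."""

    cohorts: dict[str, CohortDataset]
    gene_sets: dict[str, list[str]]
    esnp_map: pd.DataFrame  # gene_id, snp_id, tissue_label
    truth: dict


# ---------------------------------------------------------------------------
# genotypes

_rho_cache: dict[tuple[float, float], float] = {}


def _latent_rho(maf: float, target_r: float) -> float:
    """Latent normal correlation whose thresholded alleles give genotype
    correlation ``target_r`` at allele frequency ``maf``."""
    if target_r <= 0:
        return 0.0
    key = (round(maf, 3), round(target_r, 4))
    if key in _rho_cache:
        return _rho_cache[key]
    t = stats.norm.ppf(maf)
    p = maf

    def allele_corr(rho: float) -> float:
        # genotype corr equals the allele-indicator corr (sum of 2 iid haplotypes)
        joint = stats.multivariate_normal([0, 0], [[1, rho], [rho, 1]]).cdf([t, t])
        return (joint - p * p) / (p * (1 - p))

    f = lambda rho: allele_corr(rho) - target_r
    hi = 0.9999
    if f(hi) < 0:  # target unreachable; use maximal dependence
        rho = hi
    else:
        rho = optimize.brentq(f, 0.0, hi, xtol=1e-4)
    _rho_cache[key] = float(rho)
    return float(rho)


def simulate_genotypes(config: SimConfig, rng: np.random.Generator) -> GenotypeMatrix:
    """Draw hard calls at HWE proportions with block LD and fixed spacing.

    SNPs are grouped into consecutive blocks of ``ld_block_size``; each
    block shares one MAF drawn uniformly from ``maf_range``. Positions
    advance in fixed 25 kb steps; a fresh chromosome starts every 400
    SNPs (rounded to whole blocks) so distance-based pruning sees
    multiple chromosomes. Missing calls are injected at ``missing_rate``.
    """
    config.validate()
    n_total = int(round(config.pool_factor * (config.n_cases_per_cohort + config.n_controls_per_cohort)))
    return _simulate_genotypes_n(config, rng, n_total)


def _simulate_genotypes_n(config: SimConfig, rng: np.random.Generator, n_samples: int) -> GenotypeMatrix:
    m = config.n_snps
    bs = config.ld_block_size
    calls = np.empty((n_samples, m), dtype=np.int8)
    mafs = np.empty(m)
    n_blocks = (m + bs - 1) // bs
    for b in range(n_blocks):
        j0, j1 = b * bs, min((b + 1) * bs, m)
        k = j1 - j0
        maf = rng.uniform(*config.maf_range)
        mafs[j0:j1] = maf
        t = stats.norm.ppf(maf)
        rho = _latent_rho(maf, config.ld_r) if k > 1 else 0.0
        g = np.zeros((n_samples, k), dtype=np.int8)
        for _hap in range(2):
            shared = rng.standard_normal((n_samples, 1))
            indiv = rng.standard_normal((n_samples, k))
            latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indiv
            g += (latent < t).astype(np.int8)
        calls[:, j0:j1] = g
    if config.missing_rate > 0:
        mask = rng.random((n_samples, m)) < config.missing_rate
        calls[mask] = MISSING

    snps_per_chrom = max(bs, (SNPS_PER_CHROM // bs) * bs)
    idx = np.arange(m)
    chrom = (idx // snps_per_chrom) + 1
    pos = (idx % snps_per_chrom + 1) * SNP_SPACING_BP
    meta = pd.DataFrame({
        "snp_id": [f"snp{i + 1:06d}" for i in idx],
        "chrom": [f"chr{c}" for c in chrom],
        "pos": pos,
        "ref": "A",
        "alt": "G",
    })
    meta["true_maf"] = mafs
    gm = GenotypeMatrix(calls, meta, [f"s{i + 1:05d}" for i in range(n_samples)])
    return gm


# ---------------------------------------------------------------------------
# binary endpoint

def _mean_filled_dosage(gm: GenotypeMatrix, cols: np.ndarray) -> np.ndarray:
    d = gm.dosages()[:, cols]
    mu = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mu, inds[1])
    return d


def tune_intercept(eta: np.ndarray, target_fraction: float) -> float:
    """Intercept c such that mean(expit(c + eta)) equals the target
    case fraction, found by bisection (the mean is monotone in c)."""
    if not (0 < target_fraction < 1):
        raise ValueError("target case fraction must be in (0, 1)")

    def g(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(c + eta))))) - target_fraction

    lo, hi = -40.0, 40.0
    if g(lo) > 0 or g(hi) < 0:
        raise ValueError("case fraction unattainable for given effects")
    return float(optimize.brentq(g, lo, hi, xtol=1e-10))


def simulate_binary_trait(
    gm: GenotypeMatrix,
    config: SimConfig,
    causal_idx: np.ndarray,
    rng: np.random.Generator,
    covariate_eta: np.ndarray | None = None,
    interaction_eta: np.ndarray | None = None,
) -> np.ndarray:
    """Draw case/control labels from an additive logistic model.

    logit P(case) = c + sum log(or_causal) * dosage + covariate terms
    (+ any interaction terms), with c tuned by bisection so the realized
    case fraction matches the configured design fraction. Returns the
    0/1 label vector for every sample in ``gm``; exact-count cohort
    ascertainment is done by :func:`sample_case_control`.
    """
    eta = np.zeros(gm.n_samples)
    if len(causal_idx) > 0:
        d = _mean_filled_dosage(gm, np.asarray(causal_idx))
        eta = eta + np.log(config.or_causal) * (d - d.mean(axis=0)).sum(axis=1)
    if covariate_eta is not None:
        eta = eta + covariate_eta
    if interaction_eta is not None:
        eta = eta + interaction_eta
    frac = config.n_cases_per_cohort / (config.n_cases_per_cohort + config.n_controls_per_cohort)
    c = tune_intercept(eta, frac)
    prob = 1.0 / (1.0 + np.exp(-(c + eta)))
    return (rng.random(gm.n_samples) < prob).astype(int)


def sample_case_control(
    labels: np.ndarray, n_cases: int, n_controls: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of an exact-count case-control sample from a labeled pool."""
    cases = np.flatnonzero(labels == 1)
    controls = np.flatnonzero(labels == 0)
    if len(cases) < n_cases or len(controls) < n_controls:
        raise ValueError(
            f"pool too small: {len(cases)} cases / {len(controls)} controls available, "
            f"need {n_cases}/{n_controls}"
        )
    pick = np.concatenate([
        rng.choice(cases, n_cases, replace=False),
        rng.choice(controls, n_controls, replace=False),
    ])
    return np.sort(pick)


# ---------------------------------------------------------------------------
# quantitative biomarkers

def simulate_quantitative_traits(
    gm: GenotypeMatrix,
    config: SimConfig,
    causal_by_trait: dict[str, np.ndarray],
    signs_by_trait: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Standardized biomarkers: trait = sum sign*beta*dosage + N(0,1).

    Each trait has its own causal SNP set with recorded per-SNP effect
    signs (needed downstream to test risk-score sign reversal for the
    protective traits). Output columns are standardized to mean 0, SD 1.
    """
    out = {}
    for trait in QUANT_TRAITS:
        idx = np.asarray(causal_by_trait.get(trait, np.array([], dtype=int)))
        y = rng.standard_normal(gm.n_samples)
        if len(idx) > 0:
            d = _mean_filled_dosage(gm, idx)
            signs = np.asarray(signs_by_trait[trait], dtype=float)
            y = y + (d * (config.beta_quant * signs)).sum(axis=1)
        sd = y.std()
        out[trait] = (y - y.mean()) / (sd if sd > 0 else 1.0)
    return pd.DataFrame(out, index=gm.sample_ids)


# ---------------------------------------------------------------------------
# environment and interactions

def interaction_eta(
    gm: GenotypeMatrix,
    gxe_idx: np.ndarray,
    env: np.ndarray,
    gxe_beta: float,
) -> np.ndarray:
    """Pure-interaction logit contribution: beta * dosage * E with the
    dosage centered so the SNPs carry no marginal effect."""
    if len(gxe_idx) == 0:
        return np.zeros(gm.n_samples)
    d = _mean_filled_dosage(gm, np.asarray(gxe_idx))
    dc = d - d.mean(axis=0)
    return gxe_beta * (dc * env[:, None]).sum(axis=1)


# ---------------------------------------------------------------------------
# gene sets and the eSNP map

def simulate_gene_sets_and_esnp_map(
    config: SimConfig,
    snp_ids: pd.Series,
    causal_snp_ids: list[str],
    rng: np.random.Generator,
) -> tuple[dict[str, list[str]], pd.DataFrame, list[str]]:
    """Disjoint synthetic gene sets plus a gene -> eSNP map.

    Enriched sets (the first ``round(enriched_set_fraction * n_gene_sets)``
    after shuffling) draw each eSNP from the causal pool with probability
    ``enriched_causal_fraction``; null sets draw uniformly from all SNPs.
    Returns (sets, esnp map, enriched set names).
    """
    all_snps = list(snp_ids)
    snp_set = set(all_snps)
    for s in causal_snp_ids:
        if s not in snp_set:
            raise ValueError(f"causal SNP {s} not present in genotype panel")
    n_enriched = int(round(config.enriched_set_fraction * config.n_gene_sets))
    order = rng.permutation(config.n_gene_sets)
    enriched_ids = set(order[:n_enriched])

    sets: dict[str, list[str]] = {}
    records = []
    enriched_names = []
    gene_counter = 0
    for s_i in range(config.n_gene_sets):
        name = f"set{s_i + 1:03d}"
        is_enriched = s_i in enriched_ids
        if is_enriched:
            enriched_names.append(name)
        genes = []
        slots = config.genes_per_set * config.esnps_per_gene
        # eSNPs are distinct within a set (each gene has its own eQTLs);
        # an enriched set realizes the configured causal fraction exactly
        # (up to rounding and pool size)
        chosen: list[str] = []
        if is_enriched and causal_snp_ids:
            n_causal = min(int(round(config.enriched_causal_fraction * slots)),
                           len(causal_snp_ids), slots)
            chosen = list(rng.choice(causal_snp_ids, n_causal, replace=False))
        while len(chosen) < slots:
            snp = all_snps[rng.integers(len(all_snps))]
            if snp not in chosen:
                chosen.append(snp)
        chosen = list(rng.permutation(chosen))
        for g in range(config.genes_per_set):
            gene_counter += 1
            gene = f"gene{gene_counter:05d}"
            genes.append(gene)
            for snp in chosen[g * config.esnps_per_gene:(g + 1) * config.esnps_per_gene]:
                records.append((gene, snp, "synthetic_tissue"))
        sets[name] = genes
    esnp_map = pd.DataFrame(records, columns=["gene_id", "snp_id", "tissue_label"])
    return sets, esnp_map, enriched_names


# ---------------------------------------------------------------------------
# whole-study assembly

def _pick_disjoint(rng: np.random.Generator, n_snps: int, sizes: list[int]) -> list[np.ndarray]:
    total = sum(sizes)
    if total > n_snps:
        raise ValueError("not enough SNPs for disjoint causal sets")
    pool = rng.choice(n_snps, size=total, replace=False)
    out, at = [], 0
    for s in sizes:
        out.append(np.sort(pool[at:at + s]))
        at += s
    return out


def simulate_cohort(
    config: SimConfig,
    name: str,
    rng: np.random.Generator,
    causal_binary: np.ndarray,
    causal_by_trait: dict[str, np.ndarray],
    signs_by_trait: dict[str, np.ndarray],
    gxe_idx: np.ndarray,
) -> CohortDataset:
    """One cohort: pool genotypes, endpoint with covariates and pure
    interactions, exact case/control ascertainment, biomarkers."""
    gm_pool = simulate_genotypes(config, rng)
    n = gm_pool.n_samples

    age = rng.normal(62.0, 7.0, n)
    smoke = (rng.random(n) < 0.15).astype(int)
    alcohol = rng.standard_normal(n)
    pcs = rng.standard_normal((n, config.n_pcs))
    # mild risk contributions give the Table-1-style case-control imbalance
    cov_eta = 0.03 * (age - age.mean()) + 0.4 * (smoke - smoke.mean())
    ix_eta = interaction_eta(gm_pool, gxe_idx, alcohol, config.gxe_beta)

    labels = simulate_binary_trait(gm_pool, config, causal_binary, rng, cov_eta, ix_eta)
    keep = sample_case_control(labels, config.n_cases_per_cohort, config.n_controls_per_cohort, rng)

    gm = gm_pool.subset_samples(keep)
    pheno = pd.DataFrame(index=gm.sample_ids)
    pheno.index.name = "sample_id"
    pheno["status"] = labels[keep]
    traits = simulate_quantitative_traits(gm, config, causal_by_trait, signs_by_trait, rng)
    for t in QUANT_TRAITS:
        pheno[t] = traits[t].to_numpy()
    pheno["alcohol"] = alcohol[keep]
    pheno["age"] = age[keep]
    pheno["smoke"] = smoke[keep]
    for j in range(config.n_pcs):
        pheno[f"pc{j + 1}"] = pcs[keep, j]

    snp_ids = gm.snp_meta["snp_id"]
    truth = {
        "causal_binary": [snp_ids[i] for i in causal_binary],
        "causal_by_trait": {t: [snp_ids[i] for i in v] for t, v in causal_by_trait.items()},
        "trait_effect_signs": {t: [int(s) for s in signs_by_trait[t]] for t in causal_by_trait},
        "gxe_snps": [snp_ids[i] for i in gxe_idx],
    }
    return CohortDataset(name, gm, pheno, truth)


def simulate_study(config: SimConfig) -> StudyData:
    """The full two-cohort study sharing one SNP panel, causal
    architecture, gene sets and eSNP map; genotype draws are independent
    between cohorts (they are disjoint subject samples)."""
    config.validate()
    root = np.random.default_rng(config.seed)
    # causal architecture chosen once at study level
    sizes = [config.n_causal_binary] + [config.n_causal_quant] * len(QUANT_TRAITS) + [config.gxe_snp_count]
    picks = _pick_disjoint(root, config.n_snps, sizes)
    causal_binary = picks[0]
    causal_by_trait = {t: picks[1 + i] for i, t in enumerate(QUANT_TRAITS)}
    gxe_idx = picks[-1]
    signs_by_trait = {
        t: root.choice([-1, 1], size=len(causal_by_trait[t])) for t in QUANT_TRAITS
    }

    cohorts = {}
    for cname in ("cohort_f", "cohort_m"):
        crng = np.random.default_rng(root.integers(2**31))
        cohorts[cname] = simulate_cohort(
            config, cname, crng, causal_binary, causal_by_trait, signs_by_trait, gxe_idx
        )

    any_gm = next(iter(cohorts.values())).genotypes
    snp_ids = any_gm.snp_meta["snp_id"]
    causal_names = [snp_ids[i] for i in causal_binary]
    sets, esnp_map, enriched = simulate_gene_sets_and_esnp_map(
        config, snp_ids, causal_names, np.random.default_rng(root.integers(2**31))
    )
    truth = dict(next(iter(cohorts.values())).truth)
    truth["enriched_sets"] = enriched
    return StudyData(cohorts, sets, esnp_map, truth)


def write_study(study: StudyData, outdir: str | Path, config: SimConfig | None = None) -> None:
    """Write a study to disk: per-cohort VCF + phenotype TSV, shared GMT
    gene sets, eSNP map TSV and truth JSON."""
    from . import io as gio  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, cohort in study.cohorts.items():
        gio.write_vcf(cohort.genotypes, outdir / f"{name}.vcf")
        gio.write_phenotypes(cohort.phenotypes, outdir / f"{name}.pheno.tsv")
    gio.write_gmt(study.gene_sets, outdir / "gene_sets.gmt")
    gio.write_esnp_map(study.esnp_map, outdir / "esnp_map.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=1)
    if config is not None:
        with open(outdir / "sim_config.json", "w") as fh:
            json.dump(asdict(config), fh, indent=1)
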
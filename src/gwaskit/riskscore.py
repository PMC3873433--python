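"""Aggregate allele-count genotype risk scores.

From a trait's association results the top-N SNPs (ascending p) are
selected with a greedy >=100 kb distance-pruning sweep, each entry
carrying the allele linked to the *higher* trait level and a trait-level
sign: +1 for risk-direction traits (LDL, total cholesterol, apoB,
triglycerides, CRP, MI) and -1 for the protective traits (HDL,
adiponectin), whose raising alleles should lower the score. A subject
scores, per entry, sign x (+1 if homozygous for the scored allele, -1
if homozygous for the other allele, 0 if heterozygous or missing), and
the summed score is tested against the binary endpoint by logistic
regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import fit_logistic
from .containers import MISSING, GenotypeMatrix

MIN_DISTANCE_BP = 100_000

#: trait-level score signs; reversal only for the protective traits
TRAIT_SIGNS: dict[str, int] = {
    "mi": 1, "ldl": 1, "tc": 1, "apob": 1, "tg": 1, "crp": 1,
    "hdl": -1, "adiponectin": -1,
}

DEFAULT_N_GRID = (10, 50, 100, 500, 1000)


@dataclass
class ScoreAlleleSet:
    """Ordered (ascending source p) list of scored alleles.

    ``entries`` columns: snp_id, chrom, pos, scored_allele (the allele
    linked to higher trait level), other_allele, sign, trait, p.
    """

    entries: pd.DataFrame
    traits: tuple[str, ...]
    n_requested: int

    def __len__(self) -> int:
        return len(self.entries)

    def check_spacing(self, min_distance: int = MIN_DISTANCE_BP) -> bool:
        e = self.entries
        for c, grp in e.groupby("chrom"):
            pos = np.sort(grp["pos"].to_numpy())
            if len(pos) > 1 and np.min(np.diff(pos)) < min_distance:
                return False
        return True


def select_score_alleles(
    assoc_results: pd.DataFrame,
    n: int,
    min_distance: int = MIN_DISTANCE_BP,
    trait_signs: dict[str, int] | None = None,
) -> ScoreAlleleSet:
    """Greedy top-N selection with distance pruning.

    Candidates are swept in ascending p; a candidate is kept iff it is
    >= ``min_distance`` (inclusive) from every *already kept* SNP on the
    same chromosome, until N SNPs are kept or candidates run out. The
    scored allele is the one whose dosage associates positively with
    the trait (the counted allele when effect > 0, otherwise the other
    allele). ``assoc_results`` needs columns snp_id, chrom, pos, allele,
    effect (or z), p, trait, and ref if allele flips are to name the
    other allele.
    """
    if n <= 0:
        raise ValueError("N must be positive")
    signs = trait_signs or TRAIT_SIGNS
    cand = assoc_results.dropna(subset=["p"]).sort_values("p", kind="mergesort")
    cand = cand.drop_duplicates("snp_id", keep="first")
    kept_pos: dict[str, list[int]] = {}
    rows = []
    for _, r in cand.iterrows():
        c, pos = r["chrom"], int(r["pos"])
        if any(abs(pos - kp) < min_distance for kp in kept_pos.get(c, ())):
            continue
        direction = r["effect"] if np.isfinite(r.get("effect", np.nan)) else r["z"]
        ref = r.get("ref", "N")
        if direction >= 0:
            scored, other = r["allele"], ref
        else:
            scored, other = ref, r["allele"]
        trait = r.get("trait", "mi")
        rows.append({
            "snp_id": r["snp_id"], "chrom": c, "pos": pos,
            "scored_allele": scored, "other_allele": other,
            "sign": int(signs.get(trait, 1)), "trait": trait, "p": float(r["p"]),
        })
        kept_pos.setdefault(c, []).append(pos)
        if len(rows) == n:
            break
    entries = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "scored_allele",
                                          "other_allele", "sign", "trait", "p"])
    traits = tuple(sorted(entries["trait"].unique())) if len(entries) else ()
    return ScoreAlleleSet(entries, traits, n)


def score_samples(gm: GenotypeMatrix, allele_set: ScoreAlleleSet) -> np.ndarray:
    """Integer risk score per sample.

    For each entry: +1 if homozygous for the scored allele, -1 if
    homozygous for the other allele, 0 if heterozygous or missing, all
    multiplied by the entry's trait-level sign. Entries whose SNP is
    absent from the matrix contribute 0.
    """
    scores = np.zeros(gm.n_samples, dtype=int)
    id_to_col = {s: i for i, s in enumerate(gm.snp_meta["snp_id"])}
    alt = gm.snp_meta["alt"].to_numpy()
    for _, e in allele_set.entries.iterrows():
        j = id_to_col.get(e["snp_id"])
        if j is None:
            continue
        calls = gm.calls[:, j]
        # dosage counts the alt allele; re-orient to count the scored allele
        scored_is_alt = e["scored_allele"] == alt[j]
        contrib = np.zeros(gm.n_samples, dtype=int)
        hom_scored = calls == (2 if scored_is_alt else 0)
        hom_other = calls == (0 if scored_is_alt else 2)
        contrib[hom_scored] = 1
        contrib[hom_other] = -1
        contrib[calls == MISSING] = 0
        scores += int(e["sign"]) * contrib
    return scores


def evaluate_score(
    scores: np.ndarray,
    status: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Logistic regression of the binary endpoint on the score."""
    y = np.asarray(status, dtype=float)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if s.std() == 0:
        raise ValueError("score is constant")
    cols = [np.ones(len(s)), s]
    if covariates is not None and covariates.shape[1]:
        cols.append(covariates.to_numpy(dtype=float))
    X = np.column_stack(cols)
    fit = fit_logistic(X, y)
    z = fit.params[1] / fit.bse[1]
    return {
        "effect": float(fit.params[1]),
        "se": float(fit.bse[1]),
        "z": float(z),
        "p": 2.0 * float(stats.norm.sf(abs(z))),
        "n": int(len(y)),
    }


def merge_trait_results(assoc_by_trait: dict[str, pd.DataFrame], traits: list[str]) -> pd.DataFrame:
    """Concatenate per-trait association tables for a combined score,
    deduplicating SNPs shared between traits (keep the smaller source p)."""
    frames = [assoc_by_trait[t] for t in traits]
    merged = pd.concat(frames, ignore_index=True).dropna(subset=["p"])
    merged = merged.sort_values("p", kind="mergesort").drop_duplicates("snp_id", keep="first")
    return merged.reset_index(drop=True)


def sweep_thresholds(
    assoc_by_trait: dict[str, pd.DataFrame],
    gm: GenotypeMatrix,
    status: np.ndarray,
    ns: tuple[int, ...] = DEFAULT_N_GRID,
    combos: list[list[str]] | None = None,
    covariates: pd.DataFrame | None = None,
    min_distance: int = MIN_DISTANCE_BP,
) -> pd.DataFrame:
    """Score->endpoint evaluation over an N grid and trait combinations.

    ``combos`` defaults to each single trait, all biomarkers combined,
    and biomarkers+MI when an "mi" table is present. Merged candidate
    lists are deduplicated before the distance rule is re-applied.
    """
    if combos is None:
        traits = list(assoc_by_trait)
        biomarkers = [t for t in traits if t != "mi"]
        combos = [[t] for t in traits]
        if len(biomarkers) > 1:
            combos.append(biomarkers)
        if "mi" in traits and biomarkers:
            combos.append(biomarkers + ["mi"])
    rows = []
    for combo in combos:
        merged = merge_trait_results(assoc_by_trait, combo)
        for n in ns:
            aset = select_score_alleles(merged, n, min_distance)
            if len(aset) == 0:
                continue
            s = score_samples(gm, aset)
            if s.std() == 0:
                continue
            ev = evaluate_score(s, status, covariates)
            rows.append({
                "traits": "+".join(combo), "n_requested": n, "n_snps": len(aset),
                "effect": ev["effect"], "se": ev["se"], "z": ev["z"], "p": ev["p"],
            })
    return pd.DataFrame(rows)
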
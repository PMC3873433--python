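"""Core in-memory containers shared across the pipeline.

Genotypes are hard calls coded 0/1/2 as the number of copies of the
alternate (counted) allele, with ``-1`` marking a missing call. SNP
metadata travels alongside the call matrix as a pandas DataFrame so
that positional operations (distance pruning, per-chromosome logic)
never lose track of which column is which variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd

MISSING = -1

SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs hard-call matrix with per-SNP metadata.

    Parameters
    ----------
    calls
        Integer array of shape ``(n_samples, n_snps)`` with values in
        ``{0, 1, 2, -1}``; ``-1`` is a missing call.
    snp_meta
        DataFrame with columns ``snp_id, chrom, pos, ref, alt``;
        positions are 1-based. ``snp_id`` must be unique.
    sample_ids
        Unique sample identifiers, one per row of ``calls``.
    """

    calls: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x SNPs array")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        missing_cols = [c for c in SNP_META_COLUMNS if c not in self.snp_meta.columns]
        if missing_cols:
            raise ValueError(f"snp_meta missing columns: {missing_cols}")
        if len(self.snp_meta) != self.calls.shape[1]:
            raise ValueError("snp_meta rows must match number of SNP columns")
        if len(self.sample_ids) != self.calls.shape[0]:
            raise ValueError("sample_ids must match number of rows")
        if self.snp_meta["snp_id"].duplicated().any():
            raise ValueError("snp ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if (self.snp_meta["pos"] <= 0).any():
            raise ValueError("positions must be strictly positive (1-based)")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, -1}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> pd.Series:
        return self.snp_meta["snp_id"]

    def dosages(self) -> np.ndarray:
        """Calls as float with missing mapped to NaN."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def snp_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP over non-missing calls."""
        d = self.dosages()
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def alt_freq(self) -> np.ndarray:
        d = self.dosages()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    # -- subsetting --------------------------------------------------------

    def subset_snps(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, (list, tuple, pd.Index, set)):
            keep = self.snp_meta["snp_id"].isin(list(mask_or_ids)).to_numpy()
        else:
            keep = np.asarray(mask_or_ids)
            if keep.dtype != bool:
                idx = np.zeros(self.n_snps, dtype=bool)
                idx[keep] = True
                keep = idx
        return GenotypeMatrix(
            self.calls[:, keep],
            self.snp_meta.loc[keep].reset_index(drop=True),
            list(self.sample_ids),
        )

    def subset_samples(self, mask_or_index) -> "GenotypeMatrix":
        keep = np.asarray(mask_or_index)
        if keep.dtype != bool:
            idx = np.zeros(self.n_samples, dtype=bool)
            idx[keep] = True
            keep = idx
        sids = [s for s, k in zip(self.sample_ids, keep) if k]
        return GenotypeMatrix(self.calls[keep], self.snp_meta.copy(), sids)

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero((self.snp_meta["snp_id"] == snp_id).to_numpy())
        if len(hits) == 0:
            raise KeyError(f"unknown SNP id: {snp_id}")
        return int(hits[0])


ASSOC_COLUMNS = [
    "snp_id", "chrom", "pos", "allele", "maf", "trait", "cohort",
    "effect", "se", "z", "p", "n_used", "flag",
]


def genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """(n_AA, n_Aa, n_aa) counts from a 0/1/2 dosage vector, NaN ignored."""
    d = np.asarray(dosage, dtype=float)
    d = d[~np.isnan(d)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())
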
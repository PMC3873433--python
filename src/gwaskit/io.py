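"""Readers and writers for the pipeline's file formats.

Genotypes come in as VCF (GT fields, parsed with cyvcf2) or as a plain
TSV dosage matrix (header row of SNP ids, first column sample_id, cells
in {0,1,2,NA}); gene sets as GMT; the eSNP map and phenotypes as TSV.
All output TSVs start with commented provenance header lines (tool
version, config hash, seed) so a result file is self-describing.
Positions are 1-based throughout, matching VCF convention.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genotypes

def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GT-only VCF 4.2 file."""
    path = Path(path)
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=gwaskit {__version__}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        meta = gm.snp_meta
        order = meta.sort_values(["chrom", "pos"]).index
        for j in order:
            row = meta.loc[j]
            gts = "\t".join(code[int(c)] for c in gm.calls[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT hard calls from a VCF; multi-allelic records are skipped
    with a logged count; half-missing or missing GTs become missing."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls_cols, recs = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(var.gt_types)  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        col = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING)))
        calls_cols.append(col.astype(np.int8))
        recs.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                     var.REF, var.ALT[0]))
    vcf.close()
    if n_multi:
        logger.info("skipped %d multi-allelic VCF records", n_multi)
    if not recs:
        raise ValueError(f"no biallelic records in {path}")
    meta = pd.DataFrame(recs, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(np.column_stack(calls_cols), meta, samples)


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    vals = gm.calls.astype(str).astype(object)
    vals[gm.calls == MISSING] = "NA"
    d = pd.DataFrame(vals, index=gm.sample_ids, columns=gm.snp_meta["snp_id"])
    d.index.name = "sample_id"
    d.to_csv(path, sep="\t")
    meta_path = Path(path).with_suffix(".snps.tsv")
    gm.snp_meta.to_csv(meta_path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path, snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Plain TSV dosage matrix: header of SNP ids, first column
    sample_id, cells in {0,1,2,NA}. A sidecar ``<path>.snps.tsv`` (or an
    explicit ``snp_meta``) supplies chrom/pos/alleles; without one,
    placeholder metadata is synthesized."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id', got '{df.columns[0]}'")
    samples = df["sample_id"].tolist()
    body = df.drop(columns="sample_id")
    calls = np.full(body.shape, MISSING, dtype=np.int8)
    for i, col in enumerate(body.columns):
        vals = body[col].to_numpy()
        for r, v in enumerate(vals):
            if v == "NA" or v is np.nan or (isinstance(v, float) and np.isnan(v)):
                continue
            if v not in ("0", "1", "2"):
                raise ValueError(f"{path}: line {r + 2}: bad genotype value '{v}' for {col}")
            calls[r, i] = int(v)
    if snp_meta is None:
        sidecar = Path(path).with_suffix(".snps.tsv")
        if sidecar.exists():
            snp_meta = pd.read_csv(sidecar, sep="\t")
        else:
            snp_meta = pd.DataFrame({
                "snp_id": body.columns, "chrom": "chr1",
                "pos": np.arange(1, body.shape[1] + 1), "ref": "A", "alt": "G",
            })
    return GenotypeMatrix(calls, snp_meta, samples)


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on format (``vcf``/``tsv``; inferred from the suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("vcf" if path.suffix in (".vcf", ".gz") else "tsv")
    return read_vcf(path) if fmt == "vcf" else read_genotype_tsv(path)


# ---------------------------------------------------------------------------
# gene sets, eSNP map, phenotypes

def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: name <tab> description <tab> gene ids. Duplicate set names
    are an error; duplicate genes within a set collapse with a warning."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: GMT rows need name, description, >=1 gene")
            name, genes = parts[0], parts[2:]
            if name in sets:
                raise ValueError(f"{path}: line {ln}: duplicate set name '{name}'")
            uniq = list(dict.fromkeys(g for g in genes if g))
            if len(uniq) < len([g for g in genes if g]):
                logger.warning("set %s: duplicate genes collapsed", name)
            if not uniq:
                raise ValueError(f"{path}: line {ln}: set '{name}' is empty")
            sets[name] = uniq
    return sets


def write_esnp_map(esnp_map: pd.DataFrame, path: str | Path) -> None:
    esnp_map.to_csv(path, sep="\t", index=False)


def read_esnp_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "snp_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: eSNP map missing required column '{col}'")
    if "tissue_label" not in df.columns:
        df["tissue_label"] = "unknown"
    n_dup = int(df.duplicated(["gene_id", "snp_id"]).sum())
    if n_dup:
        logger.info("collapsed %d duplicate (gene, snp) records", n_dup)
        df = df.drop_duplicates(["gene_id", "snp_id"])
    return df.reset_index(drop=True)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", na_rep="NA")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("sample_id", "status"):
        if col not in df.columns:
            raise ValueError(f"{path}: phenotype table missing required column '{col}'")
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# result tables with provenance headers

def write_table(df: pd.DataFrame, path: str | Path, config: dict | None = None,
                seed: int | None = None) -> None:
    """TSV with commented provenance header (version, config hash, seed)."""
    cfg_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    with open(path, "w") as fh:
        fh.write(f"# gwaskit {__version__}\n")
        fh.write(f"# config_sha256 {cfg_hash}\n")
        fh.write(f"# seed {seed if seed is not None else 'NA'}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
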
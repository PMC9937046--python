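"""Readers and writers for the pipeline's tabular and genomic formats.

Allele counts travel as a wide TSV (one row per SNP, two columns per
library: ``<sample>:REF`` and ``<sample>:ALT``) or as a VCF with per-sample
allelic depths (``AD``).  Sample metadata, truth labels and clone matrices
are plain TSV; gene models are GFF3.  All SNP coordinates are 1-based (VCF
convention); BED repeat intervals are 0-based half-open.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

META_COLUMNS = ["sample_id", "role", "stock", "dam_stock", "sire_stock",
                "tissue", "generation", "sex"]
COUNT_KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]


def sample_columns(sample_ids) -> list[str]:
    cols = []
    for sid in sample_ids:
        cols.extend([f"{sid}:REF", f"{sid}:ALT"])
    return cols


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"sample_id", "role", "tissue"} - set(meta.columns)
    if missing:
        raise ValueError(f"sample sheet missing required columns: {sorted(missing)}")
    for col in META_COLUMNS:
        if col not in meta.columns:
            meta[col] = ""
    bad = meta.loc[(meta["role"] == "f1")
                   & ((meta["dam_stock"] == "") | (meta["sire_stock"] == "")), "sample_id"]
    if len(bad):
        raise ValueError(f"f1 samples missing dam_stock/sire_stock: {bad.tolist()}")
    return meta[META_COLUMNS]


def load_allele_counts(path, sample_sheet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load a wide allele-count TSV plus its sample sheet.

    Validates the schema against the declared samples, enforces integer
    counts, and rejects duplicated (chrom, pos) rows.
    """
    meta = sample_sheet if isinstance(sample_sheet, pd.DataFrame) else read_sample_sheet(sample_sheet)
    counts = pd.read_csv(path, sep="\t")
    missing = set(COUNT_KEY_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"allele-count table missing columns: {sorted(missing)}")
    expected = sample_columns(meta["sample_id"])
    missing = set(expected) - set(counts.columns)
    if missing:
        raise ValueError(f"allele-count table missing sample columns: {sorted(missing)}")
    for col in expected:
        values = counts[col]
        if not np.issubdtype(values.dtype, np.integer):
            as_float = pd.to_numeric(values, errors="raise")
            if not np.all(np.mod(as_float, 1) == 0):
                raise ValueError(f"non-integer counts in column {col}")
            counts[col] = as_float.astype(np.int64)
        if (counts[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    dup = counts.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        first = counts.loc[dup, ["chrom", "pos"]].iloc[0]
        raise ValueError(f"duplicated SNP position {first['chrom']}:{first['pos']}")
    return counts[COUNT_KEY_COLUMNS + expected], meta


def read_vcf_counts(path, sample_ids=None) -> pd.DataFrame:
    """Read per-sample allelic depths from a VCF into the wide count table.

    Uses the FORMAT ``AD`` field (reference depth first, as emitted by
    standard callers).  Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples) if sample_ids is None else list(sample_ids)
    rows = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS}; split it first"
            )
        ad = variant.format("AD")
        if ad is None:
            raise ValueError(f"no AD field at {variant.CHROM}:{variant.POS}")
        row = {"chrom": variant.CHROM, "pos": variant.POS,
               "ref": variant.REF, "alt": variant.ALT[0]}
        for i, sid in enumerate(vcf.samples):
            if sid not in samples:
                continue
            ref_d, alt_d = int(ad[i, 0]), int(ad[i, 1])
            row[f"{sid}:REF"] = max(ref_d, 0)
            row[f"{sid}:ALT"] = max(alt_d, 0)
        rows.append(row)
    counts = pd.DataFrame(rows)
    dup = counts.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        first = counts.loc[dup, ["chrom", "pos"]].iloc[0]
        raise ValueError(f"duplicated SNP position {first['chrom']}:{first['pos']}")
    return counts


def read_bed_intervals(path) -> dict[str, np.ndarray]:
    """Read a BED file into per-chromosome sorted (start, end) arrays.

    Intervals are 0-based half-open.  Unsorted input is sorted with a
    warning; overlapping intervals are merged.
    """
    bed = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                      names=["chrom", "start", "end"], comment="#")
    out: dict[str, np.ndarray] = {}
    for chrom, grp in bed.groupby("chrom", sort=False):
        arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
        if not np.all(np.diff(arr[:, 0]) >= 0):
            warnings.warn(f"unsorted BED intervals on {chrom}; sorting", stacklevel=2)
            arr = arr[np.argsort(arr[:, 0], kind="stable")]
        merged = []
        for start, end in arr:
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        out[str(chrom)] = np.asarray(merged, dtype=np.int64)
    return out


def write_gff3(genes: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    """Write gene models (1-based inclusive coordinates) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        exon_groups = {g: grp for g, grp in exons.groupby("gene_id", sort=False)}
        for _, gene in genes.iterrows():
            strand = gene.get("strand", "+")
            fh.write("\t".join([
                str(gene["chrom"]), "imprintase", "gene", str(gene["start"]),
                str(gene["end"]), ".", strand, ".", f"ID={gene['gene_id']}",
            ]) + "\n")
            for i, (_, exon) in enumerate(exon_groups.get(gene["gene_id"], pd.DataFrame()).iterrows(), 1):
                fh.write("\t".join([
                    str(exon["chrom"]), "imprintase", "exon", str(exon["start"]),
                    str(exon["end"]), ".", strand, ".",
                    f"ID={gene['gene_id']}.exon{i};Parent={gene['gene_id']}",
                ]) + "\n")


def read_gff3(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read gene and exon features back from a GFF3 file."""
    rows = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "frame", "attributes"],
        dtype={"chrom": str},
    )

    def attr(text: str, key: str) -> str:
        for part in text.split(";"):
            if part.startswith(key + "="):
                return part[len(key) + 1:]
        return ""

    genes = rows[rows["type"] == "gene"].copy()
    genes["gene_id"] = genes["attributes"].map(lambda a: attr(a, "ID"))
    exons = rows[rows["type"] == "exon"].copy()
    exons["gene_id"] = exons["attributes"].map(lambda a: attr(a, "Parent"))
    return (genes[["gene_id", "chrom", "start", "end", "strand"]].reset_index(drop=True),
            exons[["gene_id", "chrom", "start", "end"]].reset_index(drop=True))


def read_clone_matrix(path) -> pd.DataFrame:
    """Read a clone-by-CpG matrix TSV with M/U/. calls."""
    clones = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "clone_id" not in clones.columns:
        raise ValueError("clone matrix must have a clone_id column")
    if "allele_tag" not in clones.columns:
        clones.insert(1, "allele_tag", "unknown")
    cpg_cols = [c for c in clones.columns if c not in ("clone_id", "allele_tag")]
    if not cpg_cols:
        raise ValueError("clone matrix has no CpG columns")
    bad = ~clones[cpg_cols].isin(["M", "U", "."]).all(axis=None)
    if bad:
        raise ValueError("clone matrix calls must be one of M, U, .")
    return clones


def write_clone_matrix(clones: pd.DataFrame, path) -> None:
    clones.to_csv(path, sep="\t", index=False)
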
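"""Per-SNP allelic ratios and gene-level parent-of-origin summaries.

For each F1 library, the reference-allele fraction at an informative SNP is
the reference read count over total depth; the maternal fraction follows
from the SNP's origin map for that library's cross direction.  Gene-level
summaries pool raw counts (depth-weighted) over all informative SNPs and
F1 libraries within each cross direction, yielding

* ``p1`` — LL1-allele fraction in the LL1(dam) x LL2(sire) cross, and
* ``p2`` — LL1-allele fraction in the reciprocal LL2 x LL1 cross.

Under this orientation the maternal fraction is ``p1`` in direction 1 and
``1 - p2`` in direction 2: an imprinted gene shows a flipped pattern
(maternal fraction high or low in *both* directions), while a cis-eQTL
gene's LL1 bias stays on the same side of 0.5 in both.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DIR1, DIR2 = "LL1xLL2", "LL2xLL1"


def direction_label(dam_stock: str, sire_stock: str) -> str:
    return f"{dam_stock}x{sire_stock}"


def snp_allelic_ratios(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    informative: pd.DataFrame,
    min_depth: int = 8,
) -> pd.DataFrame:
    """Long table of per-SNP, per-F1-library allelic ratios.

    Libraries below ``min_depth`` at a SNP are absent (not zero).  Columns:
    chrom, pos, sample_id, tissue, direction, ref_count, alt_count, depth,
    ref_fraction, maternal_fraction, ll1_count.
    """
    f1 = meta[meta["role"] == "f1"]
    merged = informative.merge(counts, on=["chrom", "pos", "ref", "alt"], how="left")
    frames = []
    for _, sample in f1.iterrows():
        sid = sample["sample_id"]
        direction = direction_label(sample["dam_stock"], sample["sire_stock"])
        ref_c = merged[f"{sid}:REF"].to_numpy(dtype=np.int64)
        alt_c = merged[f"{sid}:ALT"].to_numpy(dtype=np.int64)
        depth = ref_c + alt_c
        keep = depth >= min_depth
        if not keep.any():
            continue
        maternal_allele = merged[f"maternal_allele_{direction}"].to_numpy()[keep]
        ref_k, alt_k, depth_k = ref_c[keep], alt_c[keep], depth[keep]
        maternal_count = np.where(maternal_allele == "ref", ref_k, alt_k)
        ll1_count = np.where(merged["ll1_allele"].to_numpy()[keep] == "ref", ref_k, alt_k)
        frames.append(pd.DataFrame({
            "chrom": merged["chrom"].to_numpy()[keep],
            "pos": merged["pos"].to_numpy()[keep],
            "sample_id": sid,
            "tissue": sample["tissue"],
            "direction": direction,
            "ref_count": ref_k,
            "alt_count": alt_k,
            "depth": depth_k,
            "ref_fraction": ref_k / depth_k,
            "maternal_fraction": maternal_count / depth_k,
            "ll1_count": ll1_count,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "sample_id", "tissue", "direction",
                                     "ref_count", "alt_count", "depth", "ref_fraction",
                                     "maternal_fraction", "ll1_count"])
    return pd.concat(frames, ignore_index=True)


def assign_genes(snps: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Map each SNP to a gene by position within the gene interval.

    A SNP covered by several gene models is assigned to the lexicographically
    first gene_id (ties between equal point overlaps), with a warning.
    """
    assigned = pd.Series(pd.NA, index=snps.index, dtype="object")
    n_ambiguous = 0
    for chrom, grp in genes.groupby("chrom", sort=False):
        sel = snps["chrom"].astype(str) == str(chrom)
        if not sel.any():
            continue
        pos = snps.loc[sel, "pos"].to_numpy(dtype=np.int64)
        best = np.full(pos.shape, None, dtype=object)
        hits = np.zeros(pos.shape, dtype=np.int64)
        for _, gene in grp.sort_values("gene_id").iterrows():
            inside = (pos >= gene["start"]) & (pos <= gene["end"])
            hits += inside
            fill = inside & (best == None)  # noqa: E711  - elementwise
            best[fill] = gene["gene_id"]
        n_ambiguous += int((hits > 1).sum())
        assigned.loc[sel] = best
    if n_ambiguous:
        warnings.warn(f"{n_ambiguous} SNPs overlap multiple gene models; "
                      "assigned lexicographically", stacklevel=2)
    return assigned


def aggregate_genes(ratios: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Pool per-SNP counts to gene x tissue allelic summaries.

    Pools raw LL1-allele and total counts over all informative SNPs and F1
    libraries within each cross direction (depth-weighted), then computes
    p1/p2 and the per-direction maternal fractions from the pooled counts.
    Genes with no informative SNPs are absent.
    """
    if not len(ratios):
        return pd.DataFrame(columns=[
            "gene_id", "tissue", "p1", "p2", "maternal_fraction_dir1",
            "maternal_fraction_dir2", "n_informative_snps",
            "pooled_depth_dir1", "pooled_depth_dir2"])
    ratios = ratios.copy()
    if "gene_id" not in ratios.columns:
        ratios["gene_id"] = assign_genes(ratios, genes).to_numpy()
    ratios = ratios[ratios["gene_id"].notna()]

    rows = []
    for (gene_id, tissue), grp in ratios.groupby(["gene_id", "tissue"], sort=True):
        rec = {"gene_id": gene_id, "tissue": tissue,
               "n_informative_snps": grp[["chrom", "pos"]].drop_duplicates().shape[0]}
        for dname, key in ((DIR1, "dir1"), (DIR2, "dir2")):
            sub = grp[grp["direction"] == dname]
            depth = int(sub["depth"].sum())
            rec[f"pooled_depth_{key}"] = depth
            p = float(sub["ll1_count"].sum()) / depth if depth else np.nan
            rec[f"p_{key}"] = p
        rec["p1"], rec["p2"] = rec.pop("p_dir1"), rec.pop("p_dir2")
        rec["maternal_fraction_dir1"] = rec["p1"]
        rec["maternal_fraction_dir2"] = 1.0 - rec["p2"] if not np.isnan(rec["p2"]) else np.nan
        rows.append(rec)
    out = pd.DataFrame(rows)
    cols = ["gene_id", "tissue", "p1", "p2", "maternal_fraction_dir1",
            "maternal_fraction_dir2", "n_informative_snps",
            "pooled_depth_dir1", "pooled_depth_dir2"]
    return out[cols]


def per_sample_gene_fractions(ratios: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per gene x tissue x F1-library maternal fraction (pooled over SNPs)."""
    ratios = ratios.copy()
    if "gene_id" not in ratios.columns:
        ratios["gene_id"] = assign_genes(ratios, genes).to_numpy()
    ratios = ratios[ratios["gene_id"].notna()].copy()
    ratios["maternal_count"] = (ratios["maternal_fraction"] * ratios["depth"]).round().astype(int)
    grouped = ratios.groupby(["gene_id", "tissue", "sample_id"], sort=True).agg(
        maternal_count=("maternal_count", "sum"), depth=("depth", "sum")).reset_index()
    grouped["maternal_fraction"] = grouped["maternal_count"] / grouped["depth"]
    return grouped[["gene_id", "tissue", "sample_id", "maternal_fraction", "depth"]]


def expression_gate(
    gene_ase: pd.DataFrame,
    expression: pd.DataFrame,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Flag genes as expression-detected (FPKM >= threshold) per tissue.

    Genes without an expression value get a missing flag with a warning;
    they remain callable downstream.
    """
    out = gene_ase.merge(expression[["gene_id", "tissue", "fpkm"]],
                         on=["gene_id", "tissue"], how="left")
    missing = out["fpkm"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} gene x tissue records lack an "
                      "expression value; detection flag left unknown", stacklevel=2)
    detected = pd.array(out["fpkm"] >= threshold, dtype="boolean")
    detected[missing.to_numpy()] = pd.NA
    out["expression_detected"] = detected
    return out
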
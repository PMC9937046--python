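"""Flipped-ratio imprinting classifier with a cis-eQTL guard.

A gene is called maternally expressed (MEG) when the LL1-allele fraction is
high in the LL1(dam) x LL2 cross and low in the reciprocal (p1 > 0.65 and
p2 < 0.35 by default) — the allelic bias *flips* with the cross direction,
which is the signature of a parent-of-origin effect.  Paternally expressed
(PEG) is the mirror image.  Genes biased to the same side of 0.5 in both
directions are cis-eQTL patterns and are never called imprinted.  Genes on
unplaced or X scaffolds whose expression is essentially 100% maternal in
every covered library are re-flagged as imprinted-XCI candidates and kept
out of autosomal summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

STATUSES = ("MEG", "PEG", "biallelic", "undetermined", "xci_candidate", "not_detectable")
DEFAULT_XCI_CHROMS = ("chrUn", "chrX")


@dataclass
class CallerConfig:
    """Thresholds for the flipped-ratio caller.

    ``upper``/``lower`` bound the allelic-imbalance cutoffs (lower must be
    1 - upper); comparisons are strict by default, so boundary values fall
    through to biallelic/undetermined.  ``xci_maternal_min`` tolerates
    single stray reads when testing for 100% maternal expression.
    """

    upper: float = 0.65
    lower: float = 0.35
    xci_maternal_min: float = 0.99
    strict_inequality: bool = True

    def validate(self) -> None:
        if not (0.5 < self.upper < 1.0):
            raise ValueError("upper must be in (0.5, 1)")
        if abs(self.lower - (1.0 - self.upper)) > 1e-12:
            raise ValueError("lower must equal 1 - upper")
        if not (0.0 <= self.xci_maternal_min <= 1.0):
            raise ValueError("xci_maternal_min must be in [0, 1]")


def call_genes(gene_ase: pd.DataFrame, cfg: CallerConfig | None = None) -> pd.DataFrame:
    """Classify every gene x tissue record as MEG/PEG/biallelic/undetermined.

    Records whose expression gate failed are ``not_detectable``; a missing
    direction gives ``undetermined``.  Mixed patterns (one direction
    extreme, one central) and same-side cis-eQTL patterns are
    ``undetermined`` — only a flipped pattern is positively imprinted.
    """
    cfg = cfg or CallerConfig()
    cfg.validate()
    p1 = gene_ase["p1"].to_numpy(dtype=float)
    p2 = gene_ase["p2"].to_numpy(dtype=float)
    if cfg.strict_inequality:
        hi1, lo1 = p1 > cfg.upper, p1 < cfg.lower
        hi2, lo2 = p2 > cfg.upper, p2 < cfg.lower
    else:
        hi1, lo1 = p1 >= cfg.upper, p1 <= cfg.lower
        hi2, lo2 = p2 >= cfg.upper, p2 <= cfg.lower
    meg = hi1 & lo2
    peg = lo1 & hi2
    central1 = (p1 >= cfg.lower) & (p1 <= cfg.upper)
    central2 = (p2 >= cfg.lower) & (p2 <= cfg.upper)
    biallelic = central1 & central2 & ~meg & ~peg
    missing = np.isnan(p1) | np.isnan(p2)

    if "expression_detected" in gene_ase.columns:
        not_detect = gene_ase["expression_detected"].to_numpy(dtype=object) == False  # noqa: E712
    else:
        not_detect = np.zeros(len(gene_ase), dtype=bool)

    status = np.select(
        [not_detect, missing, meg, peg, biallelic],
        ["not_detectable", "undetermined", "MEG", "PEG", "biallelic"],
        default="undetermined",
    )
    flipped = (meg | peg) & ~not_detect & ~missing

    mat1 = gene_ase.get("maternal_fraction_dir1", pd.Series(p1)).to_numpy(dtype=float)
    mat2 = gene_ase.get("maternal_fraction_dir2", pd.Series(1.0 - p2)).to_numpy(dtype=float)
    expressed_parent = np.select([status == "MEG", status == "PEG"],
                                 ["maternal", "paternal"], default="none")
    frac1 = np.select([status == "MEG", status == "PEG"], [mat1, 1.0 - mat1], default=np.nan)
    frac2 = np.select([status == "MEG", status == "PEG"], [mat2, 1.0 - mat2], default=np.nan)

    out = gene_ase[["gene_id", "tissue"]].copy()
    out["status"] = status
    out["expressed_parent"] = expressed_parent
    out["expressed_parent_fraction_dir1"] = frac1
    out["expressed_parent_fraction_dir2"] = frac2
    out["flipped"] = flipped
    out["p1"] = p1
    out["p2"] = p2
    n_snps = gene_ase.get("n_informative_snps", pd.Series([np.nan] * len(gene_ase)))
    d1 = gene_ase.get("pooled_depth_dir1", pd.Series([np.nan] * len(gene_ase)))
    d2 = gene_ase.get("pooled_depth_dir2", pd.Series([np.nan] * len(gene_ase)))
    out["evidence"] = [
        f"n_snps={s}; depth_dir1={a}; depth_dir2={b}"
        for s, a, b in zip(n_snps, d1, d2)
    ]
    return out


def call_gene(p1: float, p2: float, cfg: CallerConfig | None = None,
              expression_detected: bool = True) -> str:
    """Scalar convenience wrapper around :func:`call_genes`."""
    frame = pd.DataFrame({"gene_id": ["g"], "tissue": ["t"], "p1": [p1], "p2": [p2],
                          "expression_detected": [expression_detected]})
    return call_genes(frame, cfg)["status"].iloc[0]


def flag_xci_candidates(
    calls: pd.DataFrame,
    gene_chroms: pd.DataFrame,
    cfg: CallerConfig | None = None,
    per_sample_maternal: pd.DataFrame | None = None,
    xci_chroms: tuple = DEFAULT_XCI_CHROMS,
) -> pd.DataFrame:
    """Re-label near-100%-maternal genes on unplaced/X scaffolds.

    A MEG call on an ``xci_chroms`` scaffold becomes ``xci_candidate`` when
    the maternal fraction reaches ``cfg.xci_maternal_min`` in every covered
    F1 library (or, without per-library data, in both pooled directions).
    Candidates below the threshold stay MEG with a warning.
    """
    cfg = cfg or CallerConfig()
    chrom_map = dict(zip(gene_chroms["gene_id"], gene_chroms["chrom"].astype(str)))
    out = calls.copy()
    for idx, row in out.iterrows():
        if row["status"] != "MEG" or chrom_map.get(row["gene_id"]) not in xci_chroms:
            continue
        if per_sample_maternal is not None:
            sub = per_sample_maternal[
                (per_sample_maternal["gene_id"] == row["gene_id"])
                & (per_sample_maternal["tissue"] == row["tissue"])]
            fractions = sub["maternal_fraction"].to_numpy(dtype=float)
        else:
            fractions = np.array([row["expressed_parent_fraction_dir1"],
                                  row["expressed_parent_fraction_dir2"]], dtype=float)
        fractions = fractions[~np.isnan(fractions)]
        if len(fractions) and np.all(fractions >= cfg.xci_maternal_min):
            out.loc[idx, "status"] = "xci_candidate"
        else:
            warnings.warn(
                f"{row['gene_id']} ({row['tissue']}) on an XCI scaffold but below "
                f"the {cfg.xci_maternal_min:.0%} maternal threshold; kept as MEG",
                stacklevel=2)
    return out


def summarize_calls(calls: pd.DataFrame) -> dict:
    """Per-tissue imprinting counts and cross-tissue concordance.

    ``imprinted_both`` lists genes MEG/PEG in every tissue; genes imprinted
    in one tissue split by whether the other tissue was undetectable.
    """
    tissues = sorted(calls["tissue"].unique()) if len(calls) else []
    per_tissue = {}
    for tissue in tissues:
        sub = calls[calls["tissue"] == tissue]
        counts = {s: int((sub["status"] == s).sum()) for s in STATUSES}
        per_tissue[tissue] = counts
    imprinted = calls[calls["status"].isin(["MEG", "PEG"])]
    by_gene = imprinted.groupby("gene_id")["tissue"].nunique() if len(imprinted) else pd.Series(dtype=int)
    both, single_nd, single_other = [], [], []
    for gene_id in sorted(by_gene.index):
        if by_gene[gene_id] == len(tissues) and len(tissues) > 1:
            both.append(gene_id)
        elif len(tissues) > 1:
            others = calls[(calls["gene_id"] == gene_id) & ~calls["status"].isin(["MEG", "PEG"])]
            if len(others) and (others["status"] == "not_detectable").all():
                single_nd.append(gene_id)
            else:
                single_other.append(gene_id)
        else:
            both.append(gene_id)
    return {
        "per_tissue": per_tissue,
        "imprinted_by_tissue": {
            t: sorted(imprinted.loc[imprinted["tissue"] == t, "gene_id"]) for t in tissues},
        "imprinted_both": both,
        "imprinted_single_not_detectable": single_nd,
        "imprinted_single_discordant": single_other,
    }
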
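"""Candidate-SNP discovery, stock genotyping, informativeness, and masking.

The reciprocal-cross design only tracks parental origin at *informative*
SNPs: sites where the two stocks are fixed for opposite alleles, so every
F1 read is unambiguously maternal or paternal.  Discovery keeps sites with
pooled depth >= 40 across all libraries; stock genotypes are inferred from
the purebred parental libraries (optionally overridden by a known-genotype
table standing in for Sanger confirmation); informative sites additionally
need each stock's allele seen at >= 8x and coverage in at least three of
the four F1 libraries.  Sites inside repeat intervals or near exon-intron
junctions are masked out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io

DIRECTIONS = ("LL1xLL2", "LL2xLL1")

#: sequencing-error tolerance for calling a stock homozygous
HOM_MAX_MINOR_FRACTION = 0.05


def _pool(counts: pd.DataFrame, sample_ids, allele: str) -> np.ndarray:
    cols = [f"{sid}:{allele}" for sid in sample_ids]
    if not cols:
        return np.zeros(len(counts), dtype=np.int64)
    return counts[cols].to_numpy(dtype=np.int64).sum(axis=1)


def discover_candidate_snps(counts: pd.DataFrame, min_pooled_depth: int = 40) -> pd.DataFrame:
    """Keep SNPs whose depth pooled over every library is >= the cutoff."""
    sids = [c[:-4] for c in counts.columns if c.endswith(":REF")]
    pooled = _pool(counts, sids, "REF") + _pool(counts, sids, "ALT")
    return counts.loc[pooled >= min_pooled_depth].reset_index(drop=True)


def genotype_stocks(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    min_depth: int = 8,
    het_min_minor_fraction: float = 0.20,
    hom_max_minor_fraction: float = HOM_MAX_MINOR_FRACTION,
) -> pd.DataFrame:
    """Call each stock's genotype at every SNP from pooled parental counts.

    A stock is ``unknown`` below ``min_depth``; homozygous when the minor
    allele is at most ``hom_max_minor_fraction`` of reads; heterozygous
    when it reaches ``het_min_minor_fraction``; ``unknown`` in between.
    """
    parental = meta[meta["role"] == "parental"]
    out = counts[["chrom", "pos", "ref", "alt"]].copy()
    for stock in ("LL1", "LL2"):
        sids = parental.loc[parental["stock"] == stock, "sample_id"].tolist()
        if not sids:
            raise ValueError(f"no parental samples for stock {stock}")
        ref = _pool(counts, sids, "REF")
        alt = _pool(counts, sids, "ALT")
        depth = ref + alt
        with np.errstate(invalid="ignore", divide="ignore"):
            minor = np.minimum(ref, alt) / np.where(depth > 0, depth, 1)
        genotype = np.select(
            [depth < min_depth,
             minor <= hom_max_minor_fraction,
             minor >= het_min_minor_fraction],
            ["unknown",
             np.where(ref >= alt, "ref_hom", "alt_hom"),
             "het"],
            default="unknown",
        )
        key = stock.lower()
        out[f"{key}_genotype"] = genotype
        out[f"{key}_ref"] = ref
        out[f"{key}_alt"] = alt
    return out


def apply_genotype_override(genotypes: pd.DataFrame, override: pd.DataFrame) -> pd.DataFrame:
    """Replace inferred stock genotypes with externally confirmed ones.

    ``override`` carries chrom, pos and any of ll1_genotype/ll2_genotype;
    it stands in for Sanger confirmation of RNA-called genotypes.
    """
    out = genotypes.copy()
    merged = out.merge(override, on=["chrom", "pos"], how="left",
                       suffixes=("", "_override"))
    for key in ("ll1_genotype", "ll2_genotype"):
        col = f"{key}_override"
        if col in merged.columns:
            confirmed = merged[col].notna()
            out.loc[confirmed.to_numpy(), key] = merged.loc[confirmed, col].to_numpy()
    return out


def assess_informativeness(
    genotypes: pd.DataFrame,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    min_f1_covered: int = 3,
    min_depth: int = 8,
) -> pd.DataFrame:
    """Classify SNPs as informative and assign parental origin per direction.

    Informative requires the stocks to be opposite homozygotes, each stock's
    own allele covered at >= ``min_depth`` in its parental libraries, and at
    least ``min_f1_covered`` of the F1 libraries in ``meta`` at >=
    ``min_depth`` total depth.  The origin map follows the cross direction:
    the LL1 allele is maternal when the dam is LL1 and paternal otherwise.
    """
    merged = genotypes.merge(counts, on=["chrom", "pos", "ref", "alt"], how="inner")
    ll1_g = merged["ll1_genotype"].to_numpy()
    ll2_g = merged["ll2_genotype"].to_numpy()
    opposite = ((ll1_g == "ref_hom") & (ll2_g == "alt_hom")) | (
        (ll1_g == "alt_hom") & (ll2_g == "ref_hom"))

    ll1_allele = np.where(ll1_g == "ref_hom", "ref", "alt")
    ll1_own = np.where(ll1_allele == "ref", merged["ll1_ref"], merged["ll1_alt"])
    ll2_own = np.where(ll1_allele == "ref", merged["ll2_alt"], merged["ll2_ref"])
    parental_ok = (ll1_own >= min_depth) & (ll2_own >= min_depth)

    f1 = meta[meta["role"] == "f1"]
    covered = np.zeros(len(merged), dtype=np.int64)
    for sid in f1["sample_id"]:
        depth = merged[f"{sid}:REF"].to_numpy() + merged[f"{sid}:ALT"].to_numpy()
        covered += depth >= min_depth
    f1_ok = covered >= min_f1_covered

    keep = opposite & parental_ok & f1_ok
    out = merged.loc[keep, ["chrom", "pos", "ref", "alt"]].copy()
    out["ll1_allele"] = ll1_allele[keep]
    # dam LL1 in LL1xLL2: LL1 allele is maternal; flipped in the reciprocal
    out["maternal_allele_LL1xLL2"] = out["ll1_allele"]
    out["maternal_allele_LL2xLL1"] = np.where(out["ll1_allele"] == "ref", "alt", "ref")
    out["f1_samples_covered"] = covered[keep]
    return out.reset_index(drop=True)


@dataclass
class MaskSet:
    """Repeat intervals and exon-junction exclusion zones.

    ``repeat_intervals`` maps chrom to a sorted, merged (n, 2) array of
    0-based half-open intervals; ``exon_boundaries`` maps chrom to sorted
    1-based positions of exon edges that abut an intron.  SNPs inside a
    repeat or within ``boundary_distance`` bp of a junction are excluded.
    """

    repeat_intervals: dict = field(default_factory=dict)
    exon_boundaries: dict = field(default_factory=dict)
    boundary_distance: int = 5

    @classmethod
    def from_inputs(cls, repeats_bed=None, exons: pd.DataFrame | None = None,
                    boundary_distance: int = 5) -> "MaskSet":
        repeats = io.read_bed_intervals(repeats_bed) if repeats_bed is not None else {}
        boundaries: dict[str, np.ndarray] = {}
        if exons is not None and len(exons):
            points: dict[str, list[int]] = {}
            for _, grp in exons.groupby("gene_id", sort=False):
                grp = grp.sort_values("start")
                chrom = str(grp["chrom"].iloc[0])
                # internal edges only: last base of each exon but the final
                # one, first base of each exon but the first
                ends = grp["end"].to_numpy()[:-1]
                starts = grp["start"].to_numpy()[1:]
                points.setdefault(chrom, []).extend(ends.tolist())
                points.setdefault(chrom, []).extend(starts.tolist())
            boundaries = {c: np.unique(np.asarray(p, dtype=np.int64))
                          for c, p in points.items()}
        return cls(repeat_intervals=repeats, exon_boundaries=boundaries,
                   boundary_distance=boundary_distance)


def apply_masks(snps: pd.DataFrame, masks: MaskSet) -> tuple[pd.DataFrame, dict]:
    """Drop SNPs in repeats or near exon-intron junctions.

    Returns the filtered table and a tally of removals per rule.
    """
    if not len(snps):
        return snps.copy(), {"removed_repeat": 0, "removed_boundary": 0}
    pos = snps["pos"].to_numpy(dtype=np.int64)
    chroms = snps["chrom"].astype(str).to_numpy()

    in_repeat = np.zeros(len(snps), dtype=bool)
    for chrom, intervals in masks.repeat_intervals.items():
        sel = chroms == chrom
        if not sel.any() or not len(intervals):
            continue
        pos0 = pos[sel] - 1  # 1-based SNP -> 0-based point
        idx = np.searchsorted(intervals[:, 0], pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < intervals[np.clip(idx, 0, None), 1])
        in_repeat[np.flatnonzero(sel)[inside]] = True

    near_boundary = np.zeros(len(snps), dtype=bool)
    for chrom, points in masks.exon_boundaries.items():
        sel = chroms == chrom
        if not sel.any() or not len(points):
            continue
        p = pos[sel]
        idx = np.searchsorted(points, p)
        dist = np.full(p.shape, np.iinfo(np.int64).max, dtype=np.int64)
        right_ok = idx < len(points)
        dist[right_ok] = np.abs(points[idx[right_ok]] - p[right_ok])
        left_ok = idx > 0
        dist[left_ok] = np.minimum(dist[left_ok], np.abs(p[left_ok] - points[idx[left_ok] - 1]))
        near_boundary[np.flatnonzero(sel)[dist <= masks.boundary_distance]] = True

    near_boundary &= ~in_repeat  # tally each SNP once
    keep = ~(in_repeat | near_boundary)
    log = {"removed_repeat": int(in_repeat.sum()),
           "removed_boundary": int(near_boundary.sum())}
    return snps.loc[keep].reset_index(drop=True), log
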
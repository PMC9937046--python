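"""Bisulfite clone methylation calling and promoter DMR classification.

After sodium-bisulfite treatment, unmethylated cytosines read as thymine
while methylated CpG cytosines stay cytosine, so each cloned molecule gives
a per-CpG methylation vector.  Clones may carry a parent-of-origin tag from
a linked SNP inside the amplicon.  A promoter CpG island whose aggregate
methylation sits near 50% with the two parental alleles at opposite
extremes is the hallmark of a differentially methylated region (DMR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: clones with a non-CpG cytosine conversion rate below this are excluded
MIN_CONVERSION_RATE = 0.95


@dataclass
class BisulfiteClone:
    """One cloned molecule's ordered CpG calls (M / U / missing ``.``)."""

    clone_id: str
    calls: list = field(default_factory=list)
    allele_tag: str = "unknown"  # maternal / paternal / unknown
    non_cpg_conversion_rate: float | None = None
    excluded: bool = False


def find_cpg_sites(reference: str) -> list[int]:
    """0-based positions of CpG cytosines in the reference region."""
    ref = reference.upper()
    return [i for i in range(len(ref) - 1) if ref[i: i + 2] == "CG"]


def call_clone_from_sequence(
    reference: str,
    clone_sequence: str,
    clone_id: str = "clone",
    allele_tag: str = "unknown",
    min_conversion_rate: float = MIN_CONVERSION_RATE,
) -> BisulfiteClone:
    """Call CpG methylation from one bisulfite-converted clone sequence.

    The clone must align end-to-end against the reference in the
    bisulfite-converted frame (reference C may read as C or T; everything
    else must match, ambiguity giving a missing call at CpGs).  At each
    reference CpG: C -> M, T -> U, anything else -> missing.  The fraction
    of converted non-CpG cytosines estimates bisulfite conversion
    completeness; clones below ``min_conversion_rate`` are flagged
    excluded (failed-conversion artifacts masquerade as methylation).
    """
    ref = reference.upper()
    clone = clone_sequence.upper()
    if len(ref) != len(clone):
        raise ValueError(
            f"clone length {len(clone)} != reference length {len(ref)}; "
            "end-to-end alignment required")
    cpg_sites = set(find_cpg_sites(ref))
    calls = []
    converted = unconverted = 0
    for i, (rb, cb) in enumerate(zip(ref, clone)):
        if i in cpg_sites:
            calls.append({"C": "M", "T": "U"}.get(cb, "."))
        elif rb == "C":
            if cb == "T":
                converted += 1
            elif cb == "C":
                unconverted += 1
    total = converted + unconverted
    rate = converted / total if total else None
    excluded = rate is not None and rate < min_conversion_rate
    return BisulfiteClone(clone_id=clone_id, calls=calls, allele_tag=allele_tag,
                          non_cpg_conversion_rate=rate, excluded=excluded)


def clones_from_matrix(matrix: pd.DataFrame) -> list[BisulfiteClone]:
    """Build clones from a clone-by-CpG call matrix (M / U / ``.``)."""
    cpg_cols = [c for c in matrix.columns if c not in ("clone_id", "allele_tag")]
    out = []
    for _, row in matrix.iterrows():
        out.append(BisulfiteClone(
            clone_id=str(row["clone_id"]),
            calls=[row[c] for c in cpg_cols],
            allele_tag=str(row.get("allele_tag", "unknown")),
        ))
    return out


@dataclass
class RegionMethylation:
    """Aggregate promoter methylation: mean over CpG-site percentages."""

    region_id: str
    mean_percent: float
    n_clones: int
    n_cpgs: int
    per_allele_means: tuple | None = None  # (maternal, paternal); None = untagged


def cpg_percentages(
    clones: list[BisulfiteClone],
    region_id: str = "region",
) -> tuple[pd.DataFrame, RegionMethylation | None]:
    """Per-CpG methylation percentages and the region mean.

    Excluded clones never contribute; missing calls are dropped from each
    site's denominator.  Returns ``(site_table, region)``; both empty/None
    when no clone passes the conversion filter.
    """
    included = [c for c in clones if not c.excluded]
    if not included:
        return (pd.DataFrame(columns=["region_id", "index", "percent_methylated", "n_calls"]),
                None)
    n_cpgs = len(included[0].calls)
    if any(len(c.calls) != n_cpgs for c in included):
        raise ValueError("clones disagree on region CpG count")
    rows = []
    fractions = []
    for j in range(n_cpgs):
        m = sum(1 for c in included if c.calls[j] == "M")
        u = sum(1 for c in included if c.calls[j] == "U")
        frac = m / (m + u) if (m + u) else np.nan
        fractions.append(frac)
        rows.append(dict(region_id=region_id, index=j + 1,
                         percent_methylated=100.0 * frac if not np.isnan(frac) else np.nan,
                         n_calls=m + u))
    sites = pd.DataFrame(rows)
    mean = float(np.nanmean(fractions))
    region = RegionMethylation(region_id=region_id, mean_percent=mean,
                               n_clones=len(included), n_cpgs=n_cpgs)
    return sites, region


def partition_by_allele(clones: list[BisulfiteClone]) -> dict:
    """Mean methylation per parental allele over tagged, included clones.

    Untagged clones stay in the region mean but not in the partition.
    Returns a dict with ``maternal``/``paternal`` means (None when that
    allele has no tagged clone) and ``one_sided`` when only one allele is
    represented.
    """
    means = {}
    for tag in ("maternal", "paternal"):
        sub = [c for c in clones if not c.excluded and c.allele_tag == tag]
        calls = [x for c in sub for x in c.calls if x in ("M", "U")]
        means[tag] = (sum(1 for x in calls if x == "M") / len(calls)) if calls else None
    means["one_sided"] = (means["maternal"] is None) != (means["paternal"] is None)
    return means


@dataclass
class DmrCall:
    region_id: str
    classification: str  # DMR / methylated / unmethylated / intermediate_unresolved
    methylated_parent: str = "unknown"  # maternal / paternal / none / unknown


def classify_dmr(
    region: RegionMethylation,
    band: tuple = (0.30, 0.70),
    allele_diff_min: float = 0.40,
    unmethylated_max: float = 0.20,
    methylated_min: float = 0.80,
) -> DmrCall:
    """Classify a promoter CpG island from its aggregate methylation.

    Region means below ``unmethylated_max`` / above ``methylated_min`` are
    plain unmethylated/methylated promoters.  A mean inside ``band`` —
    approximately 50% methylation — is the DMR hallmark, but is only
    confirmed as a DMR when per-allele means differ by at least
    ``allele_diff_min``; otherwise (or without allele tags) it stays
    ``intermediate_unresolved``.
    """
    mean = region.mean_percent
    if mean < unmethylated_max:
        return DmrCall(region.region_id, "unmethylated", "none")
    if mean > methylated_min:
        return DmrCall(region.region_id, "methylated", "unknown")
    if band[0] <= mean <= band[1] and region.per_allele_means is not None:
        mat, pat = region.per_allele_means
        if mat is not None and pat is not None and abs(mat - pat) >= allele_diff_min:
            parent = "maternal" if mat > pat else "paternal"
            return DmrCall(region.region_id, "DMR", parent)
    return DmrCall(region.region_id, "intermediate_unresolved", "unknown")


def analyse_region(
    clones: list[BisulfiteClone],
    region_id: str = "region",
    **classify_kwargs,
) -> tuple[pd.DataFrame, RegionMethylation | None, DmrCall | None]:
    """Full region workflow: percentages, allele partition, DMR call."""
    sites, region = cpg_percentages(clones, region_id=region_id)
    if region is None:
        return sites, None, None
    partition = partition_by_allele(clones)
    if partition["maternal"] is not None or partition["paternal"] is not None:
        region.per_allele_means = (partition["maternal"], partition["paternal"])
    call = classify_dmr(region, **classify_kwargs)
    return sites, region, call


def lollipop(clones: list[BisulfiteClone]) -> str:
    """Text rendering of a clone matrix (``●`` methylated, ``○`` not)."""
    glyph = {"M": "●", "U": "○", ".": " "}
    lines = []
    for c in clones:
        if c.excluded:
            continue
        tag = {"maternal": "mat", "paternal": "pat"}.get(c.allele_tag, "  ?")
        lines.append(f"{c.clone_id:>10} [{tag}] " + "".join(glyph.get(x, " ") for x in c.calls))
    return "\n".join(lines)
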
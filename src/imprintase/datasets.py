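"""Packaged worked-example fixtures.

Two small datasets ship with the package:

* the published table of ten novel imprinted genes (expressed allele and
  allelic percentage per tissue), usable directly as a gene-level ASE
  fixture for the caller; and
* a programmatically built 22-gene candidate fixture reproducing the
  screening outcome in which three candidates (*Matn2*, *Prkaa2*, *Parp4*)
  showed apparently flipped allelic patterns that genotype confirmation
  revealed to be artifacts of SNPs homozygous in the reciprocal F1s,
  leaving 19 candidates.

Chromosome assignments and SNP coordinates in the candidate fixture are
synthetic stand-ins; allelic fractions follow the published per-gene
percentages.  The two unnamed X-linked candidates carry synthetic
placeholder names (``XlncUn1``/``XlncUn2``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FETAL_BRAIN, PLACENTA = "fetal_brain", "placenta"

#: gene, chrom, n informative SNPs, (parent, %) in fetal brain, (parent, %) in placenta
_TABLE1 = [
    ("Ipncr1", "chr1", 3, ("maternal", 95.5), None),
    ("Pou5f3", "chr1", 2, ("paternal", 97.8), ("paternal", 71.6)),
    ("Npdc1", "chr1", 7, ("paternal", 97.7), ("paternal", 90.0)),
    ("Rwdd2a", "chr2", 3, ("paternal", 99.4), ("paternal", 98.6)),
    ("Zfp68", "chr2", 1, ("paternal", 100.0), ("paternal", 100.0)),
    ("Ipncr5", "chr3", 3, ("paternal", 98.1), ("paternal", 97.6)),
    ("Ipncr2", "chr6", 4, ("paternal", 98.6), None),
    ("Nkrfl1", "chr6", 3, ("paternal", 99.9), ("paternal", 100.0)),
    ("Nkrfl2", "chr6", 3, ("paternal", 99.9), ("paternal", 99.7)),
    ("Fam169a", "chr3", 2, ("maternal", 98.6), ("maternal", 94.2)),
]


def table1() -> pd.DataFrame:
    """The ten novel imprinted genes with their printed allelic percentages.

    One row per gene x tissue; ``detectable`` is False where expression was
    below the detection gate in that tissue (``NA`` percentages).
    """
    rows = []
    for gene, chrom, n_snps, fb, eem in _TABLE1:
        for tissue, entry in ((FETAL_BRAIN, fb), (PLACENTA, eem)):
            rows.append(dict(
                gene_id=gene, chrom=chrom, n_informative_snps=n_snps, tissue=tissue,
                expressed_parent=entry[0] if entry else "none",
                expressed_percent=entry[1] if entry else np.nan,
                detectable=entry is not None,
            ))
    return pd.DataFrame(rows)


def table1_gene_ase() -> pd.DataFrame:
    """Gene-level ASE records reconstructed from the printed percentages.

    The published expressed-allele percentage maps to the maternal fraction
    (``pct/100`` for maternal expression, ``1 - pct/100`` for paternal),
    and under the standard orientation ``p1`` equals the maternal fraction
    while ``p2`` equals one minus it.
    """
    rows = []
    for _, row in table1().iterrows():
        if row["detectable"]:
            frac = row["expressed_percent"] / 100.0
            maternal = frac if row["expressed_parent"] == "maternal" else 1.0 - frac
            p1, p2 = maternal, 1.0 - maternal
        else:
            maternal = p1 = p2 = np.nan
        rows.append(dict(
            gene_id=row["gene_id"], tissue=row["tissue"], p1=p1, p2=p2,
            maternal_fraction_dir1=maternal, maternal_fraction_dir2=maternal,
            n_informative_snps=row["n_informative_snps"],
            expression_detected=bool(row["detectable"]),
        ))
    return pd.DataFrame(rows)


#: 22 screening candidates: gene, chrom, apparent maternal fraction in F1s
#: (chromosomes/fractions for the non-tabulated genes are representative)
_CANDIDATES = [
    # previously known imprinted genes
    ("H19", "chr5", 1.00),
    ("Igf2r", "chr2", 0.95),
    ("Peg10", "chr8", 0.00),
    # ten novel autosomal genes (fetal-brain fractions)
    ("Ipncr1", "chr1", 0.955),
    ("Pou5f3", "chr1", 0.022),
    ("Npdc1", "chr1", 0.023),
    ("Rwdd2a", "chr2", 0.006),
    ("Zfp68", "chr2", 0.00),
    ("Ipncr5", "chr3", 0.019),
    ("Ipncr2", "chr6", 0.014),
    ("Nkrfl1", "chr6", 0.001),
    ("Nkrfl2", "chr6", 0.001),
    ("Fam169a", "chr3", 0.986),
    # six 100%-maternal candidates on the unplaced (X-linked) scaffold
    ("Smc6l2", "chrUn", 1.00),
    ("Smc6l4", "chrUn", 1.00),
    ("Ipncr3", "chrUn", 1.00),
    ("Ipncr4", "chrUn", 1.00),
    ("XlncUn1", "chrUn", 1.00),
    ("XlncUn2", "chrUn", 1.00),
    # artifacts: apparently flipped, but the SNPs are homozygous in the F1s
    ("Matn2", "chr3", 1.00),
    ("Prkaa2", "chr2", 0.00),
    ("Parp4", "chr4", 1.00),
]

ARTIFACT_GENES = ("Matn2", "Prkaa2", "Parp4")

_PARENTAL_DEPTH = 15  # per parental library per SNP
_F1_DEPTH = 30


def candidate_fixture() -> dict:
    """Build the 22-gene candidate screening fixture.

    Returns a dict with ``counts`` (wide allele-count table), ``meta``
    (sample sheet; fetal brain only), ``genes`` (gene models),
    ``expression`` (all detected), and ``override`` — the confirmed-genotype
    table marking the three artifact genes' SNPs as segregating in both
    stocks, which removes their informative status.
    """
    meta_rows = []
    for stock in ("LL1", "LL2"):
        for i in (1, 2):
            meta_rows.append(dict(sample_id=f"{stock}_{i}_fb", role="parental",
                                  stock=stock, dam_stock=stock, sire_stock=stock,
                                  tissue=FETAL_BRAIN, generation="P", sex="F"))
    for dam, sire in (("LL1", "LL2"), ("LL2", "LL1")):
        for i in (1, 2):
            meta_rows.append(dict(sample_id=f"F1_{dam}x{sire}_{i}_fb", role="f1",
                                  stock="", dam_stock=dam, sire_stock=sire,
                                  tissue=FETAL_BRAIN, generation="F1", sex="F"))
    meta = pd.DataFrame(meta_rows)

    gene_rows, count_rows, override_rows = [], [], []
    cursor: dict[str, int] = {}
    for gene, chrom, maternal in _CANDIDATES:
        start = cursor.get(chrom, 1)
        cursor[chrom] = start + 5000
        end = start + 999
        gene_rows.append(dict(gene_id=gene, chrom=chrom, start=start, end=end, strand="+"))
        for k, pos in enumerate((start + 100, start + 600)):
            row = {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"}
            for stock in ("LL1", "LL2"):
                for i in (1, 2):
                    sid = f"{stock}_{i}_fb"
                    # stocks look like opposite homozygotes in the RNA data
                    row[f"{sid}:REF"] = _PARENTAL_DEPTH if stock == "LL1" else 0
                    row[f"{sid}:ALT"] = 0 if stock == "LL1" else _PARENTAL_DEPTH
            for dam, sire in (("LL1", "LL2"), ("LL2", "LL1")):
                # LL1 allele (= ref) is maternal when the dam is LL1
                ll1_fraction = maternal if dam == "LL1" else 1.0 - maternal
                ref_count = int(round(_F1_DEPTH * ll1_fraction))
                for i in (1, 2):
                    sid = f"F1_{dam}x{sire}_{i}_fb"
                    row[f"{sid}:REF"] = ref_count
                    row[f"{sid}:ALT"] = _F1_DEPTH - ref_count
            count_rows.append(row)
            if gene in ARTIFACT_GENES:
                override_rows.append(dict(chrom=chrom, pos=pos,
                                          ll1_genotype="het", ll2_genotype="het"))
    genes = pd.DataFrame(gene_rows)
    counts = pd.DataFrame(count_rows)
    override = pd.DataFrame(override_rows)
    expression = pd.DataFrame(dict(gene_id=genes["gene_id"], tissue=FETAL_BRAIN, fpkm=5.0))
    return dict(counts=counts, meta=meta, genes=genes, expression=expression,
                override=override)
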
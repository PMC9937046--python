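"""Synthetic reciprocal-cross datasets with known imprinting truth.

Emulates an F1 reciprocal-cross RNA-seq experiment between two random-bred
stocks (``LL1`` and ``LL2``): purebred parental-cross fetuses provide the
stock genotype evidence, and F1 fetuses from both cross directions
(LL1 dam x LL2 sire, and the reciprocal) provide parent-of-origin allelic
read counts.  Gene classes cover biallelic expression, maternally/paternally
expressed imprinted genes (MEG/PEG), cis-eQTL genes whose allelic bias
follows the stock of origin rather than the parent, and X-linked genes
subject to imprinted X inactivation (100% maternal expression, placed on an
unplaced scaffold ``chrUn``).

A separate generator produces bisulfite-cloning data for promoter
methylation analysis: clone-by-CpG methylation call matrices with per-allele
methylation probabilities, an incomplete-conversion error rate, and an
optional allele-tagging SNP, plus rendering of clone sequences against a
reference region so the sequence-calling path can be exercised end to end.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STOCKS = ("LL1", "LL2")
GENE_CLASSES = ("biallelic", "meg", "peg", "cis_eqtl", "xci")
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 9))
XCI_CHROM = "chrUn"
TISSUES = ("fetal_brain", "placenta")

#: gene geometry: two exons separated by one intron (1-based, inclusive)
_EXON_LEN = 400
_INTRON_LEN = 1000
_GENE_SPACING = 10_000


def _default_proportions() -> dict:
    # enriched for the non-biallelic classes relative to genome-wide rates
    # (~0.5% imprinted) so modest n_genes exercises every class
    return {"biallelic": 0.88, "meg": 0.03, "peg": 0.03, "cis_eqtl": 0.03, "xci": 0.03}


@dataclass
class SimulationConfig:
    """Stated world of the reciprocal-cross simulation.

    Parameters
    ----------
    n_genes
        Number of genes to simulate.
    snps_per_gene_mean
        Mean exonic SNP count per gene (Poisson, floored at 1).
    class_proportions
        Mapping of gene class to fraction; must sum to 1.
    imprint_strength
        Expressed-parent allele fraction for MEG/PEG genes, in (0.5, 1].
    cis_eqtl_bias
        LL1-haplotype expression fraction for cis-eQTL genes, in (0.5, 1];
        the bias has the same sign in both cross directions.
    stock_divergence
        Probability a site is fixed for opposite alleles in the two stocks.
    shared_polymorphism_fraction
        Probability a site segregates in both stocks (allele frequency 0.5
        in each), mimicking the shared ancestry of the two stocks.
    depth_mean, depth_dispersion
        Negative-binomial read depth per SNP per library (size parameter
        ``depth_dispersion``).
    n_f1_per_direction
        F1 fetuses per reciprocal direction (default 2).
    tissues
        Tissues profiled per individual (default fetal brain and placenta).
    seed
        Seed for the single random generator; identical config + seed gives
        byte-identical outputs.
    """

    n_genes: int = 200
    snps_per_gene_mean: float = 4.0
    class_proportions: dict = field(default_factory=_default_proportions)
    imprint_strength: float = 0.98
    cis_eqtl_bias: float = 0.75
    stock_divergence: float = 0.06
    shared_polymorphism_fraction: float = 0.30
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    n_f1_per_direction: int = 2
    tissues: tuple = TISSUES
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (self.snps_per_gene_mean > 0 and math.isfinite(self.snps_per_gene_mean)):
            raise ValueError("snps_per_gene_mean must be a positive finite real")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes in class_proportions: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class_proportions must sum to 1 (got {total!r})")
        if any(not (0.0 <= v <= 1.0) for v in self.class_proportions.values()):
            raise ValueError("class_proportions entries must be in [0, 1]")
        for name in ("imprint_strength", "cis_eqtl_bias"):
            v = getattr(self, name)
            if not (0.5 < v <= 1.0):
                raise ValueError(f"{name} must be in (0.5, 1]")
        for name in ("stock_divergence", "shared_polymorphism_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 and math.isfinite(v)):
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.stock_divergence + self.shared_polymorphism_fraction > 1.0 + 1e-12:
            raise ValueError("stock_divergence + shared_polymorphism_fraction must be <= 1")
        if not (self.depth_mean > 0 and math.isfinite(self.depth_mean)):
            raise ValueError("depth_mean must be positive and finite")
        if not (self.depth_dispersion > 0 and math.isfinite(self.depth_dispersion)):
            raise ValueError("depth_dispersion must be positive and finite")
        if self.n_f1_per_direction < 1:
            raise ValueError("n_f1_per_direction must be >= 1")
        if len(self.tissues) < 1:
            raise ValueError("at least one tissue required")


@dataclass
class CrossDataset:
    """Bundle returned by :func:`simulate_cross_dataset`.

    ``counts`` is the wide per-SNP allele-count table; ``meta`` one row per
    library; ``genes``/``exons`` the gene models; ``truth`` the per-gene
    truth labels; ``sites`` per-SNP site truth (realized stock genotypes);
    ``expression`` the per-gene, per-tissue FPKM analogue.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    genes: pd.DataFrame
    exons: pd.DataFrame
    truth: pd.DataFrame
    sites: pd.DataFrame
    expression: pd.DataFrame


def _individuals(n_f1: int) -> list[dict]:
    inds = []
    for stock in STOCKS:
        for i in (1, 2):
            inds.append(
                dict(ind_id=f"{stock}_{i}", role="parental", stock=stock,
                     dam_stock=stock, sire_stock=stock)
            )
    for dam, sire in (("LL1", "LL2"), ("LL2", "LL1")):
        for i in range(1, n_f1 + 1):
            inds.append(
                dict(ind_id=f"F1_{dam}x{sire}_{i}", role="f1", stock="",
                     dam_stock=dam, sire_stock=sire)
            )
    return inds


def _maternal_expression_fraction(true_class: str, ind: dict, cfg: SimulationConfig) -> float:
    """Fraction of reads from the maternal haplotype for one individual."""
    if true_class == "biallelic":
        return 0.5
    if true_class == "meg":
        return cfg.imprint_strength
    if true_class == "peg":
        return 1.0 - cfg.imprint_strength
    if true_class == "xci":
        return 1.0
    # cis-eQTL: expression bias follows the stock of origin of each
    # haplotype, so it does not flip between reciprocal crosses
    if ind["dam_stock"] == ind["sire_stock"]:
        return 0.5
    return cfg.cis_eqtl_bias if ind["dam_stock"] == "LL1" else 1.0 - cfg.cis_eqtl_bias


def _genotype_name(n_alt_haps: int, n_haps: int) -> str:
    if n_alt_haps == 0:
        return "ref_hom"
    if n_alt_haps == n_haps:
        return "alt_hom"
    return "het"


_BASES = np.array(list("ACGT"))


def simulate_cross_dataset(config: SimulationConfig) -> CrossDataset:
    """Simulate a full reciprocal-cross allele-count dataset.

    Every SNP site is assigned a between-stock polymorphism type
    (fixed-different / shared segregating / fixed-identical), individual
    haplotypes are drawn from the stock allele frequencies, read depth is
    negative-binomial per library, and the reference-allele read count is
    binomial with success probability set by the individual's two allelic
    states weighted by the gene class's maternal expression fraction.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- genes -----------------------------------------------------------
    classes = list(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    gene_class = rng.choice(classes, size=cfg.n_genes, p=probs)
    n_snps_per_gene = np.maximum(1, rng.poisson(cfg.snps_per_gene_mean, size=cfg.n_genes))

    gene_rows, exon_rows = [], []
    chrom_cursor: dict[str, int] = {}
    auto_i = 0
    snp_chrom, snp_pos, snp_gene = [], [], []
    for g in range(cfg.n_genes):
        gid = f"gene{g + 1:04d}"
        if gene_class[g] == "xci":
            chrom = XCI_CHROM
        else:
            chrom = AUTOSOMES[auto_i % len(AUTOSOMES)]
            auto_i += 1
        start = chrom_cursor.get(chrom, 1)
        chrom_cursor[chrom] = start + _GENE_SPACING
        e1 = (start, start + _EXON_LEN - 1)
        e2 = (e1[1] + _INTRON_LEN + 1, e1[1] + _INTRON_LEN + _EXON_LEN)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append(dict(gene_id=gid, chrom=chrom, start=e1[0], end=e2[1], strand=strand))
        exon_rows.append(dict(gene_id=gid, chrom=chrom, start=e1[0], end=e1[1]))
        exon_rows.append(dict(gene_id=gid, chrom=chrom, start=e2[0], end=e2[1]))
        exonic = np.concatenate(
            [np.arange(e1[0], e1[1] + 1), np.arange(e2[0], e2[1] + 1)]
        )
        pos = np.sort(rng.choice(exonic, size=min(n_snps_per_gene[g], exonic.size), replace=False))
        snp_chrom.extend([chrom] * pos.size)
        snp_pos.extend(pos.tolist())
        snp_gene.extend([g] * pos.size)

    genes = pd.DataFrame(gene_rows)
    exons = pd.DataFrame(exon_rows)
    snp_gene = np.asarray(snp_gene)
    n_snps = snp_gene.size

    # --- site polymorphism types and stock allele frequencies ------------
    u = rng.random(n_snps)
    d, s = cfg.stock_divergence, cfg.shared_polymorphism_fraction
    site_type = np.where(u < d, "fixed_diff", np.where(u < d + s, "shared_poly", "fixed_same"))
    ll1_freq = np.zeros(n_snps)
    ll2_freq = np.zeros(n_snps)
    flip = rng.random(n_snps) < 0.5
    fd = site_type == "fixed_diff"
    ll1_freq[fd & flip] = 1.0
    ll2_freq[fd & ~flip] = 1.0
    sp = site_type == "shared_poly"
    ll1_freq[sp] = 0.5
    ll2_freq[sp] = 0.5
    freq = {"LL1": ll1_freq, "LL2": ll2_freq}

    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
    ref_base = _BASES[ref_idx]
    alt_base = _BASES[alt_idx]

    # --- haplotypes and expected reference fraction per individual -------
    inds = _individuals(cfg.n_f1_per_direction)
    hap_mat, hap_pat, p_ref = {}, {}, {}
    class_per_snp = gene_class[snp_gene]
    for ind in inds:
        hm = (rng.random(n_snps) < freq[ind["dam_stock"]]).astype(int)  # 1 = alt
        hp = (rng.random(n_snps) < freq[ind["sire_stock"]]).astype(int)
        m = np.array(
            [_maternal_expression_fraction(c, ind, cfg) for c in class_per_snp]
        )
        hap_mat[ind["ind_id"]], hap_pat[ind["ind_id"]] = hm, hp
        p_ref[ind["ind_id"]] = m * (1 - hm) + (1 - m) * (1 - hp)

    # realized stock genotypes from the parental individuals' haplotypes
    stock_gt = {}
    for stock in STOCKS:
        haps = [h for ind in inds if ind["role"] == "parental" and ind["stock"] == stock
                for h in (hap_mat[ind["ind_id"]], hap_pat[ind["ind_id"]])]
        n_alt = np.sum(haps, axis=0)
        stock_gt[stock] = np.where(
            n_alt == 0, "ref_hom", np.where(n_alt == len(haps), "alt_hom", "het")
        )

    # --- libraries: counts per SNP per (individual x tissue) -------------
    nb_p = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)
    counts = pd.DataFrame(
        {"chrom": snp_chrom, "pos": np.asarray(snp_pos), "ref": ref_base, "alt": alt_base}
    )
    meta_rows = []
    for ind in inds:
        for tissue in cfg.tissues:
            sid = f"{ind['ind_id']}_{tissue}"
            depth = rng.negative_binomial(cfg.depth_dispersion, nb_p, size=n_snps)
            ref_count = rng.binomial(depth, p_ref[ind["ind_id"]])
            counts[f"{sid}:REF"] = ref_count
            counts[f"{sid}:ALT"] = depth - ref_count
            meta_rows.append(
                dict(sample_id=sid, role=ind["role"], stock=ind["stock"],
                     dam_stock=ind["dam_stock"], sire_stock=ind["sire_stock"],
                     tissue=tissue, generation="P" if ind["role"] == "parental" else "F1",
                     sex="F")
            )
    meta = pd.DataFrame(meta_rows)

    # --- truth channels --------------------------------------------------
    expressed_parent_fraction = np.where(
        gene_class == "biallelic", 0.5,
        np.where(gene_class == "xci", 1.0,
                 np.where(gene_class == "cis_eqtl", cfg.cis_eqtl_bias, cfg.imprint_strength)),
    )
    truth = pd.DataFrame(
        dict(gene_id=genes["gene_id"], true_class=gene_class,
             true_expressed_parent_fraction=expressed_parent_fraction,
             chrom=genes["chrom"])
    )
    sites = pd.DataFrame(
        dict(chrom=snp_chrom, pos=np.asarray(snp_pos),
             gene_id=genes["gene_id"].to_numpy()[snp_gene], site_type=site_type,
             ll1_true_genotype=stock_gt["LL1"], ll2_true_genotype=stock_gt["LL2"])
    )
    expr_rows = []
    for tissue in cfg.tissues:
        fpkm = rng.lognormal(mean=1.5, sigma=1.0, size=cfg.n_genes)
        expr_rows.append(pd.DataFrame(dict(gene_id=genes["gene_id"], tissue=tissue, fpkm=fpkm)))
    expression = pd.concat(expr_rows, ignore_index=True)

    return CrossDataset(counts=counts, meta=meta, genes=genes, exons=exons,
                        truth=truth, sites=sites, expression=expression)


# --------------------------------------------------------------------------
# bisulfite clone simulation
# --------------------------------------------------------------------------

def simulate_bisulfite_clones(
    n_clones: int,
    n_cpgs: int,
    maternal_meth_prob: float,
    paternal_meth_prob: float,
    conversion_failure_rate: float = 0.0,
    with_allele_snp: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a clone-by-CpG methylation call matrix.

    Each cloned molecule derives from the maternal or paternal allele with
    probability 0.5; each CpG is methylated with that allele's probability;
    unmethylated cytosines escape bisulfite conversion (and so read as
    methylated) at ``conversion_failure_rate``.  The allele tag is exposed
    in the clone matrix only when ``with_allele_snp`` is set, mirroring a
    single perfectly linked SNP inside the amplicon; the truth record
    always carries the real tags.

    Returns ``(clones, truth)`` where ``clones`` has columns ``clone_id``,
    ``allele_tag`` and one ``cpg_*`` column per site with M/U calls.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    for name, v in (("maternal_meth_prob", maternal_meth_prob),
                    ("paternal_meth_prob", paternal_meth_prob),
                    ("conversion_failure_rate", conversion_failure_rate)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    is_maternal = rng.random(n_clones) < 0.5
    prob = np.where(is_maternal, maternal_meth_prob, paternal_meth_prob)
    methylated = rng.random((n_clones, n_cpgs)) < prob[:, None]
    escaped = rng.random((n_clones, n_cpgs)) < conversion_failure_rate
    calls = methylated | escaped  # unconverted unmethylated C reads as M

    true_tag = np.where(is_maternal, "maternal", "paternal")
    clones = pd.DataFrame({"clone_id": [f"clone{i + 1:03d}" for i in range(n_clones)],
                           "allele_tag": true_tag if with_allele_snp else "unknown"})
    for j in range(n_cpgs):
        clones[f"cpg_{j + 1}"] = np.where(calls[:, j], "M", "U")
    truth = dict(true_allele=pd.Series(true_tag, index=clones["clone_id"].to_numpy()),
                 maternal_meth_prob=maternal_meth_prob,
                 paternal_meth_prob=paternal_meth_prob,
                 conversion_failure_rate=conversion_failure_rate)
    return clones, truth


#: repeating unit with one non-CpG cytosine (QC signal) and one CpG
_REFERENCE_UNIT = "TCACGA"


def bisulfite_reference(n_cpgs: int) -> str:
    """Deterministic reference region with ``n_cpgs`` CpG sites.

    Each 6-mer unit carries one non-CpG cytosine, so the conversion-rate QC
    on sequence-derived clones is always measurable.
    """
    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    return _REFERENCE_UNIT * n_cpgs


def render_clone_sequences(
    reference: str,
    clones: pd.DataFrame,
    conversion_failure_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Render bisulfite-converted read sequences from a clone call matrix.

    CpG cytosines stay ``C`` when the call is M and convert to ``T`` when U;
    non-CpG cytosines convert to ``T`` except when conversion fails (they
    remain ``C`` with probability ``conversion_failure_rate``).  Missing
    calls render as ``N``.
    """
    rng = np.random.default_rng(seed)
    cpg_cols = [c for c in clones.columns if c.startswith("cpg_")]
    cpg_positions = [i for i in range(len(reference) - 1) if reference[i:i + 2] == "CG"]
    if len(cpg_positions) != len(cpg_cols):
        raise ValueError(
            f"reference has {len(cpg_positions)} CpGs but matrix has {len(cpg_cols)} columns"
        )
    out = []
    for _, row in clones.iterrows():
        seq = list(reference)
        for pos, col in zip(cpg_positions, cpg_cols):
            call = row[col]
            seq[pos] = {"M": "C", "U": "T"}.get(call, "N")
        for i, base in enumerate(reference):
            if base == "C" and reference[i + 1: i + 2] != "G" and i not in cpg_positions:
                seq[i] = "C" if rng.random() < conversion_failure_rate else "T"
        out.append("".join(seq))
    return out
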
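# Methods

## The reciprocal-cross design

Two outbred stocks, LL1 and LL2, are mated in both directions
(LL1 dam × LL2 sire and the reciprocal). At a SNP where the stocks are
fixed for opposite alleles, each F1 read's parental origin is unambiguous:
in the LL1×LL2 cross the LL1 allele came from the dam, in the LL2×LL1
cross from the sire. Let p₁ and p₂ be the LL1-allele expression fractions
pooled within each direction. Parent-of-origin effects *flip* between the
directions (maternal fraction = p₁ in direction 1 and 1 − p₂ in direction
2), while *cis*-regulatory strain effects do not. The flipped requirement
is what separates imprinting from cis-eQTL signal; it is the core of the
caller and is enforced symmetrically (swapping the direction labels maps
every MEG call to a PEG call and vice versa — a property test asserts
this over a dense (p₁, p₂) grid).

## Pipeline stages and thresholds

| parameter | default | role |
|---|---|---|
| `min_pooled_depth` | 40 | SNP discovery: total depth pooled over all libraries |
| `min_sample_depth` | 8 | per-library depth for genotype, informativeness and ratio use |
| `min_f1_covered` | 3 | F1 libraries (of 4 per tissue) that must reach 8× |
| `hom_max_minor_fraction` | 0.05 | sequencing-error tolerance for a homozygote call |
| `het_min_minor_fraction` | 0.20 | minimum minor fraction to call a stock heterozygous |
| `boundary_distance` | 5 bp | exclusion zone around exon–intron junctions |
| `upper` / `lower` | 0.65 / 0.35 | flipped-ratio cutoffs (strict inequalities) |
| `fpkm_min` | 1.0 | expression-detection gate (genes below are `not_detectable`) |
| `xci_maternal_min` | 0.99 | "100% maternal" with tolerance for single stray reads |

Stock genotypes are called from pooled parental read counts. Real studies
confirm such calls by Sanger sequencing of genomic DNA; the package models
that step as a *confirmed-genotype override* table that replaces inferred
calls before informativeness is assessed. This is how apparently flipped
candidates whose SNPs are actually segregating in both stocks (homozygous
in the F1s) are removed — the packaged 22-gene screening fixture loses
exactly its three artifact genes this way.

Gene-level summaries pool raw counts (depth-weighted) over SNPs and F1
replicates within a direction rather than averaging per-SNP ratios: SNPs
have very unequal depths and pooling is the efficient estimator. A fixture
where the two estimators differ (a 90-read all-reference SNP plus a
10-read all-alternative SNP) pins the pooled behaviour at 0.9, not 0.5.

Calls use strict inequalities at the cutoffs, so boundary ratios fall to
biallelic/undetermined. `undetermined` is deliberately distinct from
`biallelic`: mixed patterns (one direction extreme, one central) and
same-side cis-eQTL patterns are not evidence of biallelic expression, only
absence of a flipped pattern. A record missing one direction is
`undetermined`; a record failing the expression gate is `not_detectable`
(an expression outcome, not an informativeness outcome). No
multiple-testing correction is applied — the procedure is a fixed-cutoff
screen, not a hypothesis test.

MEG calls on `chrUn`/`chrX` with maternal fraction ≥ 0.99 in every covered
F1 library are re-labelled `xci_candidate` (marsupial X inactivation
silences the paternal X, so X-linked genes mimic MEGs) and are excluded
from the autosomal count used for extrapolation.

## Genome-wide extrapolation

With `n_detected` autosomal MEG+PEG genes and coverage fraction *c* =
|covered ∩ expressed| / |expressed|, the genome-wide point estimate is
`n_detected / c`. With the covered-gene denominator available, the
interval is Clopper–Pearson on the detection proportion scaled back to the
genome; without it, Garwood's exact Poisson interval on the count scaled
by 1/*c*. Both contain the point estimate by construction. The estimator
assumes imprinting status is independent of informative-SNP coverage and
that detection power within covered genes is ~1; a seeded-replicate test
checks interval coverage of the simulated truth (≥ 90% across replicates).

## The synthetic-data generator

The generator emulates the stated cross design: 2 purebred parental-cross
fetuses per stock and 2 F1 fetuses per reciprocal direction, each profiled
in fetal brain and placenta (16 libraries). Per SNP site the stocks are
fixed-different (probability `stock_divergence`, default 0.06),
segregating in both at allele frequency ½ (`shared_polymorphism_fraction`,
default 0.30 — the stocks share ancestry, so shared polymorphism is
common), or fixed-identical. With ~4 SNPs per gene the default divergence
puts gene-level informative coverage near 20%, the coverage regime the
design targets. Each individual's haplotypes are drawn from its parents'
stock frequencies; reads are binomial in the maternal-haplotype expression
fraction *m* of the gene class:

| class | m | notes |
|---|---|---|
| biallelic | 0.5 | |
| MEG / PEG | s / 1 − s | `imprint_strength` s, default 0.98 |
| XCI | 1.0 | genes placed on `chrUn` |
| cis-eQTL | bias follows the stock of origin | default LL1 fraction 0.75, same side in both directions |

Depth is negative-binomial (`depth_mean` 30, dispersion 5 — overdispersed
RNA-seq coverage; no depth distribution is prescribed by the design, only
the 8×/40× cutoffs). Expression (FPKM analogue) is lognormal(μ=1.5, σ=1)
so the detection gate triggers for ~7% of genes. A single seeded generator
drives everything; identical config + seed gives byte-identical outputs.

Deliberate simplifications: F1 gametes are drawn at the stock level (no
explicit shared dam/sire individuals, hence no sibling haplotype
correlation); no mapping bias, batch effects, isoforms or read-level
error; X dosage is not modelled beyond the XCI class. Because shared
polymorphism is simulated faithfully, the generator *does* reproduce the
screening artifact in which a segregating site masquerades as informative
— green recovery tests therefore establish correctness of the filtering
logic given the count model, not robustness to alignment artefacts.

Bisulfite clones: each cloned molecule is maternal or paternal with
probability ½; CpG calls are Bernoulli in the allele's methylation
probability; unmethylated cytosines escape conversion (read as methylated)
at `conversion_failure_rate`. A deterministic reference (`TCACGA` repeats)
provides one non-CpG cytosine per CpG so the conversion-QC path is always
exercised; rendering clones to sequences and re-calling them reproduces
the truth matrix exactly at zero failure rate (equivalence test).

## Methylation analysis choices

Clones whose non-CpG cytosine conversion rate is below 0.95 are excluded
(standard bisulfite QC; a clone with no non-CpG cytosines passes, with the
rate undefined). Missing calls never enter a site's denominator. The
region mean is the mean over CpG-site percentages, so a 50/50 mixture of
fully methylated and fully unmethylated clones is exactly 0.5. DMR
screening: region mean < 0.20 → unmethylated, > 0.80 → methylated, inside
[0.30, 0.70] → DMR when |maternal − paternal| ≥ 0.40 (classification is
monotone in the allele difference), otherwise `intermediate_unresolved` —
as is the gap between the bands. The 0.30–0.70 band encloses the
~35–60% aggregate methylation typical of promoter DMRs with margin; the
0.40 allele-difference floor cleanly separates observations like 96%
maternal vs 18% paternal methylation. All cutoffs are keyword arguments.

## Known limitations

- Stock genotyping from expression data is confounded at imprinted genes
  (a purebred heterozygote expressing one allele looks homozygous); the
  override interface is the remedy, as in practice.
- SNPs are assigned to genes by position; a SNP inside two overlapping
  gene models goes to the lexicographically first gene with a warning
  (point overlap cannot break the tie), which can misattribute reads in
  dense loci.
- The extrapolation inherits the independence assumption above and is a
  screening estimate, not a posterior.
- Indel markers and multi-allelic sites are out of scope (SNVs only);
  multi-SNP amplicon phasing for bisulfite clones is not modelled (one
  linked tag SNP per amplicon).
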
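"""Genome-wide imprinted-gene count extrapolation from detection coverage.

Informative SNPs only cover a fraction of the expressed transcriptome (two
random-bred stocks share segregating polymorphism, so many sites are
uninformative).  If imprinted genes are distributed independently of SNP
coverage, the genome-wide count is the detected autosomal count divided by
the coverage fraction — e.g. 12 detected over 20% coverage extrapolates to
~60 imprinted autosomal genes.  A Clopper–Pearson binomial interval on the
detection count (Garwood's exact Poisson interval when the covered-gene
denominator is unknown) is scaled the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass
class GenomeEstimate:
    n_detected: int
    coverage_fraction: float
    extrapolated_total: float
    interval: tuple  # (lower, upper) on the extrapolated scale


def coverage_fraction(covered_genes, expressed_genes) -> float:
    """Fraction of expressed genes with informative-SNP coverage."""
    expressed = set(expressed_genes)
    if not expressed:
        raise ValueError("expressed gene set is empty")
    return len(set(covered_genes) & expressed) / len(expressed)


def extrapolate_total(
    n_detected: int,
    coverage: float,
    n_covered: int | None = None,
    confidence: float = 0.95,
) -> GenomeEstimate:
    """Extrapolate the genome-wide imprinted-gene count.

    ``n_detected`` is the autosomal MEG+PEG count (XCI candidates and
    undetectable genes excluded); ``coverage`` the informative-SNP coverage
    fraction of the expressed transcriptome.  The point estimate is
    ``n_detected / coverage``.  With ``n_covered`` (number of covered
    genes), the interval is Clopper–Pearson on the detection proportion,
    scaled back to a genome-wide count; without it, Garwood's exact Poisson
    interval on the count is scaled by ``1 / coverage``.
    """
    if n_detected < 0:
        raise ValueError("n_detected must be >= 0")
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must be in (0, 1]")
    alpha = 1.0 - confidence
    point = n_detected / coverage
    if n_covered is not None:
        if n_covered < n_detected:
            raise ValueError("n_covered must be >= n_detected")
        lo_p = (stats.beta.ppf(alpha / 2, n_detected, n_covered - n_detected + 1)
                if n_detected > 0 else 0.0)
        hi_p = (stats.beta.ppf(1 - alpha / 2, n_detected + 1, n_covered - n_detected)
                if n_detected < n_covered else 1.0)
        interval = (lo_p * n_covered / coverage, hi_p * n_covered / coverage)
    else:
        lo = stats.chi2.ppf(alpha / 2, 2 * n_detected) / 2 if n_detected > 0 else 0.0
        hi = stats.chi2.ppf(1 - alpha / 2, 2 * n_detected + 2) / 2
        interval = (lo / coverage, hi / coverage)
    return GenomeEstimate(n_detected=int(n_detected), coverage_fraction=float(coverage),
                          extrapolated_total=float(point),
                          interval=(float(interval[0]), float(interval[1])))
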
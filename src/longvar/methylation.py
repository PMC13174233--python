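"""Haplotype-resolved CpG methylation statistics.

Each long read carries per-CpG methylation likelihoods over a locus; reads
are near-saturated in practice (fully methylated or fully unmethylated), so
a read is classified by its mean likelihood.  Allele-specific methylation
is quantified per haplotype and tested with an exact binomial skew test:

    x = (# methylated H1 reads) + (# unmethylated H2 reads),   n = all
    phased reads, success probability 1/2, two-sided.

Chromosome-X profiles average gene-level promoter methylation fractions to
estimate X-inactivation (XCI) skew, against which the FMR1 CGG-repeat
effect on promoter methylation is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .genotype import HAPLOTYPES

#: FMR1 CGG allele classes by repeat count: normal-short (<=25),
#: intermediate (26-34), gray-zone (35-54) and above-gray-zone (>54, still
#: counted in the ">=35 repeats" grouping).
CGG_CLASSES = ("short", "intermediate", "gray-zone", "above-gray-zone")


@dataclass
class MethylRead:
    haplotag: str  # H1 | H2 | unphased
    cpg_likelihoods: list[float]

    def __post_init__(self) -> None:
        if self.haplotag not in HAPLOTYPES:
            raise ValueError(f"unknown haplotag {self.haplotag!r}")
        if len(self.cpg_likelihoods) == 0:
            raise ValueError("read must carry at least one CpG likelihood")


@dataclass
class MethylReadSet:
    locus: str
    reads: list[MethylRead] = field(default_factory=list)


@dataclass
class HaplotypeMethylation:
    """Methylated/total read counts and fraction per haplotype."""

    counts: dict  # hap -> (methylated, total)

    def fraction(self, hap: str) -> float | None:
        m, n = self.counts.get(hap, (0, 0))
        return m / n if n else None


def classify_read(read: MethylRead, threshold: float = 0.5) -> bool:
    """True (methylated) iff the mean CpG likelihood strictly exceeds the threshold."""
    return float(np.mean(read.cpg_likelihoods)) > threshold


def haplotype_fractions(
    readset: MethylReadSet, threshold: float = 0.5
) -> HaplotypeMethylation:
    """Methylated-read fraction per haplotype (unphased reads kept separate)."""
    counts = {h: [0, 0] for h in HAPLOTYPES}
    for read in readset.reads:
        c = counts[read.haplotag]
        c[1] += 1
        if classify_read(read, threshold):
            c[0] += 1
    return HaplotypeMethylation({h: tuple(c) for h, c in counts.items()})


def binomial_skew_test(readset: MethylReadSet, threshold: float = 0.5) -> float:
    """Exact two-sided binomial test of allele-specific methylation.

    Successes are methylated H1 reads plus unmethylated H2 reads out of all
    phased reads; unphased reads are excluded.  The two-sided p-value sums
    all outcomes no more probable than the observed one (the minimum-
    likelihood convention).
    """
    hm = haplotype_fractions(readset, threshold)
    m1, n1 = hm.counts["H1"]
    m2, n2 = hm.counts["H2"]
    n = n1 + n2
    if n == 0:
        raise ValueError("skew test requires at least one phased read")
    x = m1 + (n2 - m2)
    return binomtest(x, n, p=0.5, alternative="two-sided").pvalue


@dataclass
class XCIProfile:
    """Chromosome-X methylation profile across gene promoters."""

    gene_fractions: pd.DataFrame  # index gene, columns H1/H2
    average: dict  # hap -> chromosome-wide mean of gene fractions
    long_haplotype: str  # haplotype carrying the longer CGG allele
    skewness: float  # avg frac(long-CGG hap) - avg frac(short-CGG hap)


def xci_profile(
    gene_readsets: dict[str, MethylReadSet],
    fmr1_haplotype_lengths: tuple[float, float],
    min_reads: int = 3,
    threshold: float = 0.5,
) -> XCIProfile:
    """XCI skew from promoter methylation of X-chromosome genes.

    A gene enters the profile when both haplotypes have at least
    ``min_reads`` classified reads; the chromosome-wide value per haplotype
    is the unweighted mean of the gene-level fractions.  Skewness is
    oriented by the FMR1 CGG alleles: fraction of the long-CGG haplotype
    minus fraction of the short-CGG haplotype.
    """
    rows = {}
    for gene, readset in gene_readsets.items():
        hm = haplotype_fractions(readset, threshold)
        if hm.counts["H1"][1] >= min_reads and hm.counts["H2"][1] >= min_reads:
            rows[gene] = {"H1": hm.fraction("H1"), "H2": hm.fraction("H2")}
    if not rows:
        raise ValueError("no gene with sufficient reads on both haplotypes")
    fractions = pd.DataFrame.from_dict(rows, orient="index")
    average = fractions.mean(axis=0).to_dict()
    len_h1, len_h2 = fmr1_haplotype_lengths
    long_hap, short_hap = ("H1", "H2") if len_h1 >= len_h2 else ("H2", "H1")
    return XCIProfile(
        gene_fractions=fractions,
        average=average,
        long_haplotype=long_hap,
        skewness=average[long_hap] - average[short_hap],
    )


def classify_cgg(repeat_count: float) -> str:
    """CGG allele class for a (possibly fractional) repeat count."""
    if repeat_count < 0:
        raise ValueError("repeat count must be non-negative")
    if repeat_count <= 25:
        return "short"
    if repeat_count < 35:
        return "intermediate"
    if repeat_count <= 54:
        return "gray-zone"
    return "above-gray-zone"


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(np.asarray(X, dtype=float))
    if rank < X.shape[1]:
        corr = X.loc[:, X.std() > 0].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [
            f"{a}~{b}"
            for a in corr.index
            for b in corr.columns
            if a < b and corr.loc[a, b] > 0.999
        ]
        degenerate = [c for c in X.columns if X[c].std() == 0 and c != "const"]
        raise ValueError(
            "rank-deficient design; collinear columns: "
            + (", ".join(pairs + degenerate) or "unidentified")
        )


def fmr1_association(
    table: pd.DataFrame,
    methylation_col: str = "frac_hap_methyl_fmr1",
    xci_col: str = "frac_hap_methyl_xci",
    repeat_col: str = "fmr1_mean_repeat_length",
    phenotype_col: str | None = None,
) -> dict:
    """Association models for FMR1 promoter methylation.

    Fits an OLS of the FMR1 haplotype methylation fraction on XCI (average
    X-gene methylation of the haplotype) and CGG repeat length, reporting
    coefficients, p-values and the partial variance explained by each
    predictor (drop-one R-squared differences).  When ``phenotype_col`` is
    given, additionally fits a logistic regression of case status on mean
    repeat length and FMR1 methylation fraction with Wald p-values.
    """
    import statsmodels.api as sm

    cols = [methylation_col, xci_col, repeat_col]
    data = table.dropna(subset=cols)
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows for the OLS fit")
    y = data[methylation_col].astype(float)
    X = sm.add_constant(data[[xci_col, repeat_col]].astype(float))
    _check_rank(X)
    ols = sm.OLS(y, X).fit()

    def _r2(fit) -> float:  # constant response yields NaN R-squared
        r2 = fit.rsquared
        return float(r2) if np.isfinite(r2) else 0.0

    partial_r2 = {}
    for col in (xci_col, repeat_col):
        reduced = sm.OLS(y, X.drop(columns=[col])).fit()
        partial_r2[col] = _r2(ols) - _r2(reduced)

    out = {"ols": ols, "r_squared": _r2(ols), "partial_r2": partial_r2}

    if phenotype_col is not None:
        pdata = table.dropna(subset=[phenotype_col, repeat_col, methylation_col])
        pheno = pdata[phenotype_col].astype(int)
        if pheno.nunique() < 2:
            raise ValueError("logistic model requires both phenotype classes")
        Xl = sm.add_constant(pdata[[repeat_col, methylation_col]].astype(float))
        _check_rank(Xl)
        out["logistic"] = sm.Logit(pheno, Xl).fit(disp=0)
    return out
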
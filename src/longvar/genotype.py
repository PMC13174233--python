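"""Bayesian read-support genotyping of structural variants.

Per-variant, per-sample evidence is a pair of read counts: reads supporting
the ALT allele (``var_count``) and reads supporting the REF allele
(``ref_count``), optionally split by haplotype tag.  Genotype likelihoods
follow a binomial model with a per-read miscall probability ``e``:

    p(Data | 0/1) = C(n, v) (1/2)^v (1/2)^r
    p(Data | 1/1) = C(n, v) (1-e)^v e^r
    p(Data | 0/0) = C(n, v) e^v (1-e)^r

with n = v + r.  Posteriors use a uniform prior over the three genotypes.
Two Phred-scaled qualities are reported: GQ = -10 log10(1 - p(GT|Data)),
the probability the called genotype is wrong, and
SQ = -10 log10(p(0/0|Data)), the probability the sample is non-reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

GENOTYPES = ("0/0", "0/1", "1/1")
HAPLOTYPES = ("H1", "H2", "unphased")

#: Maximum reported Phred quality (VCF convention; avoids infinities when a
#: complementary posterior underflows).
MAX_PHRED = 99.0

#: Default per-read miscall probability for SV signatures in long reads.
DEFAULT_ERROR_RATE = 0.1


class ParameterError(ValueError):
    """Invalid model parameter (e.g. error rate outside (0, 0.5))."""


def _check_error_rate(e: float) -> float:
    if not 0.0 < e < 0.5:
        raise ParameterError(f"error_rate must be in (0, 0.5), got {e}")
    return float(e)


@dataclass
class ReadSupport:
    """ALT/REF supporting read counts for one variant in one sample.

    ``by_haplotype`` maps each of H1/H2/unphased to an (alt, ref) pair;
    when provided, the per-haplotype counts must sum to the totals.
    """

    var_count: int
    ref_count: int
    by_haplotype: dict[str, tuple[int, int]] | None = None
    error_rate: float = DEFAULT_ERROR_RATE

    def __post_init__(self) -> None:
        if self.var_count < 0 or self.ref_count < 0:
            raise ValueError("read counts must be non-negative")
        _check_error_rate(self.error_rate)
        if self.by_haplotype is not None:
            for hap in self.by_haplotype:
                if hap not in HAPLOTYPES:
                    raise ValueError(f"unknown haplotype label {hap!r}")
            v = sum(p[0] for p in self.by_haplotype.values())
            r = sum(p[1] for p in self.by_haplotype.values())
            if (v, r) != (self.var_count, self.ref_count):
                raise ValueError(
                    "haplotype-split counts do not sum to the totals: "
                    f"({v}, {r}) != ({self.var_count}, {self.ref_count})"
                )

    @classmethod
    def from_haplotypes(
        cls,
        h1: tuple[int, int] = (0, 0),
        h2: tuple[int, int] = (0, 0),
        unphased: tuple[int, int] = (0, 0),
        error_rate: float = DEFAULT_ERROR_RATE,
    ) -> "ReadSupport":
        split = {"H1": tuple(h1), "H2": tuple(h2), "unphased": tuple(unphased)}
        return cls(
            var_count=h1[0] + h2[0] + unphased[0],
            ref_count=h1[1] + h2[1] + unphased[1],
            by_haplotype=split,
            error_rate=error_rate,
        )

    def haplotype(self, hap: str) -> tuple[int, int]:
        if self.by_haplotype is None:
            return (0, 0)
        return tuple(self.by_haplotype.get(hap, (0, 0)))

    @property
    def depth(self) -> int:
        return self.var_count + self.ref_count


@dataclass
class GenotypeCall:
    """Called genotype with posteriors and Phred qualities."""

    gt: str
    posteriors: tuple[float, float, float]
    gq: float
    sq: float
    phased_gt: str | None = None

    def is_variant(self) -> bool:
        return self.gt != "0/0"


@dataclass
class TrioSupport:
    """Read support for proband, mother and father at one candidate SV."""

    proband: ReadSupport
    mother: ReadSupport
    father: ReadSupport

    def __post_init__(self) -> None:
        for role in ("proband", "mother", "father"):
            if getattr(self, role) is None:
                raise ValueError(f"missing {role} read support")


def log_genotype_likelihoods(support: ReadSupport) -> np.ndarray:
    """Log-likelihoods over (0/0, 0/1, 1/1).

    Computed in log space with a log-gamma binomial coefficient so that
    counts in the thousands do not underflow.
    """
    v, r = support.var_count, support.ref_count
    e = support.error_rate
    n = v + r
    logc = gammaln(n + 1) - gammaln(v + 1) - gammaln(r + 1)
    log_e, log_1me = math.log(e), math.log1p(-e)
    return np.array(
        [
            logc + v * log_e + r * log_1me,   # 0/0
            logc + n * math.log(0.5),         # 0/1
            logc + v * log_1me + r * log_e,   # 1/1
        ]
    )


def genotype_likelihoods(support: ReadSupport) -> tuple[float, float, float]:
    """Likelihood triple over (0/0, 0/1, 1/1); (1, 1, 1) for empty data."""
    return tuple(np.exp(log_genotype_likelihoods(support)))


def call_genotype(support: ReadSupport) -> GenotypeCall:
    """Posterior genotype call under a uniform prior.

    The called genotype is the posterior argmax; ties (including the empty
    data case) break toward 0/0, conservative toward reference.  GQ and SQ
    are capped at 99.
    """
    ll = log_genotype_likelihoods(support)
    logz = logsumexp(ll)
    log_post = ll - logz
    post = np.exp(log_post)

    best = int(np.argmax(post))
    # break exact ties toward the lowest index (0/0 first)
    for i in range(best):
        if post[i] >= post[best]:
            best = i
            break

    # 1 - p(best) via the complementary posteriors for precision
    p_not_best = float(np.exp(logsumexp(np.delete(ll, best)) - logz))
    gq = MAX_PHRED if p_not_best <= 0 else min(-10.0 * math.log10(p_not_best), MAX_PHRED)
    sq = min(-10.0 * log_post[0] / math.log(10.0), MAX_PHRED)

    call = GenotypeCall(
        gt=GENOTYPES[best],
        posteriors=tuple(post),
        gq=max(gq, 0.0),
        sq=max(sq, 0.0),
    )
    call.phased_gt = assign_phased_genotype(support, call)
    return call


def assign_phased_genotype(support: ReadSupport, call: GenotypeCall) -> str | None:
    """Phased genotype from the haplotype split of ALT-supporting reads.

    Heterozygous calls place the ALT allele on the haplotype with a strict
    majority of ALT-supporting reads; ties and fully unphased support give
    no phased genotype.  Homozygous calls are trivially phased.
    """
    if support.by_haplotype is None:
        return None
    if call.gt == "1/1":
        return "1|1"
    if call.gt == "0/0":
        return "0|0"
    h1_var = support.haplotype("H1")[0]
    h2_var = support.haplotype("H2")[0]
    if h1_var == h2_var:  # tie, or all ALT support unphased
        return None
    return "1|0" if h1_var > h2_var else "0|1"


def trio_denovo_filter(
    trio: TrioSupport, min_proband_reads: int = 3
) -> tuple[bool, str]:
    """De novo candidate filter for one trio.

    A candidate requires ALT support from at least ``min_proband_reads``
    phased reads in the proband, zero ALT-supporting reads in both parents,
    and, for each parent, at least one REF-supporting read on each of the
    two haplotypes (so absence in the parents is backed by coverage of both
    parental chromosomes).  Returns (flag, reason); the reason names the
    first failed criterion.
    """
    if trio.proband.var_count < min_proband_reads:
        return False, "proband_depth"
    for role in ("mother", "father"):
        parent: ReadSupport = getattr(trio, role)
        if parent.var_count > 0:
            return False, f"{role}_alt_support"
        for hap in ("H1", "H2"):
            if parent.haplotype(hap)[1] < 1:
                return False, f"{role}_haplotype_coverage"
    return True, "candidate"


def parental_allele_frequency(
    cohort: list,
    platform: str,
    min_support_reads: int = 2,
) -> float:
    """Fraction of parents carrying the variant.

    In long-read (LR) mode ``cohort`` is a list of :class:`ReadSupport` and a
    parent is a carrier when it has at least ``min_support_reads``
    ALT-supporting reads.  In short-read (SR) mode ``cohort`` is a list of
    genotype strings or :class:`GenotypeCall` and a carrier is any
    non-homozygous-reference genotype.
    """
    if not cohort:
        raise ValueError("empty parent cohort")
    if platform == "LR":
        carriers = sum(1 for s in cohort if s.var_count >= min_support_reads)
    elif platform == "SR":
        gts = [g.gt if isinstance(g, GenotypeCall) else str(g) for g in cohort]
        carriers = sum(1 for g in gts if g not in ("0/0", "0|0", "./."))
    else:
        raise ValueError(f"platform must be 'LR' or 'SR', got {platform!r}")
    return carriers / len(cohort)
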
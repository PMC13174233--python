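"""Seeded generators for every input class the toolkit consumes.

All randomness flows from a single integer seed fanned out into independent
counter-based streams, so every generator is a pure, bitwise-reproducible
function of its arguments.  Toy contigs stay small (<= 1 Mb) so the full
simulation-based test battery runs in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evidence import AlignedRead
from .genotype import DEFAULT_ERROR_RATE, ReadSupport
from .methylation import MethylRead, MethylReadSet


def stream_rng(seed: int, stream: int = 0) -> np.random.Generator:
    """Independent generator for sub-stream ``stream`` of a master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(int(stream),)))


#: ALT-read probability per true genotype at per-read miscall rate e.
def _alt_prob(genotype: str, e: float) -> dict[str, float]:
    if genotype in ("0/0", "0|0"):
        return {"H1": e, "H2": e}
    if genotype in ("1/1", "1|1"):
        return {"H1": 1 - e, "H2": 1 - e}
    if genotype in ("0/1", "0|1"):
        return {"H1": e, "H2": 1 - e}
    if genotype == "1|0":
        return {"H1": 1 - e, "H2": e}
    raise ValueError(f"unknown genotype {genotype!r}")


def simulate_read_support(
    genotype: str,
    depth: int,
    e: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    phased_fraction: float = 1.0,
) -> ReadSupport:
    """Read support drawn from a true genotype.

    Coverage splits evenly across the two haplotypes (phased long-read
    depth is balanced at a genotypable locus; an odd read goes to a random
    haplotype).  Each read supports ALT with its haplotype's allele
    probability (e for a reference haplotype, 1-e for a carrier), and loses
    its haplotag with probability ``1 - phased_fraction``.
    """
    rng = rng if rng is not None else stream_rng(seed, 0)
    p = _alt_prob(genotype if "|" in genotype else {"0/0": "0|0", "0/1": "0|1",
                                                    "1/1": "1|1"}[genotype], e)
    depths = {"H1": depth // 2, "H2": depth // 2}
    if depth % 2:
        depths["H1" if rng.random() < 0.5 else "H2"] += 1
    split = {h: [0, 0] for h in ("H1", "H2", "unphased")}
    for hap in ("H1", "H2"):
        for _ in range(depths[hap]):
            is_alt = rng.random() < p[hap]
            label = hap if rng.random() < phased_fraction else "unphased"
            split[label][0 if is_alt else 1] += 1
    return ReadSupport.from_haplotypes(
        h1=tuple(split["H1"]), h2=tuple(split["H2"]),
        unphased=tuple(split["unphased"]), error_rate=e,
    )


@dataclass
class PlantedSV:
    svtype: str  # DEL | INS
    chrom: str
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + (self.length if self.svtype == "DEL" else 0)


def _reads_for_haplotype(
    sv: PlantedSV,
    carrier: bool,
    hap: str,
    member: str,
    depth: int,
    read_length: int,
    contig_length: int,
    rng: np.random.Generator,
    alt_fraction: float = 1.0,
) -> list[AlignedRead]:
    reads = []
    for i in range(depth):
        start = int(rng.integers(max(0, sv.start - read_length + 50),
                                 sv.end + read_length - 50))
        start = min(max(start, 0), max(contig_length - read_length, 0))
        name = f"{member}_{hap}_{i}"
        has_sv = carrier and rng.random() < alt_fraction
        if has_sv and start < sv.start and start + read_length > sv.end + 20:
            pre = sv.start - start
            if sv.svtype == "DEL":
                post = read_length - pre
                cigar = [("M", pre), ("D", sv.length), ("M", post)]
            else:
                post = max(read_length - pre - sv.length, 20)
                cigar = [("M", pre), ("I", sv.length), ("M", post)]
        else:
            cigar = [("M", read_length)]
        reads.append(
            AlignedRead(name=name, chrom=sv.chrom, start=start, cigar=cigar,
                        haplotag=hap, mapq=60)
        )
    return reads


def simulate_trio_alignments(
    sv: PlantedSV,
    depth_per_haplotype: int = 5,
    read_length: int = 2000,
    contig_length: int = 100_000,
    scenario: str = "denovo",
    mosaic_fraction: float = 0.5,
    seed: int = 0,
) -> dict[str, list[AlignedRead]]:
    """Toy phased trio alignments around a planted SV.

    Scenarios: "denovo" (proband H2 carries the SV, parents do not),
    "maternal" (mother H1 and proband H2 carry it), "mosaic" (proband H2
    carries it in ``mosaic_fraction`` of reads), "absent".
    """
    rng = stream_rng(seed, 1)
    carriers = {
        "denovo": {("proband", "H2"): 1.0},
        "maternal": {("proband", "H2"): 1.0, ("mother", "H1"): 1.0},
        "mosaic": {("proband", "H2"): mosaic_fraction},
        "absent": {},
    }[scenario]
    out = {}
    for member in ("proband", "mother", "father"):
        reads = []
        for hap in ("H1", "H2"):
            frac = carriers.get((member, hap), 0.0)
            reads.extend(
                _reads_for_haplotype(
                    sv, frac > 0, hap, member, depth_per_haplotype, read_length,
                    contig_length, rng, alt_fraction=frac or 1.0,
                )
            )
        out[member] = reads
    return out


def simulate_tr_cohort(
    regions: list[str],
    n_subjects: int = 50,
    null_sd: float = 5.0,
    outliers: list[tuple[str, str, str, int]] = (),
    missing_rate: float = 0.0,
    missing_region_rates: dict[str, float] | None = None,
    quality: float = 0.99,
    reads: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort TR genotype table with planted outliers and missingness.

    Null deviations are round(N(0, null_sd)); ``outliers`` plants
    (region, subject, hap, deviation) entries.  Missingness is applied per
    haplotype at ``missing_rate`` (or a per-region override).
    """
    rng = stream_rng(seed, 2)
    planted = {(r, s, h): d for r, s, h, d in outliers}
    rows = []
    subjects = [f"S{i:03d}" for i in range(n_subjects)]
    for region in regions:
        rate = (missing_region_rates or {}).get(region, missing_rate)
        for subject in subjects:
            for hap in ("H1", "H2"):
                missing = rng.random() < rate
                dev = planted.get(
                    (region, subject, hap),
                    int(np.round(rng.normal(0.0, null_sd))) if null_sd > 0 else 0,
                )
                rows.append(
                    {
                        "region": region,
                        "subject": subject,
                        "hap": hap,
                        "deviation": np.nan if missing else dev,
                        "quality": quality,
                        "reads": reads,
                        "missing": missing,
                    }
                )
    return pd.DataFrame(rows)


def simulate_methylation_reads(
    scenario: str,
    reads_per_haplotype: int = 5,
    n_cpg: int = 10,
    locus: str = "locus",
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> MethylReadSet:
    """Phased reads with near-saturated CpG methylation likelihoods.

    Scenarios give the probability that a read of each haplotype is
    methylated: "random" (1/2, 1/2), "full-skew" (H1 unmethylated, H2
    methylated), "h1-methylated" (1, 0).  Methylated reads draw CpG
    likelihoods near 1 (uniform 0.85-1), unmethylated near 0.
    """
    rng = rng if rng is not None else stream_rng(seed, 3)
    p_meth = {
        "random": {"H1": 0.5, "H2": 0.5},
        "full-skew": {"H1": 0.0, "H2": 1.0},
        "h1-methylated": {"H1": 1.0, "H2": 0.0},
    }[scenario]
    reads = []
    for hap in ("H1", "H2"):
        for _ in range(reads_per_haplotype):
            methylated = rng.random() < p_meth[hap]
            lo, hi = (0.85, 1.0) if methylated else (0.0, 0.15)
            reads.append(MethylRead(hap, list(rng.uniform(lo, hi, size=n_cpg))))
    return MethylReadSet(locus=locus, reads=reads)


def simulate_xci_panel(
    genes: list[str],
    skew: float = 0.0,
    reads_per_haplotype: int = 5,
    seed: int = 0,
) -> dict[str, MethylReadSet]:
    """Per-gene X-chromosome readsets with a common XCI skew.

    ``skew`` is the probability shift of H1 being the methylated (inactive)
    haplotype: 0 gives balanced 50/50 methylation, +0.5 makes H1 always
    methylated.
    """
    rng = stream_rng(seed, 4)
    panels = {}
    p_h1 = min(max(0.5 + skew, 0.0), 1.0)
    for gene in genes:
        reads = []
        for hap in ("H1", "H2"):
            p = p_h1 if hap == "H1" else 1.0 - p_h1
            for _ in range(reads_per_haplotype):
                methylated = rng.random() < p
                lo, hi = (0.85, 1.0) if methylated else (0.0, 0.15)
                reads.append(MethylRead(hap, list(rng.uniform(lo, hi, size=8))))
        panels[gene] = MethylReadSet(locus=gene, reads=reads)
    return panels


def simulate_coverage(
    n_windows: int = 400,
    window_size: int = 500,
    baseline_depth: float = 30.0,
    gc_bias: float = 0.0,
    cnv_window_range: tuple[int, int] | None = None,
    cnv_copies: float = 2.0,
    mosaic_fraction: float = 1.0,
    chrom: str = "chr1",
    seed: int = 0,
) -> pd.DataFrame:
    """Windowed coverage track with optional GC bias and a planted CNV.

    Window depth is Poisson-distributed aggregate coverage: the total
    aligned bases in a window are drawn Poisson(expected depth x width) and
    divided by the width, emulating mean per-bp coverage of the window.
    GC fractions are uniform in (0.3, 0.7); ``gc_bias`` scales expected
    depth by (1 + gc_bias x (gc - 0.5)).  Inside ``cnv_window_range``
    (half-open window indices) expected depth is scaled by the copy number
    implied by ``cnv_copies`` present in ``mosaic_fraction`` of cells.
    """
    rng = stream_rng(seed, 5)
    gc = rng.uniform(0.3, 0.7, size=n_windows) if gc_bias != 0 else np.full(
        n_windows, 0.5
    )
    expected = baseline_depth * (1.0 + gc_bias * (gc - 0.5))
    cn = np.full(n_windows, 2.0)
    if cnv_window_range is not None:
        lo, hi = cnv_window_range
        cn[lo:hi] = 2.0 + mosaic_fraction * (cnv_copies - 2.0)
    expected = expected * cn / 2.0
    depth = rng.poisson(expected * window_size) / window_size
    starts = np.arange(n_windows) * window_size
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window_size,
            "depth": depth,
            "gc": gc,
        }
    )


def simulate_family_cohort(
    n_families: int = 200,
    burden_beta: float = 0.0,
    baseline_rate: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """1:1 matched case/control families with a Poisson burden covariate.

    Each family contributes one case and one control; burden counts are
    Poisson(baseline_rate) and, under ``burden_beta`` != 0, case status is
    assigned within family by the conditional logistic model with that
    log-odds ratio.
    """
    rng = stream_rng(seed, 6)
    rows = []
    for f in range(n_families):
        b = rng.poisson(baseline_rate, size=2)
        # conditional probability the first member is the case
        logit = burden_beta * (float(b[0]) - float(b[1]))
        p_first = 1.0 / (1.0 + np.exp(-logit))
        first_is_case = rng.random() < p_first
        for j, burden in enumerate(b):
            rows.append(
                {
                    "fid": f"F{f:04d}",
                    "subject": f"F{f:04d}_{j}",
                    "phenotype": int((j == 0) == first_is_case),
                    "burden": int(burden),
                }
            )
    return pd.DataFrame(rows)
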
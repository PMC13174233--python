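"""Merging of SV call sets within and across sequencing platforms.

Records of the same SV type are unified when they overlap reciprocally by at
least a configured fraction of each record's own span (both-fraction
semantics; a config switch relaxes this to the smaller interval).
Insertions, which are points with a length, are compared through
pseudo-intervals extending the anchor symmetrically by half the insertion
length.  Breakpoints of a merged pair come from the higher-priority set
(e.g. the Sniffles2-like caller over the LUMPY-like one, long-read over
short-read), and the platform of origin is tracked on every record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .genotype import GenotypeCall, ReadSupport


@dataclass
class MergeConfig:
    reciprocal_fraction: float = 0.5
    tr_overlap_fraction: float = 0.5
    min_cohort_support_reads: int = 1
    #: "both" requires the overlap fraction of each interval; "smaller"
    #: only of the shorter interval.
    reciprocal_mode: str = "both"
    #: minimum SQ for a re-genotyped call to count as cross-platform support
    rescue_min_sq: float = 0.0

    def __post_init__(self) -> None:
        for name in ("reciprocal_fraction", "tr_overlap_fraction"):
            f = getattr(self, name)
            if not 0.0 < f <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {f}")


@dataclass
class SVRecord:
    """One structural variant with provenance and per-sample genotypes."""

    id: str
    svtype: str
    chrom: str
    start: int
    end: int
    length: int
    source_callers: set = field(default_factory=set)
    platform: str = "LR"  # LR | SR | both
    genotypes: dict = field(default_factory=dict)  # sample -> GenotypeCall
    support: dict = field(default_factory=dict)  # sample -> ReadSupport

    def __post_init__(self) -> None:
        if self.svtype == "INS":
            if self.length <= 0:
                raise ValueError(f"{self.id}: INS length must be positive")
        elif self.end <= self.start:
            raise ValueError(f"{self.id}: end must exceed start")

    def interval(self) -> tuple[int, int]:
        if self.svtype == "INS":
            return insertion_pseudo_interval(self)
        return (self.start, self.end)

    def total_alt_reads(self) -> int:
        return sum(s.var_count for s in self.support.values())


def insertion_pseudo_interval(record: SVRecord) -> tuple[int, int]:
    """Symmetric pseudo-breakpoints for an insertion.

    The anchor is extended by half the insertion length in each direction
    (floor on the left, ceil on the right, clamped at the chromosome start),
    guaranteeing a nonzero-width interval even for 1 bp insertions.
    """
    if record.svtype != "INS":
        raise ValueError("pseudo-interval is defined for insertions only")
    half = record.length / 2.0
    lo = max(0, math.floor(record.start - half))
    hi = math.ceil(record.start + half)
    return (lo, hi)


def reciprocal_overlap(
    a: tuple[int, int], b: tuple[int, int], fraction: float, mode: str = "both"
) -> bool:
    """True when the overlap covers >= fraction of each (or the smaller) interval."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return False
    len_a, len_b = a[1] - a[0], b[1] - b[0]
    if mode == "both":
        return ov >= fraction * len_a and ov >= fraction * len_b
    if mode == "smaller":
        return ov >= fraction * min(len_a, len_b)
    raise ValueError(f"unknown reciprocal mode {mode!r}")


def _merge_records(primary: SVRecord, secondary: SVRecord) -> SVRecord:
    """Unify two matched records, keeping the primary's breakpoints."""
    merged = replace(
        primary,
        source_callers=set(primary.source_callers) | set(secondary.source_callers),
    )
    if primary.platform != secondary.platform:
        merged.platform = "both"
    merged.genotypes = {**secondary.genotypes, **primary.genotypes}
    merged.support = {**secondary.support, **primary.support}
    return merged


def merge_pairwise(
    set_a: list[SVRecord],
    set_b: list[SVRecord],
    config: MergeConfig | None = None,
) -> list[SVRecord]:
    """Merge two call sets; ``set_a`` has breakpoint priority.

    Records are compared per chromosome and SV type.  Matching is greedy in
    coordinate order: each A record absorbs every still-unmatched B record
    it overlaps reciprocally, so transitive chains resolve deterministically.
    Unmatched records pass through with their original provenance.
    """
    config = config or MergeConfig()
    frac, mode = config.reciprocal_fraction, config.reciprocal_mode

    by_key: dict[tuple[str, str], list[SVRecord]] = {}
    for rec in set_b:
        by_key.setdefault((rec.chrom, rec.svtype), []).append(rec)
    for recs in by_key.values():
        recs.sort(key=lambda r: (r.start, r.end, r.id))

    matched_b: set[int] = set()
    out: list[SVRecord] = []
    for rec in sorted(set_a, key=lambda r: (r.chrom, r.start, r.end, r.id)):
        merged = rec
        for other in by_key.get((rec.chrom, rec.svtype), []):
            if id(other) in matched_b:
                continue
            if reciprocal_overlap(merged.interval(), other.interval(), frac, mode):
                merged = _merge_records(merged, other)
                matched_b.add(id(other))
        out.append(merged)
    for recs in by_key.values():
        out.extend(r for r in recs if id(r) not in matched_b)
    out.sort(key=lambda r: (r.chrom, r.start, r.end, r.id))
    return out


def exclude_tr_overlap(
    svs: list[SVRecord],
    tr_regions: list[tuple[str, int, int]],
    config: MergeConfig | None = None,
) -> tuple[list[SVRecord], list[SVRecord]]:
    """Split SVs into (kept, excluded) by reciprocal overlap with TR regions.

    An SV is excluded when it overlaps any single TR region by strictly more
    than the configured fraction of both spans; such calls represent TR
    expansions/contractions handled by the repeat genotyper instead.
    """
    config = config or MergeConfig()
    frac = config.tr_overlap_fraction
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in tr_regions:
        by_chrom.setdefault(chrom, []).append((start, end))

    kept, excluded = [], []
    for rec in svs:
        iv = rec.interval()
        hit = False
        for tr in by_chrom.get(rec.chrom, []):
            ov = min(iv[1], tr[1]) - max(iv[0], tr[0])
            if ov <= 0:
                continue
            if ov > frac * (iv[1] - iv[0]) and ov > frac * (tr[1] - tr[0]):
                hit = True
                break
        (excluded if hit else kept).append(rec)
    return kept, excluded


def retain_min_support(
    svs: list[SVRecord], config: MergeConfig | None = None
) -> list[SVRecord]:
    """Keep records with at least the configured total ALT reads across subjects."""
    config = config or MergeConfig()
    thr = config.min_cohort_support_reads
    return [rec for rec in svs if rec.total_alt_reads() >= thr]


def crossplatform_rescue(
    lr_only: list[SVRecord],
    sr_only: list[SVRecord],
    sr_genotypes_of_lr: dict[str, GenotypeCall],
    lr_genotypes_of_sr: dict[str, GenotypeCall],
    config: MergeConfig | None = None,
) -> tuple[list[SVRecord], list[SVRecord]]:
    """Reassign platform-specific SVs with cross-platform genotype support.

    A platform-specific record whose re-genotyping on the other platform's
    data yields a non-reference call (with SQ at or above the configured
    floor) moves to the intersection set (platform="both").
    """
    config = config or MergeConfig()

    def supportive(call: GenotypeCall | None) -> bool:
        return (
            call is not None
            and call.is_variant()
            and call.sq >= config.rescue_min_sq
        )

    def relabel(records: list[SVRecord], regeno: dict) -> list[SVRecord]:
        out = []
        for rec in records:
            if supportive(regeno.get(rec.id)):
                rec = replace(rec, platform="both")
            out.append(rec)
        return out

    return relabel(lr_only, sr_genotypes_of_lr), relabel(sr_only, lr_genotypes_of_sr)
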
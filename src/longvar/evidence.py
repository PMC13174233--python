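"""Extract SV read support and tandem-repeat length deviations from phased alignments.

Reads carry haplotype tags (HP-style, mapped to H1/H2/unphased).  For a
candidate SV, each read spanning the locus is classified as ALT-supporting
(it carries an alignment signature matching the candidate), REF-supporting
(it spans both breakpoints cleanly), or uninformative (it does not span).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genotype import DEFAULT_ERROR_RATE, ReadSupport

# CIGAR operation consumption, following the SAM specification
_CONSUMES_REF = set("MDN=X")
_CONSUMES_QUERY = set("MIS=X")


@dataclass
class AlignedRead:
    """Minimal alignment record sufficient for SV-signature extraction."""

    name: str
    chrom: str
    start: int  # 0-based leftmost reference position
    cigar: list[tuple[str, int]]
    haplotag: str = "unphased"  # H1 | H2 | unphased
    is_supplementary: bool = False
    mapq: int = 60
    strand: str = "+"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("alignment start must be >= 0")
        for op, length in self.cigar:
            if op not in "MIDNSHP=X" or length < 0:
                raise ValueError(f"bad CIGAR element ({op}, {length})")

    @property
    def end(self) -> int:
        """Reference end (0-based, exclusive)."""
        return self.start + sum(n for op, n in self.cigar if op in _CONSUMES_REF)

    @property
    def query_start(self) -> int:
        """Offset of the first aligned base in the (clipped) query."""
        qs = 0
        for op, n in self.cigar:
            if op in "SH":
                qs += n
            else:
                break
        return qs

    def deletions(self) -> list[tuple[int, int, int]]:
        """(ref_start, ref_end, length) of every deletion CIGAR run."""
        out, pos = [], self.start
        for op, n in self.cigar:
            if op == "D":
                out.append((pos, pos + n, n))
            if op in _CONSUMES_REF:
                pos += n
        return out

    def insertions(self) -> list[tuple[int, int]]:
        """(ref_pos, length) of every insertion CIGAR op."""
        out, pos = [], self.start
        for op, n in self.cigar:
            if op == "I":
                out.append((pos, n))
            if op in _CONSUMES_REF:
                pos += n
        return out


def read_from_pysam(aln) -> AlignedRead:
    """Adapter from a pysam AlignedSegment (HP tag -> H1/H2)."""
    hp = None
    try:
        hp = aln.get_tag("HP")
    except KeyError:
        pass
    haplotag = {1: "H1", 2: "H2"}.get(hp, "unphased")
    cigar = [("MIDNSHP=X"[op], length) for op, length in (aln.cigartuples or [])]
    return AlignedRead(
        name=aln.query_name,
        chrom=aln.reference_name,
        start=aln.reference_start,
        cigar=cigar,
        haplotag=haplotag,
        is_supplementary=aln.is_supplementary,
        mapq=aln.mapping_quality,
        strand="-" if aln.is_reverse else "+",
        sequence=aln.query_sequence,
    )


def load_reads(path, chrom=None, start=None, end=None) -> list[AlignedRead]:
    """Read alignments from a SAM/BAM file, optionally over a region."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path)) as fh:
        it = fh.fetch(chrom, start, end) if chrom else fh
        for aln in it:
            if aln.is_unmapped:
                continue
            reads.append(read_from_pysam(aln))
    return reads


@dataclass
class SVCandidate:
    """One candidate structural variant (0-based half-open coordinates)."""

    svtype: str  # DEL | INS | DUP | INV
    chrom: str
    start: int
    end: int
    length: int

    def __post_init__(self) -> None:
        if self.svtype not in ("DEL", "INS", "DUP", "INV"):
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.svtype == "INS":
            if self.length <= 0:
                raise ValueError("insertion length must be positive")
        elif self.start >= self.end:
            raise ValueError("start must be < end for DEL/DUP/INV")


def _length_ok(observed: int, expected: int, tolerance: float) -> bool:
    return (1 - tolerance) * expected <= observed <= (1 + tolerance) * expected


def _split_pairs(group: list[AlignedRead]):
    """Ordered alignment pairs of one read, by query offset."""
    if len(group) < 2:
        return []
    ordered = sorted(group, key=lambda r: r.query_start)
    return list(zip(ordered[:-1], ordered[1:]))


def _supports_del(group, cand, window, tol) -> bool:
    for read in group:
        for dstart, dend, dlen in read.deletions():
            if (
                abs(dstart - cand.start) <= window
                and abs(dend - cand.end) <= window
                and _length_ok(dlen, cand.length, tol)
            ):
                return True
    # split alignment: two same-strand pieces with a reference gap at the candidate
    for a, b in _split_pairs(group):
        if a.strand != b.strand:
            continue
        gap = b.start - a.end
        if (
            abs(a.end - cand.start) <= window
            and abs(b.start - cand.end) <= window
            and _length_ok(gap, cand.length, tol)
        ):
            return True
    return False


def _supports_ins(group, cand, window, tol) -> bool:
    for read in group:
        for pos, ilen in read.insertions():
            if abs(pos - cand.start) <= window and _length_ok(ilen, cand.length, tol):
                return True
    return False


def _supports_dup(group, cand, window, tol) -> bool:
    # tandem duplication: read passes the right breakpoint then re-enters at the
    # left breakpoint on the same strand (reference position jumps backwards)
    for a, b in _split_pairs(group):
        if a.strand != b.strand:
            continue
        if (
            abs(a.end - cand.end) <= window
            and abs(b.start - cand.start) <= window
            and b.start < a.end
        ):
            return True
    return False


def _supports_inv(group, cand, window, tol) -> bool:
    for a, b in _split_pairs(group):
        if a.strand == b.strand:
            continue
        bps = sorted([a.end, b.end]) + sorted([a.start, b.start])
        near_start = min(abs(a.end - cand.start), abs(b.start - cand.start),
                         abs(a.start - cand.start), abs(b.end - cand.start))
        near_end = min(abs(a.end - cand.end), abs(b.start - cand.end),
                       abs(a.start - cand.end), abs(b.end - cand.end))
        if near_start <= window and near_end <= window:
            return True
    return False


_SUPPORT_FN = {
    "DEL": _supports_del,
    "INS": _supports_ins,
    "DUP": _supports_dup,
    "INV": _supports_inv,
}


def extract_sv_support(
    reads: list[AlignedRead],
    candidate: SVCandidate,
    window: int = 100,
    size_tolerance: float = 0.5,
    min_mapq: int = 1,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> ReadSupport:
    """Classify spanning reads as ALT/REF support for one candidate SV.

    Alignments of one read (primary + supplementary) are considered
    together, so a read with several qualifying signatures still counts
    once.  Reads with mapping quality below ``min_mapq`` are ignored.
    For DUP/INV candidates, support requires a supplementary-alignment pair
    with the orientation appropriate to the type; lone clipped alignments
    are uninformative.
    """
    groups: dict[str, list[AlignedRead]] = {}
    for read in reads:
        if read.chrom != candidate.chrom or read.mapq < min_mapq:
            continue
        groups.setdefault(read.name, []).append(read)

    if candidate.svtype == "INS":
        span_lo, span_hi = candidate.start - 1, candidate.end + 1
    else:
        span_lo, span_hi = candidate.start, candidate.end

    split = {h: [0, 0] for h in ("H1", "H2", "unphased")}
    support_fn = _SUPPORT_FN[candidate.svtype]
    for group in groups.values():
        lo = min(r.start for r in group)
        hi = max(r.end for r in group)
        is_alt = support_fn(group, candidate, window, size_tolerance)
        if not is_alt:
            # REF support requires one alignment spanning both breakpoints
            spans = any(r.start <= span_lo and r.end >= span_hi for r in group)
            if not spans:
                continue  # uninformative
        hap = group[0].haplotag
        split[hap][0 if is_alt else 1] += 1
    return ReadSupport.from_haplotypes(
        h1=tuple(split["H1"]),
        h2=tuple(split["H2"]),
        unphased=tuple(split["unphased"]),
        error_rate=error_rate,
    )


def extract_repeat_lengths(
    reads: list[AlignedRead],
    region: tuple[str, int, int],
    motif_length: int,
    reference_repeats: float = 0.0,
    min_mapq: int = 1,
) -> dict:
    """Per-read TR length deviations and per-haplotype mean repeat counts.

    Each read fully spanning ``region`` contributes a signed base-pair
    deviation: inserted bases minus deleted bases within the region.  The
    repeat count of a haplotype is the reference count plus the mean
    deviation of its reads divided by the motif length.  Haplotypes with no
    spanning read are reported as missing (absent from the result).
    """
    chrom, start, end = region
    deviations: dict[str, list[int]] = {}
    for read in reads:
        if read.chrom != chrom or read.mapq < min_mapq or read.is_supplementary:
            continue
        if read.start > start or read.end < end:
            continue
        dev = sum(n for pos, n in read.insertions() if start <= pos < end)
        dev -= sum(
            min(dend, end) - max(dstart, start)
            for dstart, dend, _ in read.deletions()
            if dstart < end and dend > start
        )
        deviations.setdefault(read.haplotag, []).append(dev)

    result = {"deviations": deviations, "repeat_counts": {}}
    for hap in ("H1", "H2"):
        devs = deviations.get(hap)
        if devs:
            mean_dev = sum(devs) / len(devs)
            result["repeat_counts"][hap] = reference_repeats + mean_dev / motif_length
    return result
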
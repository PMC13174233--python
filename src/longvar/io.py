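"""Readers and writers for the standard interchange formats.

SV records round-trip through VCF 4.2 (INFO: SVTYPE, SVLEN, END, PLATFORM,
SOURCES; FORMAT: GT, AD, DP, GQ, SQ) with 1-based VCF coordinates converted
to the 0-based half-open convention used internally.  TR regions come from
BED; tabular inputs (TR genotype tables, per-read methylation calls,
coverage tracks) are TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .genotype import GenotypeCall, ReadSupport
from .merge import SVRecord

_VCF_HEADER_LINES = [
    ('INFO', 'SVTYPE', '1', 'String', 'Structural variant type'),
    ('INFO', 'SVLEN', '1', 'Integer', 'Structural variant length'),
    ('INFO', 'END', '1', 'Integer', 'End position (1-based inclusive)'),
    ('INFO', 'PLATFORM', '1', 'String', 'Platform of origin (LR, SR or both)'),
    ('INFO', 'SOURCES', '.', 'String', 'Discovery callers'),
    ('FORMAT', 'GT', '1', 'String', 'Genotype'),
    ('FORMAT', 'AD', '2', 'Integer', 'Read depth by allele (ref, alt)'),
    ('FORMAT', 'DP', '1', 'Integer', 'Total read depth'),
    ('FORMAT', 'GQ', '1', 'Float', 'Phred-scaled genotype quality'),
    ('FORMAT', 'SQ', '1', 'Float', 'Phred-scaled non-reference sample quality'),
]


def write_sv_vcf(records: list[SVRecord], path, samples: list[str] | None = None,
                 contig_lengths: dict[str, int] | None = None) -> None:
    """Write SV records as VCF (symbolic ALT alleles, 1-based coordinates)."""
    if samples is None:
        seen = []
        for rec in records:
            for s in rec.genotypes:
                if s not in seen:
                    seen.append(s)
        samples = seen
    header = pysam.VariantHeader()
    contigs = contig_lengths or {}
    for rec in records:
        contigs.setdefault(rec.chrom, 300_000_000)
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    for kind, name, number, vtype, desc in _VCF_HEADER_LINES:
        header.add_meta(
            kind,
            items=[("ID", name), ("Number", number), ("Type", vtype),
                   ("Description", desc)],
        )
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.chrom, r.start, r.id)):
            # VCF SV convention: POS is the padding base before the event,
            # so the 1-based POS equals the 0-based internal start.
            v = out.new_record(
                contig=rec.chrom,
                start=max(rec.start - 1, 0),
                alleles=("N", f"<{rec.svtype}>"),
                id=rec.id,
            )
            v.info["SVTYPE"] = rec.svtype
            v.info["SVLEN"] = (
                -rec.length if rec.svtype == "DEL" else rec.length
            )
            v.info["PLATFORM"] = rec.platform
            if rec.source_callers:
                v.info["SOURCES"] = tuple(sorted(rec.source_callers))
            # set last: htslib recomputes END from SVLEN otherwise
            v.stop = rec.end if rec.svtype != "INS" else rec.start
            for s in samples:
                call = rec.genotypes.get(s)
                sup = rec.support.get(s)
                fmt = v.samples[s]
                if call is not None:
                    gt = call.phased_gt or call.gt
                    sep = "|" if "|" in gt else "/"
                    fmt.allele_indices = tuple(int(a) for a in gt.split(sep))
                    fmt.phased = sep == "|"
                    fmt["GQ"] = round(float(call.gq), 2)
                    fmt["SQ"] = round(float(call.sq), 2)
                if sup is not None:
                    fmt["AD"] = (sup.ref_count, sup.var_count)
                    fmt["DP"] = sup.depth
            out.write(v)


def _info_get(v, key, default=None):
    """INFO accessor tolerant of fields absent from the header."""
    try:
        return v.info.get(key, default)
    except (KeyError, ValueError):
        return default


def read_sv_vcf(path) -> list[SVRecord]:
    """Read SV records from VCF; coordinates converted to 0-based half-open."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for v in vcf:
            svtype = _info_get(v, "SVTYPE")
            if svtype is None:
                raise ValueError(f"{path}: record {v.id or v.pos} lacks SVTYPE")
            svlen = abs(int(_info_get(v, "SVLEN", 0)))
            start = v.start + 1  # POS is the padding base
            end = v.stop if svtype != "INS" else start
            if svtype != "INS" and end <= start:
                raise ValueError(
                    f"{path}: record {v.id or v.pos} has END <= POS"
                )
            if svtype != "INS" and not svlen:
                svlen = end - start
            genotypes, support = {}, {}
            for s, fmt in v.samples.items():
                idx = fmt.allele_indices
                if idx is None or any(a is None for a in idx):
                    continue
                sep = "|" if fmt.phased else "/"
                gt_str = sep.join(str(a) for a in sorted(idx))
                phased = sep.join(str(a) for a in idx) if fmt.phased else None
                genotypes[s] = GenotypeCall(
                    gt=gt_str.replace("|", "/"),
                    posteriors=(float("nan"),) * 3,
                    gq=float(fmt.get("GQ") or 0.0),
                    sq=float(fmt.get("SQ") or 0.0),
                    phased_gt=phased,
                )
                ad = fmt.get("AD")
                if ad is not None and None not in ad:
                    support[s] = ReadSupport(var_count=ad[1], ref_count=ad[0])
            records.append(
                SVRecord(
                    id=v.id or f"{v.chrom}_{v.pos}_{svtype}",
                    svtype=svtype,
                    chrom=v.chrom,
                    start=start,
                    end=end if svtype != "INS" else start,
                    length=svlen,
                    source_callers=set(_info_get(v, "SOURCES", ())),
                    platform=_info_get(v, "PLATFORM", "LR"),
                    genotypes=genotypes,
                    support=support,
                )
            )
    return records


def read_bed(path) -> list[tuple[str, int, int]]:
    """BED intervals as (chrom, start, end) tuples (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    return list(df.itertuples(index=False, name=None))


def write_bed(intervals, path) -> None:
    pd.DataFrame(intervals).to_csv(path, sep="\t", header=False, index=False)


def read_tr_table(path) -> pd.DataFrame:
    """TR genotype table TSV: region, subject, hap, deviation, quality, reads."""
    df = pd.read_csv(path, sep="\t")
    required = {"region", "subject", "hap", "deviation", "quality", "reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TR table missing columns: {sorted(missing)}")
    if "missing" not in df.columns:
        df["missing"] = df["deviation"].isna()
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path):
    """Per-read methylation TSV: read, locus, haplotag, likelihoods (comma-sep)."""
    from .methylation import MethylRead, MethylReadSet

    df = pd.read_csv(path, sep="\t", dtype=str)
    loci = {}
    for row in df.itertuples(index=False):
        liks = [float(x) for x in row.likelihoods.split(",")]
        loci.setdefault(row.locus, []).append(MethylRead(row.haplotag, liks))
    return {locus: MethylReadSet(locus, reads) for locus, reads in loci.items()}


def write_methylation_tsv(readsets: dict, path) -> None:
    rows = []
    for locus, readset in readsets.items():
        for i, read in enumerate(readset.reads):
            rows.append(
                {
                    "read": f"{locus}_r{i}",
                    "locus": locus,
                    "haplotag": read.haplotag,
                    "likelihoods": ",".join(
                        f"{x:.4f}" for x in read.cpg_likelihoods
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path) -> pd.DataFrame:
    """Coverage track TSV/bedGraph with columns chrom, start, end, depth, gc."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "depth", "gc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coverage track missing columns: {sorted(missing)}")
    return df
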
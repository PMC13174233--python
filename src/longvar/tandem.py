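"""Tandem-repeat region preprocessing, cohort Z-scores and outlier burden.

A cohort TR genotype table is a long-format DataFrame with one row per
(region, subject, haplotype): signed base-pair deviation from the reference
allele, a genotype quality in [0, 1], the number of supporting reads, and a
missing flag.  Z-scores standardize each region's deviations against the
cohort-wide distribution; outlier haplotypes drive per-subject burden
scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TABLE_COLUMNS = ["region", "subject", "hap", "deviation", "quality", "reads"]


@dataclass
class TRRegion:
    chrom: str
    start: int
    end: int
    motif: str = ""
    reference_repeats: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("TR region end must exceed start")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def preprocess_regions(
    raw_regions: list[TRRegion] | list[tuple],
    merge_gap: int = 100,
    flank: int = 30,
) -> list[TRRegion]:
    """Merge nearby TR annotations and pad with flanks.

    Regions separated by at most ``merge_gap`` bp are unified, then
    ``flank`` bp is added to both ends (clamped at the chromosome start).
    Merging happens before flanking, so the output is sorted and the
    pre-flank intervals are non-overlapping.
    """
    regions = [
        r if isinstance(r, TRRegion) else TRRegion(*r) for r in raw_regions
    ]
    by_chrom: dict[str, list[TRRegion]] = {}
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        by_chrom.setdefault(r.chrom, []).append(r)

    out: list[TRRegion] = []
    for chrom in sorted(by_chrom):
        merged: list[TRRegion] = []
        for r in by_chrom[chrom]:
            if merged and r.start - merged[-1].end <= merge_gap:
                last = merged[-1]
                last.end = max(last.end, r.end)
                if r.motif and r.motif != last.motif:
                    last.motif = last.motif or r.motif
                last.reference_repeats += r.reference_repeats
            else:
                merged.append(
                    TRRegion(r.chrom, r.start, r.end, r.motif, r.reference_repeats)
                )
        for r in merged:
            r.start = max(0, r.start - flank)
            r.end = r.end + flank
        out.extend(merged)
    return out


def _observed(table: pd.DataFrame) -> pd.Series:
    if "missing" in table.columns:
        return ~table["missing"].astype(bool)
    return table["deviation"].notna()


def compute_zscores(table: pd.DataFrame) -> pd.DataFrame:
    """Per-haplotype Z-scores of base-pair deviations within each region.

    Z = (deviation - cohort mean) / cohort sample SD (ddof=1), over all
    non-missing haplotypes of the region.  Monomorphic regions (SD = 0) get
    Z = 0 everywhere; regions with fewer than two observations are skipped
    with a warning.  Returns the table with a ``z`` column (NaN where
    missing or skipped).
    """
    table = table.copy()
    table["z"] = np.nan
    obs = _observed(table)
    for region, idx in table[obs].groupby("region").groups.items():
        devs = table.loc[idx, "deviation"].astype(float)
        if len(devs) < 2:
            warnings.warn(f"region {region}: <2 observations, Z-scores skipped")
            continue
        sd = devs.std(ddof=1)
        if sd == 0:
            table.loc[idx, "z"] = 0.0
        else:
            table.loc[idx, "z"] = (devs - devs.mean()) / sd
    return table


#: Outlier criterion presets.  "burden" is the burden-score definition
#: (|dev| >= 50, quality > 0.9, |Z| > 3, >= 2 reads); "fig1h" swaps the
#: Z criterion for rarity among parental haplotypes (AF < 0.5).
OUTLIER_PRESETS = ("burden", "fig1h")


def parent_haplotype_af(
    table: pd.DataFrame, parent_subjects: set, min_deviation: int = 50
) -> pd.Series:
    """Per-region fraction of non-missing parental haplotypes with |dev| >= threshold."""
    parents = table[table["subject"].isin(parent_subjects) & _observed(table)]
    if parents.empty:
        return pd.Series(dtype=float)
    big = parents["deviation"].abs() >= min_deviation
    return big.groupby(parents["region"]).mean()


def call_outliers(
    table: pd.DataFrame,
    preset: str = "burden",
    parent_subjects: set | None = None,
    min_deviation: int = 50,
    min_quality: float = 0.9,
    min_z: float = 3.0,
    min_reads: int = 2,
    max_parent_af: float = 0.5,
) -> pd.DataFrame:
    """Outlier haplotype calls under a named criterion preset.

    Returns the qualifying rows (region, subject, hap, deviation, z, ...).
    The "burden" preset requires |deviation| >= 50 bp, quality > 0.9,
    |Z| > 3 and support from >= 2 reads.  The "fig1h" preset replaces the
    Z-score criterion with rarity: the fraction of parental haplotypes with
    a >= 50 bp deviation at the region must be < 0.5.
    """
    if preset not in OUTLIER_PRESETS:
        raise ValueError(f"unknown outlier preset {preset!r}")
    obs = table[_observed(table)].copy()
    base = (
        (obs["deviation"].abs() >= min_deviation)
        & (obs["quality"] > min_quality)
        & (obs["reads"] >= min_reads)
    )
    if preset == "burden":
        if "z" not in obs.columns:
            raise ValueError("burden preset requires a 'z' column (compute_zscores)")
        mask = base & (obs["z"].abs() > min_z)
    else:
        if parent_subjects is None:
            raise ValueError("fig1h preset requires parent_subjects")
        af = parent_haplotype_af(table, parent_subjects, min_deviation)
        region_af = obs["region"].map(af).fillna(0.0)
        mask = base & (region_af < max_parent_af)
    return obs[mask]


def missingness_filter(
    table: pd.DataFrame,
    max_region_missing: float = 0.25,
    max_subject_missing: float = 0.50,
) -> pd.DataFrame:
    """Drop poorly genotyped regions, then poorly genotyped subjects.

    A subject is missing at a region when either haplotype lacks a call.
    Regions missing in more than ``max_region_missing`` of subjects are
    removed first; subjects then missing more than ``max_subject_missing``
    of the remaining regions are removed.  The order matters and follows
    the region-first convention.
    """
    # subject x region completeness: every haplotype row observed
    df = table.assign(_obs=_observed(table))
    complete = df.groupby(["region", "subject"])["_obs"].all()
    wide = complete.unstack("subject").fillna(False)
    region_missing = 1.0 - wide.mean(axis=1)
    bad_regions = set(region_missing[region_missing > max_region_missing].index)
    wide = wide.drop(index=bad_regions, errors="ignore")
    if len(wide):
        subject_missing = 1.0 - wide.mean(axis=0)
        bad_subjects = set(subject_missing[subject_missing > max_subject_missing].index)
    else:
        bad_subjects = set()
    return table[
        ~table["region"].isin(bad_regions) & ~table["subject"].isin(bad_subjects)
    ]


def tr_burden(
    outliers: pd.DataFrame,
    category_masks: dict[str, set] | None = None,
    region_motifs: dict[str, str] | None = None,
    exclude_homopolymers: bool = True,
) -> pd.DataFrame:
    """Per-subject burden: number of distinct outlier TR regions per category.

    A region counts once per subject regardless of how many of its
    haplotypes are outliers.  Homopolymer repeats (motif length 1) are
    excluded when motifs are supplied, reflecting their elevated genotyping
    error rate.  ``category_masks`` maps a category name to the set of
    region ids it contains; the "all" category is always reported.
    """
    calls = outliers
    if exclude_homopolymers and region_motifs:
        homopolymers = {r for r, m in region_motifs.items() if len(m) == 1}
        calls = calls[~calls["region"].isin(homopolymers)]
    per_subject = calls.groupby("subject")["region"].agg(set)
    masks = {"all": None, **(category_masks or {})}
    out = {}
    for name, mask in masks.items():
        out[name] = per_subject.map(
            lambda regions: len(regions if mask is None else regions & mask)
        )
    return pd.DataFrame(out).fillna(0).astype(int)
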
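"""Copy-number estimation from windowed read depth.

Short-read coverage is summarized as mean per-bp depth over fixed windows
(100 or 500 bp), GC-corrected with a local-regression smoother, and
normalized by flanking regions: per-window CN = 2 x depth / flank mean.
The region estimate is the mean window CN with a t-based 95% CI and a
two-sided one-sample t-test against the diploid value 2.  Intermediate
copy numbers indicate somatic mosaicism; for a one-copy heterozygous gain
the cell fraction is CN - 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRACK_COLUMNS = ["chrom", "start", "end", "depth", "gc"]


def make_track(chrom, starts, ends, depth, gc) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "depth": depth, "gc": gc}
    )


@dataclass
class CNEstimate:
    copy_number: float
    ci_low: float
    ci_high: float
    p_value: float  # two-sided t-test vs CN 2
    n_windows: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.copy_number <= self.ci_high:
            raise ValueError("CI must contain the point estimate")


def gc_correct(track: pd.DataFrame, span: float = 0.3, min_windows: int = 20) -> pd.DataFrame:
    """Divide out the GC-depth trend fitted by tricube local regression.

    corrected = depth / fitted(gc) x overall mean depth, which preserves the
    total mean.  Tracks with fewer than ``min_windows`` windows or a
    degenerate GC distribution are returned unchanged with a warning.
    """
    track = track.copy()
    depth = track["depth"].to_numpy(dtype=float)
    gc = track["gc"].to_numpy(dtype=float)
    if len(track) < min_windows or len(np.unique(gc)) < 2:
        warnings.warn("degenerate GC distribution; identity GC correction applied")
        return track
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fitted = lowess(depth, gc, frac=span, return_sorted=False)
    fitted = np.clip(fitted, np.finfo(float).eps, None)
    track["depth"] = depth / fitted * depth.mean()
    return track


def _window_mask(track: pd.DataFrame, region: tuple[str, int, int]) -> np.ndarray:
    chrom, start, end = region
    return (
        (track["chrom"] == chrom)
        & (track["end"] > start)
        & (track["start"] < end)
    ).to_numpy()


def estimate_copy_number(
    track: pd.DataFrame,
    region: tuple[str, int, int],
    flanks: tuple[tuple[str, int, int], tuple[str, int, int]] | None = None,
    buffer_windows: int = 1,
) -> CNEstimate:
    """Flank-normalized copy number of a region with CI and t-test.

    When ``flanks`` is omitted, flanking windows of the same total width as
    the region are taken on each side, separated from it by
    ``buffer_windows`` windows.  Per-window CN = 2 x depth / flank-mean;
    the point estimate, 95% CI and two-sided t-test (df = n - 1) are over
    the region windows.
    """
    in_region = _window_mask(track, region)
    if flanks is None:
        chrom, start, end = region
        width = end - start
        idx = np.flatnonzero(in_region)
        if idx.size == 0:
            raise ValueError("region contains no windows")
        wsize = int(track["end"].iloc[idx[0]] - track["start"].iloc[idx[0]])
        pad = buffer_windows * wsize
        flanks = (
            (chrom, start - pad - width, start - pad),
            (chrom, end + pad, end + pad + width),
        )
    in_flank = _window_mask(track, flanks[0]) | _window_mask(track, flanks[1])
    in_flank &= ~in_region
    if not in_flank.any():
        raise ValueError("no flanking windows available")

    region_depths = track.loc[in_region, "depth"].to_numpy(dtype=float)
    flank_depths = track.loc[in_flank, "depth"].to_numpy(dtype=float)
    flank_mean = float(flank_depths.mean())
    cns = 2.0 * region_depths / flank_mean
    n = cns.size
    point = float(cns.mean())
    if n > 1:
        sem = stats.sem(cns)
        half = stats.t.ppf(0.975, n - 1) * sem
        # Testing CN != 2 is testing equal mean depth in region and flanks.
        # A one-sample t of window CNs against 2 ignores that the flank mean
        # is itself estimated (its error shifts every CN coherently) and
        # rejects far too often; Welch's two-sample test on the depths is
        # calibrated.
        p = float(
            stats.ttest_ind(region_depths, flank_depths, equal_var=False).pvalue
        )
    else:
        half, p = 0.0, float("nan")
    return CNEstimate(point, point - half, point + half, p, n)


def mosaic_fraction(cn: float, baseline: float = 2.0) -> float:
    """Cell fraction of a one-copy heterozygous gain or loss.

    A duplication in a fraction f of cells shifts the copy number to
    baseline + f; a heterozygous deletion to baseline - f.  The estimate is
    the absolute deviation from baseline, clamped to [0, 1].
    """
    return float(np.clip(abs(cn - baseline), 0.0, 1.0))
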
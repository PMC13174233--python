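"""Family-based rare-variant burden association.

Per-subject burden scores count rare (parental allele frequency < 0.05),
high-quality (SQ > 20) SVs intersecting a functional category, excluding
calls whose breakpoints both fall inside paired segmental duplications
(likely mapping artifacts).  Association with case status is tested by
conditional logistic regression stratified on family, so only families
discordant on phenotype are informative; the burden term's significance
comes from a likelihood-ratio test, and variance explained is summarized
with Cox-Snell / Nagelkerke pseudo-R2:

    cs_r2  = 1 - exp(2/N * (loglik0 - loglikM))
    ngk_r2 = cs_r2 / (1 - exp(2/N * loglik0))

Confidence intervals are bootstrapped over families; platform-stratified
results combine by fixed-effect meta-analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from .merge import SVRecord


def _interval_hits(iv: tuple[int, int], intervals) -> bool:
    return any(iv[0] < e and iv[1] > s for s, e in intervals)


def _in_paired_segdup(sv: SVRecord, segdup_pairs) -> bool:
    """Both breakpoints inside the two halves of one segmental-duplication pair."""
    for (c1, s1, e1), (c2, s2, e2) in segdup_pairs:
        if sv.chrom not in (c1, c2):
            continue
        bp1, bp2 = sv.start, sv.end
        in_a = lambda bp, c, s, e: c == sv.chrom and s <= bp < e
        if (in_a(bp1, c1, s1, e1) and in_a(bp2, c2, s2, e2)) or (
            in_a(bp1, c2, s2, e2) and in_a(bp2, c1, s1, e1)
        ):
            return True
    return False


def sv_burden_scores(
    svs: list[SVRecord],
    subjects: list[str],
    category_masks: dict[str, dict[str, list[tuple[int, int]]]],
    parental_af: dict[str, float],
    segdup_pairs: list | None = None,
    sq_min: float = 20.0,
    max_af: float = 0.05,
    extra_events: dict[str, dict[str, int]] | None = None,
) -> pd.DataFrame:
    """Per-subject counts of rare high-quality SVs per functional category.

    ``category_masks`` maps category -> chrom -> interval list; an SV counts
    for a subject when the subject's call is non-reference with SQ above
    ``sq_min``, the variant's parental allele frequency is below ``max_af``,
    its span intersects the category, and it is not a paired-segdup
    artifact.  ``extra_events`` adds designated events (e.g. an aneuploidy)
    to chosen categories for chosen subjects.
    """
    segdup_pairs = segdup_pairs or []
    counts = pd.DataFrame(0, index=pd.Index(subjects, name="subject"),
                          columns=list(category_masks))
    for sv in svs:
        if parental_af.get(sv.id, 1.0) >= max_af:
            continue
        if _in_paired_segdup(sv, segdup_pairs):
            continue
        iv = sv.interval()
        cats = [
            name
            for name, mask in category_masks.items()
            if _interval_hits(iv, mask.get(sv.chrom, []))
        ]
        if not cats:
            continue
        for subject, call in sv.genotypes.items():
            if subject in counts.index and call.is_variant() and call.sq > sq_min:
                counts.loc[subject, cats] += 1
    for subject, extras in (extra_events or {}).items():
        for cat, k in extras.items():
            if subject in counts.index and cat in counts.columns:
                counts.loc[subject, cat] += k
    return counts


@dataclass
class ConditionalLogitFit:
    params: pd.Series
    bse: pd.Series
    llf: float
    llnull: float
    n_subjects: int
    n_informative_strata: int
    result: object  # underlying statsmodels results


def null_conditional_loglik(df: pd.DataFrame, outcome: str, strata: str) -> float:
    """Covariate-free conditional log-likelihood: sum of -log C(n_i, k_i)."""
    ll = 0.0
    for _, g in df.groupby(strata):
        k = int(g[outcome].sum())
        n = len(g)
        if 0 < k < n:
            ll -= math.log(comb(n, k, exact=True))
    return ll


def fit_conditional_logistic(
    df: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    strata: str = "fid",
) -> ConditionalLogitFit:
    """Conditional logistic regression stratified on family.

    Maximizes the within-stratum conditional likelihood; strata concordant
    on the outcome contribute nothing and are dropped.  Raises on a
    rank-deficient design (naming the collinear columns) and warns on
    apparent separation (inflated coefficients).
    """
    from statsmodels.discrete.conditional_models import ConditionalLogit

    informative = df.groupby(strata)[outcome].transform(
        lambda s: 0 < s.sum() < len(s)
    )
    data = df[informative.astype(bool)]
    n_strata = data[strata].nunique()
    if n_strata < 2:
        raise ValueError("need at least two outcome-discordant strata")

    X = data[covariates].astype(float)
    if np.linalg.matrix_rank(X.to_numpy()) < len(covariates):
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [
            f"{a}~{b}"
            for a in corr.index
            for b in corr.columns
            if a < b and corr.loc[a, b] > 0.999
        ]
        raise ValueError(
            "rank-deficient design; collinear columns: " + (", ".join(pairs) or "?")
        )

    model = ConditionalLogit(
        data[outcome].astype(int).to_numpy(), X, groups=data[strata].to_numpy()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0)
    params = pd.Series(res.params, index=covariates)
    if params.abs().max() > 15:
        warnings.warn(
            "near-infinite coefficient: possible separation; interpret with care"
        )
    return ConditionalLogitFit(
        params=params,
        bse=pd.Series(res.bse, index=covariates),
        llf=float(res.llf),
        llnull=null_conditional_loglik(data, outcome, strata),
        n_subjects=len(data),
        n_informative_strata=n_strata,
        result=res,
    )


def lrt_burden(full: ConditionalLogitFit, null: ConditionalLogitFit | float,
               df_diff: int | None = None) -> float:
    """Likelihood-ratio p-value for the burden term(s).

    ``null`` may be a fitted reduced model or a bare log-likelihood (the
    covariate-free conditional likelihood has closed form).  The statistic
    2(loglikM - loglik0) is referred to chi-square with df equal to the
    parameter-count difference.
    """
    null_llf = null if isinstance(null, (int, float)) else null.llf
    if df_diff is None:
        if isinstance(null, (int, float)):
            df_diff = len(full.params)
        else:
            df_diff = len(full.params) - len(null.params)
    stat = 2.0 * (full.llf - null_llf)
    if df_diff == 0:
        if abs(stat) < 1e-8:
            return 1.0
        raise ValueError("models with equal parameter counts are not nested")
    if df_diff < 0:
        raise ValueError("null model has more parameters than the full model")
    return float(stats.chi2.sf(max(stat, 0.0), df_diff))


def nagelkerke_r2(loglik0: float, loglikM: float, n: int) -> tuple[float, float]:
    """(Cox-Snell R2, Nagelkerke R2) from null/full log-likelihoods."""
    if loglikM < loglik0 - 1e-9:
        raise ValueError("full-model log-likelihood below the null's")
    cs = 1.0 - math.exp(2.0 / n * (loglik0 - loglikM))
    denom = 1.0 - math.exp(2.0 / n * loglik0)
    return cs, cs / denom


def bootstrap_ci(
    statistic,
    df: pd.DataFrame,
    strata: str = "fid",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI resampling whole strata (families).

    ``statistic`` maps a resampled DataFrame to a scalar.  Families are
    drawn with replacement and relabelled so repeated draws stay distinct
    strata.  Resamples where the statistic fails (degenerate outcome
    pattern) are skipped; more than half failing is an error.
    """
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    families = df[strata].unique()
    groups = {f: g for f, g in df.groupby(strata)}
    values = []
    for _ in range(n_boot):
        chosen = rng.choice(families, size=len(families), replace=True)
        parts = []
        for i, fam in enumerate(chosen):
            g = groups[fam].copy()
            g[strata] = f"bs{i}"
            parts.append(g)
        sample = pd.concat(parts, ignore_index=True)
        try:
            values.append(float(statistic(sample)))
        except Exception:
            continue
    if len(values) < n_boot / 2:
        raise ValueError("bootstrap failed on most resamples (degenerate data)")
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def meta_analyze(
    results: list[tuple[float, float]],
    method: str = "inverse_variance",
    sample_sizes: list[int] | None = None,
) -> dict:
    """Combine per-platform (beta, SE) estimates.

    Fixed-effect inverse-variance weighting by default; the alternative
    weights z-scores by sqrt(sample size).  A single stratum passes through
    with a note.
    """
    if not results:
        raise ValueError("no results to combine")
    if len(results) == 1:
        beta, se = results[0]
        z = beta / se
        return {
            "beta": beta, "se": se, "z": z,
            "p": float(2 * stats.norm.sf(abs(z))),
            "note": "single stratum: passthrough",
        }
    betas = np.array([b for b, _ in results], dtype=float)
    ses = np.array([s for _, s in results], dtype=float)
    if method == "inverse_variance":
        w = 1.0 / ses**2
        beta = float(np.sum(w * betas) / np.sum(w))
        se = float(1.0 / math.sqrt(np.sum(w)))
        z = beta / se
    elif method == "sample_size":
        if sample_sizes is None:
            raise ValueError("sample_size method requires sample_sizes")
        zs = betas / ses
        w = np.sqrt(np.asarray(sample_sizes, dtype=float))
        z = float(np.sum(w * zs) / math.sqrt(np.sum(w**2)))
        beta, se = float("nan"), float("nan")
    else:
        raise ValueError(f"unknown meta-analysis method {method!r}")
    return {"beta": beta, "se": se, "z": float(z),
            "p": float(2 * stats.norm.sf(abs(z)))}
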
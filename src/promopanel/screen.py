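"""Candidate marker screening between two sample groups.

Two complementary screens operate on a promoter count matrix:

* a negative-binomial exact test per region with a pooled (common)
  dispersion, Benjamini-Hochberg FDR control, and fold-change / expression
  thresholds, yielding candidate marker promoters; and
* a complete-separation screen that reports promoters whose CPM ranges in
  the two groups are disjoint, i.e. a single expression threshold
  classifies every sample correctly.

The exact test conditions on each region's total count after equalizing
library sizes: the sum of counts in a group of n samples sharing mean mu and
dispersion phi is itself negative binomial with mean n*mu and dispersion
phi/n, so the two-sided p-value is the total conditional probability of all
splits of the total no more probable than the observed one
(minimum-likelihood method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix, cpm

#: log-probability tie tolerance when summing outcomes "no more probable
#: than observed" (guards against floating-point ties).
_LOG_TIE_TOL = 1e-10


@dataclass(frozen=True)
class ScreenThresholds:
    """Candidate thresholds; all comparisons are strict."""

    max_fdr: float = 0.01
    min_fold: float = 4.0  # linear fold change, either direction
    min_cpm: float = 4.0

    def __post_init__(self) -> None:
        if self.max_fdr <= 0 or self.min_fold <= 0 or self.min_cpm <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class SeparatorResult:
    region_id: str
    direction: str  # name of the group with uniformly higher CPM
    threshold: float  # CPM value separating the groups
    margin: float  # log2(min of high group / max of low group)


def _scale_to_common_libsize(
    counts: np.ndarray, lib_sizes: np.ndarray | None
) -> np.ndarray:
    """Equalize library sizes by deterministic scaling to the geometric mean."""
    counts = np.asarray(counts, dtype=float)
    if lib_sizes is None:
        return np.rint(counts)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    common = np.exp(np.mean(np.log(lib_sizes)))
    return np.rint(counts * common / lib_sizes)


def _group_sum_logpmf(x: np.ndarray, n: int, mu: float, phi: float) -> np.ndarray:
    """log pmf of the sum of n iid NB(mean mu, dispersion phi) counts."""
    mean = n * mu
    if phi == 0.0:
        return poisson.logpmf(x, mean)
    r = n / phi
    p = r / (r + mean)
    return nbinom.logpmf(x, r, p)


def nb_exact_test(
    counts_a,
    counts_b,
    phi: float,
    lib_sizes=None,
) -> float:
    """Two-sided exact NB test of equal mean between two groups.

    Parameters
    ----------
    counts_a, counts_b
        Raw counts of one region in the two groups.
    phi
        Common NB dispersion (variance = mu + phi*mu^2); 0 gives Poisson.
    lib_sizes
        Library sizes ordered as ``list(counts_a) + list(counts_b)``; when
        given, counts are scaled to the geometric-mean library size and
        rounded before testing.

    Returns
    -------
    float
        p-value in (0, 1].
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    scaled = _scale_to_common_libsize(np.concatenate([a, b]), lib_sizes)
    na, nb_ = len(a), len(b)
    sa = int(scaled[:na].sum())
    total = int(scaled.sum())
    if total == 0:
        return 1.0
    mu = total / (na + nb_)
    x = np.arange(total + 1)
    logp = _group_sum_logpmf(x, na, mu, phi) + _group_sum_logpmf(
        total - x, nb_, mu, phi
    )
    keep = logp <= logp[sa] + _LOG_TIE_TOL
    pval = float(np.exp(logsumexp(logp[keep]) - logsumexp(logp)))
    return min(pval, 1.0)


def estimate_common_dispersion(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    lib_sizes: pd.Series | None = None,
) -> float:
    """Pooled method-of-moments estimate of the common NB dispersion.

    Counts are scaled to the geometric-mean library size; per region the
    moment estimate (var - mean) / mean^2 is averaged over the two groups,
    and the estimator is the median over regions, floored at zero.
    """
    for g in (group_a, group_b):
        if len(g) < 2:
            raise ValueError("each group needs >= 2 samples to estimate dispersion")
    ests = []
    for g in (group_a, group_b):
        y = counts[g].to_numpy(dtype=float)
        if lib_sizes is not None:
            ls = lib_sizes[g].to_numpy(dtype=float)
            y = y * np.exp(np.mean(np.log(ls))) / ls
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ests.append(np.where(m > 0, (v - m) / m**2, np.nan))
    per_region = np.nanmean(np.column_stack(ests), axis=1)
    per_region = per_region[~np.isnan(per_region)]
    if per_region.size == 0:
        return 0.0
    return float(max(0.0, np.median(per_region)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def candidate_filter(
    results: pd.DataFrame, thresholds: ScreenThresholds = ScreenThresholds()
) -> tuple[pd.Index, pd.Index]:
    """Partition candidate regions into (up in group1, up in group2).

    A candidate satisfies fdr < max_fdr, |linear fold change| > min_fold and
    mean_cpm > min_cpm, all strict. ``log2fc > 0`` means higher in the
    second-named group.
    """
    keep = (
        (results["fdr"] < thresholds.max_fdr)
        & (np.abs(results["log2fc"]) > np.log2(thresholds.min_fold))
        & (results["mean_cpm"] > thresholds.min_cpm)
    )
    cand = results.loc[keep]
    up_group1 = cand.index[cand["log2fc"] < 0]
    up_group2 = cand.index[cand["log2fc"] > 0]
    return up_group1, up_group2


def complete_separation(
    values_a, values_b, region_id: str = "", names: tuple[str, str] = ("A", "B")
) -> SeparatorResult | None:
    """Report a separating threshold if the two groups' values are disjoint.

    Returns ``None`` when the ranges overlap or the boundary values tie. The
    threshold is the geometric mean of the two boundary values (arithmetic
    midpoint when the lower boundary is zero); the margin is
    ``log2(min of high group / max of low group)`` (infinite when the low
    group is entirely zero).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.max() < b.min():
        low_max, high_min, direction = a.max(), b.min(), names[1]
    elif b.max() < a.min():
        low_max, high_min, direction = b.max(), a.min(), names[0]
    else:
        return None
    if low_max == 0.0:
        threshold = high_min / 2.0
        margin = np.inf
    else:
        threshold = float(np.sqrt(low_max * high_min))
        margin = float(np.log2(high_min / low_max))
    return SeparatorResult(region_id, direction, threshold, margin)


def run_screen(
    m: CountMatrix,
    sample_table: pd.DataFrame,
    group_a: str,
    group_b: str,
    thresholds: ScreenThresholds = ScreenThresholds(),
    phi: float | None = None,
    by: str = "subtype",
    log2fc_prior_count: float = 0.5,
) -> pd.DataFrame:
    """Full candidate screen between two groups of samples.

    Runs the NB exact test per region (``log2fc > 0`` means higher in
    ``group_b``), adjusts with BH, applies the candidate thresholds, and
    searches for completely separating promoters among the candidates.

    Returns a DataFrame indexed by region id with columns mean_cpm, log2fc,
    pvalue, fdr, candidate, separator, direction, sep_threshold, margin.
    """
    labels = sample_table.loc[m.samples, by]
    ids_a = list(labels.index[labels == group_a])
    ids_b = list(labels.index[labels == group_b])
    if not ids_a or not ids_b:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    sub = m.subset_samples(ids_a + ids_b)
    if phi is None:
        phi = estimate_common_dispersion(
            sub.counts, ids_a, ids_b, lib_sizes=sub.library_sizes
        )

    cpm_ab = cpm(sub)
    mean_cpm = cpm_ab.mean(axis=1)
    # prior count of 0.5 on the common-library-size scale, expressed in CPM,
    # stabilizes fold changes at zero counts
    common = np.exp(np.mean(np.log(sub.library_sizes.to_numpy(dtype=float))))
    prior_cpm = log2fc_prior_count * 1e6 / common
    mean_a = cpm_ab[ids_a].mean(axis=1)
    mean_b = cpm_ab[ids_b].mean(axis=1)
    log2fc = np.log2((mean_b + prior_cpm) / (mean_a + prior_cpm))

    lib = sub.library_sizes[ids_a + ids_b].to_numpy()
    counts_a = sub.counts[ids_a].to_numpy()
    counts_b = sub.counts[ids_b].to_numpy()
    pvals = np.array(
        [
            nb_exact_test(counts_a[i], counts_b[i], phi, lib_sizes=lib)
            for i in range(sub.counts.shape[0])
        ]
    )
    out = pd.DataFrame(
        {
            "mean_cpm": mean_cpm,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
        },
        index=sub.counts.index,
    )
    up1, up2 = candidate_filter(out, thresholds)
    out["candidate"] = out.index.isin(up1.union(up2))

    out["separator"] = False
    out["direction"] = ""
    out["sep_threshold"] = np.nan
    out["margin"] = np.nan
    for rid in out.index[out["candidate"]]:
        sep = complete_separation(
            cpm_ab.loc[rid, ids_a],
            cpm_ab.loc[rid, ids_b],
            region_id=rid,
            names=(group_a, group_b),
        )
        if sep is not None:
            out.loc[rid, ["separator", "direction", "sep_threshold", "margin"]] = [
                True,
                sep.direction,
                sep.threshold,
                sep.margin,
            ]
    out.attrs["phi"] = phi
    out.attrs["groups"] = (group_a, group_b)
    return out
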
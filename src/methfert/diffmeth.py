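"""Differentially methylated cytosine calling.

Two site-level tests are provided:

* ``pooled`` — a coverage-pooled likelihood-ratio test: binomial regression
  of (methylated, unmethylated) counts on class membership, which reduces to
  comparing the two coverage-pooled class proportions with a chi-square(1)
  LR statistic. Powerful, but blind to inter-individual overdispersion.
* ``dispersion`` — a Wald test on the difference of class proportions with a
  beta-binomial variance; the per-class dispersion is estimated by the method
  of moments from per-sample proportions and coverages and floored at 0.
  Conservative under strong inter-individual variability.

A site is a DMC when its BH-adjusted q-value is below the threshold AND the
coverage-weighted group difference is at least ``diff_threshold`` percentage
points (both criteria required). Defaults: pooled q < 0.01, dispersion
q < 0.1, difference >= 10 points.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MethCountMatrix
from .sitefilter import coverage_filter

logger = logging.getLogger(__name__)

__all__ = [
    "weighted_group_methylation",
    "dmc_test_pooled",
    "dmc_test_dispersion",
    "adjust_pvalues",
    "site_test_table",
    "call_dmcs",
    "repeat_profile",
]


def _class_indices(matrix: MethCountMatrix, classes: pd.Series):
    labels = classes.reindex(matrix.samples)
    fert = np.flatnonzero((labels == "fertile").to_numpy())
    sub = np.flatnonzero((labels == "subfertile").to_numpy())
    if len(fert) == 0 or len(sub) == 0:
        raise ValueError("both classes must be non-empty")
    return fert, sub


def _pooled_counts(matrix, idx, use, rows=None):
    """Summed (meth, total) over a class's usable cells, per site."""
    meth = np.where(use[:, idx], matrix.meth[:, idx], 0)
    total = np.where(use[:, idx], matrix.total[:, idx], 0)
    if rows is not None:
        meth, total = meth[rows], total[rows]
    return meth.sum(axis=1).astype(float), total.sum(axis=1).astype(float)


def weighted_group_methylation(matrix: MethCountMatrix, classes: pd.Series,
                               min_reads: int = 10):
    """Coverage-weighted methylation percentage per class, per site.

    Percentage = 100 * (sum methylated) / (sum total) over the class's CpG10
    cells; NaN where a class has no usable cell.
    """
    fert, sub = _class_indices(matrix, classes)
    use = coverage_filter(matrix, min_reads)
    out = {}
    for name, idx in (("fertile", fert), ("subfertile", sub)):
        m, n = _pooled_counts(matrix, idx, use)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(n > 0, 100.0 * m / n, np.nan)
    return out["fertile"], out["subfertile"]


def _binom_ll(m, n, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return m * np.log(p) + (n - m) * np.log1p(-p)


def _pooled_lr_pvalues(m1, n1, m2, n2):
    """Vectorized LR test of equal binomial proportions from pooled counts."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = m1 / n1
        p2 = m2 / n2
        p0 = (m1 + m2) / (n1 + n2)
    lr = 2.0 * (_binom_ll(m1, n1, p1) + _binom_ll(m2, n2, p2)
                - _binom_ll(m1 + m2, n1 + n2, p0))
    lr = np.maximum(lr, 0.0)
    pvals = stats.chi2.sf(lr, df=1)
    pvals = np.where(np.isclose(p1, p2), 1.0, pvals)
    bad = (n1 == 0) | (n2 == 0)
    if np.any(bad):
        raise ValueError("pooled test requires reads in both classes at every site")
    return pvals


def _bb_class_stats(meth, total, use, min_samples=2):
    """Per-site pooled proportion and beta-binomial variance for one class.

    Method-of-moments dispersion phi from the chi-square of per-sample
    proportions around the pooled proportion::

        X2 = sum_i n_i (p_i - p)^2 / (p(1-p)),   E[X2] ~ (k-1) + phi*sum(n_i-1)
        phi = max(0, (X2 - (k-1)) / sum(n_i - 1))

    Var(p_pooled) = p(1-p) * sum n_i (1 + (n_i-1) phi) / N^2.
    Sites with fewer than ``min_samples`` usable samples get NaN.
    """
    m = np.where(use, meth, 0).astype(float)
    n = np.where(use, total, 0).astype(float)
    k = use.sum(axis=1).astype(float)
    N = n.sum(axis=1)
    M = m.sum(axis=1)
    ok = (k >= min_samples) & (N > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(N > 0, M / N, np.nan)
        # clamp away from 0/1 so the variance never degenerates exactly
        p_c = np.clip(p, 0.5 / np.maximum(N, 1), 1 - 0.5 / np.maximum(N, 1))
        pi = np.where(n > 0, m / n, 0.0)
        x2 = np.nansum(n * (pi - p_c[:, None]) ** 2, axis=1) / (p_c * (1 - p_c))
        denom = np.maximum((n - (n > 0)).sum(axis=1), 1.0)  # sum(n_i - 1)
        phi = np.maximum(0.0, (x2 - (k - 1)) / denom)
        var = (p_c * (1 - p_c)
               * (n * (1 + (n - 1) * phi[:, None])).sum(axis=1) / N**2)
    p = np.where(ok, p, np.nan)
    var = np.where(ok, var, np.nan)
    return p, var, phi


def _dispersion_pvalues(matrix, fert, sub, use):
    p1, v1, _ = _bb_class_stats(matrix.meth[:, fert], matrix.total[:, fert],
                                use[:, fert])
    p2, v2, _ = _bb_class_stats(matrix.meth[:, sub], matrix.total[:, sub],
                                use[:, sub])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (p2 - p1) / np.sqrt(v1 + v2)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.where(np.isclose(p1, p2), 1.0, pvals)
    pvals = np.where(np.isnan(p1) | np.isnan(p2), np.nan, pvals)
    return pvals


# -- per-site scalar interfaces --------------------------------------------

def dmc_test_pooled(matrix: MethCountMatrix, site: tuple[str, int],
                    classes: pd.Series, min_reads: int = 10) -> float:
    """Pooled LR p-value at one (chrom, pos) site."""
    row = matrix.site_lookup()[site]
    fert, sub = _class_indices(matrix, classes)
    use = coverage_filter(matrix, min_reads)
    m1, n1 = _pooled_counts(matrix, fert, use, rows=[row])
    m2, n2 = _pooled_counts(matrix, sub, use, rows=[row])
    return float(_pooled_lr_pvalues(m1, n1, m2, n2)[0])


def dmc_test_dispersion(matrix: MethCountMatrix, site: tuple[str, int],
                        classes: pd.Series, min_reads: int = 10) -> float:
    """Beta-binomial Wald p-value at one site; NaN if either class has <2
    usable samples (skipped, not imputed)."""
    row = matrix.site_lookup()[site]
    fert, sub = _class_indices(matrix, classes)
    use = coverage_filter(matrix, min_reads)
    sub_matrix = matrix.subset_sites([row])
    return float(_dispersion_pvalues(sub_matrix, fert, sub, use[[row]])[0])


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    if method != "bh":
        raise ValueError(f"unknown adjustment method {method!r}")
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0,1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def site_test_table(matrix: MethCountMatrix, classes: pd.Series,
               test: str = "pooled", min_reads: int = 10) -> pd.DataFrame:
    """Run the chosen test at every site of (an already-filtered) matrix.

    Returns one row per site: chrom, pos, p, q, meth_fertile,
    meth_subfertile, delta (subfertile - fertile, percentage points),
    direction, test. Sites where the test is undefined (dispersion test with
    <2 usable samples in a class) carry NaN p/q and are excluded from the BH
    adjustment; their count is logged.
    """
    if test not in ("pooled", "dispersion"):
        raise ValueError(f"unknown test {test!r}")
    fert, sub = _class_indices(matrix, classes)
    use = coverage_filter(matrix, min_reads)
    if test == "pooled":
        m1, n1 = _pooled_counts(matrix, fert, use)
        m2, n2 = _pooled_counts(matrix, sub, use)
        p = _pooled_lr_pvalues(m1, n1, m2, n2)
    else:
        p = _dispersion_pvalues(matrix, fert, sub, use)
        n_skipped = int(np.isnan(p).sum())
        if n_skipped:
            logger.info("dispersion test undefined at %d sites (skipped)", n_skipped)
    mf, ms = weighted_group_methylation(matrix, classes, min_reads)
    delta = ms - mf
    q = np.full(len(p), np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested] = adjust_pvalues(p[tested])
    out = matrix.sites[["chrom", "pos"]].copy()
    out["p"] = p
    out["q"] = q
    out["meth_fertile"] = mf
    out["meth_subfertile"] = ms
    out["delta"] = delta
    out["direction"] = np.where(delta > 0, "hyper", "hypo")
    out["test"] = test
    return out


DEFAULT_Q = {"pooled": 0.01, "dispersion": 0.1}


def call_dmcs(matrix: MethCountMatrix, classes: pd.Series,
              test: str = "pooled", q_threshold: float | None = None,
              diff_threshold: float = 10.0, min_reads: int = 10) -> pd.DataFrame:
    """DMC records: q < q_threshold AND |delta| >= diff_threshold.

    ``q_threshold`` defaults to 0.01 for the pooled test and 0.1 for the
    dispersion-aware test.
    """
    if q_threshold is None:
        q_threshold = DEFAULT_Q[test]
    table = site_test_table(matrix, classes, test=test, min_reads=min_reads)
    is_dmc = (table["q"] < q_threshold) & (table["delta"].abs() >= diff_threshold)
    return table[is_dmc.fillna(False)].reset_index(drop=True)


def repeat_profile(matrix: MethCountMatrix, classes: pd.Series,
                   min_reads: int = 10, window: int = 5) -> pd.DataFrame:
    """Per-position class means along one consensus repeat.

    ``matrix`` must be restricted to the positions of a single consensus
    element, ordered along it. Returns per-position coverage-weighted class
    percentages, their difference, and a centered moving-average trend per
    class (window from config; trend is NaN-filled when fewer than 2
    positions are available). The frame carries the overall mean difference
    in ``attrs['mean_difference']``.
    """
    mf, ms = weighted_group_methylation(matrix, classes, min_reads)
    out = matrix.sites[["chrom", "pos"]].copy()
    out["meth_fertile"] = mf
    out["meth_subfertile"] = ms
    out["difference"] = ms - mf
    if len(out) >= 2:
        roll = lambda v: (pd.Series(v).rolling(window, center=True, min_periods=1)
                          .mean().to_numpy())
        out["trend_fertile"] = roll(mf)
        out["trend_subfertile"] = roll(ms)
    else:
        out["trend_fertile"] = np.nan
        out["trend_subfertile"] = np.nan
    out.attrs["mean_difference"] = float(np.nanmean(out["difference"]))
    return out
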
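"""Accessibility matrix, size factors, negative-binomial testing and PCA.

Counting fills a peaks x samples matrix of fragment overlaps with the
atlas. Normalization uses median-of-ratios size factors. Differential
testing is a two-group negative-binomial Wald test: per-peak dispersions
come from a method-of-moments estimate shrunk in log space toward a robust
a0 + a1/mu trend fitted across peaks, and the group effect is estimated by
iteratively reweighted least squares on a log-link NB GLM with the log size
factor as offset. The moment estimate is floored at the trend value before
shrinkage: with a handful of replicates a peak cannot give usable evidence
of sub-trend dispersion, and an unfloored estimate near zero would turn
the test into a near-Poisson one and inflate false positives. The PCA
operates on log2(normalized count + 1) over the most variable peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = ["atlas_id", "baseMean", "log2FC", "lfcSE", "stat",
                  "pvalue", "qvalue", "alpha"]

_MIN_ALPHA = 1e-8


@dataclass
class AccessibilityMatrix:
    """Peaks x samples fragment counts plus per-sample size factors."""

    counts: pd.DataFrame            # rows = atlas ids, columns = samples
    size_factors: Optional[pd.Series] = None

    @property
    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not estimated yet")
        return self.counts / self.size_factors


def count_matrix(atlas: pd.DataFrame,
                 sample_fragments: Mapping[str, pd.DataFrame]
                 ) -> AccessibilityMatrix:
    """Count fragments overlapping (>= 1 bp) each atlas interval.

    Atlas intervals are disjoint; a fragment spanning a gap between two
    intervals increments both.
    """
    ids = atlas["atlas_id"].to_list()
    data = {}
    by_chrom = {chrom: sub.sort_values("start")
                for chrom, sub in atlas.groupby("chrom")}
    row_of = {aid: i for i, aid in enumerate(ids)}
    for sample, frags in sample_fragments.items():
        col = np.zeros(len(ids), dtype=np.int64)
        if len(frags) == 0:
            warnings.warn(f"sample {sample} has zero fragments")
        for chrom, sub in by_chrom.items():
            fsub = frags[frags["chrom"] == chrom]
            if len(fsub) == 0:
                continue
            istart = sub["start"].to_numpy()
            iend = sub["end"].to_numpy()
            rows = np.array([row_of[a] for a in sub["atlas_id"]])
            s = fsub["start"].to_numpy()
            e = fsub["end"].to_numpy()
            lo = np.searchsorted(iend, s, side="right")
            hi = np.searchsorted(istart, e, side="left")
            simple = hi == lo + 1
            if simple.any():
                col += np.bincount(rows[lo[simple]], minlength=len(ids))
            multi = np.flatnonzero(hi > lo + 1)
            for k in multi:
                col[rows[lo[k]:hi[k]]] += 1
        data[sample] = col
    counts = pd.DataFrame(data, index=pd.Index(ids, name="atlas_id"))
    return AccessibilityMatrix(counts)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over rows with all-positive counts."""
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no row with all-positive counts; supply a "
                         "pseudo-reference fallback")
    sub = counts.loc[positive].to_numpy(float)
    log_g = np.log(sub).mean(axis=1)
    ratios = sub / np.exp(log_g)[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns,
                     name="size_factor")


# ----------------------------------------------------------- NB Wald test

def _dispersion_trend(alpha_raw: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Robust a0 + a1/mu trend (Huber M-estimator) across peaks."""
    use = (alpha_raw > 10 * _MIN_ALPHA) & (mu > 0)
    if use.sum() < 10:
        med = float(np.median(alpha_raw[alpha_raw > 10 * _MIN_ALPHA])
                    ) if (alpha_raw > 10 * _MIN_ALPHA).any() else 0.1
        return np.full(len(mu), max(med, _MIN_ALPHA))
    X = np.column_stack([np.ones(int(use.sum())), 1.0 / mu[use]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.RLM(alpha_raw[use], X, M=sm.robust.norms.HuberT()).fit()
    a0, a1 = fit.params
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu, 1e-8)
    return np.maximum(trend, _MIN_ALPHA)


def estimate_dispersions(norm_counts: np.ndarray,
                         group2: np.ndarray) -> np.ndarray:
    """Moment dispersion per peak, shrunk in log space toward the trend.

    The raw estimate is (s^2 - ybar) / ybar^2 with the variance pooled
    within groups, floored at the trend value; the final dispersion is the
    equal-weight log-scale average of the floored estimate and the trend.
    """
    y = norm_counts
    n = y.shape[1]
    g1 = ~group2
    m1 = y[:, g1].mean(axis=1, keepdims=True)
    m2 = y[:, group2].mean(axis=1, keepdims=True)
    ss = (((y[:, g1] - m1) ** 2).sum(axis=1)
          + ((y[:, group2] - m2) ** 2).sum(axis=1))
    s2 = ss / max(n - 2, 1)
    ybar = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        moment = (s2 - ybar) / ybar ** 2
    moment = np.where(np.isfinite(moment), moment, _MIN_ALPHA)
    alpha_raw = np.maximum(moment, _MIN_ALPHA)
    trend = _dispersion_trend(alpha_raw, ybar)
    floored = np.maximum(moment, trend)
    return np.exp(0.5 * (np.log(floored) + np.log(trend)))


def _irls_two_group(counts: np.ndarray, x: np.ndarray,
                    log_sf: np.ndarray, alpha: np.ndarray,
                    n_iter: int = 50, tol: float = 1e-8):
    """Vectorized IRLS for per-peak NB GLM: log mu = log s_j + b0 + b1 x."""
    eps = 0.5
    g2 = x.astype(bool)
    y_norm = counts / np.exp(log_sf)[None, :]
    m1 = y_norm[:, ~g2].mean(axis=1)
    m2 = y_norm[:, g2].mean(axis=1)
    b0 = np.log(m1 + eps)
    b1 = np.log(m2 + eps) - np.log(m1 + eps)
    for _ in range(n_iter):
        eta = log_sf[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - log_sf[None, :]) + (counts - mu) / mu
        sw = W.sum(axis=1)
        swx = (W * x).sum(axis=1)
        swz = (W * z).sum(axis=1)
        swxz = (W * x * z).sum(axis=1)
        det = sw * swx - swx ** 2
        bad = np.abs(det) < 1e-12
        det = np.where(bad, 1.0, det)
        b0n = np.where(bad, b0, (swx * swz - swx * swxz) / det)
        b1n = np.where(bad, b1, (sw * swxz - swx * swz) / det)
        delta = max(np.max(np.abs(b0n - b0), initial=0.0),
                    np.max(np.abs(b1n - b1), initial=0.0))
        b0, b1 = b0n, b1n
        if delta < tol:
            break
    eta = log_sf[None, :] + b0[:, None] + b1[:, None] * x[None, :]
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    W = mu / (1.0 + alpha[:, None] * mu)
    sw = W.sum(axis=1)
    swx = (W * x).sum(axis=1)
    det = np.maximum(sw * swx - swx ** 2, 1e-12)
    se_b1 = np.sqrt(sw / det)
    return b1, se_b1


def nb_wald_test(matrix: AccessibilityMatrix, labels: Sequence[str],
                 group1: str, group2: str) -> pd.DataFrame:
    """Two-group NB Wald test for every atlas peak (group2 vs group1).

    Returns base mean, log2 fold change with standard error, Wald
    statistic, two-sided p and BH q (computed over peaks with positive
    base mean; all-zero peaks are reported with null statistics).
    """
    labels = np.asarray(labels)
    sel = np.isin(labels, [group1, group2])
    if (labels == group1).sum() < 2 or (labels == group2).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    counts = matrix.counts.loc[:, sel].to_numpy(float)
    if matrix.size_factors is None:
        matrix.size_factors = estimate_size_factors(matrix.counts)
    sf = matrix.size_factors.to_numpy(float)[sel]
    x = (labels[sel] == group2).astype(float)

    norm = counts / sf[None, :]
    base_mean = norm.mean(axis=1)
    nonzero = base_mean > 0

    alpha = np.full(len(base_mean), np.nan)
    l2fc = np.full(len(base_mean), np.nan)
    se = np.full(len(base_mean), np.nan)
    pval = np.full(len(base_mean), np.nan)
    if nonzero.any():
        a = estimate_dispersions(norm[nonzero], x.astype(bool))
        b1, se_b1 = _irls_two_group(counts[nonzero], x, np.log(sf), a)
        ln2 = np.log(2.0)
        alpha[nonzero] = a
        l2fc[nonzero] = b1 / ln2
        se[nonzero] = se_b1 / ln2
        pval[nonzero] = 2.0 * stats.norm.sf(np.abs(b1 / se_b1))

    qval = np.full(len(base_mean), np.nan)
    if nonzero.any():
        qval[nonzero] = multipletests(pval[nonzero], method="fdr_bh")[1]
    stat = l2fc / se
    return pd.DataFrame({
        "atlas_id": matrix.counts.index,
        "baseMean": base_mean,
        "log2FC": l2fc,
        "lfcSE": se,
        "stat": stat,
        "pvalue": pval,
        "qvalue": qval,
        "alpha": alpha,
    }).reset_index(drop=True)


def select_differential(results: pd.DataFrame, fdr: float = 0.05,
                        fc: float = 4.0) -> pd.DataFrame:
    """Apply the FDR and linear fold-change gates; label the direction."""
    log2_fc = np.log2(fc)
    keep = (results["qvalue"] < fdr) & (results["log2FC"].abs() > log2_fc)
    out = results.loc[keep.fillna(False)].copy()
    out["direction"] = np.where(out["log2FC"] > 0, "up_in_group2",
                                "up_in_group1")
    return out.reset_index(drop=True)


# -------------------------------------------------------------------- PCA

def pca_samples(matrix: AccessibilityMatrix, n_top: int = 500):
    """Sample PCA on log2(normalized count + 1) over top-variance peaks.

    Returns a frame of per-sample PC scores and the vector of explained
    variance fractions. Component signs are fixed deterministically (the
    largest-magnitude loading of each component is positive).
    """
    if matrix.counts.shape[1] < 3:
        raise ValueError("need >= 3 samples for PCA")
    if matrix.size_factors is None:
        matrix.size_factors = estimate_size_factors(matrix.counts)
    log_norm = np.log2(matrix.normalized.to_numpy(float) + 1.0)
    var = log_norm.var(axis=1)
    n_top_eff = min(n_top, len(var))
    if n_top_eff < n_top:
        warnings.warn(f"only {n_top_eff} peaks available for PCA")
    top = np.argsort(var, kind="stable")[::-1][:n_top_eff]
    X = log_norm[top]
    X = X - X.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(X.T, full_matrices=False)
    # deterministic sign convention
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    with np.errstate(invalid="ignore", divide="ignore"):
        var_frac = s ** 2 / max((s ** 2).sum(), 1e-300)
    n_pc = min(scores.shape[1], 10)
    frame = pd.DataFrame(
        scores[:, :n_pc],
        columns=[f"PC{k + 1}" for k in range(n_pc)],
        index=matrix.counts.columns)
    frame.index.name = "sample"
    return frame, var_frac[:n_pc]
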
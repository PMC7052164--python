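"""Replicate reproducibility via the irreproducible discovery rate (IDR)
and construction of the merged accessibility atlas.

Peak scores from two replicates are rank-transformed and modelled as a
two-component Gaussian copula mixture: a reproducible component
N((mu, mu), sigma^2, rho) and an independent standard-normal noise
component. The fit alternates one EM step with a pseudo-data update, in
which the normal scores are recomputed through the inverse CDF of the
current marginal mixture — the estimation scheme of the published IDR
procedure. Each pair's local idr is its posterior noise probability; the
global IDR of a pair is the running mean of sorted local idr values up to
it. A peak is reproducible within a sample group if it passes the IDR
threshold in at least one replicate pair; reproducible peaks from all
groups are merged (bookended intervals included) into a genome-wide atlas
with stable identifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .params import DEFAULT_PARAMS, PipelineParams


class DegenerateScoresError(ValueError):
    """Scores carry no rank information (all tied)."""


class InsufficientPairsError(ValueError):
    """Fewer than the minimum number of matched pairs for a stable fit."""


# ------------------------------------------------------------ peak matching

def peak_scores(peaks: pd.DataFrame) -> np.ndarray:
    """Evidence score fed to IDR (only ranks matter downstream).

    Prefers the caller's log-space -log10 p, which stays continuous for
    arbitrarily strong peaks; BH q-values are running minima, so their
    ties among top peaks would put point masses into the rank transform
    and destabilise the copula fit.
    """
    if "neglog10p" in peaks.columns:
        return peaks["neglog10p"].to_numpy(float)
    return -np.log10(np.maximum(peaks["qvalue"].to_numpy(float), 1e-300))


def match_replicate_peaks(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame
                          ) -> pd.DataFrame:
    """Pair peaks across two replicates by largest overlap.

    Peaks overlapping by >= 1 bp are candidates; pairs are accepted greedily
    by decreasing overlap (leftmost peak on ties) with each peak used at
    most once. Returns one row per accepted pair with both peak indices,
    footprint bounds and scores; unmatched peaks are simply absent.
    """
    if len(peaks_a) == 0 or len(peaks_b) == 0:
        warnings.warn("empty peak set: no pairs to match")
        return pd.DataFrame(columns=["idx_a", "idx_b", "chrom", "start",
                                     "end", "score_a", "score_b"])
    sa, sb = peak_scores(peaks_a), peak_scores(peaks_b)
    cand: List[Tuple[int, int, int, int]] = []  # (-overlap, start_a, ia, ib)
    for chrom in np.intersect1d(peaks_a["chrom"].unique(),
                                peaks_b["chrom"].unique()):
        ia = np.flatnonzero((peaks_a["chrom"] == chrom).to_numpy())
        ib = np.flatnonzero((peaks_b["chrom"] == chrom).to_numpy())
        as_, ae = (peaks_a["start"].to_numpy()[ia],
                   peaks_a["end"].to_numpy()[ia])
        bs, be = (peaks_b["start"].to_numpy()[ib],
                  peaks_b["end"].to_numpy()[ib])
        ov = (np.minimum(ae[:, None], be[None, :])
              - np.maximum(as_[:, None], bs[None, :]))
        ii, jj = np.nonzero(ov > 0)
        for i, j in zip(ii, jj):
            cand.append((-int(ov[i, j]), int(as_[i]), int(ia[i]),
                         int(ib[j])))
    cand.sort()
    used_a, used_b = set(), set()
    rows = []
    for _neg, _s, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        rows.append((i, j, peaks_a["chrom"].iat[i],
                     min(peaks_a["start"].iat[i], peaks_b["start"].iat[j]),
                     max(peaks_a["end"].iat[i], peaks_b["end"].iat[j]),
                     sa[i], sb[j]))
    out = pd.DataFrame(rows, columns=["idx_a", "idx_b", "chrom", "start",
                                      "end", "score_a", "score_b"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


# ------------------------------------------------------------------ IDR fit

@dataclass
class IDRFit:
    """Copula-mixture parameters and per-pair (ir)reproducibility.

    ``idr_local`` is the posterior probability of the noise component;
    ``idr_global`` the running mean of sorted local values (monotone in the
    local idr). ``converged`` is False when the iteration cap was hit, in
    which case the best estimate is still returned.
    """

    pi1: float
    mu: float
    sigma2: float
    rho: float
    idr_local: np.ndarray
    idr_global: np.ndarray
    n_iter: int
    converged: bool


def _mixture_ppf(u: np.ndarray, pi1: float, mu: float,
                 sigma2: float) -> np.ndarray:
    sd = np.sqrt(sigma2)
    lo = min(-7.0, mu - 7.0 * sd)
    hi = max(7.0, mu + 7.0 * sd)
    grid = np.linspace(lo, hi, 8192)
    cdf = pi1 * stats.norm.cdf(grid, mu, sd) + (1 - pi1) * stats.norm.cdf(
        grid)
    return np.interp(u, cdf, grid)


def _posterior_noise(z1, z2, pi1, mu, sigma2, rho):
    det = sigma2 ** 2 * (1.0 - rho ** 2)
    d1, d2 = z1 - mu, z2 - mu
    q = (d1 ** 2 + d2 ** 2 - 2 * rho * d1 * d2) / (sigma2 * (1 - rho ** 2))
    f1 = np.exp(-0.5 * q) / (2 * np.pi * np.sqrt(det))
    f0 = np.exp(-0.5 * (z1 ** 2 + z2 ** 2)) / (2 * np.pi)
    num1 = pi1 * f1
    den = num1 + (1 - pi1) * f0
    den = np.maximum(den, 1e-300)
    return (1 - pi1) * f0 / den, num1 / den


_EM_INITS = ((0.5, 1.0, 0.5), (0.9, 2.0, 0.8), (0.3, 3.0, 0.3))


def _run_ecm(u1, u2, init, max_iter, tol):
    """Pseudo-data ECM from one starting point; returns fit + likelihood."""
    pi1, mu, rho = init
    sigma2 = 1.0  # fixed at the noise scale; see fit_idr notes
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z1 = _mixture_ppf(u1, pi1, mu, sigma2)
        z2 = _mixture_ppf(u2, pi1, mu, sigma2)
        g0, g1 = _posterior_noise(z1, z2, pi1, mu, sigma2, rho)
        w = g1.sum()
        if w < 1e-12:
            break
        pi1_n = float(np.clip(g1.mean(), 1e-4, 1 - 1e-4))
        mu_n = float((g1 * (z1 + z2)).sum() / (2 * w))
        d1, d2 = z1 - mu_n, z2 - mu_n
        rho_n = float(np.clip((g1 * d1 * d2).sum() / (w * sigma2),
                              0.0, 0.999))
        delta = max(abs(pi1_n - pi1), abs(mu_n - mu), abs(rho_n - rho))
        pi1, mu, rho = pi1_n, mu_n, rho_n
        if delta < tol:
            converged = True
            break
    z1 = _mixture_ppf(u1, pi1, mu, sigma2)
    z2 = _mixture_ppf(u2, pi1, mu, sigma2)
    det = sigma2 ** 2 * (1.0 - rho ** 2)
    d1, d2 = z1 - mu, z2 - mu
    q = (d1 ** 2 + d2 ** 2 - 2 * rho * d1 * d2) / (sigma2 * (1 - rho ** 2))
    f1 = np.exp(-0.5 * q) / (2 * np.pi * np.sqrt(det))
    f0 = np.exp(-0.5 * (z1 ** 2 + z2 ** 2)) / (2 * np.pi)
    loglik = float(np.log(np.maximum(pi1 * f1 + (1 - pi1) * f0,
                                     1e-300)).sum())
    return (pi1, mu, sigma2, rho), converged, it, loglik


def fit_idr(scores_a: np.ndarray, scores_b: np.ndarray,
            max_iter: int = 500, tol: float = 1e-6,
            min_pairs: int = 20) -> IDRFit:
    """Fit the reproducibility copula mixture to paired peak scores.

    Average ranks map each margin to uniform quantiles (n+1 denominator);
    the pseudo-data normal scores are refreshed from the current mixture
    CDF inverse after every EM step until parameters move < ``tol`` or the
    iteration cap is reached (flagged, best estimate returned). The
    reproducible component's variance is pinned to the noise variance
    (sigma^2 = 1): with a free variance the rank transform lets the EM
    manufacture likelihood by compressing pseudo-data into a shrinking
    component, a degenerate optimum that small peak sets reliably find.
    Three deterministic starting points are run and the best
    pseudo-likelihood wins.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    n = len(scores_a)
    if n != len(scores_b):
        raise ValueError("score vectors differ in length")
    if n < min_pairs:
        raise InsufficientPairsError(
            f"need >= {min_pairs} pairs, got {n}")
    if not (np.isfinite(scores_a).all() and np.isfinite(scores_b).all()):
        raise ValueError("scores must be finite")
    if np.unique(scores_a).size < 2 or np.unique(scores_b).size < 2:
        raise DegenerateScoresError("all scores tied in one replicate")

    u1 = stats.rankdata(scores_a, method="average") / (n + 1)
    u2 = stats.rankdata(scores_b, method="average") / (n + 1)

    best = None
    for init in _EM_INITS:
        fit = _run_ecm(u1, u2, init, max_iter, tol)
        if best is None or fit[3] > best[3]:
            best = fit
    (pi1, mu, sigma2, rho), converged, it, _ = best
    if not converged:
        warnings.warn("IDR EM did not converge; returning best estimate")

    z1 = _mixture_ppf(u1, pi1, mu, sigma2)
    z2 = _mixture_ppf(u2, pi1, mu, sigma2)
    idr_local, _ = _posterior_noise(z1, z2, pi1, mu, sigma2, rho)
    order = np.argsort(idr_local, kind="stable")
    running = np.cumsum(idr_local[order]) / np.arange(1, n + 1)
    idr_global = np.empty(n)
    idr_global[order] = running
    return IDRFit(pi1, mu, sigma2, rho, idr_local, idr_global, it,
                  converged)


# ------------------------------------------------- group-level reproducibility

def reproducible_peaks(replicate_peaks: Sequence[pd.DataFrame],
                       params: PipelineParams = DEFAULT_PARAMS,
                       ) -> pd.DataFrame:
    """Peaks passing IDR < threshold in at least one replicate pair.

    For every unordered replicate pair the copula mixture is fitted on
    matched peak scores; the union footprint of each passing pair is
    retained. Footprints from all pairs are merged (within-group union).
    """
    if len(replicate_peaks) < 2:
        raise ValueError("need >= 2 replicates for IDR; use a --no-idr "
                         "override for single-replicate groups")
    kept = []
    for i in range(len(replicate_peaks)):
        for j in range(i + 1, len(replicate_peaks)):
            pairs = match_replicate_peaks(replicate_peaks[i],
                                          replicate_peaks[j])
            if len(pairs) == 0:
                continue
            fit = fit_idr(pairs["score_a"].to_numpy(),
                          pairs["score_b"].to_numpy())
            ok = fit.idr_global < params.idr_threshold
            kept.append(pairs.loc[ok, ["chrom", "start", "end"]])
    if not kept:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return merge_intervals(pd.concat(kept, ignore_index=True))


# -------------------------------------------------------------------- atlas

@dataclass
class Atlas:
    """Ordered non-overlapping accessible intervals with stable ids."""

    intervals: pd.DataFrame  # chrom, start, end, atlas_id
    provenance: Dict[str, List[str]]  # atlas_id -> contributing groups


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals; overlapping or bookended intervals are merged."""
    if len(intervals) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = intervals.sort_values(["chrom", "start", "end"]).reset_index(
        drop=True)
    rows = []
    cur = None
    for rec in df.itertuples(index=False):
        if (cur is not None and rec.chrom == cur[0]
                and rec.start <= cur[2]):
            cur[2] = max(cur[2], rec.end)
        else:
            if cur is not None:
                rows.append(tuple(cur))
            cur = [rec.chrom, rec.start, rec.end]
    rows.append(tuple(cur))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def build_atlas(group_peaks: Mapping[str, pd.DataFrame]) -> Atlas:
    """Merge per-group reproducible peak sets into the genome-wide atlas."""
    if not group_peaks:
        raise ValueError("need at least one group")
    merged = merge_intervals(pd.concat(
        [df[["chrom", "start", "end"]] for df in group_peaks.values()],
        ignore_index=True))
    merged = merged.copy()
    merged["atlas_id"] = [f"atlas_{i + 1:04d}" for i in range(len(merged))]
    provenance: Dict[str, List[str]] = {}
    for rec in merged.itertuples(index=False):
        contributing = []
        for label, df in group_peaks.items():
            sub = df[df["chrom"] == rec.chrom]
            if len(sub) and ((sub["start"] < rec.end)
                             & (sub["end"] > rec.start)).any():
                contributing.append(label)
        provenance[rec.atlas_id] = sorted(contributing)
    return Atlas(merged, provenance)
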
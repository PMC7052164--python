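"""RPM coverage tracks, pooled group tracks, peak-centered signal matrices,
IQR capping and K-means signature clustering.

Tracks count fragments in 10-bp bins scaled to reads-per-million, with
blacklisted bins zeroed and flagged. Replicate tracks of a sample group are
pooled bin-wise by arithmetic mean. Each atlas peak contributes one row of
200 bins covering +/- 1 kb around its center; rows are K-means clustered
into accessibility signatures, and for display the matrix is capped at the
75th percentile + 1.5 x IQR of its entries (capping never feeds back into
analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .params import DEFAULT_PARAMS, PipelineParams


@dataclass
class CoverageTrack:
    """Binned RPM coverage with a blacklist mask, anchored at coordinate 0."""

    bin_size: int
    data: Dict[str, np.ndarray]
    mask: Dict[str, np.ndarray]  # True where the bin intersects blacklist
    chrom_sizes: Dict[str, int]
    total_fragments: int


def coverage_track(frags: pd.DataFrame, chrom_sizes: Mapping[str, int],
                   blacklist: Optional[pd.DataFrame] = None,
                   params: PipelineParams = DEFAULT_PARAMS
                   ) -> CoverageTrack:
    """RPM coverage in fixed bins; blacklisted bins are zeroed and flagged."""
    n = len(frags)
    if n == 0:
        raise ValueError("cannot build an RPM track from zero fragments")
    res = params.track_bin
    scale = 1e6 / n
    data, mask = {}, {}
    for chrom, length in chrom_sizes.items():
        n_bins = -(-length // res)
        diff = np.zeros(n_bins + 1)
        sub = frags[frags["chrom"] == chrom]
        if len(sub):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            np.add.at(diff, starts // res, 1.0)
            np.add.at(diff, (ends - 1) // res + 1, -1.0)
        values = np.cumsum(diff[:-1]) * scale
        m = np.zeros(n_bins, dtype=bool)
        if blacklist is not None and len(blacklist):
            bsub = blacklist[blacklist["chrom"] == chrom]
            for rec in bsub.itertuples(index=False):
                m[rec.start // res:(rec.end - 1) // res + 1] = True
        values[m] = 0.0
        data[chrom] = values
        mask[chrom] = m
    return CoverageTrack(res, data, mask, dict(chrom_sizes), n)


def pool_group_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Bin-wise arithmetic mean of replicate RPM tracks (same grid)."""
    if not tracks:
        raise ValueError("no tracks to pool")
    first = tracks[0]
    for t in tracks[1:]:
        if (t.bin_size != first.bin_size
                or set(t.data) != set(first.data)
                or any(len(t.data[c]) != len(first.data[c])
                       for c in first.data)):
            raise ValueError("replicate tracks are on different bin grids")
    data = {c: np.mean([t.data[c] for t in tracks], axis=0)
            for c in first.data}
    mask = {c: np.logical_or.reduce([t.mask[c] for t in tracks])
            for c in first.data}
    total = sum(t.total_fragments for t in tracks)
    return CoverageTrack(first.bin_size, data, mask,
                         dict(first.chrom_sizes), total)


@dataclass
class SignalMatrix:
    """Peaks x bins matrix of pooled RPM signal around peak centers."""

    matrix: np.ndarray              # (n_peaks, 2 * halfwidth / bin)
    atlas_ids: Sequence[str]
    edge_clipped: np.ndarray        # rows padded at a chromosome edge
    cluster: Optional[np.ndarray] = None


def peak_centered_matrix(track: CoverageTrack, atlas: pd.DataFrame,
                         params: PipelineParams = DEFAULT_PARAMS
                         ) -> SignalMatrix:
    """Rows of 200 track bins covering [center - 1 kb, center + 1 kb).

    The peak center is floor((start + end) / 2); rows running past a
    chromosome edge are zero-padded and flagged. Peaks are unstranded, so
    no row is flipped.
    """
    res = track.bin_size
    half_bins = params.matrix_halfwidth // res
    n_cols = 2 * half_bins
    out = np.zeros((len(atlas), n_cols))
    clipped = np.zeros(len(atlas), dtype=bool)
    for i, rec in enumerate(atlas.itertuples(index=False)):
        center = (rec.start + rec.end) // 2
        first = (center - params.matrix_halfwidth) // res
        values = track.data[rec.chrom]
        lo = max(first, 0)
        hi = min(first + n_cols, len(values))
        if lo > first or hi < first + n_cols:
            clipped[i] = True
        out[i, lo - first:hi - first] = values[lo:hi]
    return SignalMatrix(out, list(atlas["atlas_id"]), clipped)


def cap_matrix(matrix: np.ndarray,
               threshold: Optional[float] = None
               ) -> Tuple[np.ndarray, float]:
    """Cap entries at Q75 + 1.5 x IQR (type-7 linear quantiles).

    Display-only transform: clustering and statistics always run on the
    uncapped matrix. An externally fixed threshold may be supplied.
    """
    if matrix.size == 0:
        raise ValueError("empty matrix")
    if threshold is None:
        q25, q75 = np.percentile(matrix, [25, 75], method="linear")
        threshold = float(q75 + 1.5 * (q75 - q25))
    return np.minimum(matrix, threshold), float(threshold)


def kmeans_rows(matrix: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Euclidean K-means over rows (k-means++ init, 10 restarts).

    Labels are renumbered by decreasing cluster mean signal, so label 0 is
    always the strongest signature and the output is deterministic for a
    fixed seed.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > matrix.shape[0]:
        raise ValueError("k exceeds the number of rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=seed)
    raw = km.fit_predict(matrix)
    means = np.array([matrix[raw == c].mean() if (raw == c).any() else
                      -np.inf for c in range(k)])
    order = np.argsort(-means, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw]
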
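"""Read-level filtering, deduplication, Tn5 shifting and insert-size QC.

The filter mirrors the standard ATAC flag screen (drop unmapped,
mate-unmapped, secondary, platform-failed and duplicate-flagged records —
the SAM ``-F 1804`` set) plus mitochondrial removal. Positional
deduplication collapses records sharing (chrom, start, end). The Tn5 shift
moves each fragment to (start+4, end-5) so coordinates represent insertion
centers rather than the 9-bp-offset cut sites of the transposase dimer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .io import (FILTER_MASK, FLAG_DUPLICATE, FLAG_MATE_UNMAPPED,
                 FLAG_QCFAIL, FLAG_SECONDARY, FLAG_UNMAPPED)
from .params import DEFAULT_PARAMS, PipelineParams

_REASON_BITS = {
    "unmapped": FLAG_UNMAPPED,
    "mate_unmapped": FLAG_MATE_UNMAPPED,
    "secondary": FLAG_SECONDARY,
    "qcfail": FLAG_QCFAIL,
    "duplicate": FLAG_DUPLICATE,
}


@dataclass
class FilterStats:
    """Removal counts per reason; a record can fail several predicates."""

    n_input: int = 0
    n_retained: int = 0
    removed: Dict[str, int] = field(default_factory=dict)


def filter_fragments(frags: pd.DataFrame,
                     params: PipelineParams = DEFAULT_PARAMS
                     ) -> Tuple[pd.DataFrame, FilterStats]:
    """Drop flag-failing and mitochondrial records; preserve input order."""
    stats = FilterStats(n_input=len(frags))
    if len(frags) == 0:
        stats.removed = {k: 0 for k in list(_REASON_BITS) + ["mito",
                                                             "low_mapq"]}
        return frags.copy(), stats
    flags = frags["flags"].to_numpy()
    for reason, bit in _REASON_BITS.items():
        stats.removed[reason] = int((flags & bit != 0).sum())
    mito = (frags["chrom"] == params.mito_name).to_numpy()
    stats.removed["mito"] = int(mito.sum())
    low_mapq = (frags["mapq"] < params.min_mapq).to_numpy()
    stats.removed["low_mapq"] = int(low_mapq.sum())
    keep = (flags & FILTER_MASK == 0) & ~mito & ~low_mapq
    out = frags.loc[keep].reset_index(drop=True)
    stats.n_retained = len(out)
    out.attrs = dict(frags.attrs)
    return out, stats


def deduplicate(frags: pd.DataFrame) -> Tuple[pd.DataFrame, int]:
    """Keep the first record of each (chrom, start, end) coordinate triple.

    Fragments are unstranded after pairing, so strand is not part of the
    key. Returns the retained records (input order) and the removed count.
    """
    if len(frags) == 0:
        return frags.copy(), 0
    dup = frags.duplicated(subset=["chrom", "start", "end"], keep="first")
    out = frags.loc[~dup].reset_index(drop=True)
    out.attrs = dict(frags.attrs)
    return out, int(dup.sum())


def tn5_shift(frags: pd.DataFrame,
              params: PipelineParams = DEFAULT_PARAMS
              ) -> Tuple[pd.DataFrame, int]:
    """Apply the +4/-5 cut-site correction to each fragment.

    Each fragment becomes (start+4, end-5); fragments at most 9 bp long
    collapse to an empty interval and are dropped (counted). A marker in
    ``DataFrame.attrs`` makes the operation a no-op on already-shifted
    input, so filter→dedup→shift is idempotent on its own output.
    """
    if frags.attrs.get("tn5_shifted"):
        return frags.copy(), 0
    out = frags.copy()
    out["start"] = out["start"] + params.shift_pos
    out["end"] = out["end"] + params.shift_neg
    keep = out["end"] > out["start"]
    n_dropped = int((~keep).sum())
    out = out.loc[keep].reset_index(drop=True)
    out["insert_len"] = out["end"] - out["start"]
    out.attrs["tn5_shifted"] = True
    return out, n_dropped


@dataclass
class InsertSizeProfile:
    """Integer insert-size histogram with QC summaries.

    ``modes`` lists detected local maxima of the (lightly smoothed)
    histogram, largest first; ``frac_sub100`` is the sub-nucleosomal
    fraction and ``frac_mono`` the mononucleosomal [150, 300] fraction.
    """

    counts: np.ndarray  # index = insert length in bp
    n_fragments: int
    modes: Tuple[int, ...]
    frac_sub100: float
    frac_mono: float

    def histogram(self) -> Dict[int, int]:
        nz = np.flatnonzero(self.counts)
        return {int(i): int(self.counts[i]) for i in nz}


def insert_size_profile(frags: pd.DataFrame,
                        smooth: int = 21) -> InsertSizeProfile:
    """Histogram of insert lengths plus mode detection.

    Modes are local maxima of a ``smooth``-bp moving-average of the
    histogram with at least 2% relative prominence, reported in decreasing
    height order.
    """
    n = len(frags)
    if n == 0:
        return InsertSizeProfile(np.zeros(1, dtype=np.int64), 0, (), 0.0,
                                 0.0)
    lengths = frags["insert_len"].to_numpy()
    counts = np.bincount(lengths)
    dens = uniform_filter1d(counts.astype(float), size=smooth)
    peaks, props = find_peaks(dens, prominence=0.02 * dens.max(),
                              distance=smooth)
    order = np.argsort(dens[peaks])[::-1]
    modes = tuple(int(p) for p in peaks[order])
    return InsertSizeProfile(
        counts=counts,
        n_fragments=n,
        modes=modes,
        frac_sub100=float((lengths < 100).mean()),
        frac_mono=float(((lengths >= 150) & (lengths <= 300)).mean()),
    )
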
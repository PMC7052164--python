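import numpy as np
import pandas as pd
import pytest

import atacatlas as aa
from atacatlas.io import FRAGMENT_COLUMNS


def make_fragments(rows):
    """Build a fragment frame from (chrom, start, end[, flags]) tuples."""
    recs = []
    for i, row in enumerate(rows):
        chrom, start, end = row[:3]
        flags = row[3] if len(row) > 3 else 0
        recs.append((chrom, start, end, f"f{i}", 60, "+", end - start,
                     flags))
    return pd.DataFrame(recs, columns=FRAGMENT_COLUMNS)


def make_peaks(intervals, qvalues=None, chrom="chr1"):
    """Peak frame from (start, end) pairs with optional q-values."""
    n = len(intervals)
    if qvalues is None:
        qvalues = np.full(n, 1e-6)
    return pd.DataFrame({
        "chrom": chrom,
        "start": [s for s, _ in intervals],
        "end": [e for _, e in intervals],
        "name": [f"p{i}" for i in range(n)],
        "summit": [(s + e) // 2 for s, e in intervals],
        "pvalue": np.asarray(qvalues) / 10,
        "neglog10p": -np.log10(np.asarray(qvalues, float) / 10),
        "qvalue": np.asarray(qvalues, float),
        "fold": np.full(n, 5.0),
    })


@pytest.fixture(scope="session")
def small_config():
    """One-lineage-per-arm day-8 design on the default toy genome."""
    return aa.SimConfig(
        seed=3,
        groups=[aa.GroupSpec("TFH_d8", 2, "A", 2),
                aa.GroupSpec("TH1_d8", 2, "B", 2)])


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return aa.simulate_experiment(small_config)


@pytest.fixture(scope="session")
def shifted_samples(small_experiment):
    """Filtered, deduplicated, Tn5-shifted fragments per sample."""
    *_, frag = small_experiment
    out = {}
    for (group, rep), df in frag.items():
        kept, _ = aa.filter_fragments(df)
        kept, _ = aa.deduplicate(kept)
        shifted, _ = aa.tn5_shift(kept)
        out[f"{group}_rep{rep}"] = shifted
    return out


@pytest.fixture(scope="session")
def truth_atlas(small_experiment):
    """The planted regions as an atlas frame (ground-truth row space)."""
    *_, truth, _ = small_experiment
    atlas = truth.regions.rename(columns={"region_id": "atlas_id"})
    return atlas[["chrom", "start", "end", "atlas_id"]]


@pytest.fixture(scope="session")
def toy_genes():
    rng = np.random.default_rng(42)
    rows = []
    pos = 5_000
    for i in range(10):
        length = int(rng.integers(2_000, 8_000))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = pos, pos + length
        tss = start if strand == "+" else end - 1
        tes = end - 1 if strand == "+" else start
        rows.append((f"g{i:02d}", "chr1", strand, start, end, tss, tes))
        pos = end + int(rng.integers(6_000, 20_000))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand",
                                       "start", "end", "tss", "tes"])
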
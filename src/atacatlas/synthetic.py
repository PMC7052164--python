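"""Synthetic ATAC-seq experiment generator.

Builds a toy genome with non-overlapping gene models, plants per-lineage
chromatin-accessibility programs (shared, lineage-A-specific and
lineage-B-specific regions with a graded openness over timepoints), and
draws per-replicate fragment sets with the statistical structure the
downstream pipeline assumes: a nucleosome-periodic insert-size mixture,
open-region fragment enrichment, PCR duplicates, mitochondrial
contamination, flag-failing records and replicate-discordant regions that
exercise the reproducibility filter.

All randomness flows from a single seed through documented stream keys:
``(seed, 0)`` annotation, ``(seed, 1)`` truth program, ``(seed, 3, g)`` the
group-level discordant-region assignment and ``(seed, 2, g, r)`` the
fragment draw of replicate ``r`` of group ``g``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import (FLAG_MATE_UNMAPPED, FLAG_QCFAIL, FLAG_SECONDARY,
                 FLAG_UNMAPPED, FRAGMENT_COLUMNS)


class SizingError(ValueError):
    """Requested gene count does not fit on the configured chromosomes."""


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


@dataclass(frozen=True)
class GroupSpec:
    """One sample group: label, replicate count, lineage and timepoint.

    ``lineage`` is ``"A"`` (the T_FH-like program), ``"B"`` (T_H1-like) or
    ``None`` (naive: only shared regions open). ``timepoint`` indexes into
    ``SimConfig.timepoint_gradient``.
    """

    label: str
    n_replicates: int = 3
    lineage: Optional[str] = None
    timepoint: Optional[int] = None


def default_groups(n_replicates: int = 3) -> List[GroupSpec]:
    """Naive plus two lineages sampled at three post-infection timepoints."""
    groups = [GroupSpec("naive", n_replicates, None, None)]
    for lineage, name in (("A", "TFH"), ("B", "TH1")):
        for tp, day in enumerate((2, 5, 8)):
            groups.append(GroupSpec(f"{name}_d{day}", n_replicates,
                                    lineage, tp))
    return groups


@dataclass
class SimConfig:
    """Configuration of the synthetic experiment.

    Defaults emulate a small two-lineage time course: two 5-Mb autosomes
    plus a 16-kb mitochondrial chromosome, 200 genes, 120 planted accessible
    regions (40% shared between lineages, the rest split between them),
    ten-fold fragment enrichment in open chromatin, a sub-nucleosomal /
    mono- / di-nucleosomal insert mixture, and a doubling of
    lineage-specific openness per timepoint.
    """

    seed: int = 0
    chrom_sizes: Dict[str, int] = field(default_factory=lambda: {
        "chr1": 5_000_000, "chr2": 5_000_000, "chrM": 16_000})
    mito_name: str = "chrM"
    n_genes: int = 200
    groups: List[GroupSpec] = field(default_factory=default_groups)
    depth: int = 600_000
    open_enrichment: float = 10.0
    insert_mixture: Sequence[Tuple[float, float, float]] = (
        (0.55, 60.0, 15.0), (0.35, 200.0, 35.0), (0.10, 400.0, 45.0))
    dup_rate: float = 0.05
    mito_rate: float = 0.05
    flag_fail_rates: Dict[str, float] = field(default_factory=lambda: {
        "unmapped": 0.01, "mate_unmapped": 0.01,
        "secondary": 0.005, "qcfail": 0.005})
    discordant_peak_rate: float = 0.1
    timepoint_gradient: Sequence[float] = (1.0, 2.0, 4.0)
    n_open_regions: int = 120
    open_width: int = 500
    shared_fraction: float = 0.4
    strength_range: Tuple[float, float] = (0.5, 3.0)
    n_blacklist: int = 5

    def __post_init__(self) -> None:
        self.groups = [g if isinstance(g, GroupSpec) else GroupSpec(**g)
                       for g in self.groups]
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        w = sum(c[0] for c in self.insert_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("insert_mixture weights must sum to 1")
        for name in ("dup_rate", "mito_rate", "discordant_peak_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        lo, hi = self.strength_range
        if not 0.0 < lo <= hi:
            raise ValueError("strength_range must satisfy 0 < lo <= hi")
        for k, v in self.flag_fail_rates.items():
            if not 0.0 <= v < 1.0:
                raise ValueError(f"flag_fail_rates[{k}] must lie in [0, 1)")
        if self.open_enrichment < 1.0:
            raise ValueError("open_enrichment must be >= 1")
        if self.mito_name not in self.chrom_sizes:
            raise ValueError("chrom_sizes must include the mitochondrial "
                             "chromosome")

    # ------------------------------------------------------------- (de)serialization
    def to_dict(self) -> dict:
        d = asdict(self)
        d["insert_mixture"] = [list(c) for c in self.insert_mixture]
        d["timepoint_gradient"] = list(self.timepoint_gradient)
        d["strength_range"] = list(self.strength_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "insert_mixture" in d:
            d["insert_mixture"] = [tuple(c) for c in d["insert_mixture"]]
        if "timepoint_gradient" in d:
            d["timepoint_gradient"] = tuple(d["timepoint_gradient"])
        if "strength_range" in d:
            d["strength_range"] = tuple(d["strength_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # ------------------------------------------------------------- helpers
    def group(self, label: str) -> GroupSpec:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(f"unknown group {label!r}")

    def group_index(self, label: str) -> int:
        for i, g in enumerate(self.groups):
            if g.label == label:
                return i
        raise KeyError(f"unknown group {label!r}")

    @property
    def autosomes(self) -> List[str]:
        return [c for c in self.chrom_sizes if c != self.mito_name]


# =============================================================== annotation

_MIN_GENE_LEN, _MAX_GENE_LEN = 2_000, 8_000
_MIN_GAP = 4_000          # between gene bodies; leaves room for 2-kb flanks
_BLACKLIST_MARGIN = 2_500  # keep blacklist clear of genes and planted regions


def make_genome_annotation(config: SimConfig):
    """Generate chromosome sizes, non-overlapping gene models and a blacklist.

    Returns ``(chrom_sizes, (genes, exons), blacklist)`` where genes/exons/
    blacklist are data frames. Genes carry strand, TSS (txStart on +,
    txEnd-1 on -) and the 3' end; each has at least one exon. Blacklist
    intervals sit in intergenic space, clear of gene bodies.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(config.seed, 0)
    autosomes = config.autosomes
    if not autosomes:
        raise ValueError("need at least one non-mitochondrial chromosome")
    total_len = sum(config.chrom_sizes[c] for c in autosomes)

    # apportion genes to chromosomes by length (largest remainder)
    quota = {c: config.n_genes * config.chrom_sizes[c] / total_len
             for c in autosomes}
    counts = {c: int(np.floor(q)) for c, q in quota.items()}
    short = config.n_genes - sum(counts.values())
    for c in sorted(autosomes, key=lambda c: quota[c] - counts[c],
                    reverse=True)[:short]:
        counts[c] += 1

    gene_rows, exon_rows = [], []
    gid = 0
    for chrom in autosomes:
        n = counts[chrom]
        if n == 0:
            continue
        length = config.chrom_sizes[chrom]
        lens = rng.integers(_MIN_GENE_LEN, _MAX_GENE_LEN + 1, n)
        slack = length - int(lens.sum()) - (n + 1) * _MIN_GAP
        if slack < 0:
            raise SizingError(
                f"{chrom} ({length} bp) too small for {n} genes")
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for i in range(n):
            pos += _MIN_GAP + int(extra[i])
            start, end = pos, pos + int(lens[i])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            gene_id = f"gene_{gid:04d}"
            tss = start if strand == "+" else end - 1
            tes = end - 1 if strand == "+" else start
            gene_rows.append((gene_id, chrom, strand, start, end, tss, tes))
            for es, ee in _make_exons(rng, start, end):
                exon_rows.append((gene_id, chrom, es, ee))

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand",
                                             "start", "end", "tss", "tes"])
    exons = pd.DataFrame(exon_rows,
                         columns=["gene_id", "chrom", "start", "end"])
    blacklist = _make_blacklist(rng, config, genes)
    return dict(config.chrom_sizes), (genes, exons), blacklist


def _make_exons(rng: np.random.Generator, start: int, end: int):
    glen = end - start
    n_exons = int(rng.integers(1, 4))
    if n_exons == 1 or glen < 4 * n_exons:
        return [(start, end)]
    cuts = np.sort(rng.choice(np.arange(1, glen), 2 * (n_exons - 1),
                              replace=False))
    bounds = np.concatenate([[0], cuts, [glen]])
    return [(start + int(bounds[2 * i]), start + int(bounds[2 * i + 1]))
            for i in range(n_exons)]


def _make_blacklist(rng: np.random.Generator, config: SimConfig,
                    genes: pd.DataFrame) -> pd.DataFrame:
    rows = []
    want = config.n_blacklist
    for chrom in config.autosomes:
        sub = genes[genes["chrom"] == chrom]
        edges = np.concatenate([[0], np.ravel(sub[["start", "end"]]),
                                [config.chrom_sizes[chrom]]])
        gaps = [(int(edges[i]), int(edges[i + 1]))
                for i in range(0, len(edges), 2)]
        for lo, hi in gaps:
            lo, hi = lo + _BLACKLIST_MARGIN, hi - _BLACKLIST_MARGIN
            if hi - lo >= 2_000:
                rows.append((chrom, lo, hi))
    rows.sort()
    if not rows or want == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    take = rng.choice(len(rows), size=min(want, len(rows)), replace=False)
    out = []
    for i in sorted(take):
        chrom, lo, hi = rows[i]
        width = int(rng.integers(500, 2001))
        width = min(width, hi - lo)
        s = int(rng.integers(lo, hi - width + 1))
        out.append((chrom, s, s + width))
    return (pd.DataFrame(out, columns=["chrom", "start", "end"])
            .sort_values(["chrom", "start"]).reset_index(drop=True))


# ============================================================ truth program

@dataclass
class TruthProgram:
    """Planted accessibility programs: which regions are open where.

    ``regions`` holds one interval per linked gene with a label in
    {shared, A, B} and a per-region strength multiplier (real peak
    intensities span orders of magnitude, and rank-based reproducibility
    scoring relies on that heterogeneity); ``openness(group)`` returns the
    per-region program multiplier for a sample group (0 = closed), which
    the simulator combines with the strength and the global enrichment.
    """

    regions: pd.DataFrame  # region_id, chrom, start, end, gene_id, label
    timepoint_gradient: Sequence[float]

    def openness(self, group: GroupSpec) -> np.ndarray:
        lab = self.regions["label"].to_numpy()
        out = np.zeros(len(self.regions))
        out[lab == "shared"] = 1.0
        if group.lineage is not None:
            scale = (1.0 if group.timepoint is None
                     else float(self.timepoint_gradient[group.timepoint]))
            out[lab == group.lineage] = scale
        return out


def make_truth_program(genes: pd.DataFrame, config: SimConfig) -> TruthProgram:
    """Plant open intervals near genes and label them shared / A / B."""
    if len(genes) == 0:
        raise ValueError("genes must be nonempty")
    rng = _rng(config.seed, 1)
    n = min(config.n_open_regions, len(genes))
    pick = np.sort(rng.choice(len(genes), n, replace=False))
    w = config.open_width
    rows = []
    for i, gi in enumerate(pick):
        g = genes.iloc[gi]
        center = int(rng.integers(g["start"] - 1_500, g["end"] + 1_500))
        start = max(0, center - w // 2)
        end = start + w
        limit = config.chrom_sizes[g["chrom"]]
        if end > limit:
            end = limit
            start = max(0, end - w)
        rows.append((f"region_{i + 1:04d}", g["chrom"], start, end,
                     g["gene_id"]))
    regions = pd.DataFrame(rows, columns=["region_id", "chrom", "start",
                                          "end", "gene_id"])
    lo, hi = config.strength_range
    regions["strength"] = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    n_shared = int(round(config.shared_fraction * n))
    n_a = (n - n_shared) // 2
    labels = np.array(["shared"] * n_shared + ["A"] * n_a
                      + ["B"] * (n - n_shared - n_a), dtype=object)
    regions["label"] = labels[rng.permutation(n)]
    return TruthProgram(regions, tuple(config.timepoint_gradient))


# ========================================================== fragment draws

def replicate_openness(truth: TruthProgram, group_label: str,
                       replicate: int, config: SimConfig) -> np.ndarray:
    """Effective openness for one replicate after discordant-region dropout.

    A fixed fraction of regions is marked discordant per group (stream
    ``(seed, 3, g)``) and each discordant region is owned by exactly one
    replicate; other replicates see it closed.
    """
    group = config.group(group_label)
    gi = config.group_index(group_label)
    base = truth.openness(group)
    rng = _rng(config.seed, 3, gi)
    n = len(base)
    discordant = rng.random(n) < config.discordant_peak_rate
    owner = rng.integers(0, group.n_replicates, n)
    eff = base.copy()
    eff[discordant & (owner != replicate)] = 0.0
    return eff


def expected_open_fraction(truth: TruthProgram, group_label: str,
                           replicate: int, config: SimConfig) -> float:
    """Closed-form probability that a clean fragment midpoint lands in an
    open region, under the generative background+enrichment mixture."""
    eff = replicate_openness(truth, group_label, replicate, config)
    widths = (truth.regions["end"] - truth.regions["start"]).to_numpy()
    on_auto = truth.regions["chrom"].isin(config.autosomes).to_numpy()
    strength = truth.regions["strength"].to_numpy()
    rate = np.maximum(config.open_enrichment * eff * strength, 1.0)
    rate[eff == 0.0] = 1.0
    l_auto = sum(config.chrom_sizes[c] for c in config.autosomes)
    extra = (widths * (rate - 1.0) * on_auto).sum()
    open_mass = (widths * rate * on_auto * (eff > 0)).sum()
    return float(open_mass / (l_auto + extra))


def simulate_replicate(truth: TruthProgram, group_label: str,
                       replicate: int, config: SimConfig) -> pd.DataFrame:
    """Draw exactly ``config.depth`` fragment records for one replicate.

    Clean fragment midpoints follow a background-uniform plus
    open-region-enriched mixture; insert lengths follow the configured
    nucleosome-periodic mixture (truncated at 10 bp); the configured
    fractions of PCR-duplicate (exact coordinate copies), mitochondrial and
    flag-failing records are interleaved. Deterministic per
    (seed, group, replicate).
    """
    group = config.group(group_label)
    gi = config.group_index(group_label)
    if not 0 <= replicate < group.n_replicates:
        raise KeyError(f"replicate {replicate} out of range for "
                       f"{group_label}")
    rng = _rng(config.seed, 2, gi, replicate)
    eff = replicate_openness(truth, group_label, replicate, config)

    flag_order = ["unmapped", "mate_unmapped", "secondary", "qcfail"]
    flag_bits = {"unmapped": FLAG_UNMAPPED,
                 "mate_unmapped": FLAG_MATE_UNMAPPED,
                 "secondary": FLAG_SECONDARY, "qcfail": FLAG_QCFAIL}
    probs = [config.mito_rate, config.dup_rate]
    probs += [config.flag_fail_rates.get(k, 0.0) for k in flag_order]
    p_clean = 1.0 - sum(probs)
    if p_clean <= 0:
        raise ValueError("category rates sum to >= 1")
    counts = rng.multinomial(config.depth,
                             np.array([p_clean] + probs))
    n_clean, n_mito, n_dup = counts[0], counts[1], counts[2]
    n_flags = counts[3:]

    autosomes = config.autosomes
    lens = np.array([config.chrom_sizes[c] for c in autosomes],
                    dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])
    l_auto = int(offsets[-1])

    regions = truth.regions
    on_auto = regions["chrom"].isin(autosomes).to_numpy()
    active = (eff > 0) & on_auto
    r_start = regions["start"].to_numpy()[active]
    r_width = (regions["end"] - regions["start"]).to_numpy()[active]
    r_chrom = regions["chrom"].to_numpy()[active]
    r_strength = regions["strength"].to_numpy()[active]
    r_rate = np.maximum(
        config.open_enrichment * eff[active] * r_strength, 1.0)
    extra_mass = r_width * (r_rate - 1.0)
    cum_extra = np.cumsum(extra_mass)
    total_mass = l_auto + (cum_extra[-1] if len(cum_extra) else 0.0)

    def genome_pos(linear: np.ndarray):
        ci = np.searchsorted(offsets, linear, side="right") - 1
        return (np.array(autosomes, dtype=object)[ci],
                (linear - offsets[ci]).astype(np.int64))

    def draw_clean(n: int):
        u = rng.random(n) * total_mass
        bg = u < l_auto
        chroms = np.empty(n, dtype=object)
        mids = np.empty(n, dtype=np.int64)
        chroms[bg], mids[bg] = genome_pos(np.floor(u[bg]).astype(np.int64))
        k = (~bg).sum()
        if k:
            idx = np.searchsorted(cum_extra, u[~bg] - l_auto, side="right")
            chroms[~bg] = r_chrom[idx]
            mids[~bg] = (r_start[idx]
                         + np.floor(rng.random(k) * r_width[idx]).astype(
                             np.int64))
        return chroms, mids

    def draw_inserts(n: int):
        weights = np.array([c[0] for c in config.insert_mixture])
        comp = rng.choice(len(weights), size=n, p=weights)
        means = np.array([c[1] for c in config.insert_mixture])[comp]
        sds = np.array([c[2] for c in config.insert_mixture])[comp]
        return np.maximum(10, np.rint(rng.normal(means, sds)).astype(
            np.int64))

    def make_records(chroms, mids, inserts, flag_value):
        sizes = np.array([config.chrom_sizes[c] for c in chroms],
                         dtype=np.int64)
        starts = mids - inserts // 2
        starts = np.clip(starts, 0, np.maximum(0, sizes - inserts))
        ends = np.minimum(starts + inserts, sizes)
        return pd.DataFrame({
            "chrom": chroms, "start": starts, "end": ends,
            "insert_len": ends - starts,
            "flags": np.full(len(starts), flag_value, dtype=np.int64)})

    parts = []
    chroms, mids = draw_clean(int(n_clean))
    clean = make_records(chroms, mids, draw_inserts(int(n_clean)), 0)
    parts.append(clean)
    if n_mito:
        mito_len = config.chrom_sizes[config.mito_name]
        mids = rng.integers(0, mito_len, int(n_mito))
        parts.append(make_records(
            np.full(int(n_mito), config.mito_name, dtype=object), mids,
            draw_inserts(int(n_mito)), 0))
    if n_dup and len(clean):
        base = rng.integers(0, len(clean), int(n_dup))
        parts.append(clean.iloc[base].reset_index(drop=True))
    elif n_dup:
        chroms, mids = draw_clean(int(n_dup))
        parts.append(make_records(chroms, mids, draw_inserts(int(n_dup)), 0))
    for name, n_f in zip(flag_order, n_flags):
        if n_f:
            chroms, mids = draw_clean(int(n_f))
            parts.append(make_records(chroms, mids, draw_inserts(int(n_f)),
                                      flag_bits[name]))

    frags = pd.concat(parts, ignore_index=True)
    total = len(frags)
    frags["name"] = [f"frag_{group_label}_{replicate}_{i:07d}"
                     for i in range(total)]
    frags["mapq"] = rng.integers(30, 61, total)
    frags["strand"] = np.where(rng.random(total) < 0.5, "+", "-")
    frags = frags.iloc[rng.permutation(total)].reset_index(drop=True)
    return frags[FRAGMENT_COLUMNS]


def simulate_experiment(config: SimConfig):
    """Generate annotation, truth program and all replicate fragment sets.

    Returns ``(chrom_sizes, (genes, exons), blacklist, truth, fragments)``
    with ``fragments`` keyed by ``(group_label, replicate)``.
    """
    chrom_sizes, (genes, exons), blacklist = make_genome_annotation(config)
    truth = make_truth_program(genes, config)
    fragments = {}
    for group in config.groups:
        for rep in range(group.n_replicates):
            fragments[(group.label, rep)] = simulate_replicate(
                truth, group.label, rep, config)
    return chrom_sizes, (genes, exons), blacklist, truth, fragments
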
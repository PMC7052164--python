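"""Pipeline-wide parameters.

Every tunable constant of the analysis lives here so that the stages share a
single source of truth: the Tn5 cut-site correction, the peak-calling and
reproducibility thresholds, the gene-assignment windows, the differential
gates and the heatmap geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping


@dataclass(frozen=True)
class PipelineParams:
    """Constants used across the accessibility pipeline.

    Attributes
    ----------
    shift_pos, shift_neg
        Tn5 cut-site correction applied to fragment ends: the 5' end moves
        ``+4`` bp and the 3' end ``-5`` bp, compensating the 9-bp duplication
        the transposase dimer leaves between its two insertion points.
    tn5_gap
        The 9-bp dimer gap; equals ``shift_pos - shift_neg``.
    mito_name
        Chromosome label whose fragments are discarded (mitochondrial
        contamination).
    min_mapq
        Mapping-quality cutoff; the published filter is flag-based only, so
        the default keeps every mapped record.
    q_atac, q_chip
        Peak-level q-value thresholds for accessibility (0.01) and ChIP
        (0.05) calling.
    pcut, merge_gap, min_len
        Candidate-region detection inside the caller: per-base Poisson
        p-value cutoff, maximal gap bridged between significant runs, and
        minimal run length kept.
    idr_threshold
        Global IDR below which a replicate peak pair counts as reproducible.
    fdr, fc_strict, fc_loose
        Differential-accessibility gates: BH FDR 0.05 combined with linear
        fold change > 4 (lineage contrasts) or > 1.5 (perturbation
        contrasts).
    assign_flank
        Gene-assignment flank: a peak touching the transcribed region
        extended by 2 kb on both sides is assigned to that gene.
    promoter_window
        A peak whose center lies within 5 kb of the TSS is classified as
        promoter.
    track_bin, matrix_halfwidth
        Coverage-track bin size (10 bp) and half-width of the peak-centered
        signal matrix (1 kb, i.e. 200 bins per row).
    k_clusters
        Number of K-means signature clusters for the heatmap.
    """

    shift_pos: int = 4
    shift_neg: int = -5
    tn5_gap: int = 9
    mito_name: str = "chrM"
    min_mapq: int = 0
    q_atac: float = 0.01
    q_chip: float = 0.05
    pcut: float = 1e-5
    merge_gap: int = 75
    min_len: int = 100
    idr_threshold: float = 0.005
    fdr: float = 0.05
    fc_strict: float = 4.0
    fc_loose: float = 1.5
    assign_flank: int = 2000
    promoter_window: int = 5000
    track_bin: int = 10
    matrix_halfwidth: int = 1000
    k_clusters: int = 4
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.tn5_gap != self.shift_pos - self.shift_neg:
            raise ValueError("tn5_gap must equal shift_pos - shift_neg")
        for name in ("assign_flank", "promoter_window", "track_bin",
                     "matrix_halfwidth", "min_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("q_atac", "q_chip", "idr_threshold", "fdr", "pcut"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    def replace(self, **kwargs) -> "PipelineParams":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kwargs)
        return PipelineParams(**d)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineParams":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in mapping.items() if k in known})


DEFAULT_PARAMS = PipelineParams()
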
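"""Priority-rule assignment of atlas peaks to genes and feature labels.

Rule 1: a peak touching a gene's transcribed region extended by 2 kb on
both sides is assigned to that gene (nearest TSS by peak center among
several candidates). Rule 2: any remaining peak goes to the gene minimizing
the distance from the peak center to the TSS or the 3' end. Features are
then classified with promoter (center within 5 kb of the TSS) taking
priority over exon, intron, flank and distal.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .params import DEFAULT_PARAMS, PipelineParams

ASSIGNMENT_COLUMNS = ["atlas_id", "gene_id", "rule", "feature", "distance"]


def peak_center(start: int, end: int) -> int:
    return (int(start) + int(end)) // 2


def _candidate_order(d_tss: np.ndarray, d_tes: np.ndarray,
                     gene_ids: np.ndarray) -> int:
    """Index of the best candidate under nearest-TSS / nearest-3' /
    lexicographic gene id tie-breaking."""
    order = np.lexsort((gene_ids, d_tes, d_tss))
    return int(order[0])


def assign_peak(chrom: str, start: int, end: int, genes: pd.DataFrame,
                params: PipelineParams = DEFAULT_PARAMS
                ) -> Tuple[Optional[str], str, int]:
    """Assign one peak; returns (gene_id, rule, signed distance to TSS).

    The distance is measured center-to-TSS in gene orientation: negative
    values lie upstream of the TSS. A peak on a chromosome without genes
    returns ``(None, "unassigned", 0)``.
    """
    sub = genes[genes["chrom"] == chrom]
    if len(sub) == 0:
        return None, "unassigned", 0
    center = peak_center(start, end)
    gstart = sub["start"].to_numpy()
    gend = sub["end"].to_numpy()
    tss = sub["tss"].to_numpy()
    tes = sub["tes"].to_numpy()
    gids = sub["gene_id"].to_numpy()
    d_tss = np.abs(center - tss)
    d_tes = np.abs(center - tes)

    flank = params.assign_flank
    hits = (gstart - flank < end) & (gend + flank > start)
    if hits.any():
        best = _candidate_order(d_tss[hits], d_tes[hits], gids[hits])
        idx = np.flatnonzero(hits)[best]
        rule = "overlap_or_flank"
    else:
        d_min = np.minimum(d_tss, d_tes)
        order = np.lexsort((gids, d_tes, d_tss, d_min))
        idx = int(order[0])
        rule = "nearest"
    strand = sub["strand"].to_numpy()[idx]
    signed = (center - tss[idx]) if strand == "+" else (tss[idx] - center)
    return str(gids[idx]), rule, int(signed)


def classify_feature(chrom: str, start: int, end: int, gene: pd.Series,
                     exons: pd.DataFrame,
                     params: PipelineParams = DEFAULT_PARAMS) -> str:
    """Feature label of an assigned peak, in priority order.

    promoter (center within 5 kb of the TSS) > exon > intron >
    upstream/downstream (within the 2-kb flank, by gene orientation) >
    distal.
    """
    center = peak_center(start, end)
    if abs(center - gene["tss"]) <= params.promoter_window:
        return "promoter"
    gene_id = gene.get("gene_id", gene.name)
    inside = gene["start"] <= center < gene["end"]
    if inside:
        ex = exons[(exons["gene_id"] == gene_id)
                   & (exons["start"] <= center) & (center < exons["end"])]
        return "exon" if len(ex) else "intron"
    flank = params.assign_flank
    if gene["start"] - flank <= center < gene["start"]:
        side_is_upstream = gene["strand"] == "+"
    elif gene["end"] <= center < gene["end"] + flank:
        side_is_upstream = gene["strand"] == "-"
    else:
        return "distal"
    return "upstream" if side_is_upstream else "downstream"


def assign_peaks(atlas: pd.DataFrame, genes: pd.DataFrame,
                 exons: pd.DataFrame,
                 params: PipelineParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Assign every atlas peak to exactly one gene (or an explicit
    unassigned record) and classify its feature."""
    rows = []
    gene_index = genes.set_index("gene_id")
    for rec in atlas.itertuples(index=False):
        gene_id, rule, dist = assign_peak(rec.chrom, rec.start, rec.end,
                                          genes, params)
        if gene_id is None:
            feature = "distal"
        else:
            feature = classify_feature(rec.chrom, rec.start, rec.end,
                                       gene_index.loc[gene_id], exons,
                                       params)
        rows.append((rec.atlas_id, gene_id, rule, feature, dist))
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
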
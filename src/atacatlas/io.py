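"""Readers and writers for the pipeline's on-disk formats.

Fragments travel as an extended BED8 (chrom, start, end, name, mapq, strand,
insert_len, flags); gene models as GTF; blacklists as BED3; peaks as ENCODE
narrowPeak; coverage as bedGraph; matrices as TSV. The flags column carries
the SAM bits the upstream filter acts on (4 unmapped, 8 mate-unmapped,
256 secondary, 512 qcfail, 1024 duplicate — the ``-F 1804`` set).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Mapping

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end", "name", "mapq", "strand",
                    "insert_len", "flags"]

# SAM flag bits handled by the read-level filter (-F 1804 without bit 2).
FLAG_UNMAPPED = 4
FLAG_MATE_UNMAPPED = 8
FLAG_SECONDARY = 256
FLAG_QCFAIL = 512
FLAG_DUPLICATE = 1024
FILTER_MASK = (FLAG_UNMAPPED | FLAG_MATE_UNMAPPED | FLAG_SECONDARY
               | FLAG_QCFAIL | FLAG_DUPLICATE)  # == 1804

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------- fragments

def write_fragments_bed(frags: pd.DataFrame, path) -> None:
    frags.to_csv(path, sep="\t", header=False, index=False,
                 columns=FRAGMENT_COLUMNS)


def read_fragments_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS,
                     dtype={"chrom": str, "start": np.int64, "end": np.int64,
                            "name": str, "mapq": np.int64, "strand": str,
                            "insert_len": np.int64, "flags": np.int64})
    return df


def read_fragments_sam(path) -> pd.DataFrame:
    """Build fragment records from a paired-end SAM/BAM file.

    One record per template, taken from the leftmost mate (template length
    > 0) or, for unpaired/unmapped records, from the read itself with a
    length-0 placeholder interval of its read span.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_paired and read.template_length <= 0:
                # keep only the leftmost mate of each pair
                if not (read.is_unmapped and read.is_read1):
                    continue
            if read.is_unmapped:
                chrom, start = (read.reference_name or "*"), 0
                end, tlen = 1, 1
            else:
                chrom = read.reference_name
                start = read.reference_start
                tlen = (abs(read.template_length)
                        or (read.reference_end - read.reference_start))
                end = start + tlen
            flags = read.flag & FILTER_MASK
            rows.append((chrom, start, end, read.query_name,
                         read.mapping_quality,
                         "-" if read.is_reverse else "+", tlen, flags))
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


# ------------------------------------------------------------ plain intervals

def write_bed3(intervals: pd.DataFrame, path) -> None:
    intervals.to_csv(path, sep="\t", header=False, index=False,
                     columns=["chrom", "start", "end"])


def read_bed3(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                       names=["chrom", "start", "end"],
                       dtype={"chrom": str, "start": np.int64,
                              "end": np.int64})


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, length = line.split()[:2]
            sizes[chrom] = int(length)
    return sizes


# ---------------------------------------------------------------- gene models

def write_gtf(genes: pd.DataFrame, exons: pd.DataFrame, path,
              source: str = "atacatlas") -> None:
    """Write gene and exon features as GTF (1-based, closed intervals)."""
    with open(path, "w") as fh:
        for gene in genes.itertuples():
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(f"{gene.chrom}\t{source}\tgene\t{gene.start + 1}\t"
                     f"{gene.end}\t.\t{gene.strand}\t.\t{attrs}\n")
            sub = exons[exons["gene_id"] == gene.gene_id]
            for ex in sub.itertuples():
                fh.write(f"{gene.chrom}\t{source}\texon\t{ex.start + 1}\t"
                         f"{ex.end}\t.\t{gene.strand}\t.\t{attrs}\n")


def read_gtf(path):
    """Read gene/exon features from GTF into (genes, exons) frames."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    genes, exons = [], []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes["gene_id"][0]
        start, end = feat.start - 1, feat.end
        tss = start if feat.strand == "+" else end - 1
        tes = end - 1 if feat.strand == "+" else start
        genes.append((gid, feat.seqid, feat.strand, start, end, tss, tes))
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        gid = feat.attributes["gene_id"][0]
        exons.append((gid, feat.seqid, feat.start - 1, feat.end))
    genes_df = pd.DataFrame(
        genes, columns=["gene_id", "chrom", "strand", "start", "end",
                        "tss", "tes"])
    exons_df = pd.DataFrame(exons,
                            columns=["gene_id", "chrom", "start", "end"])
    return genes_df, exons_df


# -------------------------------------------------------------------- peaks

def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    """Write peaks as ENCODE narrowPeak (BED6+4).

    signalValue carries the fold enrichment, pValue/qValue the -log10
    probabilities, peak the summit offset from start.
    """
    out = pd.DataFrame({
        "chrom": peaks["chrom"],
        "start": peaks["start"],
        "end": peaks["end"],
        "name": peaks["name"],
        "score": np.minimum(1000, np.round(
            -10 * np.log10(np.maximum(peaks["qvalue"], 1e-100)))).astype(int),
        "strand": ".",
        "signalValue": peaks["fold"],
        "pValue": (peaks["neglog10p"] if "neglog10p" in peaks.columns
                   else -np.log10(np.maximum(peaks["pvalue"], 1e-300))),
        "qValue": -np.log10(np.maximum(peaks["qvalue"], 1e-300)),
        "peak": peaks["summit"] - peaks["start"],
    })
    out.to_csv(path, sep="\t", header=False, index=False,
               float_format=FLOAT_FORMAT)


def read_narrowpeak(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score",
                            "strand", "signalValue", "pValue", "qValue",
                            "peak"],
                     dtype={"chrom": str})
    return pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(np.int64),
        "end": df["end"].astype(np.int64),
        "name": df["name"],
        "summit": (df["start"] + df["peak"]).astype(np.int64),
        "pvalue": np.maximum(np.power(10.0, -df["pValue"]), 1e-300),
        "neglog10p": df["pValue"].astype(float),
        "qvalue": np.power(10.0, -df["qValue"]),
        "fold": df["signalValue"],
    })


# -------------------------------------------------------------------- tracks

def write_bedgraph(track, path) -> None:
    """Write a binned coverage track as bedGraph, merging equal-value runs."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            values = track.data[chrom]
            length = track.chrom_sizes[chrom]
            if len(values) == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(values)]])
            for s, e in zip(starts, ends):
                v = values[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s * track.bin_size}\t"
                         f"{min(e * track.bin_size, length)}\t"
                         f"{FLOAT_FORMAT % v}\n")


# -------------------------------------------------------------- tables / json

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
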
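"""Flat-file I/O: bedGraph tracks, BED6/BED12 intervals, TSV tables.

All coordinates are 0-based half-open, the native BED/bedGraph convention.
bedGraph is the canonical track dialect of the package; runs of equal-valued
bins are collapsed on write and expanded back onto the bin grid on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tracks import BinnedTrack

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bedgraph(track: BinnedTrack, path) -> None:
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom in track.chroms:
            v = track.values[chrom]
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s * bw}\t{e * bw}\t{v[s]:g}\n")


def read_bedgraph(path, chrom_sizes: dict[str, int], bin_width: int = 50,
                  normalization: str = "raw", strand: str = "both") -> BinnedTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    values = {}
    for chrom, size in chrom_sizes.items():
        nb = -(-size // bin_width)
        v = np.zeros(nb)
        sub = df[df["chrom"] == chrom]
        for s, e, val in zip(sub["start"], sub["end"], sub["value"]):
            v[s // bin_width: -(-e // bin_width)] = val
        values[chrom] = v
    return BinnedTrack(values, bin_width=bin_width, normalization=normalization,
                       strand=strand)


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, :6]
    df.columns = BED6_COLS
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = "."
    if "score" not in out.columns:
        out["score"] = 0
    out[BED6_COLS].to_csv(path, sep="\t", header=False, index=False)


def write_bed12(genes: pd.DataFrame, path) -> None:
    """Write single-exon gene models as BED12 (one block spanning the gene)."""
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            size = int(g["end"]) - int(g["start"])
            fh.write("\t".join(map(str, [
                g["chrom"], g["start"], g["end"], g["gene_id"], 0, g["strand"],
                g["start"], g["end"], "0,0,0", 1, f"{size},", "0,",
            ])) + "\n")


def read_bed12(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    return pd.DataFrame({
        "gene_id": df[3], "chrom": df[0], "start": df[1].astype(int),
        "end": df[2].astype(int), "strand": df[5],
    })


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
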
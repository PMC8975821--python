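"""Binned genomic coverage tracks and the arithmetic built on them.

The unit of all signal handling is the :class:`BinnedTrack`: per chromosome a
dense vector of fixed-width bins (50 bp by default, matching the resolution at
which nascent-RNA and occupancy coverage is analyzed).  On top of it sit CPM
normalization, log2 change tracks, relative (ratio-of-ratios) tracks, metagene
matrices, replicate correlation and the Tn5 insertion-site offset used for
ATAC-style data.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats


class GridMismatchError(ValueError):
    """Two tracks do not share the same bin grid (bin width or chromosomes)."""


class CoordinateError(ValueError):
    """An interval falls outside its chromosome."""


@dataclass
class BinnedTrack:
    """Fixed-width binned signal, one vector per chromosome.

    values        : dict chrom -> float vector of length ceil(chrom_length/bin_width)
    bin_width     : bin size in bp
    normalization : one of {"raw", "CPM", "log2ratio", "relative"}
    strand        : "+", "-" or "both"
    """

    values: dict[str, np.ndarray]
    bin_width: int = 50
    normalization: str = "raw"
    strand: str = "both"
    total_reads: float | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        if self.normalization in ("raw", "CPM"):
            for chrom, v in self.values.items():
                if np.any(v < 0):
                    raise ValueError(f"negative {self.normalization} values on {chrom}")

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and set(self.values) == set(other.values)
            and all(len(self.values[c]) == len(other.values[c]) for c in self.values)
        )

    def region_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Bin values fully or partially covered by [start, end)."""
        if end <= start:
            raise CoordinateError(f"empty region {chrom}:{start}-{end}")
        lo = start // self.bin_width
        hi = -(-end // self.bin_width)
        return self.values[chrom][lo:hi]

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of bin values over [start, end), edge bins weighted by overlap."""
        bw = self.bin_width
        v = self.values[chrom]
        lo, hi = start // bw, -(-end // bw)
        hi = min(hi, len(v))
        if hi <= lo:
            return 0.0
        w = np.ones(hi - lo)
        w[0] = (min(end, (lo + 1) * bw) - start) / bw
        if hi - lo > 1:
            w[-1] = (end - (hi - 1) * bw) / bw if end < hi * bw else 1.0
        return float(np.dot(v[lo:hi], w))


def _check_intervals(df: pd.DataFrame, chrom_sizes: dict[str, int]) -> None:
    for chrom, sub in df.groupby("chrom"):
        if chrom not in chrom_sizes:
            raise CoordinateError(f"unknown chromosome {chrom}")
        size = chrom_sizes[chrom]
        if (sub["start"] < 0).any() or (sub["end"] > size).any():
            raise CoordinateError(f"interval outside {chrom} (size {size})")
        if (sub["end"] <= sub["start"]).any():
            raise CoordinateError("interval with end <= start")


def bin_reads(
    reads: pd.DataFrame,
    bin_width: int,
    chrom_sizes: dict[str, int],
    mode: str = "depth",
    strand: str | None = None,
) -> BinnedTrack:
    """Bin stranded read intervals into a coverage track.

    reads must have columns chrom/start/end (0-based half-open) and, if
    ``strand`` filtering is requested, a strand column.

    mode="depth"  : bin value = mean per-base read depth within the bin
                    (total overlapping read-bases / bin_width).
    mode="starts" : bin value = number of read 5' ends in the bin (the 5' end
                    is ``start`` on + and ``end - 1`` on -); used where region
                    read *counts* are needed (RPKM-style densities).
    """
    if mode not in ("depth", "starts"):
        raise ValueError(f"unknown binning mode {mode!r}")
    if strand is not None:
        reads = reads[reads["strand"] == strand]
    _check_intervals(reads, chrom_sizes) if len(reads) else None
    values: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        nb = -(-size // bin_width)
        sub = reads[reads["chrom"] == chrom] if len(reads) else reads
        if len(sub) == 0:
            values[chrom] = np.zeros(nb)
            continue
        if mode == "starts":
            if "strand" in sub.columns:
                five = np.where(sub["strand"].to_numpy() == "-",
                                sub["end"].to_numpy() - 1, sub["start"].to_numpy())
            else:
                five = sub["start"].to_numpy()
            values[chrom] = np.bincount(five // bin_width, minlength=nb).astype(float)
        else:
            # per-base depth via a difference array, then mean per bin
            diff = np.zeros(size + 1)
            np.add.at(diff, sub["start"].to_numpy(), 1.0)
            np.add.at(diff, sub["end"].to_numpy(), -1.0)
            depth = np.cumsum(diff[:-1])
            pad = nb * bin_width - size
            if pad:
                depth = np.concatenate([depth, np.zeros(pad)])
            values[chrom] = depth.reshape(nb, bin_width).mean(axis=1)
    return BinnedTrack(values, bin_width=bin_width, normalization="raw",
                       strand=strand or "both", total_reads=float(len(reads)))


def cpm_normalize(track: BinnedTrack, total_reads: float | None = None) -> BinnedTrack:
    """Scale a raw track by 1e6 / total mapped reads (counts-per-million)."""
    if total_reads is None:
        total_reads = track.total_reads
    if not total_reads or total_reads <= 0:
        raise ValueError("total_reads must be positive for CPM normalization")
    scale = 1e6 / total_reads
    return replace(track, values={c: v * scale for c, v in track.values.items()},
                   normalization="CPM")


def log2_change_track(a: BinnedTrack, b: BinnedTrack, pseudocount: float = 1.0) -> BinnedTrack:
    """Per-bin log2((a + pc) / (b + pc)) of two CPM tracks on one grid."""
    if not a.same_grid(b):
        raise GridMismatchError("log2_change_track requires identical bin grids")
    vals = {c: np.log2((a.values[c] + pseudocount) / (b.values[c] + pseudocount))
            for c in a.values}
    return BinnedTrack(vals, bin_width=a.bin_width, normalization="log2ratio",
                       strand=a.strand)


def relative_change_track(mark_change: BinnedTrack, ref_change: BinnedTrack) -> BinnedTrack:
    """Change of a mark relative to a reference: per-bin difference of two
    log2-ratio tracks (e.g. Ser-2p change minus total Pol II change)."""
    if not mark_change.same_grid(ref_change):
        raise GridMismatchError("relative_change_track requires identical bin grids")
    if mark_change.normalization != "log2ratio" or ref_change.normalization != "log2ratio":
        raise ValueError("relative_change_track expects log2ratio tracks")
    vals = {c: mark_change.values[c] - ref_change.values[c] for c in mark_change.values}
    return BinnedTrack(vals, bin_width=mark_change.bin_width, normalization="relative",
                       strand=mark_change.strand)


def _resample_mean(row: np.ndarray, n_cols: int) -> np.ndarray:
    """Resample a vector to n_cols columns; each column is the mean of its
    (near-equal) share of source bins."""
    edges = np.linspace(0, len(row), n_cols + 1)
    idx = np.round(edges).astype(int)
    # guard against empty slices when n_cols > len(row)
    out = np.empty(n_cols)
    for j in range(n_cols):
        lo, hi = idx[j], max(idx[j + 1], idx[j] + 1)
        out[j] = row[lo:min(hi, len(row))].mean() if lo < len(row) else row[-1]
    return out


@dataclass
class MetageneMatrix:
    """Regions x positions matrix of track values, 5'->3' oriented."""

    matrix: np.ndarray
    region_ids: list[str]
    mode: str
    dropped: list[str] = field(default_factory=list)

    def profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.region_ids)


def metagene(
    track: BinnedTrack,
    regions: pd.DataFrame,
    mode: str = "scale_regions",
    n_body_cols: int = 100,
    flank_bp: int = 2000,
    reference: str = "TSS",
) -> MetageneMatrix:
    """Build a metagene matrix from strand-annotated regions.

    mode="scale_regions"  : each region body resampled to ``n_body_cols``.
    mode="reference_point": fixed window of ±``flank_bp`` around the TSS or TES.
    Minus-strand rows are reversed so that columns always read 5'->3'.
    Regions too short (or too close to a chromosome edge) for the requested
    window are dropped and reported, never padded.
    """
    if mode not in ("scale_regions", "reference_point"):
        raise ValueError(f"unknown metagene mode {mode!r}")
    bw = track.bin_width
    rows, ids, dropped = [], [], []
    for _, r in regions.iterrows():
        chrom, start, end, strand = r["chrom"], int(r["start"]), int(r["end"]), r["strand"]
        nb_chrom = track.n_bins(chrom)
        if mode == "scale_regions":
            lo, hi = start // bw, end // bw
            if hi - lo < 1:
                dropped.append(r["gene_id"]); continue
            row = track.values[chrom][lo:hi]
            row = _resample_mean(row, n_body_cols)
        else:
            anchor = (start if strand == "+" else end - 1) if reference == "TSS" \
                else (end - 1 if strand == "+" else start)
            fb = flank_bp // bw
            c = anchor // bw
            if c - fb < 0 or c + fb > nb_chrom:
                dropped.append(r["gene_id"]); continue
            row = track.values[chrom][c - fb:c + fb]
        if strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(r["gene_id"])
    mat = np.vstack(rows) if rows else np.empty((0, n_body_cols))
    return MetageneMatrix(mat, ids, mode, dropped)


@dataclass
class CorrelationResult:
    r: float
    passed: bool
    undefined: bool = False


def track_pearson(
    a: BinnedTrack,
    b: BinnedTrack,
    regions: pd.DataFrame | None = None,
    threshold: float = 0.90,
) -> CorrelationResult:
    """Pearson r between two tracks over per-bin values (optionally restricted
    to regions).  Replicates with r > 0.90 are conventionally called highly
    reproducible; ``passed`` reports that comparison."""
    if not a.same_grid(b):
        raise GridMismatchError("track_pearson requires identical bin grids")
    if regions is None:
        xs = np.concatenate([a.values[c] for c in sorted(a.values)])
        ys = np.concatenate([b.values[c] for c in sorted(a.values)])
    else:
        xs = np.concatenate([a.region_values(r["chrom"], int(r["start"]), int(r["end"]))
                             for _, r in regions.iterrows()])
        ys = np.concatenate([b.region_values(r["chrom"], int(r["start"]), int(r["end"]))
                             for _, r in regions.iterrows()])
    if np.std(xs) == 0 or np.std(ys) == 0:
        return CorrelationResult(r=float("nan"), passed=False, undefined=True)
    r = float(stats.pearsonr(xs, ys).statistic)
    return CorrelationResult(r=r, passed=r > threshold)


def tn5_offset(reads: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Convert stranded reads to single-base Tn5 insertion sites.

    + reads: site = start + 4.  - reads: site = (end - 1) - 5, i.e. the
    rightmost aligned base shifted 5 bp inward.  Sites shifted beyond the
    chromosome are clamped and flagged in the ``clamped`` column.
    """
    chrom = reads["chrom"].to_numpy()
    plus = reads["strand"].to_numpy() == "+"
    site = np.where(plus, reads["start"].to_numpy() + 4, reads["end"].to_numpy() - 1 - 5)
    sizes = np.array([chrom_sizes[c] for c in chrom])
    clamped = (site < 0) | (site >= sizes)
    site = np.clip(site, 0, sizes - 1)
    return pd.DataFrame({
        "chrom": chrom, "start": site, "end": site + 1,
        "strand": reads["strand"].to_numpy(), "clamped": clamped,
    })
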
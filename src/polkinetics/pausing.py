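"""Traveling-ratio pausing metrics and gene grouping.

The traveling ratio (TR, also called pausing index) of a gene is its Pol II
read density (RPKM) over the promoter window divided by the density over the
gene body; a high TR means polymerase accumulates near the promoter relative
to the body.  Defaults: promoter = [TSS-50, TSS+300), body = [TSS+300, TES),
both strand-aware.  A gene is evaluable only when promoter density exceeds
0.005 and body density is positive.  TR fold changes >= 1.5 between
conditions are called meaningful.

Genes are also grouped by expression (Silent / Low / Medium / High from TPM
quartiles of non-silent genes) and into the 3x3 grid of TR status x
transcriptional-output status (nine groups, row-major with rows TR
decreased/unaffected/increased and columns output decreased/unaffected/
increased, so Groups 1-3 share decreased TR and Groups 1,4,7 decreased
output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import BinnedTrack

DECREASED, UNAFFECTED, INCREASED = "decreased", "unaffected", "increased"
_STATUS_ORDER = [DECREASED, UNAFFECTED, INCREASED]


def region_density(track: BinnedTrack, chrom: str, start: int, end: int,
                   total_reads: float | None = None) -> float:
    """RPKM over a region: reads / (region kb x total mapped reads in millions).

    The track must be in read-start counts mode so that bin sums are read
    counts.
    """
    if end <= start:
        raise ValueError(f"empty region {chrom}:{start}-{end}")
    total = total_reads if total_reads is not None else track.total_reads
    if not total or total <= 0:
        raise ValueError("total mapped reads must be positive")
    reads = track.region_sum(chrom, start, end)
    return reads / ((end - start) / 1e3) / (total / 1e6)


@dataclass
class TravelingRatio:
    gene_id: str
    promoter_density: float
    body_density: float
    tr: float | None
    evaluable: bool


def promoter_body_windows(gene: pd.Series, upstream: int = 50,
                          downstream: int = 300) -> tuple[tuple[int, int], tuple[int, int]]:
    """Strand-aware promoter and body windows for one gene."""
    s, e = int(gene["start"]), int(gene["end"])
    if gene["strand"] == "+":
        return (s - upstream, s + downstream), (s + downstream, e)
    return (e - downstream, e + upstream), (s, e - downstream)


def traveling_ratio(track: BinnedTrack, gene: pd.Series,
                    promoter_upstream: int = 50, promoter_downstream: int = 300,
                    density_floor: float = 0.005,
                    total_reads: float | None = None) -> TravelingRatio:
    (ps, pe), (bs, be) = promoter_body_windows(gene, promoter_upstream,
                                               promoter_downstream)
    gid = gene["gene_id"]
    if be <= bs:
        return TravelingRatio(gid, 0.0, 0.0, None, evaluable=False)
    prom = region_density(track, gene["chrom"], max(ps, 0), pe, total_reads)
    body = region_density(track, gene["chrom"], bs, be, total_reads)
    if prom <= density_floor or body <= 0:
        return TravelingRatio(gid, prom, body, None, evaluable=False)
    return TravelingRatio(gid, prom, body, prom / body, evaluable=True)


def tr_change(tr_ctrl: float | None, tr_ko: float | None,
              fc_threshold: float = 1.5) -> str | None:
    """TR status in knockout vs control; None when either TR is unavailable.

    decreased: ctrl/KO >= threshold; increased: KO/ctrl >= threshold
    (thresholds inclusive); otherwise unaffected.
    """
    if tr_ctrl is None or tr_ko is None:
        return None
    if tr_ctrl <= 0 or tr_ko <= 0:
        return None
    if tr_ctrl / tr_ko >= fc_threshold:
        return DECREASED
    if tr_ko / tr_ctrl >= fc_threshold:
        return INCREASED
    return UNAFFECTED


def expression_groups(mean_tpm: pd.Series, relocate_silent: pd.Index | None = None
                      ) -> pd.Series:
    """Silent / Low / Medium / High from mean TPM.

    Silent: TPM < 1.  Among non-silent genes, Low is below the first quartile
    of their mean TPM, High above the third quartile, Medium in between (ties
    at the quartile edges resolve to Medium).  ``relocate_silent`` optionally
    names genes to move from Silent into Low (used for direct-target sets too
    small to analyse separately).
    """
    if len(mean_tpm) == 0:
        raise ValueError("empty TPM table")
    groups = pd.Series("Medium", index=mean_tpm.index, dtype=object)
    silent = mean_tpm < 1.0
    groups[silent] = "Silent"
    ns = mean_tpm[~silent]
    if len(ns):
        q1, q3 = np.quantile(ns, [0.25, 0.75])
        groups[ns.index[ns < q1]] = "Low"
        groups[ns.index[ns > q3]] = "High"
    if relocate_silent is not None:
        sel = groups.index.isin(relocate_silent) & (groups == "Silent")
        groups[sel] = "Low"
    return groups


def nine_groups(tr_statuses: pd.Series, output_statuses: pd.Series) -> pd.DataFrame:
    """Assign genes to the 3x3 TR-by-output grid.

    group_id = 3*row(TR status) + col(output status) + 1 in row-major order;
    genes missing either status are excluded.
    """
    common = tr_statuses.dropna().index.intersection(output_statuses.dropna().index)
    rows = []
    for gid in common:
        trs, outs = tr_statuses[gid], output_statuses[gid]
        if trs not in _STATUS_ORDER or outs not in _STATUS_ORDER:
            continue
        gidx = 3 * _STATUS_ORDER.index(trs) + _STATUS_ORDER.index(outs) + 1
        rows.append((gid, trs, outs, gidx))
    return pd.DataFrame(rows, columns=["gene_id", "tr_status", "output_status",
                                       "group_id"])


def group_region_lists(groups: pd.DataFrame, genes: pd.DataFrame
                       ) -> dict[int, pd.DataFrame]:
    """Per-group gene regions, directly consumable by tracks.metagene."""
    merged = groups.merge(genes, on="gene_id")
    return {int(g): sub[["gene_id", "chrom", "start", "end", "strand"]].reset_index(drop=True)
            for g, sub in merged.groupby("group_id")}
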
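"""Stranded extragenic transcript detection and annotation.

Islands of extragenic transcription are called per strand with the classic
window/gap broad-enrichment scheme: the genome is tiled into fixed windows
(500 bp), a window is eligible when its read count is improbable under the
Poisson background (tail probability < 0.1), eligible windows separated by
gaps of at most 1000 bp form islands, and an island's score is the summed
Poisson surprisal of its windows.  The island-score threshold is calibrated
by seeded Monte-Carlo simulation of pure background so that the expected
number of background islands reaching the threshold is the e-value (100 by
default).

Reads overlapping protein-coding genes are excluded before calling; islands
from both conditions are merged per strand and kept only with >= 50 reads in
each replicate of at least one condition; surviving regions are annotated by
priority: lncRNA > enhancer > antisense > PROMPT > readthrough >
promoter-convergent > other, with "near" meaning overlap of the +/-2 kb
window around the TSS or TES anchor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CLASS_PRIORITY = ["lncRNA", "enhancer", "antisense", "PROMPT", "readthrough",
                  "promoter_convergent", "other"]


# ---------------------------------------------------------------------------
# interval utilities


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Union of possibly-overlapping intervals (sorted sweep)."""
    s = np.asarray(starts, int)
    e = np.asarray(ends, int)
    if len(s) == 0:
        return s, e
    order = np.argsort(s, kind="mergesort")
    s, e = s[order], e[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] < out_e[-1]:          # half-open: touching intervals stay separate
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i]); out_e.append(e[i])
    return np.array(out_s), np.array(out_e)


def overlaps_any(q_start, q_end, ref_starts, ref_ends) -> np.ndarray:
    """For each query interval, whether it overlaps any reference interval."""
    qs = np.atleast_1d(np.asarray(q_start, int))
    qe = np.atleast_1d(np.asarray(q_end, int))
    ms, me = merge_intervals(ref_starts, ref_ends)
    if len(ms) == 0:
        return np.zeros(len(qs), bool)
    idx = np.searchsorted(ms, qe, side="left") - 1
    hit = (idx >= 0) & (me[np.clip(idx, 0, None)] > qs)
    return hit


def exclude_genic_reads(reads: pd.DataFrame, protein_coding: pd.DataFrame,
                        same_strand_only: bool = False) -> pd.DataFrame:
    """Drop reads overlapping protein-coding gene bodies (any strand by
    default, matching a strand-agnostic interval subtraction)."""
    if len(reads) == 0 or len(protein_coding) == 0:
        return reads
    keep = np.ones(len(reads), bool)
    for chrom, sub in reads.groupby("chrom"):
        g = protein_coding[protein_coding["chrom"] == chrom]
        if len(g) == 0:
            continue
        if same_strand_only:
            for strand in ("+", "-"):
                rsub = sub[sub["strand"] == strand]
                gs = g[g["strand"] == strand]
                if len(rsub) == 0 or len(gs) == 0:
                    continue
                hit = overlaps_any(rsub["start"], rsub["end"], gs["start"], gs["end"])
                keep[rsub.index[hit]] = False
        else:
            hit = overlaps_any(sub["start"], sub["end"], g["start"], g["end"])
            keep[sub.index[hit]] = False
    return reads[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# island calling


def _windows_to_islands(eligible_idx: np.ndarray, counts: np.ndarray,
                        lam: float, window: int, gap: int):
    """Group eligible windows into islands; gap measured in bp between
    consecutive eligible windows."""
    max_skip = gap // window
    islands = []
    if len(eligible_idx) == 0:
        return islands
    start = prev = eligible_idx[0]
    members = [prev]
    for w in eligible_idx[1:]:
        if w - prev - 1 <= max_skip:
            members.append(w)
        else:
            islands.append((start, prev, members))
            start, members = w, [w]
        prev = w
    islands.append((start, prev, members))
    out = []
    for s, e, mem in islands:
        score = float(-stats.poisson.logpmf(counts[mem], lam).sum())
        out.append((s * window, (e + 1) * window, score,
                    int(counts[mem].sum())))
    return out


def eligibility_threshold(lam: float, tail_p: float = 0.1) -> int:
    """Smallest count whose Poisson upper tail P(X >= k) is below tail_p."""
    k = 1
    while stats.poisson.sf(k - 1, lam) >= tail_p:
        k += 1
    return k


def calibrate_score_threshold(lam: float, n_windows: int, window: int,
                              gap: int, e_value: float, tail_p: float = 0.1,
                              n_sims: int = 50, seed: int = 0) -> float:
    """Monte-Carlo island-score threshold: the smallest score such that the
    expected number of pure-background islands at or above it is <= e_value."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 721]))
    k0 = eligibility_threshold(lam, tail_p)
    scores = []
    for _ in range(n_sims):
        counts = rng.poisson(lam, size=n_windows)
        elig = np.flatnonzero(counts >= k0)
        for _, _, sc, _ in _windows_to_islands(elig, counts, lam, window, gap):
            scores.append(sc)
    allowed = int(np.floor(e_value * n_sims))
    scores = sorted(scores, reverse=True)
    if len(scores) <= allowed:
        return 0.0
    # threshold just above the score of the (allowed+1)-th strongest bg island
    return scores[allowed] + 1e-9


def call_islands(reads: pd.DataFrame, strand: str, chrom_sizes: dict[str, int],
                 window: int = 500, gap: int = 1_000, e_value: float = 100.0,
                 tail_p: float = 0.1, seed: int = 0) -> pd.DataFrame:
    """Call read-enriched islands on one strand.

    Reads are reduced to their 5' positions; the Poisson background rate per
    window is N * window / L per chromosome.
    """
    sub = reads[reads["strand"] == strand]
    rows = []
    for chrom, L in chrom_sizes.items():
        r = sub[sub["chrom"] == chrom]
        if len(r) == 0:
            continue
        five = np.where(r["strand"].to_numpy() == "-", r["end"].to_numpy() - 1,
                        r["start"].to_numpy())
        n_windows = -(-L // window)
        counts = np.bincount(five // window, minlength=n_windows)
        lam = len(r) * window / L
        k0 = eligibility_threshold(lam, tail_p)
        elig = np.flatnonzero(counts >= k0)
        cand = _windows_to_islands(elig, counts, lam, window, gap)
        if not cand:
            continue
        thresh = calibrate_score_threshold(lam, n_windows, window, gap,
                                           e_value, tail_p, seed=seed)
        for s, e, score, nreads in cand:
            if score >= thresh:
                rows.append((chrom, s, min(e, L), strand, score, nreads))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "score", "n_reads"])


# ---------------------------------------------------------------------------
# merging, support filtering, annotation


def count_reads_in_region(reads: pd.DataFrame, chrom: str, start: int,
                          end: int, strand: str | None = None) -> int:
    sub = reads[reads["chrom"] == chrom]
    if strand is not None:
        sub = sub[sub["strand"] == strand]
    return int(((sub["start"] < end) & (sub["end"] > start)).sum())


def merge_and_filter(
    islands_by_condition: dict[str, pd.DataFrame],
    reads: pd.DataFrame,
    samples_by_condition: dict[str, list[str]],
    support_floor: int = 50,
) -> pd.DataFrame:
    """Merge same-strand overlapping islands across conditions and keep the
    merged regions with >= support_floor reads in every replicate of at
    least one condition."""
    allisl = pd.concat(islands_by_condition.values(), ignore_index=True) \
        if islands_by_condition else pd.DataFrame(
            columns=["chrom", "start", "end", "strand"])
    rows = []
    for (chrom, strand), sub in allisl.groupby(["chrom", "strand"]):
        ms, me = merge_intervals(sub["start"], sub["end"])
        for s, e in zip(ms, me):
            counts = {}
            for cond, samples in samples_by_condition.items():
                for samp in samples:
                    rs = reads[reads["sample"] == samp]
                    counts[samp] = count_reads_in_region(rs, chrom, int(s),
                                                         int(e), strand)
            supported = any(
                all(counts[samp] >= support_floor for samp in samples)
                for cond, samples in samples_by_condition.items())
            if supported:
                rows.append((chrom, int(s), int(e), strand, *counts.values()))
    all_samples = [s for ss in samples_by_condition.values() for s in ss]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       *all_samples])


def _near_anchor(start: int, end: int, anchor: int, window: int = 2_000) -> bool:
    return start < anchor + window and end > anchor - window


def annotate_class(region: pd.Series, genes: pd.DataFrame,
                   lncrnas: pd.DataFrame, enhancers: pd.DataFrame,
                   window: int = 2_000) -> tuple[str, str]:
    """Assign one transcript class to an extragenic region.

    Priority: lncRNA (same-strand overlap) > enhancer (overlap) > antisense
    (opposite-strand gene-body overlap) > PROMPT (within 2 kb of a TSS,
    direction opposite to the mRNA) > readthrough (within 2 kb of a TES, same
    direction) > promoter-convergent (within 2 kb of a TSS, same direction) >
    other.  Returns (class, linked feature id).
    """
    chrom, s, e, strand = region["chrom"], int(region["start"]), \
        int(region["end"]), region["strand"]
    lnc = lncrnas[(lncrnas["chrom"] == chrom) & (lncrnas["strand"] == strand)]
    hit = lnc[(lnc["start"] < e) & (lnc["end"] > s)]
    if len(hit):
        return "lncRNA", str(hit.iloc[0]["name"])
    enh = enhancers[enhancers["chrom"] == chrom]
    hit = enh[(enh["start"] < e) & (enh["end"] > s)]
    if len(hit):
        return "enhancer", str(hit.iloc[0]["name"])
    g = genes[(genes["chrom"] == chrom) & (genes["biotype"] == "protein_coding")] \
        if "biotype" in genes.columns else genes[genes["chrom"] == chrom]
    anti = g[(g["strand"] != strand) & (g["start"] < e) & (g["end"] > s)]
    if len(anti):
        return "antisense", str(anti.iloc[0]["gene_id"])
    tss = np.where(g["strand"].to_numpy() == "+", g["start"].to_numpy(),
                   g["end"].to_numpy() - 1)
    tes = np.where(g["strand"].to_numpy() == "+", g["end"].to_numpy() - 1,
                   g["start"].to_numpy())
    same = g["strand"].to_numpy() == strand
    for cls, anchors, want_same in (("PROMPT", tss, False),
                                    ("readthrough", tes, True),
                                    ("promoter_convergent", tss, True)):
        mask = same == want_same
        for gi, a in zip(g["gene_id"].to_numpy()[mask], anchors[mask]):
            if _near_anchor(s, e, int(a), window):
                return cls, str(gi)
    return "other", ""


def annotate_regions(regions: pd.DataFrame, genes: pd.DataFrame,
                     lncrnas: pd.DataFrame, enhancers: pd.DataFrame,
                     window: int = 2_000) -> pd.DataFrame:
    out = regions.copy()
    classes, linked = [], []
    for _, r in regions.iterrows():
        c, l = annotate_class(r, genes, lncrnas, enhancers, window)
        classes.append(c); linked.append(l)
    out["class"] = classes
    out["linked"] = linked
    return out


def reconcile_replicate_peaks(merged_peaks: pd.DataFrame,
                              rep1_peaks: pd.DataFrame,
                              rep2_peaks: pd.DataFrame,
                              require: str = "both") -> pd.DataFrame:
    """High-confidence peaks: merged-replicate peaks supported by the
    individual replicates (overlap with >= 1 peak in both replicates by
    default; ``require="either"`` keeps peaks seen in at least one)."""
    if require not in ("both", "either"):
        raise ValueError(f"unknown requirement {require!r}")
    keep = np.ones(len(merged_peaks), bool)
    for i, (_, p) in enumerate(merged_peaks.iterrows()):
        hits = []
        for rep in (rep1_peaks, rep2_peaks):
            sub = rep[rep["chrom"] == p["chrom"]]
            hits.append(bool(overlaps_any(p["start"], p["end"], sub["start"],
                                          sub["end"])[0]) if len(sub) else False)
        keep[i] = all(hits) if require == "both" else any(hits)
    return merged_peaks[keep].reset_index(drop=True)
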
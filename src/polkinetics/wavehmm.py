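"""Elongation-front detection on binned labeled-RNA coverage.

After synchronized release from a transcription block, newly labeled RNA
forms a "wave" that advances from the TSS at the elongation speed; the most
3' position it has reached at a given time is the elongation front.  The
front is decoded per gene with a three-state left-to-right hidden Markov
model on log1p(coverage): WAVE -> FRONT -> BACKGROUND, with forbidden
backward transitions, Gaussian emissions, deterministic quantile-based
initialization, Baum-Welch refinement and Viterbi decoding.  The boundary is
the 3' end of the last bin decoded WAVE or FRONT (the decaying front belongs
to the traveled distance).

A boundary is only reported as "clear" when the decoded path has at least
five leading WAVE bins, at least five trailing BACKGROUND bins, and the
boundary is not within two bins of either segment edge; genes without a
clear boundary in *both* replicates at every required time point are
ineligible for rate estimation.  The 2 kb immediately upstream of the TES is
never included (signal there is unstable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

from .tracks import BinnedTrack

WAVE, FRONT, BACKGROUND = 0, 1, 2


@dataclass
class HmmSpec:
    max_iter: int = 50
    tol: float = 1e-4
    quantile: float = 0.30      # fraction of bins defining the WAVE / BACKGROUND init means
    min_var: float = 1e-3


@dataclass
class WaveBoundary:
    gene_id: str
    condition: str
    replicate: int
    time_min: int
    boundary_bp: float | None
    clear: bool
    reason: str = ""
    path_summary: str = ""


def extract_gene_segment(track: BinnedTrack, gene: pd.Series,
                         tes_exclusion: int = 2_000) -> np.ndarray:
    """Gene-body bins from the TSS to TES - 2 kb, oriented 5'->3'."""
    bw = track.bin_width
    start, end = int(gene["start"]), int(gene["end"])
    if end - start < tes_exclusion + 2 * bw:
        raise ValueError(
            f"gene {gene.get('gene_id', '?')} shorter than {tes_exclusion} bp "
            "TES exclusion plus two bins")
    if gene["strand"] == "+":
        seg = track.values[gene["chrom"]][start // bw:(end - tes_exclusion) // bw]
        return np.asarray(seg, float)
    seg = track.values[gene["chrom"]][(start + tes_exclusion) // bw:end // bw]
    return np.asarray(seg[::-1], float)


def _run_lengths(path: np.ndarray) -> str:
    names = "WFB"
    out = []
    i = 0
    while i < len(path):
        j = i
        while j < len(path) and path[j] == path[i]:
            j += 1
        out.append(f"{j - i}{names[path[i]]}")
        i = j
    return "/".join(out)


def _refine_boundary(obs: np.ndarray, b_idx: int, halfwin: int = 20) -> int:
    """Local two-level least-squares changepoint around the decoded front.

    Scans split points k in a window around the Viterbi boundary and returns
    the k minimising the residual sum of squares of a high/low two-level fit
    (high level left of k).  For any front shape that decays symmetrically
    about its midpoint, this changepoint is an unbiased estimate of the
    midpoint, which the raw end-of-front anchor is not.  Returns the index of
    the last high bin.
    """
    lo = max(1, b_idx - halfwin)
    hi = min(len(obs) - 1, b_idx + halfwin + 1)
    y = obs[max(0, lo - halfwin):min(len(obs), hi + halfwin)]
    off = max(0, lo - halfwin)
    best, best_k = np.inf, b_idx + 1
    for k in range(lo - off, hi - off):
        left, right = y[:k], y[k:]
        if len(left) == 0 or len(right) == 0 or left.mean() <= right.mean():
            continue
        rss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if rss < best:
            best, best_k = rss, k
    return best_k + off - 1


def fit_and_decode(segment: np.ndarray, spec: HmmSpec | None = None,
                   bin_width: int = 50, gene_id: str = "", condition: str = "",
                   replicate: int = 0, time_min: int = 0) -> tuple[np.ndarray, WaveBoundary]:
    """Fit the three-state left-to-right HMM on one gene segment and decode.

    Returns the Viterbi state path and the resulting WaveBoundary.
    """
    spec = spec or HmmSpec()
    meta = dict(gene_id=gene_id, condition=condition, replicate=replicate,
                time_min=time_min)
    if len(segment) < 12:
        return np.array([], int), WaveBoundary(
            boundary_bp=None, clear=False, reason="segment_too_short", **meta)
    obs = np.log1p(np.asarray(segment, float))
    if np.ptp(obs) == 0:
        return np.full(len(obs), BACKGROUND), WaveBoundary(
            boundary_bp=None, clear=False, reason="zero_variance", **meta)

    srt = np.sort(obs)
    k = max(1, int(len(obs) * spec.quantile))
    mu_bg, mu_wave = srt[:k].mean(), srt[-k:].mean()
    mu_front = 0.5 * (mu_bg + mu_wave)
    var0 = max(obs.var(), spec.min_var)

    model = GaussianHMM(n_components=3, covariance_type="diag",
                        init_params="", params="tmc",
                        n_iter=spec.max_iter, tol=spec.tol)
    model.startprob_ = np.array([1.0, 0.0, 0.0])
    model.transmat_ = np.array([[0.95, 0.05, 0.0],
                                [0.00, 0.80, 0.2],
                                [0.00, 0.00, 1.0]])
    model.means_ = np.array([[mu_wave], [mu_front], [mu_bg]])
    model.covars_ = np.full((3, 1), var0)
    X = obs[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model.fit(X)
        except ValueError:
            pass  # EM hit a degenerate corner; decode from the current params
        if not np.all(np.isfinite(model.transmat_)):
            model.transmat_ = np.array([[0.95, 0.05, 0.0],
                                        [0.00, 0.80, 0.2],
                                        [0.00, 0.00, 1.0]])
        model.covars_ = np.maximum(model.covars_.reshape(3, 1), spec.min_var)
        _, path = model.decode(X, algorithm="viterbi")

    summary = _run_lengths(path)
    means = model.means_.ravel()
    if not (means[WAVE] >= means[FRONT] - 1e-9 >= means[BACKGROUND] - 2e-9):
        return path, WaveBoundary(boundary_bp=None, clear=False,
                                  reason="state_order", path_summary=summary, **meta)
    non_bg = np.flatnonzero(path != BACKGROUND)
    if len(non_bg) == 0 or path[-1] != BACKGROUND:
        return path, WaveBoundary(boundary_bp=None, clear=False,
                                  reason="no_terminal_background",
                                  path_summary=summary, **meta)
    b_idx = _refine_boundary(obs, int(non_bg[-1]))
    boundary_bp = (b_idx + 1) * bin_width

    lead_wave = int(np.argmax(path != WAVE)) if np.any(path != WAVE) else len(path)
    trail_bg = len(path) - 1 - b_idx
    clear = lead_wave >= 5 and trail_bg >= 5 and 2 <= b_idx <= len(path) - 3
    reason = "" if clear else "unclear_front"
    return path, WaveBoundary(boundary_bp=float(boundary_bp) if clear else None,
                              clear=clear, reason=reason, path_summary=summary,
                              **meta)


def cohort_boundaries(
    tracks: dict[tuple[str, int, int], BinnedTrack],
    genes: pd.DataFrame,
    spec: HmmSpec | None = None,
    times: tuple[int, ...] = (10, 20),
    tes_exclusion: int = 2_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decode boundaries for a gene cohort across conditions and replicates.

    Returns (boundaries, eligibility): per-track boundary calls, and per
    gene x condition x time an ``eligible`` flag requiring a clear boundary
    in every replicate.
    """
    spec = spec or HmmSpec()
    keys = sorted(tracks)
    conditions = sorted({k[0] for k in keys})
    rows = []
    for _, gene in genes.iterrows():
        for cond, rep, t in keys:
            if t not in times:
                continue
            track = tracks[(cond, rep, t)]
            seg = extract_gene_segment(track, gene, tes_exclusion)
            _, wb = fit_and_decode(seg, spec, bin_width=track.bin_width,
                                   gene_id=gene["gene_id"], condition=cond,
                                   replicate=rep, time_min=t)
            rows.append(wb)
    bdf = pd.DataFrame([vars(w) for w in rows])

    elig_rows = []
    for gid in genes["gene_id"]:
        for cond in conditions:
            for t in times:
                sub = bdf[(bdf["gene_id"] == gid) & (bdf["condition"] == cond)
                          & (bdf["time_min"] == t)]
                n_reps = len({k[1] for k in keys if k[0] == cond})
                eligible = len(sub) == n_reps and bool(sub["clear"].all())
                elig_rows.append((gid, cond, t, eligible))
    elig = pd.DataFrame(elig_rows, columns=["gene_id", "condition", "time_min",
                                            "eligible"])
    return bdf, elig
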
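"""Elongation rates from wave boundaries, rate-change classification, and the
pausing-vs-rate contingency analysis.

Rates over the 0-10 and 0-20 min windows are the mean replicate travel
distance (kb) divided by elongation time.  The 10-20 min ("late productive
elongation") rate is the OLS slope of replicate-level (time, distance)
points; its 50% confidence interval uses the Student-t quantile with n-2
degrees of freedom, and an estimate is kept only when the slope is positive,
the full CI width is below 0.5 kb/min and the time-axis intercept is later
than -10 min.

Between-condition rate changes follow the either-replicate rule: a gene
elongates faster upon knockout when every knockout replicate distance
exceeds every control replicate distance (strict separation), slower in the
mirror case, otherwise unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FASTER, SLOWER, UNAFFECTED = "faster", "slower", "unaffected"


# ---------------------------------------------------------------------------
# gene eligibility


def eligible_genes(genes: pd.DataFrame, min_length: int,
                   upstream_clearance: int = 2_000) -> set[str]:
    """Genes longer than ``min_length``, not overlapping any other gene, and
    with no other gene within ``upstream_clearance`` bp upstream of the TSS.

    ``min_length`` is 30000 for 0-10 min analyses and 60000 for 0-20 min.
    """
    gid = genes["gene_id"].to_numpy()
    chrom = genes["chrom"].to_numpy()
    start = genes["start"].to_numpy(int)
    end = genes["end"].to_numpy(int)
    strand = genes["strand"].to_numpy()
    n = len(genes)
    length_ok = (end - start) > min_length

    up_s = np.where(strand == "+", start - upstream_clearance, end)
    up_e = np.where(strand == "+", start, end + upstream_clearance)
    overlap = np.zeros(n, bool)
    clear_up = np.ones(n, bool)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        order = idx[np.argsort(start[idx], kind="mergesort")]
        s, e = start[order], end[order]
        for ii, i in enumerate(order):
            hit = (s < end[i]) & (e > start[i])
            hit[ii] = False
            if hit.any():
                overlap[i] = True
            if ((s < up_e[i]) & (e > up_s[i]) & (order != i)).any():
                clear_up[i] = False
    keep = length_ok & ~overlap & clear_up
    return set(gid[keep])


# ---------------------------------------------------------------------------
# rate estimates


@dataclass
class RateEstimate:
    gene_id: str
    condition: str
    interval: str                      # r0_10 | r0_20 | r10_20
    rate: float | None
    ci_halfwidth: float | None = None  # kb/min (r10_20 only)
    intercept_time: float | None = None  # min (r10_20 only)
    passes_filters: bool = True
    reasons: tuple[str, ...] = ()


def simple_rate(distances_kb, time_min: int, gene_id: str = "",
                condition: str = "") -> RateEstimate:
    """Rate (kb/min) = mean replicate travel distance / elongation time."""
    d = np.asarray(list(distances_kb), float)
    if len(d) == 0:
        raise ValueError("no replicate distances")
    return RateEstimate(gene_id=gene_id, condition=condition,
                        interval=f"r0_{time_min}",
                        rate=float(d.mean() / time_min))


def ols_slope_ci(times, distances, conf: float = 0.50):
    """Closed-form OLS of distance on time with a symmetric CI on the slope.

    Returns (slope, intercept, ci_halfwidth, dof).
    """
    t = np.asarray(times, float)
    d = np.asarray(distances, float)
    if np.ptp(t) == 0:
        raise ValueError("degenerate fit: no spread in time")
    n = len(t)
    tbar, dbar = t.mean(), d.mean()
    sxx = float(((t - tbar) ** 2).sum())
    slope = float(((t - tbar) * (d - dbar)).sum() / sxx)
    intercept = dbar - slope * tbar
    resid = d - (intercept + slope * t)
    dof = n - 2
    if dof <= 0:
        raise ValueError("need more than two points for a confidence interval")
    se = np.sqrt(max(float((resid ** 2).sum()), 0.0) / dof / sxx)
    tq = stats.t.ppf(0.5 + conf / 2.0, dof)
    return slope, float(intercept), float(tq * se), dof


def fitted_rate_10_20(
    distances_10_kb, distances_20_kb, gene_id: str = "", condition: str = "",
    ci_max_width: float = 0.5, intercept_floor: float = -10.0,
) -> RateEstimate:
    """Late elongation rate: OLS slope of replicate-level (time, distance).

    passes_filters requires a positive slope, a 50% CI narrower than
    ``ci_max_width`` kb/min (full width) and a time-axis intercept greater
    than ``intercept_floor`` min.
    """
    d10 = list(distances_10_kb)
    d20 = list(distances_20_kb)
    if len(d10) < 2 or len(d20) < 2:
        raise ValueError("need >= 2 replicate boundaries at 10 and at 20 min")
    times = [10.0] * len(d10) + [20.0] * len(d20)
    dist = d10 + d20
    slope, intercept, ci_half, _ = ols_slope_ci(times, dist)
    reasons = []
    if slope <= 0:
        reasons.append("nonpositive slope")
        t_axis = None
    else:
        t_axis = -intercept / slope
        if t_axis <= intercept_floor:
            reasons.append("intercept before -10 min")
    if 2 * ci_half >= ci_max_width:
        reasons.append("CI too wide")
    ok = not reasons
    return RateEstimate(gene_id=gene_id, condition=condition, interval="r10_20",
                        rate=float(slope) if ok else None,
                        ci_halfwidth=ci_half, intercept_time=t_axis,
                        passes_filters=ok, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# rate-change classification


def classify_rate_change(ctrl_distances, ko_distances, rule: str = "strict") -> str:
    """Either-replicate rule for knockout-vs-control travel distances.

    strict (default): faster iff min(KO) > max(Ctrl); slower iff
    max(KO) < min(Ctrl); else unaffected.  The lenient any-vs-any reading is
    available (``rule="lenient"``); when it labels a gene both faster and
    slower it falls back to unaffected.
    """
    c = np.asarray(list(ctrl_distances), float)
    k = np.asarray(list(ko_distances), float)
    if len(c) == 0 or len(k) == 0:
        raise ValueError("need at least one replicate distance per condition")
    if rule == "strict":
        if k.min() > c.max():
            return FASTER
        if k.max() < c.min():
            return SLOWER
        return UNAFFECTED
    if rule == "lenient":
        faster = k.max() > c.min()
        slower = k.min() < c.max()
        if faster and not slower:
            return FASTER
        if slower and not faster:
            return SLOWER
        return UNAFFECTED
    raise ValueError(f"unknown rule {rule!r}")


def late_rate_composite(early_call: str, late_call: str) -> str:
    """Composite late-elongation verdict from the 0-10 and 10-20 min calls.

    A gene has decreased late productive elongation when its rate did not
    decrease early but decreased late (early faster-or-unaffected with late
    slower), or when an early speed-up was not sustained (early faster with
    late unaffected).
    """
    for call in (early_call, late_call):
        if call not in (FASTER, SLOWER, UNAFFECTED):
            raise ValueError(f"unknown category {call!r}")
    if late_call == SLOWER and early_call in (FASTER, UNAFFECTED):
        return "decreased_late"
    if late_call == UNAFFECTED and early_call == FASTER:
        return "decreased_late"
    return "not_decreased_late"


# ---------------------------------------------------------------------------
# contingency analysis


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float
    std_residuals: np.ndarray


def chisq_independence(table) -> ContingencyResult:
    """Pearson chi-square test of independence with adjusted standardized
    residuals r_ij = (O-E)/sqrt(E(1-row_i/N)(1-col_j/N))."""
    obs = np.asarray(table, float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2D non-negative array")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(obs, correction=False)
    n = obs.sum()
    expected = res.expected_freq
    adj = (obs - expected) / np.sqrt(
        expected * (1 - rows[:, None] / n) * (1 - cols[None, :] / n))
    return ContingencyResult(observed=obs, expected=expected,
                             chi2=float(res.statistic), df=int(res.dof),
                             p_value=float(res.pvalue), std_residuals=adj)
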
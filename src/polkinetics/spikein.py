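"""Spike-in normalization and threshold-based differential classification.

Exogenous spike-in RNA (e.g. labeled yeast RNA added per microgram of human
RNA) provides features whose true abundance is equal across samples, so
per-sample scale factors computed from spike-ins alone can reveal global
shifts in transcriptional output that ordinary library-size normalization
would erase.  Scale factors use the median-of-ratios construction: reference
= per-feature geometric mean across samples, factor = median over spike-in
features of count/reference.

Differential calls are threshold-based: a feature is "up"/"down" only when it
clears an abundance floor (mean CPM or TPM), a fold-change threshold
(inclusive), and a BH-adjusted p-value threshold.  The default significance
engine is a pooled-dispersion negative-binomial Wald test: a single
overdispersion is estimated across all target features by the method of
moments and per-feature Wald z statistics are built from it, so that designs
with two replicates per condition still borrow strength across features.
Exact label-permutation and Welch-t engines are available via ``test=``.

Presets mirror the thresholds used for the assays this package models:
    rnaseq     : TPM >= 1, q < 0.05, FC >= 1.5
    ttseq      : CPM >= 1, q < 0.05, FC >= 1.2
    extragenic : CPM >= 1, q < 0.05, FC >= 1.5
    atac_peak  : q < 0.01, FC >= 2
    atac_body  : q < 0.05, FC >= 1.2
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

PRESETS = {
    "rnaseq": dict(fc_threshold=1.5, q_threshold=0.05, abundance_floor=1.0, abundance_unit="TPM"),
    "ttseq": dict(fc_threshold=1.2, q_threshold=0.05, abundance_floor=1.0, abundance_unit="CPM"),
    "extragenic": dict(fc_threshold=1.5, q_threshold=0.05, abundance_floor=1.0, abundance_unit="CPM"),
    "atac_peak": dict(fc_threshold=2.0, q_threshold=0.01, abundance_floor=0.0, abundance_unit="CPM"),
    "atac_body": dict(fc_threshold=1.2, q_threshold=0.05, abundance_floor=0.0, abundance_unit="CPM"),
}


@dataclass
class CountMatrix:
    """Features x samples integer counts with spike-in flags and metadata."""

    counts: pd.DataFrame                 # features x samples
    lengths: pd.Series                   # bp per feature
    spikein: pd.Series                   # bool per feature
    condition: pd.Series                 # condition label per sample

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.condition.index]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def target(self) -> pd.DataFrame:
        return self.counts.loc[~self.spikein]

    def spike(self) -> pd.DataFrame:
        return self.counts.loc[self.spikein]

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition[s] == condition]

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"feature": self.counts.index,
                            "length": self.lengths.reindex(self.counts.index),
                            "spikein": self.spikein.reindex(self.counts.index)})
        out = pd.concat([out.reset_index(drop=True),
                         self.counts.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, condition: dict[str, str] | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = df[["feature", "length", "spikein"]]
        counts = df.drop(columns=["feature", "length", "spikein"])
        counts.index = meta["feature"]
        if condition is None:
            condition = {s: s.rsplit("_rep", 1)[0] for s in counts.columns}
        return cls(counts=counts,
                   lengths=pd.Series(meta["length"].to_numpy(), index=counts.index),
                   spikein=pd.Series(meta["spikein"].to_numpy(), index=counts.index),
                   condition=pd.Series(condition))


def size_factors_median_of_ratios(spike_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios scale factor per sample, from spike-in counts only.

    Features with a zero in any sample drop out of the geometric-mean
    reference (their log is undefined); at least one all-nonzero feature is
    required.
    """
    m = spike_counts.to_numpy(float)
    keep = (m > 0).all(axis=1)
    if not keep.any():
        raise ValueError("no spike-in feature has nonzero counts in all samples")
    logm = np.log(m[keep])
    ref = logm.mean(axis=1)
    factors = np.exp(np.median(logm - ref[:, None], axis=0))
    return pd.Series(factors, index=spike_counts.columns)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, per sample."""
    tot = counts.sum(axis=0)
    if (tot == 0).any():
        raise ValueError("sample with zero total count")
    return counts * 1e6 / tot


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-rate normalized, scaled to 1e6/sample."""
    lens = lengths.reindex(counts.index).to_numpy(float)
    if (lens <= 0).any():
        raise ValueError("zero-length feature")
    rate = counts.div(lens, axis=0)
    return rate * 1e6 / rate.sum(axis=0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


# --- significance engines ---------------------------------------------------


def _pooled_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> float:
    """Method-of-moments NB dispersion pooled across features.

    Ratio-of-sums estimator: alpha = sum_i (s2_i - mu_i) / sum_i mu_i^2 over
    all features and within-condition groups.  With few replicates each
    per-feature variance has almost no degrees of freedom, so only the pooled
    ratio (not a median of per-feature ratios, which is badly biased at 1 df)
    is stable enough to calibrate the Wald test.
    """
    num = 0.0
    den = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        ok = mu > 0
        num += float((var[ok] - mu[ok]).sum())
        den += float((mu[ok] ** 2).sum())
    return max(num / den, 0.0) if den > 0 else 0.0


def _nb_wald_p(norm: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Wald test of equal NB means on normalized counts, pooled dispersion."""
    alpha = _pooled_dispersion(norm, [g1, g2])
    mu_all = norm.mean(axis=1)
    z = np.zeros(norm.shape[0])
    m1, m2 = norm[:, g1].mean(axis=1), norm[:, g2].mean(axis=1)
    ok = (m1 > 0) & (m2 > 0) & (mu_all > 0)
    # delta-method variance of log mean under H0, information pooled at the
    # grand mean so null calibration does not depend on which group is larger
    var_log = (alpha + 1.0 / mu_all[ok]) * (1.0 / len(g1) + 1.0 / len(g2))
    z[ok] = (np.log(m2[ok]) - np.log(m1[ok])) / np.sqrt(var_log)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~ok] = 1.0
    return p


def _welch_p(logn: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    res = stats.ttest_ind(logn[:, g2], logn[:, g1], axis=1, equal_var=False)
    p = np.asarray(res.pvalue, float)
    return np.where(np.isnan(p), 1.0, p)


def _permutation_p(logn: np.ndarray, g1: np.ndarray, g2: np.ndarray,
                   rng: np.random.Generator, max_exact: int = 20,
                   n_mc: int = 1000) -> np.ndarray:
    """Two-sided label-permutation p on the difference of group means.

    Exact enumeration when the number of distinct label splits is small,
    Monte-Carlo otherwise.
    """
    idx_all = np.concatenate([g1, g2])
    n1 = len(g1)
    splits = list(combinations(range(len(idx_all)), n1))
    obs = np.abs(logn[:, g2].mean(axis=1) - logn[:, g1].mean(axis=1))
    if len(splits) <= max_exact:
        perms = splits
    else:
        perms = [tuple(rng.choice(len(idx_all), size=n1, replace=False))
                 for _ in range(n_mc)]
    count = np.zeros(logn.shape[0])
    for sp in perms:
        a = idx_all[list(sp)]
        b = idx_all[[i for i in range(len(idx_all)) if i not in sp]]
        d = np.abs(logn[:, b].mean(axis=1) - logn[:, a].mean(axis=1))
        count += d >= obs - 1e-12
    return count / len(perms)


def de_classify(
    matrix: CountMatrix,
    factors: pd.Series | None = None,
    fc_threshold: float = 1.2,
    q_threshold: float = 0.05,
    abundance_floor: float = 1.0,
    abundance_unit: str = "CPM",
    conditions: tuple[str, str] | None = None,
    test: str = "nbwald",
    preset: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify target features as up / down / unchanged / filtered.

    ``factors`` are per-sample scale factors (spike-in median-of-ratios when
    provided; defaults to 1).  Fold change is the ratio of normalized
    condition means (baseline = first condition); thresholds are inclusive.
    """
    if preset is not None:
        opts = PRESETS[preset]
        fc_threshold, q_threshold = opts["fc_threshold"], opts["q_threshold"]
        abundance_floor, abundance_unit = opts["abundance_floor"], opts["abundance_unit"]
    conds = conditions or tuple(dict.fromkeys(matrix.condition[matrix.samples]))
    if len(conds) != 2:
        raise ValueError("de_classify needs exactly two conditions")
    s1, s2 = matrix.samples_of(conds[0]), matrix.samples_of(conds[1])
    if min(len(s1), len(s2)) < 2 and test != "welch_unsafe":
        raise ValueError("each condition needs >= 2 replicates")

    target = matrix.target()
    if factors is None:
        factors = pd.Series(1.0, index=matrix.samples)
    norm = target / factors.reindex(target.columns)
    cols = list(target.columns)
    g1 = np.array([cols.index(s) for s in s1])
    g2 = np.array([cols.index(s) for s in s2])
    arr = norm.to_numpy(float)

    m1, m2 = arr[:, g1].mean(axis=1), arr[:, g2].mean(axis=1)
    pseud = 1e-8
    log2fc = np.log2((m2 + pseud) / (m1 + pseud))

    if abundance_unit.upper() == "TPM":
        abund = tpm(target, matrix.lengths).mean(axis=1).to_numpy()
    else:
        abund = cpm(matrix.counts).loc[target.index].mean(axis=1).to_numpy()

    if test == "nbwald":
        p = _nb_wald_p(arr, g1, g2)
    elif test == "welch":
        p = _welch_p(np.log2(arr + 1.0), g1, g2)
    elif test == "permutation":
        p = _permutation_p(np.log2(arr + 1.0), g1, g2,
                           np.random.default_rng(seed))
    else:
        raise ValueError(f"unknown test {test!r}")
    q = bh_adjust(p)

    status = np.array(["unchanged"] * len(target), dtype=object)
    passing = (q < q_threshold) & (2.0 ** np.abs(log2fc) >= fc_threshold)
    status[passing & (log2fc > 0)] = "up"
    status[passing & (log2fc < 0)] = "down"
    status[abund < abundance_floor] = "filtered"
    return pd.DataFrame({
        "feature_id": target.index, "log2fc": log2fc,
        "mean_abundance": abund, "p_value": p, "q_value": q, "status": status,
    }).reset_index(drop=True)
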
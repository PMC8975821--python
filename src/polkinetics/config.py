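"""Configuration objects: the synthetic-data generator (SimConfig) and the
end-to-end pipeline (RunConfig).

Every numeric analysis threshold in RunConfig defaults to the value used by
the study design this package implements (length filters 30/60 kb, CI width
0.5 kb/min, intercept bound -10 min, TR floor 0.005 and fold change 1.5,
abundance floors TPM/CPM >= 1, DE fold changes 1.2/1.5/2, q cutoffs
0.05/0.01, island parameters 500/1000/100, 50-read support floor, Pearson
reproducibility floor 0.90).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml


class SizingError(ValueError):
    """The chromosome is too small for the requested gene complement."""


def _default_speeds() -> dict[str, float]:
    # control at the typical human elongation rate (~3.8 kb/min); knockout
    # faster, emulating loss of a pausing/elongation restraint
    return {"control": 3.8, "ko": 4.4}


def _default_extragenic() -> dict[str, int]:
    return {"lncRNA": 3, "enhancer": 3, "antisense": 2, "PROMPT": 4,
            "readthrough": 3, "promoter_convergent": 2, "other": 3}


@dataclass
class NoiseConfig:
    """Signal/noise levels of simulated coverage.

    background : mean background counts per 50-bp bin
    wave_mean  : mean counts per bin inside the labeled-RNA wave
    dispersion : negative-binomial dispersion (var = m + a*m^2); 0 -> Poisson
    """

    background: float = 0.2
    wave_mean: float = 15.0
    dispersion: float = 0.05


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 60
    chrom_length: int | None = None          # bp; None -> auto-sized
    gene_length_range: tuple[int, int] = (8_000, 150_000)
    bin_width: int = 50
    wave_speed_by_condition: dict[str, float] = field(default_factory=_default_speeds)
    time_points: tuple[int, ...] = (0, 10, 20)
    replicates_per_condition: int = 2
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    pausing_index_range: tuple[float, float] = (1.0, 10.0)
    spikein_n: int = 50
    de_fraction: float = 0.1
    de_fold: float = 2.0
    extragenic_classes: dict[str, int] = field(default_factory=_default_extragenic)

    # secondary knobs (documented in the methods note)
    front_decay_width: int = 250             # bp, logistic transition zone at the wave front
    speed_jitter_sd: float = 0.05            # lognormal sd of per-gene speed around the condition mean
    deterministic_signal: bool = False       # emit expected values instead of sampling
    overlap_violations: int = 3              # genes given an overlapping partner
    upstream_violations: int = 3             # genes given a neighbor <2 kb upstream
    composition_shift: float = 1.0           # global fold applied to all KO target features
    tr_affected_fraction: float = 0.4        # genes whose KO traveling ratio is shifted
    tr_fold: float = 2.0                     # fold by which affected KO TRs decrease
    count_mean_range: tuple[float, float] = (100.0, 2000.0)
    depth_factor_range: tuple[float, float] = (0.7, 1.3)
    island_mean_reads: float = 150.0         # per-sample reads on a simulated extragenic island
    background_read_rate: float = 5e-5       # intergenic background reads per bp per sample

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for cond, v in self.wave_speed_by_condition.items():
            if v <= 0:
                raise ValueError(f"wave speed for {cond!r} must be > 0")
        if self.chrom_length is not None and self.chrom_length % self.bin_width:
            raise ValueError("bin_width must divide chrom_length")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range must be (lo, hi)")
        if self.replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named child RNG streams, all derived from the root seed.

        One fixed spawn order keeps every component reproducible and
        independent of how many of them a given run uses.
        """
        names = ["annotation", "waves", "occupancy", "counts", "extragenic"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class RunConfig:
    """All thresholds of the end-to-end pipeline, in one flat namespace."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "polkinetics_run"
    seed: int = 0

    # elongation-rate stage
    min_length_10min: int = 30_000
    min_length_20min: int = 60_000
    upstream_clearance: int = 2_000
    tes_exclusion: int = 2_000
    ci_max_width: float = 0.5                # kb/min, full 50% CI width
    intercept_floor: float = -10.0           # min
    rate_change_rule: str = "strict"

    # pausing stage
    promoter_upstream: int = 50
    promoter_downstream: int = 300
    tr_promoter_floor: float = 0.005
    tr_fc_threshold: float = 1.5

    # differential output stage
    de_fc_threshold: float = 1.2
    de_q_threshold: float = 0.05
    abundance_floor: float = 1.0
    de_test: str = "nbwald"

    # extragenic stage
    island_window: int = 500
    island_gap: int = 1_000
    island_e_value: float = 100.0
    support_floor: int = 50

    pearson_floor: float = 0.90

    def validate(self) -> list[str]:
        """Report (not raise) out-of-range settings."""
        problems = []
        if self.de_fc_threshold < 1:
            problems.append(f"de_fc_threshold {self.de_fc_threshold} < 1")
        if not 0 < self.de_q_threshold < 1:
            problems.append(f"de_q_threshold {self.de_q_threshold} outside (0,1)")
        if self.ci_max_width <= 0:
            problems.append("ci_max_width must be > 0")
        if self.support_floor < 0:
            problems.append("support_floor must be >= 0")
        if self.tr_fc_threshold < 1:
            problems.append("tr_fc_threshold must be >= 1")
        if not 0 < self.pearson_floor <= 1:
            problems.append("pearson_floor outside (0,1]")
        try:
            self.sim.validate()
        except ValueError as exc:
            problems.append(str(exc))
        return problems


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _tuplify_sim(d: dict) -> SimConfig:
    kw = dict(d)
    if "noise" in kw and isinstance(kw["noise"], dict):
        kw["noise"] = NoiseConfig(**kw["noise"])
    for key in ("gene_length_range", "time_points", "pausing_index_range",
                "count_mean_range", "depth_factor_range"):
        if key in kw and isinstance(kw[key], list):
            kw[key] = tuple(kw[key])
    return SimConfig(**kw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "sim" in d:
        d["sim"] = _tuplify_sim(d["sim"])
    return RunConfig(**d)
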
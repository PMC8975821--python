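"""End-to-end orchestration: simulate -> wave boundaries -> rates -> traveling
ratios -> output calls -> nine groups -> extragenic transcripts.

``run`` executes every stage from one RunConfig, writes each stage's table
under the output directory and a manifest recording the configuration, seed
and SHA-256 digest of every output, so that a rerun with the same config can
be verified bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import numpy as np
import pandas as pd

from . import extragenic as xg
from . import io, pausing, rates, simulate, spikein, wavehmm
from .config import RunConfig, _to_plain


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _travel_distances(bdf: pd.DataFrame, gene_id: str, cond: str, t: int) -> list[float]:
    sub = bdf[(bdf["gene_id"] == gene_id) & (bdf["condition"] == cond)
              & (bdf["time_min"] == t) & bdf["clear"]]
    return [b / 1e3 for b in sub["boundary_bp"]]


def validate(config: RunConfig) -> list[str]:
    """Report-only config check (unknown keys are caught at load time)."""
    return config.validate()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns stage tables and the manifest."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    os.makedirs(config.out_dir, exist_ok=True)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    results: dict = {}

    # --- stage 1: synthetic inputs
    ann = simulate.make_annotation(sim)
    genes = ann.genes
    results["annotation"] = genes
    results["gene_truth"] = ann.truth

    # --- stage 2: wave boundaries
    wave_tracks, wave_truth = simulate.simulate_wave_tracks(sim, ann)
    conditions = sorted(sim.wave_speed_by_condition)
    ctrl, ko = conditions[0], conditions[-1] if len(conditions) > 1 else conditions[0]
    elig30 = rates.eligible_genes(genes, config.min_length_10min,
                                  config.upstream_clearance)
    elig60 = rates.eligible_genes(genes, config.min_length_20min,
                                  config.upstream_clearance)
    g30 = genes[genes["gene_id"].isin(elig30)]
    g60 = genes[genes["gene_id"].isin(elig60)]
    spec = wavehmm.HmmSpec()
    b10, _ = wavehmm.cohort_boundaries(wave_tracks, g30, spec, times=(10,),
                                       tes_exclusion=config.tes_exclusion)
    b20, _ = wavehmm.cohort_boundaries(wave_tracks, g60, spec, times=(20,),
                                       tes_exclusion=config.tes_exclusion)
    boundaries = pd.concat([b10, b20], ignore_index=True)
    results["boundaries"] = boundaries
    results["wave_truth"] = wave_truth

    # --- stage 3: rates and rate changes
    def _clear_in_all(gid: str, conds, ts) -> bool:
        for c in conds:
            for t in ts:
                sub = boundaries[(boundaries["gene_id"] == gid)
                                 & (boundaries["condition"] == c)
                                 & (boundaries["time_min"] == t)]
                if len(sub) == 0 or not sub["clear"].all():
                    return False
        return True

    rate_rows, change_rows = [], []
    for gid in sorted(elig30):
        if not _clear_in_all(gid, conditions, (10,)):
            continue
        dists = {c: _travel_distances(boundaries, gid, c, 10) for c in conditions}
        for c in conditions:
            est = rates.simple_rate(dists[c], 10, gene_id=gid, condition=c)
            rate_rows.append((gid, c, est.interval, est.rate, None, None, True))
        early = rates.classify_rate_change(dists[ctrl], dists[ko],
                                           rule=config.rate_change_rule)
        change_rows.append((gid, "r0_10", early))

    late_rows = []
    for gid in sorted(elig60):
        if not _clear_in_all(gid, conditions, (10, 20)):
            continue
        d10 = {c: _travel_distances(boundaries, gid, c, 10) for c in conditions}
        d20 = {c: _travel_distances(boundaries, gid, c, 20) for c in conditions}
        for c in conditions:
            est = rates.fitted_rate_10_20(
                d10[c], d20[c], gene_id=gid, condition=c,
                ci_max_width=config.ci_max_width,
                intercept_floor=config.intercept_floor)
            rate_rows.append((gid, c, est.interval, est.rate, est.ci_halfwidth,
                              est.intercept_time, est.passes_filters))
            est020 = rates.simple_rate([d for d in d20[c]], 20, gene_id=gid,
                                       condition=c)
            rate_rows.append((gid, c, est020.interval, est020.rate, None, None,
                              True))
        early = rates.classify_rate_change(d10[ctrl], d10[ko],
                                           rule=config.rate_change_rule)
        deltas = {c: [b - a for a, b in zip(d10[c], d20[c])] for c in conditions}
        late = rates.classify_rate_change(deltas[ctrl], deltas[ko],
                                          rule=config.rate_change_rule)
        change_rows.append((gid, "r10_20", late))
        late_rows.append((gid, early, late,
                          rates.late_rate_composite(early, late)))
    rate_df = pd.DataFrame(rate_rows, columns=[
        "gene_id", "condition", "interval", "rate", "ci_halfwidth",
        "intercept_time", "passes_filters"])
    change_df = pd.DataFrame(change_rows, columns=["gene_id", "interval",
                                                   "category"])
    late_df = pd.DataFrame(late_rows, columns=["gene_id", "early", "late",
                                               "composite"])
    results["rates"] = rate_df
    results["rate_changes"] = change_df
    results["late_composite"] = late_df

    # --- stage 4: traveling ratios
    occ_tracks, occ_truth = simulate.simulate_occupancy_track(sim, ann)
    pooled = {}
    for c in conditions:
        reps = [occ_tracks[(c, r)] for r in range(1, sim.replicates_per_condition + 1)]
        vals = {ch: np.sum([t.values[ch] for t in reps], axis=0)
                for ch in reps[0].values}
        pooled[c] = reps[0].__class__(vals, bin_width=reps[0].bin_width,
                                      normalization="raw",
                                      total_reads=float(sum(t.total_reads for t in reps)))
    tr_rows = []
    pc = genes[genes["biotype"] == "protein_coding"]
    for _, g in pc.iterrows():
        trs = {c: pausing.traveling_ratio(
            pooled[c], g, config.promoter_upstream, config.promoter_downstream,
            config.tr_promoter_floor) for c in conditions}
        status = pausing.tr_change(trs[ctrl].tr, trs[ko].tr,
                                   config.tr_fc_threshold)
        tr_rows.append((g["gene_id"], trs[ctrl].tr, trs[ko].tr, status))
    tr_df = pd.DataFrame(tr_rows, columns=["gene_id", "tr_ctrl", "tr_ko",
                                           "tr_status"])
    results["traveling_ratio"] = tr_df
    results["occupancy_truth"] = occ_truth

    # --- stage 5: spike-in normalized output calls
    matrix, count_truth, sample_truth = simulate.simulate_counts(sim, ann)
    factors = spikein.size_factors_median_of_ratios(matrix.spike())
    de = spikein.de_classify(matrix, factors, preset="ttseq",
                             conditions=(ctrl, ko), test=config.de_test,
                             fc_threshold=config.de_fc_threshold,
                             q_threshold=config.de_q_threshold,
                             seed=config.seed)
    results["size_factors"] = factors.rename_axis("sample").reset_index(name="factor")
    results["de"] = de
    results["count_truth"] = count_truth
    results["sample_truth"] = sample_truth

    # --- stage 6: nine groups and contingency
    out_status = de.set_index("feature_id")["status"].map(
        {"up": "increased", "down": "decreased", "unchanged": "unaffected"})
    groups = pausing.nine_groups(tr_df.set_index("gene_id")["tr_status"],
                                 out_status)
    results["nine_groups"] = groups

    tab = pd.crosstab(change_df[change_df["interval"] == "r0_10"]
                      .set_index("gene_id")["category"],
                      tr_df.set_index("gene_id")["tr_status"])
    if tab.size and (tab.sum(axis=1) > 0).all() and (tab.sum(axis=0) > 0).all() \
            and tab.shape[0] > 1 and tab.shape[1] > 1:
        ct = rates.chisq_independence(tab.to_numpy())
        results["contingency"] = {
            "rows": list(tab.index), "cols": list(tab.columns),
            "observed": ct.observed.tolist(), "chi2": ct.chi2, "df": ct.df,
            "p_value": ct.p_value, "std_residuals": ct.std_residuals.tolist(),
        }

    # --- stage 7: extragenic transcripts
    reads, island_truth = simulate.simulate_extragenic_reads(sim, ann)
    clean = xg.exclude_genic_reads(reads, pc)
    samples_by_cond = {c: [f"{c}_rep{r}"
                           for r in range(1, sim.replicates_per_condition + 1)]
                       for c in conditions}
    islands_by_cond = {}
    for c in conditions:
        csub = clean[clean["sample"].isin(samples_by_cond[c])]
        per_strand = [xg.call_islands(csub, strand, ann.chrom_sizes,
                                      window=config.island_window,
                                      gap=config.island_gap,
                                      e_value=config.island_e_value,
                                      seed=config.seed)
                      for strand in "+-"]
        islands_by_cond[c] = pd.concat(per_strand, ignore_index=True)
    merged = xg.merge_and_filter(islands_by_cond, clean, samples_by_cond,
                                 support_floor=config.support_floor)
    annotated = xg.annotate_regions(merged, genes, ann.lncrnas, ann.enhancers)
    results["extragenic"] = annotated
    results["island_truth"] = island_truth

    # --- outputs + manifest
    manifest = {"config": _to_plain(config), "seed": config.seed, "outputs": {}}
    for name in ("annotation", "gene_truth", "boundaries", "rates",
                 "rate_changes", "late_composite", "traveling_ratio", "de",
                 "size_factors", "nine_groups", "extragenic", "wave_truth",
                 "occupancy_truth", "count_truth", "sample_truth",
                 "island_truth"):
        path = os.path.join(config.out_dir, f"{name}.tsv")
        io.write_tsv(results[name], path)
        manifest["outputs"][name] = _sha256(path)
    if "contingency" in results:
        path = os.path.join(config.out_dir, "contingency.json")
        with open(path, "w") as fh:
            json.dump(results["contingency"], fh, indent=1, sort_keys=True)
        manifest["outputs"]["contingency"] = _sha256(path)
    mpath = os.path.join(config.out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results
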
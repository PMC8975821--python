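"""Synthetic-data generator.

Produces every input the analysis stages consume — gene annotation, 4sU
labeled-RNA wave tracks at 0/10/20 min after release from a transcription
block, promoter-peaked Pol II occupancy tracks, spike-in bearing count
matrices, and stranded extragenic read sets — with the statistical structure
the downstream methods assume, plus machine-readable truth tables so every
estimate can be checked against what was simulated.

All randomness flows from ``SimConfig.seed`` through named child streams
(annotation / waves / occupancy / counts / extragenic), so a fixed seed gives
bit-identical datasets regardless of which components a run touches.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io
from .config import SimConfig, SizingError
from .spikein import CountMatrix
from .tracks import BinnedTrack

CHROM = "chrS"
READ_LEN = 100


# ---------------------------------------------------------------------------
# annotation


@dataclass
class GenomeAnnotation:
    genes: pd.DataFrame                      # gene_id chrom start end strand biotype
    lncrnas: pd.DataFrame
    enhancers: pd.DataFrame
    chrom_sizes: dict[str, int]
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def gene(self, gene_id: str) -> pd.Series:
        return self.genes.set_index("gene_id").loc[gene_id]


def _upstream_window(start: int, end: int, strand: str, clearance: int) -> tuple[int, int]:
    return (start - clearance, start) if strand == "+" else (end, end + clearance)


def _overlaps(s1, e1, s2, e2) -> bool:
    return s1 < e2 and s2 < e1


def compute_gene_truth(genes: pd.DataFrame, clearance: int = 2000) -> pd.DataFrame:
    """Per-gene filter facts: pairwise overlap, upstream clearance, and the
    30/60 kb eligibility calls built from them."""
    pc = genes[genes["biotype"] == "protein_coding"].reset_index(drop=True)
    n = len(pc)
    overlaps = np.zeros(n, bool)
    clear_up = np.ones(n, bool)
    for i in range(n):
        si, ei = int(pc.loc[i, "start"]), int(pc.loc[i, "end"])
        us, ue = _upstream_window(si, ei, pc.loc[i, "strand"], clearance)
        for j in range(n):
            if i == j:
                continue
            sj, ej = int(pc.loc[j, "start"]), int(pc.loc[j, "end"])
            if _overlaps(si, ei, sj, ej):
                overlaps[i] = True
            if _overlaps(us, ue, sj, ej):
                clear_up[i] = False
    length = (pc["end"] - pc["start"]).to_numpy()
    return pd.DataFrame({
        "gene_id": pc["gene_id"], "chrom": pc["chrom"], "start": pc["start"],
        "end": pc["end"], "strand": pc["strand"], "length": length,
        "overlaps_other": overlaps, "clear_upstream": clear_up,
        "eligible_30k": (length > 30_000) & ~overlaps & clear_up,
        "eligible_60k": (length > 60_000) & ~overlaps & clear_up,
    })


def make_annotation(cfg: SimConfig) -> GenomeAnnotation:
    """Lay out genes on one synthetic chromosome.

    Genes are placed sequentially with intergenic gaps of 2.6-6 kb, covering
    short (<30 kb), medium (30-60 kb) and long (>60 kb) length strata, plus a
    configurable number of deliberate filter violations (overlapping partners
    and sub-2-kb upstream neighbours).  An intergenic arena at the 3' end of
    the chromosome hosts lncRNA and enhancer intervals and leaves space for
    purely intergenic transcription.
    """
    cfg.validate()
    rng = cfg.streams()["annotation"]
    bw = cfg.bin_width
    lo, hi = cfg.gene_length_range

    genes = []
    pos = 10_000
    strata = [(lo, min(hi, 30_000)), (max(lo, 30_000), min(hi, 60_000)),
              (max(lo, 60_000), hi)]
    strata = [(a, b) for a, b in strata if a < b]
    for i in range(cfg.n_genes):
        a, b = strata[i % len(strata)]
        length = int(rng.integers(a, b)) // bw * bw
        strand = "+" if rng.random() < 0.5 else "-"
        start = pos
        genes.append((f"gene_{i:04d}", CHROM, start, start + length, strand,
                      "protein_coding"))
        gap = int(rng.integers(2_600, 6_000)) // bw * bw
        pos = start + length + gap

    # deliberate filter violations
    extra = []
    main_idx = rng.permutation(cfg.n_genes) if cfg.n_genes else np.array([], int)
    k = 0
    for v in range(min(cfg.overlap_violations, cfg.n_genes // 4)):
        gid, chrom, s, e, strand, _ = genes[main_idx[k]]; k += 1
        ps = max(s + bw, e - 2_000)
        extra.append((f"ovl_{v:03d}", chrom, ps, e + 500, strand, "protein_coding"))
    for v in range(min(cfg.upstream_violations, cfg.n_genes // 4)):
        gid, chrom, s, e, strand, _ = genes[main_idx[k]]; k += 1
        if strand == "+":
            extra.append((f"ups_{v:03d}", chrom, s - 1_500, s - 700, strand,
                          "protein_coding"))
        else:
            extra.append((f"ups_{v:03d}", chrom, e + 700, e + 1_500, strand,
                          "protein_coding"))

    gene_df = pd.DataFrame(genes + extra, columns=[
        "gene_id", "chrom", "start", "end", "strand", "biotype"])

    # intergenic arena: lncRNAs, enhancers, room for intergenic islands
    n_lnc = cfg.extragenic_classes.get("lncRNA", 0) + 1
    n_enh = cfg.extragenic_classes.get("enhancer", 0) + 1
    n_other = cfg.extragenic_classes.get("other", 0) + 1
    arena = pos + 20_000
    lnc_rows, enh_rows = [], []
    for i in range(n_lnc):
        strand = "+" if rng.random() < 0.5 else "-"
        lnc_rows.append((f"lnc_{i:03d}", CHROM, arena, arena + 2_000, strand))
        arena += 10_000
    for i in range(n_enh):
        enh_rows.append((f"enh_{i:03d}", CHROM, arena, arena + 1_000, "."))
        arena += 10_000
    arena += n_other * 10_000 + 10_000

    required = -(-arena // bw) * bw
    if cfg.chrom_length is not None:
        if cfg.chrom_length < required:
            raise SizingError(
                f"chrom_length {cfg.chrom_length} bp cannot hold {cfg.n_genes} "
                f"genes plus the intergenic arena (need >= {required} bp)")
        chrom_len = cfg.chrom_length
    else:
        chrom_len = required

    lnc_df = pd.DataFrame(lnc_rows, columns=["name", "chrom", "start", "end", "strand"])
    enh_df = pd.DataFrame(enh_rows, columns=["name", "chrom", "start", "end", "strand"])
    truth = compute_gene_truth(gene_df) if len(gene_df) else pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end", "strand", "length",
                 "overlaps_other", "clear_upstream", "eligible_30k", "eligible_60k"])
    return GenomeAnnotation(gene_df, lnc_df, enh_df, {CHROM: chrom_len}, truth)


# ---------------------------------------------------------------------------
# sampling helpers


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixing; dispersion 0 is Poisson."""
    mean = np.asarray(mean, float)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    out = np.zeros_like(mean)
    nz = mean > 0
    lam = rng.gamma(1.0 / dispersion, mean[nz] * dispersion)
    out[nz] = rng.poisson(lam)
    return out


# ---------------------------------------------------------------------------
# 4sU wave tracks


def wave_profile(n_bins: int, front_bp: float, wave_mean: float, bin_width: int,
                 decay_width: int) -> np.ndarray:
    """Expected wave signal along a gene (bp from TSS, one value per bin).

    The wave carries ``wave_mean`` per bin and falls off logistically across
    a transition zone of ``decay_width`` bp centred on the nominal front
    ``front_bp`` (= speed x time): the polymerases at the wave tip are spread
    symmetrically about their mean position, so coverage is at half the wave
    level exactly at the front, ~88% half a width before it and ~12% half a
    width past it (scale ``decay_width/8``).
    """
    if front_bp <= 0:
        return np.zeros(n_bins)
    x = (np.arange(n_bins) + 0.5) * bin_width
    return wave_mean * expit((front_bp - x) / (decay_width / 8.0))


def simulate_wave_tracks(
    cfg: SimConfig, ann: GenomeAnnotation
) -> tuple[dict[tuple[str, int, int], BinnedTrack], pd.DataFrame]:
    """Simulate labeled-RNA coverage for every condition x replicate x time.

    Returns the tracks keyed by (condition, replicate, time_min) and a truth
    table with the per-gene speed and nominal front position of every
    replicate track.
    """
    cfg.validate()
    rng = cfg.streams()["waves"]
    bw = cfg.bin_width
    chrom_len = ann.chrom_sizes[CHROM]
    n_bins = -(-chrom_len // bw)
    genes = ann.genes[ann.genes["biotype"] == "protein_coding"]

    conditions = sorted(cfg.wave_speed_by_condition)
    speeds = {}  # (gene_id, condition) -> kb/min
    for cond in conditions:
        base = cfg.wave_speed_by_condition[cond]
        jit = np.exp(rng.normal(0.0, cfg.speed_jitter_sd, size=len(genes)))
        for g, j in zip(genes["gene_id"], jit):
            speeds[(g, cond)] = base * j

    tracks: dict[tuple[str, int, int], BinnedTrack] = {}
    truth_rows = []
    for cond in conditions:
        for rep in range(1, cfg.replicates_per_condition + 1):
            for t in sorted(cfg.time_points):
                mean = np.full(n_bins, cfg.noise.background, float)
                for _, g in genes.iterrows():
                    v = speeds[(g["gene_id"], cond)]
                    front = v * 1000.0 * t
                    glen = int(g["end"] - g["start"])
                    gb0, gb1 = int(g["start"]) // bw, int(g["end"]) // bw
                    prof = wave_profile(gb1 - gb0, min(front, glen),
                                        cfg.noise.wave_mean, bw,
                                        cfg.front_decay_width)
                    if g["strand"] == "-":
                        prof = prof[::-1]
                    mean[gb0:gb1] += prof
                    truth_rows.append((g["gene_id"], cond, rep, t, v, front, glen))
                vals = mean if cfg.deterministic_signal else _nb_sample(
                    rng, mean, cfg.noise.dispersion)
                tracks[(cond, rep, t)] = BinnedTrack(
                    {CHROM: vals}, bin_width=bw, normalization="raw")
    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "condition", "replicate", "time_min", "speed_kb_min",
        "front_bp", "gene_length"])
    return tracks, truth


# ---------------------------------------------------------------------------
# occupancy tracks (traveling-ratio substrate)


def simulate_occupancy_track(
    cfg: SimConfig, ann: GenomeAnnotation
) -> tuple[dict[tuple[str, int], BinnedTrack], pd.DataFrame]:
    """Promoter-peaked Pol II occupancy per condition x replicate.

    Tracks are in read-start counts per bin.  Each gene draws a body density
    and a true traveling ratio (promoter/body density ratio) from
    ``pausing_index_range``; in the knockout a configurable fraction of genes
    has its promoter density divided by ``tr_fold`` (TR decreased upon loss of
    the pausing factor).  Truth records the density pair per condition.
    """
    cfg.validate()
    rng = cfg.streams()["occupancy"]
    bw = cfg.bin_width
    chrom_len = ann.chrom_sizes[CHROM]
    n_bins = -(-chrom_len // bw)
    genes = ann.genes[ann.genes["biotype"] == "protein_coding"].reset_index(drop=True)
    conditions = sorted(cfg.wave_speed_by_condition)

    body_rate = np.exp(rng.normal(np.log(0.02), 0.4, size=len(genes)))  # starts/bp
    lo, hi = cfg.pausing_index_range
    tr_true = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes))) \
        if lo > 0 else rng.uniform(lo, hi, size=len(genes))
    affected = rng.random(len(genes)) < cfg.tr_affected_fraction

    truth_rows = []
    rates = {}
    for cond in conditions:
        ko = cond != conditions[0]
        for i, g in genes.iterrows():
            tr = tr_true[i] / cfg.tr_fold if (ko and affected[i]) else tr_true[i]
            rates[(g["gene_id"], cond)] = (tr * body_rate[i], body_rate[i])
            truth_rows.append((g["gene_id"], cond, tr, tr * body_rate[i],
                               body_rate[i], bool(affected[i])))

    # unspecific background scales with the configured background noise
    # (0.001 starts/bp at the default level; exactly zero when noise is off)
    bg_rate = cfg.noise.background / 200.0

    tracks: dict[tuple[str, int], BinnedTrack] = {}
    for cond in conditions:
        for rep in range(1, cfg.replicates_per_condition + 1):
            mean = np.full(n_bins, bg_rate * bw, float)
            for _, g in genes.iterrows():
                prom_rate, brate = rates[(g["gene_id"], cond)]
                s, e = int(g["start"]), int(g["end"])
                if g["strand"] == "+":
                    pw = (s - 50, s + 300)
                    bodyw = (s + 300, e)
                else:
                    pw = (e - 300, e + 50)
                    bodyw = (s, e - 300)
                for (ws, we), rate in ((pw, prom_rate), (bodyw, brate)):
                    b0, b1 = max(ws, 0) // bw, -(-we // bw)
                    edges = np.arange(b0, b1 + 1) * bw
                    overlap = (np.minimum(edges[1:], we)
                               - np.maximum(edges[:-1], ws)).clip(min=0)
                    mean[b0:b1] += rate * overlap
            vals = mean if cfg.deterministic_signal else rng.poisson(mean).astype(float)
            tracks[(cond, rep)] = BinnedTrack(
                {CHROM: vals}, bin_width=bw, normalization="raw",
                total_reads=float(vals.sum()))
    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "condition", "tr_true", "promoter_rate", "body_rate",
        "tr_affected"])
    return tracks, truth


# ---------------------------------------------------------------------------
# count matrices with spike-ins


def simulate_counts(
    cfg: SimConfig, ann: GenomeAnnotation
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial gene x sample counts with unchanged spike-in features.

    A ``de_fraction`` of target features is perturbed ``de_fold``-fold in the
    knockout (half up, half down); ``composition_shift`` applies a global fold
    to *all* knockout target features, which only spike-in normalization can
    undo.  Per-sample sequencing-depth factors are drawn and recorded in the
    truth table so size-factor recovery can be checked.
    """
    cfg.validate()
    if cfg.spikein_n <= 0:
        raise ValueError("spikein_n must be > 0")
    rng = cfg.streams()["counts"]
    genes = ann.genes[ann.genes["biotype"] == "protein_coding"].reset_index(drop=True)
    target_ids = list(genes["gene_id"])
    target_len = (genes["end"] - genes["start"]).to_numpy()
    spike_ids = [f"spike_{i:03d}" for i in range(cfg.spikein_n)]
    feat_ids = target_ids + spike_ids
    lengths = np.concatenate([target_len, np.full(cfg.spikein_n, 1_500)])
    spike_flag = np.array([False] * len(target_ids) + [True] * cfg.spikein_n)

    conditions = sorted(cfg.wave_speed_by_condition)
    samples = [f"{c}_rep{r}" for c in conditions
               for r in range(1, cfg.replicates_per_condition + 1)]
    cond_of = {s: s.rsplit("_rep", 1)[0] for s in samples}
    depth = dict(zip(samples, rng.uniform(*cfg.depth_factor_range, size=len(samples))))

    lo, hi = cfg.count_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(feat_ids)))
    labels = np.array(["null"] * len(feat_ids), dtype=object)
    n_de = int(round(cfg.de_fraction * len(target_ids)))
    de_idx = rng.choice(len(target_ids), size=n_de, replace=False)
    labels[de_idx[: n_de // 2]] = "up"
    labels[de_idx[n_de // 2:]] = "down"
    labels[spike_flag] = "spikein"

    counts = np.zeros((len(feat_ids), len(samples)))
    for j, s in enumerate(samples):
        ko = cond_of[s] != conditions[0]
        fold = np.ones(len(feat_ids))
        if ko:
            fold[~spike_flag] *= cfg.composition_shift
            fold[labels == "up"] *= cfg.de_fold
            fold[labels == "down"] /= cfg.de_fold
        mean = base * depth[s] * fold
        counts[:, j] = mean if cfg.deterministic_signal else _nb_sample(
            rng, mean, cfg.noise.dispersion)
    counts = np.round(counts).astype(int)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=feat_ids, columns=samples),
        lengths=pd.Series(lengths, index=feat_ids),
        spikein=pd.Series(spike_flag, index=feat_ids),
        condition=pd.Series({s: cond_of[s] for s in samples}),
    )
    truth = pd.DataFrame({
        "feature_id": feat_ids, "spikein": spike_flag, "label": labels,
        "base_mean": base,
    })
    truth_samples = pd.DataFrame({
        "sample": samples, "condition": [cond_of[s] for s in samples],
        "depth_factor": [depth[s] for s in samples],
    })
    return matrix, truth, truth_samples


# ---------------------------------------------------------------------------
# stranded extragenic reads


def _island_anchor(cls: str, gene: pd.Series) -> tuple[int, int, str]:
    s, e, strand = int(gene["start"]), int(gene["end"]), gene["strand"]
    opp = "-" if strand == "+" else "+"
    if cls == "PROMPT":
        # kept >=600 bp clear of the TSS so that window-rounded island calls
        # cannot spill into the gene body (which would out-rank PROMPT as
        # antisense in the class priority)
        span = (s - 1_800, s - 600) if strand == "+" else (e + 600, e + 1_800)
        return (*span, opp)
    if cls == "promoter_convergent":
        span = (s - 1_800, s - 300) if strand == "+" else (e + 300, e + 1_800)
        return (*span, strand)
    if cls == "readthrough":
        span = (e + 200, e + 1_700) if strand == "+" else (s - 1_700, s - 200)
        return (*span, strand)
    if cls == "antisense":
        mid = (s + e) // 2
        return (mid - 1_000, mid + 1_000, opp)
    raise ValueError(cls)


def simulate_extragenic_reads(
    cfg: SimConfig, ann: GenomeAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stranded 100-bp read intervals forming extragenic islands of known class.

    Gene-anchored classes (PROMPT, readthrough, promoter-convergent,
    antisense) are placed on clean, well-separated genes; lncRNA and enhancer
    islands sit on the corresponding annotation intervals; "other" islands go
    deep into the intergenic arena.  Per-sample read support per island is
    negative-binomial around ``island_mean_reads`` and recorded in the truth
    table.  A thin uniform background of reads covers both strands.
    """
    cfg.validate()
    rng = cfg.streams()["extragenic"]
    chrom_len = ann.chrom_sizes[CHROM]
    truth = ann.truth
    clean = truth[(~truth["overlaps_other"]) & truth["clear_upstream"]] \
        if len(truth) else truth
    conditions = sorted(cfg.wave_speed_by_condition)
    samples = [f"{c}_rep{r}" for c in conditions
               for r in range(1, cfg.replicates_per_condition + 1)]

    gene_classes = ["PROMPT", "readthrough", "promoter_convergent", "antisense"]
    need = sum(cfg.extragenic_classes.get(c, 0) for c in gene_classes)
    pool = list(clean["gene_id"])

    pc = ann.genes[ann.genes["biotype"] == "protein_coding"]
    gs = pc["start"].to_numpy(int)
    ge = pc["end"].to_numpy(int)
    gstrand = pc["strand"].to_numpy()
    gids = pc["gene_id"].to_numpy()
    tss = np.where(gstrand == "+", gs, ge - 1)
    tes = np.where(gstrand == "+", ge - 1, gs)

    def _well_separated(s: int, e: int, cls: str, anchor_id: str) -> bool:
        """The island must be unambiguous for the class-priority annotator:
        >2 kb from every other gene's TSS and TES and (except antisense)
        clear of every gene body, with one window width (600 bp) of slack
        because called islands are rounded outward to window boundaries."""
        ps, pe = s - 600, e + 600
        for gid2, s2, e2, t2, x2 in zip(gids, gs, ge, tss, tes):
            if gid2 == anchor_id:
                continue
            if _overlaps(ps, pe, s2, e2) and cls != "antisense":
                return False
            if _overlaps(ps, pe, t2 - 2_000, t2 + 2_001):
                return False
            if _overlaps(ps, pe, x2 - 2_000, x2 + 2_001):
                return False
        if cls == "antisense":
            # must not be near the anchor's own TSS/TES either
            i = int(np.flatnonzero(gids == anchor_id)[0])
            if _overlaps(s, e, tss[i] - 2_000, tss[i] + 2_001) or \
                    _overlaps(s, e, tes[i] - 2_000, tes[i] + 2_001):
                return False
        return True

    islands = []

    def _far_from_placed(s: int, e: int, strand: str, min_sep: int = 3_000) -> bool:
        # same-strand islands closer than ~2*window+gap would be fused by the
        # island caller, so keep them well apart
        return all(not _overlaps(s - min_sep, e + min_sep, s2, e2)
                   for _, _, s2, e2, strand2, _ in islands if strand2 == strand)

    k = 0
    genes_ix = ann.genes.set_index("gene_id")
    for cls in gene_classes:
        placed = 0
        want = cfg.extragenic_classes.get(cls, 0)
        while placed < want:
            if k >= len(pool):
                raise ValueError(
                    f"could not place {want} well-separated {cls} islands; "
                    "increase n_genes")
            gid = pool[k]; k += 1
            g = genes_ix.loc[gid]
            s, e, strand = _island_anchor(cls, g)
            if s < 0 or not _well_separated(s, e, cls, gid) \
                    or not _far_from_placed(s, e, strand):
                continue
            islands.append((f"{cls}_{placed:02d}", cls, s, e, strand, gid))
            placed += 1
    for i in range(cfg.extragenic_classes.get("lncRNA", 0)):
        r = ann.lncrnas.iloc[i]
        islands.append((f"lncRNA_{i:02d}", "lncRNA", int(r["start"]), int(r["end"]),
                        r["strand"], r["name"]))
    for i in range(cfg.extragenic_classes.get("enhancer", 0)):
        r = ann.enhancers.iloc[i]
        strand = "+" if rng.random() < 0.5 else "-"
        islands.append((f"enhancer_{i:02d}", "enhancer", int(r["start"]),
                        int(r["end"]), strand, r["name"]))
    arena_start = (int(ann.enhancers["end"].max()) if len(ann.enhancers)
                   else chrom_len - 50_000) + 10_000
    for i in range(cfg.extragenic_classes.get("other", 0)):
        s = arena_start + i * 10_000
        strand = "+" if rng.random() < 0.5 else "-"
        islands.append((f"other_{i:02d}", "other", s, s + 1_500, strand, ""))

    read_rows, truth_rows = [], []
    for iid, cls, s, e, strand, linked in islands:
        supports = {}
        for samp in samples:
            n = int(_nb_sample(rng, np.array([cfg.island_mean_reads]),
                               cfg.noise.dispersion)[0])
            supports[samp] = n
            if n:
                starts = rng.integers(s, max(e - READ_LEN, s + 1), size=n)
                for st in starts:
                    read_rows.append((CHROM, int(st), int(st) + READ_LEN, iid, 0,
                                      strand, samp))
        truth_rows.append((iid, CHROM, s, e, strand, cls, linked,
                           *[supports[s_] for s_ in samples]))

    # sparse background on both strands
    for samp in samples:
        for strand in "+-":
            n_bg = rng.poisson(cfg.background_read_rate * chrom_len)
            starts = rng.integers(0, chrom_len - READ_LEN, size=n_bg)
            for st in starts:
                read_rows.append((CHROM, int(st), int(st) + READ_LEN, "bg", 0,
                                  strand, samp))

    reads = pd.DataFrame(read_rows, columns=[
        "chrom", "start", "end", "name", "score", "strand", "sample"])
    reads = reads.sort_values(["chrom", "start", "end", "strand", "sample"],
                              kind="mergesort").reset_index(drop=True)
    truth_df = pd.DataFrame(truth_rows, columns=[
        "island_id", "chrom", "start", "end", "strand", "class", "linked",
        *samples])
    return reads, truth_df


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(cfg: SimConfig, out_dir: str) -> dict[str, str]:
    """Generate the full synthetic dataset and write it as flat text files."""
    os.makedirs(out_dir, exist_ok=True)
    ann = make_annotation(cfg)
    paths = {}

    io.write_bed12(ann.genes, p := os.path.join(out_dir, "annotation.bed12"))
    paths["annotation_bed12"] = p
    io.write_tsv(ann.genes, p := os.path.join(out_dir, "genes.tsv"))
    paths["genes_tsv"] = p
    io.write_tsv(ann.truth, p := os.path.join(out_dir, "gene_truth.tsv"))
    paths["gene_truth"] = p

    wave_tracks, wave_truth = simulate_wave_tracks(cfg, ann)
    for (cond, rep, t), track in wave_tracks.items():
        name = f"wave_{cond}_rep{rep}_t{t}.bedgraph"
        io.write_bedgraph(track, p := os.path.join(out_dir, name))
        paths[name] = p
    io.write_tsv(wave_truth, p := os.path.join(out_dir, "wave_truth.tsv"))
    paths["wave_truth"] = p

    occ_tracks, occ_truth = simulate_occupancy_track(cfg, ann)
    for (cond, rep), track in occ_tracks.items():
        name = f"occupancy_{cond}_rep{rep}.bedgraph"
        io.write_bedgraph(track, p := os.path.join(out_dir, name))
        paths[name] = p
    io.write_tsv(occ_truth, p := os.path.join(out_dir, "occupancy_truth.tsv"))
    paths["occupancy_truth"] = p

    matrix, count_truth, sample_truth = simulate_counts(cfg, ann)
    matrix.to_tsv(p := os.path.join(out_dir, "counts.tsv"))
    paths["counts"] = p
    io.write_tsv(count_truth, p := os.path.join(out_dir, "count_truth.tsv"))
    paths["count_truth"] = p
    io.write_tsv(sample_truth, p := os.path.join(out_dir, "sample_truth.tsv"))
    paths["sample_truth"] = p

    reads, island_truth = simulate_extragenic_reads(cfg, ann)
    io.write_tsv(reads, p := os.path.join(out_dir, "extragenic_reads.tsv"))
    paths["extragenic_reads"] = p
    io.write_tsv(island_truth, p := os.path.join(out_dir, "island_truth.tsv"))
    paths["island_truth"] = p
    return paths
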
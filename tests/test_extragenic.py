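"""Island calling, genic-read exclusion, merging, class annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polkinetics import extragenic as xg
from polkinetics import simulate
from polkinetics.config import SimConfig


def reads_at(positions, strand="+", chrom="c", length=100, sample="s1"):
    return pd.DataFrame({
        "chrom": chrom, "start": list(positions),
        "end": [p + length for p in positions],
        "name": ".", "score": 0, "strand": strand, "sample": sample,
    })


def brute_force_islands(positions, L, window=500, gap=1000, tail_p=0.1):
    """Oracle: explicit window enumeration with the same eligibility rule."""
    lam = len(positions) * window / L
    counts = np.zeros(-(-L // window), int)
    for p in positions:
        counts[p // window] += 1
    k0 = 1
    while stats.poisson.sf(k0 - 1, lam) >= tail_p:
        k0 += 1
    eligible = [i for i, c in enumerate(counts) if c >= k0]
    islands = []
    for i in eligible:
        if islands and (i - islands[-1][-1] - 1) * window <= gap:
            islands[-1].append(i)
        else:
            islands.append([i])
    return [(mem[0] * window, (mem[-1] + 1) * window) for mem in islands]


class TestIntervalUtilities:
    def test_merge_matches_union_find_oracle(self, rng):
        starts = rng.integers(0, 5_000, size=60)
        ends = starts + rng.integers(50, 800, size=60)
        ms, me = xg.merge_intervals(starts, ends)
        # oracle: union-find over pairwise overlaps
        parent = list(range(60))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(60):
            for j in range(i + 1, 60):
                if starts[i] < ends[j] and starts[j] < ends[i]:
                    parent[find(i)] = find(j)
        comps = {}
        for i in range(60):
            comps.setdefault(find(i), []).append(i)
        expected = sorted((min(starts[m] for m in mem), max(ends[m] for m in mem))
                          for mem in comps.values())
        assert sorted(zip(ms, me)) == expected

    def test_merged_intervals_disjoint(self, rng):
        starts = rng.integers(0, 2_000, size=40)
        ends = starts + rng.integers(10, 400, size=40)
        ms, me = xg.merge_intervals(starts, ends)
        assert (ms[1:] >= me[:-1]).all()


class TestExcludeGenicReads:
    GENES = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"], "start": [1_000],
                          "end": [2_000], "strand": ["+"],
                          "biotype": ["protein_coding"]})

    def test_read_inside_gene_removed(self):
        out = xg.exclude_genic_reads(reads_at([1_500]), self.GENES)
        assert len(out) == 0

    def test_read_one_bp_outside_kept(self):
        out = xg.exclude_genic_reads(reads_at([2_000]), self.GENES)
        assert len(out) == 1
        out = xg.exclude_genic_reads(reads_at([800]), self.GENES)  # ends at 900
        assert len(out) == 1

    def test_survivors_equal_overlap_complement(self, rng):
        pos = rng.integers(0, 9_900, size=200)
        reads = reads_at(pos)
        out = xg.exclude_genic_reads(reads, self.GENES)
        expected = [p for p in pos if not (p < 2_000 and p + 100 > 1_000)]
        assert sorted(out["start"]) == sorted(expected)

    def test_opposite_strand_also_removed_by_default(self):
        out = xg.exclude_genic_reads(reads_at([1_500], strand="-"), self.GENES)
        assert len(out) == 0
        out = xg.exclude_genic_reads(reads_at([1_500], strand="-"), self.GENES,
                                     same_strand_only=True)
        assert len(out) == 1


class TestCallIslands:
    SIZES = {"c": 1_000_000}

    def test_no_reads_no_islands(self):
        empty = reads_at([])
        out = xg.call_islands(empty, "+", self.SIZES)
        assert len(out) == 0

    def test_single_dense_window_is_one_island(self):
        pos = [10_250] * 200
        out = xg.call_islands(reads_at(pos), "+", self.SIZES)
        assert len(out) == 1
        assert out.loc[0, "start"] <= 10_250 < out.loc[0, "end"]

    def test_gap_size_merging_behavior(self):
        # two clusters 1500 bp apart (> gap) -> two islands;
        # 1000 bp apart (<= gap) -> one island
        far = [1_000 + i for i in range(60)] + [3_000 + i for i in range(60)]
        near = [1_000 + i for i in range(60)] + [2_500 + i for i in range(60)]
        out_far = xg.call_islands(reads_at(far), "+", self.SIZES)
        out_near = xg.call_islands(reads_at(near), "+", self.SIZES)
        assert len(out_far) == 2 and len(out_near) == 1

    def test_matches_brute_force_enumeration_on_toy_genome(self, rng):
        sizes = {"c": 10_000}
        for _ in range(10):
            pos = rng.integers(0, 9_900, size=120)
            out = xg.call_islands(reads_at(pos), "+", sizes, e_value=1e9)
            expected = brute_force_islands(pos, 10_000)
            got = sorted(zip(out["start"], out["end"]))
            assert got == sorted(expected)

    def test_islands_on_one_strand_never_overlap(self, rng):
        pos = np.concatenate([rng.integers(k, k + 600, size=40)
                              for k in range(0, 50_000, 5_000)])
        out = xg.call_islands(reads_at(pos), "+", self.SIZES)
        s = out.sort_values("start")
        assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_background_island_count_matches_calibration(self):
        """Pure Poisson background: over 50 seeded simulations the mean
        number of called islands stays within 3 SE of the calibrated
        e-value expectation."""
        sizes = {"c": 2_000_000}
        e_value = 5.0
        rng = np.random.default_rng(99)
        counts = []
        for _ in range(50):
            pos = rng.integers(0, sizes["c"] - 100, size=4_000)
            out = xg.call_islands(reads_at(pos), "+", sizes, e_value=e_value)
            counts.append(len(out))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - e_value) <= 3 * max(se, 0.5)


class TestMergeAndFilter:
    def setup_islands(self):
        isl = pd.DataFrame({"chrom": ["c"], "start": [1_000], "end": [2_000],
                            "strand": ["+"]})
        return {"control": isl, "ko": isl.assign(start=1_500, end=2_500)}

    def reads_with_support(self, per_sample):
        frames = []
        for samp, n in per_sample.items():
            frames.append(reads_at(range(1_200, 1_200 + n), sample=samp))
        return pd.concat(frames, ignore_index=True)

    SAMPLES = {"control": ["control_rep1", "control_rep2"],
               "ko": ["ko_rep1", "ko_rep2"]}

    def test_kept_when_all_control_replicates_supported(self):
        reads = self.reads_with_support({"control_rep1": 60, "control_rep2": 55,
                                         "ko_rep1": 10, "ko_rep2": 5})
        out = xg.merge_and_filter(self.setup_islands(), reads, self.SAMPLES)
        assert len(out) == 1
        assert out.loc[0, "start"] == 1_000 and out.loc[0, "end"] == 2_500

    def test_dropped_when_no_condition_fully_supported(self):
        reads = self.reads_with_support({"control_rep1": 60, "control_rep2": 40,
                                         "ko_rep1": 45, "ko_rep2": 30})
        out = xg.merge_and_filter(self.setup_islands(), reads, self.SAMPLES)
        assert len(out) == 0

    def test_merge_equals_brute_force_on_random_sets(self, rng):
        isl = {}
        for cond in ("control", "ko"):
            starts = np.sort(rng.integers(0, 50_000, size=15))
            isl[cond] = pd.DataFrame({
                "chrom": "c", "start": starts,
                "end": starts + rng.integers(300, 3_000, size=15),
                "strand": "+"})
        both = pd.concat(isl.values())
        ms, me = xg.merge_intervals(both["start"], both["end"])
        reads = reads_at(rng.integers(0, 50_000, size=3_000),
                         sample="control_rep1")
        reads = pd.concat([reads, reads.assign(sample="control_rep2")],
                          ignore_index=True)
        out = xg.merge_and_filter(isl, reads, self.SAMPLES, support_floor=0)
        assert list(out["start"]) == list(ms) and list(out["end"]) == list(me)


@pytest.fixture(scope="module")
def ann():
    return simulate.make_annotation(SimConfig(seed=11, n_genes=30))


class TestAnnotateClass:
    def region(self, start, end, strand):
        return pd.Series({"chrom": "chrS", "start": start, "end": end,
                          "strand": strand})

    def test_lncrna_outranks_everything(self, ann):
        lnc = ann.lncrnas.iloc[0]
        cls, link = xg.annotate_class(
            self.region(lnc["start"], lnc["end"], lnc["strand"]),
            ann.genes, ann.lncrnas, ann.enhancers)
        assert cls == "lncRNA" and link == lnc["name"]

    def test_prompt_upstream_antisense(self, ann):
        g = ann.genes[(ann.genes["strand"] == "+")
                      & (ann.genes["biotype"] == "protein_coding")].iloc[1]
        clear = ann.truth.set_index("gene_id")
        gid = g["gene_id"]
        if not clear.loc[gid, "clear_upstream"]:
            g = ann.genes.set_index("gene_id").loc[
                clear[clear["clear_upstream"]
                      & (clear["strand"] == "+")].index[0]].rename(gid)
            g = pd.concat([pd.Series({"gene_id": g.name}), g])
        cls, _ = xg.annotate_class(
            self.region(int(g["start"]) - 1_500, int(g["start"]) - 600, "-"),
            ann.genes, ann.lncrnas, ann.enhancers)
        assert cls == "PROMPT"

    def test_readthrough_past_tes_same_strand(self, ann):
        clear = ann.truth
        ok = clear[~clear["overlaps_other"] & (clear["strand"] == "+")]
        g = ann.genes.set_index("gene_id").loc[ok["gene_id"].iloc[2]]
        cls, _ = xg.annotate_class(
            self.region(int(g["end"]) + 300, int(g["end"]) + 1_200, "+"),
            ann.genes, ann.lncrnas, ann.enhancers)
        assert cls == "readthrough"

    def test_every_region_gets_exactly_one_class(self, ann, rng):
        L = ann.chrom_sizes["chrS"]
        for _ in range(50):
            s = int(rng.integers(0, L - 3_000))
            r = self.region(s, s + int(rng.integers(200, 2_500)),
                            rng.choice(["+", "-"]))
            cls, _ = xg.annotate_class(r, ann.genes, ann.lncrnas, ann.enhancers)
            assert cls in xg.CLASS_PRIORITY

    def test_simulated_truth_recovered_end_to_end(self, small_cfg,
                                                  small_annotation):
        """Detected, merged and filtered islands receive their simulated
        truth class for every well-separated island."""
        reads, truth = simulate.simulate_extragenic_reads(small_cfg,
                                                          small_annotation)
        pc = small_annotation.genes[
            small_annotation.genes["biotype"] == "protein_coding"]
        clean = xg.exclude_genic_reads(reads, pc)
        samples = {c: [f"{c}_rep{r}" for r in (1, 2)]
                   for c in ("control", "ko")}
        isl = {}
        for cond in ("control", "ko"):
            sub = clean[clean["sample"].isin(samples[cond])]
            isl[cond] = pd.concat(
                [xg.call_islands(sub, s, small_annotation.chrom_sizes)
                 for s in "+-"], ignore_index=True)
        merged = xg.merge_and_filter(isl, clean, samples)
        annotated = xg.annotate_regions(merged, small_annotation.genes,
                                        small_annotation.lncrnas,
                                        small_annotation.enhancers)
        matched = 0
        for _, d in annotated.iterrows():
            hit = truth[(truth["strand"] == d["strand"])
                        & (truth["start"] < d["end"])
                        & (truth["end"] > d["start"])]
            assert len(hit) == 1
            assert hit.iloc[0]["class"] == d["class"]
            matched += 1
        # everything except the genic-overlap (antisense) islands survives
        assert matched >= len(truth) - small_cfg.extragenic_classes["antisense"]


class TestReconcilePeaks:
    MERGED = pd.DataFrame({"chrom": ["c"] * 3, "start": [100, 5_000, 9_000],
                           "end": [900, 5_800, 9_700]})

    def test_peak_in_both_replicates_kept(self):
        rep = pd.DataFrame({"chrom": ["c"], "start": [150], "end": [700]})
        out = xg.reconcile_replicate_peaks(self.MERGED.iloc[:1], rep, rep)
        assert len(out) == 1

    def test_peak_missing_from_one_replicate_removed(self):
        rep1 = pd.DataFrame({"chrom": ["c"], "start": [150], "end": [700]})
        rep2 = pd.DataFrame({"chrom": ["c"], "start": [6_000], "end": [6_500]})
        out = xg.reconcile_replicate_peaks(self.MERGED.iloc[:1], rep1, rep2)
        assert len(out) == 0
        lenient = xg.reconcile_replicate_peaks(self.MERGED.iloc[:1], rep1,
                                               rep2, require="either")
        assert len(lenient) == 1

    def test_equals_brute_force_double_overlap_filter(self, rng):
        def peaks(n):
            s = np.sort(rng.integers(0, 40_000, size=n))
            return pd.DataFrame({"chrom": "c", "start": s,
                                 "end": s + rng.integers(100, 900, size=n)})

        merged, r1, r2 = peaks(25), peaks(12), peaks(12)
        out = xg.reconcile_replicate_peaks(merged, r1, r2)
        expected = []
        for _, p in merged.iterrows():
            in1 = ((r1["start"] < p["end"]) & (r1["end"] > p["start"])).any()
            in2 = ((r2["start"] < p["end"]) & (r2["end"] > p["start"])).any()
            if in1 and in2:
                expected.append((p["start"], p["end"]))
        assert list(zip(out["start"], out["end"])) == expected
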
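"""Synthetic-data generator: determinism, truth-table fidelity, moments."""

import numpy as np
import pandas as pd
import pytest

from polkinetics import simulate
from polkinetics.config import NoiseConfig, SimConfig, SizingError


class TestMakeAnnotation:
    def test_empty_config_gives_empty_annotation(self):
        ann = simulate.make_annotation(SimConfig(seed=1, n_genes=0,
                                                 overlap_violations=0,
                                                 upstream_violations=0))
        assert len(ann.genes) == 0 and len(ann.truth) == 0

    def test_fixed_seed_is_byte_identical(self):
        a = simulate.make_annotation(SimConfig(seed=1, n_genes=25))
        b = simulate.make_annotation(SimConfig(seed=1, n_genes=25))
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.chrom_sizes == b.chrom_sizes

    def test_different_seeds_differ(self):
        a = simulate.make_annotation(SimConfig(seed=1, n_genes=25))
        b = simulate.make_annotation(SimConfig(seed=2, n_genes=25))
        assert not a.genes.equals(b.genes)

    def test_covers_three_length_strata(self, small_annotation):
        lengths = (small_annotation.genes["end"]
                   - small_annotation.genes["start"])
        assert (lengths < 30_000).any()
        assert ((lengths >= 30_000) & (lengths < 60_000)).any()
        assert (lengths >= 60_000).any()

    def test_truth_eligibility_matches_pairwise_recheck(self):
        """Oracle: exhaustive pairwise interval checks over all gene pairs."""
        cfg = SimConfig(seed=7, n_genes=50)
        ann = simulate.make_annotation(cfg)
        genes = ann.genes
        truth = ann.truth.set_index("gene_id")
        for _, g in genes.iterrows():
            s, e, strand = int(g["start"]), int(g["end"]), g["strand"]
            us, ue = (s - 2_000, s) if strand == "+" else (e, e + 2_000)
            ovl = up_blocked = False
            for _, h in genes.iterrows():
                if h["gene_id"] == g["gene_id"]:
                    continue
                if s < h["end"] and h["start"] < e:
                    ovl = True
                if us < h["end"] and h["start"] < ue:
                    up_blocked = True
            row = truth.loc[g["gene_id"]]
            assert row["overlaps_other"] == ovl
            assert row["clear_upstream"] == (not up_blocked)
            assert row["eligible_30k"] == ((e - s > 30_000) and not ovl
                                           and not up_blocked)

    def test_contains_planted_violations(self, small_annotation):
        truth = small_annotation.truth
        assert truth["overlaps_other"].any()
        assert (~truth["clear_upstream"]).any()

    def test_too_small_chromosome_raises_sizing_error(self):
        with pytest.raises(SizingError):
            simulate.make_annotation(SimConfig(seed=1, n_genes=40,
                                               chrom_length=100_000))


class TestWaveTracks:
    def test_deterministic_front_at_known_speed(self):
        """Noise-free run at 3.8 kb/min: every long gene's wave reaches
        exactly 38 kb from its TSS at 10 min (half the wave level there)."""
        cfg = SimConfig(seed=5, n_genes=12, deterministic_signal=True,
                        speed_jitter_sd=0.0,
                        wave_speed_by_condition={"control": 3.8},
                        noise=NoiseConfig(background=0.0, wave_mean=10.0,
                                          dispersion=0.0))
        ann = simulate.make_annotation(cfg)
        tracks, truth = simulate.simulate_wave_tracks(cfg, ann)
        t10 = truth[(truth["replicate"] == 1) & (truth["time_min"] == 10)]
        np.testing.assert_allclose(t10["front_bp"], 38_000)
        track = tracks[("control", 1, 10)]
        for _, g in ann.genes.iterrows():
            if g["end"] - g["start"] < 40_000:
                continue
            b0 = int(g["start"]) // 50
            if g["strand"] == "+":
                vals = track.values["chrS"][b0:b0 + (g["end"] - g["start"]) // 50]
            else:
                vals = track.values["chrS"][b0:b0 + (g["end"] - g["start"]) // 50][::-1]
            # wave level well before the front, background well after
            assert vals[700] > 9.9          # 35 kb downstream
            assert vals[820] < 0.1          # 41 kb downstream
            k = 38_000 // 50                # half the wave level at the front
            assert 4.0 < vals[k - 1] + vals[k] < 16.0

    def test_zero_time_point_is_background_only(self):
        cfg = SimConfig(seed=5, n_genes=6, deterministic_signal=True,
                        noise=NoiseConfig(background=0.3, wave_mean=12.0,
                                          dispersion=0.0))
        ann = simulate.make_annotation(cfg)
        tracks, _ = simulate.simulate_wave_tracks(cfg, ann)
        t0 = tracks[("control", 1, 0)]
        np.testing.assert_allclose(t0.values["chrS"], 0.3)

    def test_seed_reproducibility_of_noisy_tracks(self):
        cfg = SimConfig(seed=77, n_genes=8)
        ann = simulate.make_annotation(cfg)
        t1, _ = simulate.simulate_wave_tracks(cfg, ann)
        t2, _ = simulate.simulate_wave_tracks(cfg, ann)
        for k in t1:
            np.testing.assert_array_equal(t1[k].values["chrS"],
                                          t2[k].values["chrS"])

    def test_noisy_bin_means_match_configured_moments(self):
        """Monte-Carlo moment oracle: averaging many replicate simulations,
        per-bin means approach the configured expectations within 3 SE."""
        cfg = SimConfig(seed=3, n_genes=2, gene_length_range=(8_000, 12_000),
                        time_points=(10,), replicates_per_condition=1,
                        wave_speed_by_condition={"control": 0.5},
                        speed_jitter_sd=0.0,
                        noise=NoiseConfig(background=0.5, wave_mean=8.0,
                                          dispersion=0.05))
        ann = simulate.make_annotation(cfg)
        acc = None
        n_sims = 200
        for s in range(n_sims):
            c = SimConfig(**{**cfg.__dict__, "seed": 1_000 + s})
            tr, _ = simulate.simulate_wave_tracks(c, ann)
            v = tr[("control", 1, 10)].values["chrS"]
            acc = v if acc is None else acc + v
        mean = acc / n_sims
        det = SimConfig(**{**cfg.__dict__, "deterministic_signal": True})
        expected = simulate.simulate_wave_tracks(det, ann)[0][
            ("control", 1, 10)].values["chrS"]
        var = expected + 0.05 * expected ** 2
        se = np.sqrt(var / n_sims)
        assert (np.abs(mean - expected) <= 3 * se + 1e-9).mean() > 0.99

    def test_coverage_non_negative(self):
        cfg = SimConfig(seed=13, n_genes=10)
        ann = simulate.make_annotation(cfg)
        tracks, _ = simulate.simulate_wave_tracks(cfg, ann)
        for t in tracks.values():
            assert (t.values["chrS"] >= 0).all()


class TestOccupancy:
    def test_noise_free_tr_equals_truth(self):
        cfg = SimConfig(seed=9, n_genes=10, deterministic_signal=True,
                        noise=NoiseConfig(background=0.0))
        ann = simulate.make_annotation(cfg)
        occ, truth = simulate.simulate_occupancy_track(cfg, ann)
        from polkinetics import pausing
        track = occ[("control", 1)]
        t0 = truth[truth["condition"] == "control"].set_index("gene_id")
        overlapping = set(ann.truth[ann.truth["overlaps_other"]]["gene_id"])
        checked = 0
        for _, g in ann.genes.iterrows():
            if g["biotype"] != "protein_coding" or g["gene_id"] in overlapping:
                continue
            res = pausing.traveling_ratio(track, g)
            if not res.evaluable:
                continue
            assert res.tr == pytest.approx(t0.loc[g["gene_id"], "tr_true"],
                                           rel=1e-9)
            checked += 1
        assert checked >= 5

    def test_ko_trs_decrease_for_affected_genes(self):
        cfg = SimConfig(seed=9, n_genes=20, deterministic_signal=True)
        ann = simulate.make_annotation(cfg)
        _, truth = simulate.simulate_occupancy_track(cfg, ann)
        piv = truth.pivot_table(index="gene_id", columns="condition",
                                values="tr_true")
        aff = truth[truth["condition"] == "ko"].set_index("gene_id")["tr_affected"]
        ratio = piv["control"] / piv["ko"]
        assert np.allclose(ratio[aff], cfg.tr_fold)
        assert np.allclose(ratio[~aff], 1.0)


class TestCounts:
    def test_null_config_has_unit_fold_changes(self):
        cfg = SimConfig(seed=21, n_genes=15, de_fraction=0.0,
                        composition_shift=1.0, deterministic_signal=True,
                        depth_factor_range=(1.0, 1.0))
        ann = simulate.make_annotation(cfg)
        m, truth, _ = simulate.simulate_counts(cfg, ann)
        ctrl = m.counts[["control_rep1", "control_rep2"]].mean(axis=1)
        ko = m.counts[["ko_rep1", "ko_rep2"]].mean(axis=1)
        np.testing.assert_allclose(ko / ctrl, 1.0, atol=0.02)

    def test_flagged_features_at_constructed_fold(self):
        cfg = SimConfig(seed=21, n_genes=30, de_fraction=0.2, de_fold=2.0,
                        composition_shift=1.0, deterministic_signal=True,
                        depth_factor_range=(1.0, 1.0))
        ann = simulate.make_annotation(cfg)
        m, truth, _ = simulate.simulate_counts(cfg, ann)
        lab = truth.set_index("feature_id")["label"]
        ctrl = m.counts[["control_rep1", "control_rep2"]].mean(axis=1)
        ko = m.counts[["ko_rep1", "ko_rep2"]].mean(axis=1)
        fc = ko / ctrl
        assert np.allclose(fc[lab == "up"], 2.0, atol=0.05)
        assert np.allclose(fc[lab == "down"], 0.5, atol=0.05)
        assert np.allclose(fc[lab == "spikein"], 1.0, atol=0.05)

    def test_counts_are_nonnegative_integers(self):
        cfg = SimConfig(seed=2, n_genes=10)
        ann = simulate.make_annotation(cfg)
        m, _, _ = simulate.simulate_counts(cfg, ann)
        arr = m.counts.to_numpy()
        assert (arr >= 0).all() and np.issubdtype(arr.dtype, np.integer)


class TestExtragenicReads:
    def test_zero_islands_only_background(self):
        cfg = SimConfig(seed=4, n_genes=15,
                        extragenic_classes={k: 0 for k in
                                            ["lncRNA", "enhancer", "antisense",
                                             "PROMPT", "readthrough",
                                             "promoter_convergent", "other"]})
        ann = simulate.make_annotation(cfg)
        reads, truth = simulate.simulate_extragenic_reads(cfg, ann)
        assert len(truth) == 0
        assert (reads["name"] == "bg").all()

    def test_prompts_upstream_antisense_of_tss(self, small_cfg,
                                               small_annotation):
        reads, truth = simulate.simulate_extragenic_reads(small_cfg,
                                                          small_annotation)
        genes = small_annotation.genes.set_index("gene_id")
        prompts = truth[truth["class"] == "PROMPT"]
        assert len(prompts) == small_cfg.extragenic_classes["PROMPT"]
        for _, p in prompts.iterrows():
            g = genes.loc[p["linked"]]
            assert p["strand"] != g["strand"]
            if g["strand"] == "+":
                assert g["start"] - 2_000 <= p["start"] < p["end"] <= g["start"]
            else:
                assert g["end"] <= p["start"] < p["end"] <= g["end"] + 2_000

    def test_read_support_recorded_per_sample(self, small_cfg,
                                              small_annotation):
        reads, truth = simulate.simulate_extragenic_reads(small_cfg,
                                                          small_annotation)
        samples = [c for c in truth.columns if "_rep" in c]
        row = truth.iloc[0]
        for s in samples:
            n = len(reads[(reads["name"] == row["island_id"])
                          & (reads["sample"] == s)])
            assert n == row[s]

    def test_fixed_seed_reproducible(self, small_cfg, small_annotation):
        r1, t1 = simulate.simulate_extragenic_reads(small_cfg, small_annotation)
        r2, t2 = simulate.simulate_extragenic_reads(small_cfg, small_annotation)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(t1, t2)


class TestDatasetWriter:
    def test_write_dataset_round_trips_key_tables(self, tmp_path):
        cfg = SimConfig(seed=6, n_genes=30)
        paths = simulate.write_dataset(cfg, str(tmp_path))
        from polkinetics import io
        genes = io.read_tsv(paths["genes_tsv"])
        bed = io.read_bed12(paths["annotation_bed12"])
        assert len(genes) == len(bed)
        assert (genes["start"].to_numpy() == bed["start"].to_numpy()).all()
        counts = pd.read_csv(paths["counts"], sep="\t")
        assert "spikein" in counts.columns
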
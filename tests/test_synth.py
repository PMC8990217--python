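"""Synthetic-data generator: determinism, planted truth, file round-trips."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import cagecraft as cg
from cagecraft import io


class TestLandscape:
    def test_repeat_coverage_close_to_target(self, sim_config, landscape):
        genome = sum(sim_config.chrom_lengths.values())
        df = landscape.repeats.df
        for family, spec in sim_config.repeat_families.items():
            tiles = df[(df["family"] == family) & df["name"].str.contains("tile")]
            realized = (tiles["end"] - tiles["start"]).sum() / genome
            assert realized == pytest.approx(spec["coverage"], rel=0.10)

    def test_planted_fraction_within_three_se(self, sim_config, landscape):
        n = sim_config.n_enhancers
        p = sim_config.repeat_families["ERVL-MaLR"]["planted_prob"]
        planted = sum(
            1 for e in landscape.truth.enhancers if "ERVL-MaLR" in e["planted_repeats"]
        )
        se = np.sqrt(p * (1 - p) / n)
        assert abs(planted / n - p) < 3 * se

    def test_features_respect_separation_and_bounds(self, sim_config, landscape):
        by_chrom = {}
        for p in landscape.truth.promoters:
            by_chrom.setdefault(p["chrom"], []).append(p["pos"])
        for e in landscape.truth.enhancers:
            by_chrom.setdefault(e["chrom"], []).append(e["center"])
        for chrom, centers in by_chrom.items():
            centers = sorted(centers)
            assert min(np.diff(centers)) >= sim_config.feature_min_separation
            assert centers[0] >= sim_config.chrom_margin
            assert centers[-1] <= sim_config.chrom_lengths[chrom] - sim_config.chrom_margin

    def test_same_seed_reproduces_landscape(self, sim_config, landscape):
        again = cg.simulate_regulatory_landscape(sim_config)
        assert again.truth.enhancers == landscape.truth.enhancers
        pd.testing.assert_frame_equal(again.repeats.df, landscape.repeats.df)


class TestCageAtac:
    def test_balanced_enhancer_tags(self, landscape, cage_data):
        """>=95% of planted enhancers have |D| < 0.8 at default depth."""
        pooled = cg.pool_tracks(cage_data.tracks)
        ok = 0
        for e in landscape.truth.enhancers:
            span = pooled[
                (pooled["chrom"] == e["chrom"])
                & (pooled["pos"] >= e["start"])
                & (pooled["pos"] < e["end"])
            ]
            f = span.loc[span["strand"] == "+", "count"].sum()
            r = span.loc[span["strand"] == "-", "count"].sum()
            if f + r > 0 and abs(cg.directionality(f, r)) < 0.8:
                ok += 1
        assert ok / len(landscape.truth.enhancers) >= 0.95

    def test_null_fold_change_makes_conditions_exchangeable(self):
        cfg = cg.SimConfig(master_seed=5, cage_fold_change=1.0, atac_fold_change=1.0)
        land = cg.simulate_regulatory_landscape(cfg)
        cage = cg.simulate_cage_atac(cfg, land)
        cm = cage.atac_counts
        labels = cg.condition_specific_peaks(cm, cage.groups, levels=("control", "activated"))
        assert (labels["label"] != "ns").sum() <= 0.05 * cm.n_features

    def test_total_tag_moment_check(self, sim_config, landscape, cage_data):
        """Control-library tag totals match the sum of feature + background rates."""
        truth = landscape.truth
        expected = (
            sim_config.n_promoters * sim_config.promoter_tag_mean
            + sim_config.n_enhancers * 2 * sim_config.enhancer_side_tag_mean
            + 2 * sim_config.background_rate_per_bp * sum(sim_config.chrom_lengths.values())
        )
        ctrl_totals = [
            t.total_tags for t in cage_data.tracks if cage_data.groups[t.library_id] == "control"
        ]
        sd_one = np.sqrt(
            sim_config.n_promoters
            * (sim_config.promoter_tag_mean + sim_config.tag_dispersion * sim_config.promoter_tag_mean**2)
            + sim_config.n_enhancers
            * 2
            * (sim_config.enhancer_side_tag_mean + sim_config.tag_dispersion * sim_config.enhancer_side_tag_mean**2)
        )
        se = sd_one / np.sqrt(len(ctrl_totals))
        assert abs(np.mean(ctrl_totals) - expected) < 3 * se

    def test_atac_counts_reflect_closed_features_in_control(self, sim_config, landscape, cage_data):
        cm = cage_data.atac_counts
        act_ids = {e["id"] for e in landscape.truth.enhancers if e["activated"]} | {
            p["gene"] for p in landscape.truth.promoters if p["activated"]
        }
        ctrl_cols = [l for l in cm.counts.columns if cage_data.groups[l] == "control"]
        act_rows = cm.counts.loc[cm.counts.index.isin(act_ids), ctrl_cols]
        open_rows = cm.counts.loc[~cm.counts.index.isin(act_ids), ctrl_cols]
        assert act_rows.mean().mean() < open_rows.mean().mean() / 2


class TestStrtSim:
    def test_depth_factor_drives_spike_totals(self):
        cfg = cg.SimConfig(master_seed=8, sc_depth_sigma=0.0)
        sc, _ = cg.simulate_strt(cfg)
        totals = sc.spike_totals()
        assert totals.max() - totals.min() == 0  # no depth spread, equal totals

    def test_zero_planted_genes_are_exchangeable(self):
        cfg = cg.SimConfig(master_seed=9, sc_n_de_genes=0)
        sc, de_map = cg.simulate_strt(cfg)
        assert de_map == {}
        norm = cg.spikein_normalize(sc, nresamp=100, seed=1)
        res = cg.samseq_wilcoxon(norm, sc.groups, nperms=300, seed=2)
        assert (res["direction"] != "ns").sum() <= 5

    def test_same_seed_identical_matrices(self):
        cfg = cg.SimConfig(master_seed=10)
        a, de_a = cg.simulate_strt(cfg)
        b, de_b = cg.simulate_strt(cfg)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.spikes, b.spikes)
        assert de_a == de_b


@pytest.fixture(scope="module")
def outdir(tmp_path_factory):
    cfg = cg.SimConfig(
        master_seed=12,
        chrom_lengths={"chr1": 200_000, "chr2": 200_000},
        n_promoters=30,
        n_enhancers=20,
        sc_n_genes=200,
        sc_n_de_genes=10,
    )
    out = tmp_path_factory.mktemp("emit")
    cg.synth.emit(cfg, out / "a")
    cg.synth.emit(cfg, out / "b")
    return out


class TestEmitRoundTrip:
    def test_emission_is_byte_identical_across_runs(self, outdir):
        a, b = outdir / "a", outdir / "b"
        names = sorted(p.name for p in a.iterdir())
        assert names == sorted(p.name for p in b.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
        assert mismatch == [] and errors == []

    def test_files_round_trip_through_readers(self, outdir):
        a = outdir / "a"
        sizes = io.read_chrom_sizes(a / "genome.chrom.sizes")
        assert sizes == {"chr1": 200_000, "chr2": 200_000}
        ends = io.read_bed(a / "five_prime_ends.bed")
        assert len(ends) == 30
        for iv in ends:
            sizes_ok = iv.end <= sizes[iv.chrom]
            assert sizes_ok and iv.strand in "+-" and iv.name.startswith("gene")
        track = cg.TagTrack.from_ctss(a / "ctss_ctrl1.tsv")
        assert track.total_tags > 0
        rt = outdir / "ctss_rt.tsv"
        io.write_ctss(track.tags, rt)
        assert (a / "ctss_ctrl1.tsv").read_bytes() == rt.read_bytes()
        counts = io.read_counts_tsv(a / "atac_counts.tsv")
        assert counts.shape == (50, 8)
        truth = cg.GroundTruth.from_json(a / "ground_truth.json")
        assert len(truth.enhancers) == 20 and len(truth.sc_de_genes) == 10
        cfg = cg.SimConfig.from_yaml(a / "config.yaml")
        assert cfg.master_seed == 12

    def test_truth_consistent_with_emitted_repeats(self, outdir):
        a = outdir / "a"
        truth = cg.GroundTruth.from_json(a / "ground_truth.json")
        rep = cg.RepeatAnnotation.from_bed(a / "repeats.bed")
        planted = rep.df[rep.df["name"].str.contains("under")]
        by_enh = {n.split("under_")[1] for n in planted["name"]}
        truth_planted = {e["id"] for e in truth.enhancers if e["planted_repeats"]}
        assert by_enh == truth_planted
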
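"""The synthetic generator's statistical structure and determinism."""

import numpy as np
import pandas as pd
import pytest

from ste3c.config import DomainSpec, PlantedLoop, RatioComponent, SimulationConfig
from ste3c.embryo import categorize
from ste3c.fragments import digest, find_motif_positions
from ste3c.simulate import (
    expected_background,
    simulate_captures,
    simulate_embryos,
    simulate_locus,
    simulate_ratio_replicates,
    simulate_reference_pairs,
    simulate_tracks,
)


def small_config(**kw):
    defaults = dict(
        locus_length=50_000,
        viewpoint_position=10_000,
        planted_loops=[PlantedLoop(40_000, 5.0)],
        n_fragments=10,
        insulator_sites=[],
        domain_spec={"H3K9me3": [DomainSpec(0, 25_000, 10.0, "enriched"),
                                 DomainSpec(25_000, 50_000, 1.0, "depleted")]},
        seed=7,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestLocus:
    def test_viewpoint_and_target_on_distinct_fragments(self):
        cfg = small_config()
        seq, truth = simulate_locus(cfg)
        assert len(truth["motif_positions"]) >= 3
        assert truth["viewpoint"]["fragment_id"] != truth["loops"][0]["fragment_id"]

    def test_deterministic_under_fixed_seed(self):
        cfg = small_config()
        s1, t1 = simulate_locus(cfg)
        s2, t2 = simulate_locus(cfg)
        assert s1 == s2 and t1 == t2

    def test_truth_motif_count_matches_naive_scan(self):
        cfg = small_config()
        seq, truth = simulate_locus(cfg)
        assert find_motif_positions(seq, cfg.motif) == truth["motif_positions"]

    def test_target_too_close_to_viewpoint_raises_sizing_error(self):
        cfg = small_config(planted_loops=[PlantedLoop(10_003, 5.0)])
        with pytest.raises(ValueError, match="separate"):
            simulate_locus(cfg)

    def test_truth_fragments_consistent_with_digestion(self):
        cfg = small_config()
        seq, truth = simulate_locus(cfg)
        frag_ids = {f.id for f in digest(seq, cfg.motif, cfg.cut_offset, cfg.chrom)}
        assert truth["viewpoint"]["fragment_id"] in frag_ids
        assert all(l["fragment_id"] in frag_ids for l in truth["loops"])


class TestCaptures:
    def test_noiseless_power_law_halves_over_doubling(self):
        cfg = small_config(replicate_noise_sd=0.0, background_scale=100.0,
                           decay_exponent=-1.0, detection_floor=0.0)
        rng = np.random.default_rng(0)
        ratios, _ = simulate_ratio_replicates(
            np.array([50_000.0, 100_000.0]), np.ones(2), cfg, rng, n_replicates=1)
        assert ratios[1, 0] / ratios[0, 0] == pytest.approx(0.5)

    def test_noiseless_enrichment_is_exact_fold(self):
        cfg = small_config(replicate_noise_sd=0.0, detection_floor=0.0)
        rng = np.random.default_rng(0)
        ratios, _ = simulate_ratio_replicates(
            np.array([100_000.0, 100_000.0]), np.array([1.0, 10.0]), cfg, rng, 1)
        assert ratios[1, 0] / ratios[0, 0] == pytest.approx(10.0)

    def test_noiseless_background_reproduces_power_law_above_floor(self):
        cfg = small_config(replicate_noise_sd=0.0, planted_loops=[])
        seq, truth = simulate_locus(cfg)
        frags = digest(seq, cfg.motif, cfg.cut_offset, cfg.chrom)
        caps = simulate_captures(cfg, frags)
        vp = next(f for f in frags if f.id == truth["viewpoint"]["fragment_id"])
        by_id = {f.id: f for f in frags}
        for tgt, grp in caps.groupby("target_id"):
            d = abs(by_id[tgt].center - vp.center)
            expected = expected_background(cfg, d)
            got = (grp["pcr_e"] / grp["pcr_c"]).to_numpy()
            if expected >= cfg.detection_floor:
                assert np.allclose(got, expected)
                assert not grp["censored"].any()

    def test_replicate_log_mean_matches_generative_mean(self):
        cfg = small_config(replicate_noise_sd=0.2)
        rng = np.random.default_rng(5)
        n = 200
        ratios, cens = simulate_ratio_replicates(
            np.array([50_000.0]), np.ones(1), cfg, rng, n_replicates=n)
        assert not cens.any()
        logs = np.log(ratios[0])
        se = 0.2 / np.sqrt(n)
        assert abs(logs.mean() - np.log(expected_background(cfg, 50_000.0))) < 3 * se

    def test_floor_values_reported_censored_not_dropped(self):
        cfg = small_config(detection_floor=1_000.0)  # floor above every mu(d)
        seq, truth = simulate_locus(cfg)
        frags = digest(seq, cfg.motif, cfg.cut_offset, cfg.chrom)
        caps = simulate_captures(cfg, frags)
        assert caps["censored"].all()
        assert np.allclose(caps["pcr_e"] / caps["pcr_c"], 1_000.0)

    def test_missing_viewpoint_fragment_rejected(self):
        cfg = small_config()
        seq, _ = simulate_locus(cfg)
        frags = [f for f in digest(seq, cfg.motif, cfg.cut_offset, cfg.chrom)
                 if not f.contains(cfg.viewpoint_position)]
        with pytest.raises(ValueError, match="viewpoint"):
            simulate_captures(cfg, frags)

    def test_same_seed_reproduces_capture_table(self):
        cfg = small_config()
        seq, _ = simulate_locus(cfg)
        frags = digest(seq, cfg.motif, cfg.cut_offset, cfg.chrom)
        pd.testing.assert_frame_equal(simulate_captures(cfg, frags),
                                      simulate_captures(cfg, frags))

    def test_reference_pairs_in_requested_range(self):
        cfg = small_config()
        pairs = simulate_reference_pairs(cfg, n_pairs=100, d_min=2_000, d_max=50_000)
        assert pairs["distance_bp"].between(2_000, 50_000).all()


class TestTracks:
    def test_zero_noise_gives_step_function_at_boundary_bin(self):
        cfg = small_config(track_noise_sd=0.0)
        track = simulate_tracks(cfg, 500)["H3K9me3"]
        assert set(np.unique(track.values)) == {1.0, 10.0}
        # step occurs exactly at the bin containing the domain boundary
        step_bin = int(np.argmax(np.diff(track.values != 10.0)))
        assert step_bin == 25_000 // 500 - 1

    def test_same_seed_identical_tracks(self):
        cfg = small_config()
        t1 = simulate_tracks(cfg, 500)["H3K9me3"]
        t2 = simulate_tracks(cfg, 500)["H3K9me3"]
        assert np.array_equal(t1.values, t2.values)

    def test_bin_mean_matches_domain_level(self):
        cfg = small_config(locus_length=100_000, viewpoint_position=50_000,
                           planted_loops=[],
                           domain_spec={"m": [DomainSpec(0, 100_000, 10.0, "enriched")]},
                           track_noise_sd=1.0)
        track = simulate_tracks(cfg, 10)["m"]  # 10_000 bins
        se = 1.0 / np.sqrt(track.n_bins)
        assert abs(track.values.mean() - 10.0) < 3 * se

    def test_oversized_bin_rejected(self):
        with pytest.raises(ValueError):
            simulate_tracks(small_config(), 60_000)

    def test_values_never_negative(self):
        cfg = small_config(track_noise_sd=50.0)
        assert (simulate_tracks(cfg, 500)["H3K9me3"].values >= 0).all()


class TestEmbryos:
    def test_point_mass_at_unity_scores_all_no_block(self):
        cfg = small_config(construct_spec={"spacer": [RatioComponent(1.0, 1.0, 0.0)]})
        df = simulate_embryos(cfg, "spacer", 50)
        cats = (df["h_level"] / df["n_level"]).map(categorize)
        assert (cats == "no-block").all()

    def test_point_mass_at_six_scores_all_strong(self):
        cfg = small_config(construct_spec={"ins": [RatioComponent(1.0, 6.0, 0.0)]})
        df = simulate_embryos(cfg, "ins", 50)
        cats = (df["h_level"] / df["n_level"]).map(categorize)
        assert (cats == "strong").all()

    def test_mixture_category_frequencies_binomial(self):
        cfg = small_config(construct_spec={
            "mix": [RatioComponent(0.5, 1.0, 0.0), RatioComponent(0.5, 6.0, 0.0)]})
        n = 2_000
        df = simulate_embryos(cfg, "mix", n)
        cats = (df["h_level"] / df["n_level"]).map(categorize)
        se = np.sqrt(0.25 / n)
        for cat, expected in [("no-block", 0.5), ("weak", 0.0), ("medium", 0.0), ("strong", 0.5)]:
            assert abs((cats == cat).mean() - expected) <= 3 * se

    def test_unknown_construct_rejected(self):
        with pytest.raises(KeyError):
            simulate_embryos(small_config(), "nonesuch", 10)

    def test_n_levels_positive_and_lines_assigned(self):
        df = simulate_embryos(small_config(), "SF1", 30)
        assert (df["n_level"] > 0).all()
        assert df["line_id"].nunique() == 3


class TestConfigValidation:
    def test_viewpoint_outside_locus_rejected(self):
        with pytest.raises(ValueError):
            small_config(viewpoint_position=60_000)

    def test_loop_outside_locus_rejected(self):
        with pytest.raises(ValueError):
            small_config(planted_loops=[PlantedLoop(60_000, 5.0)])

    def test_sub_unity_enrichment_rejected(self):
        with pytest.raises(ValueError):
            PlantedLoop(10_000, 0.5)

    def test_untiled_domains_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            small_config(domain_spec={"m": [DomainSpec(0, 20_000, 10.0, "enriched")]})

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config()
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg
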
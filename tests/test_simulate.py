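"""Synthetic chip-image generator: growth law, drug deaths, rendering contracts."""

import numpy as np
import pandas as pd
import pytest

import chipstain as cs
from chipstain.config import ConfigurationError
from chipstain.imagecore import Channel
from chipstain.longitudinal import postprocess
from chipstain.imagecore import max_project
from chipstain.simulate import (
    CellPopulation,
    assign_splits,
    four_pl_viability,
    render_channels,
    render_tiles,
    render_zstack,
    true_viable_area,
)


def empty_population(chip_id="empty", day=0):
    cells = pd.DataFrame(
        {"x": [], "y": [], "radius": [], "live": [], "aggregate_id": []}
    )
    return CellPopulation(cells=cells, chip_id=chip_id, day=day)


class TestGeneratePopulation:
    def test_initial_condition(self, small_config):
        pop = cs.generate_population(small_config, day=0)
        assert pop.n_cells == small_config.seeding_density
        assert pop.live_fraction == 1.0
        assert pop.mean_radius() == pytest.approx(small_config.base_radius_px, rel=0.2)

    def test_growth_law_closed_form(self, small_config):
        d0 = cs.generate_population(small_config, day=0)
        d3 = cs.generate_population(small_config, day=3)
        ratio = d3.mean_radius() / d0.mean_radius()
        assert ratio == pytest.approx(small_config.growth_rate**3, rel=1e-9)

    def test_no_growth_identity(self, small_config):
        cfg = cs.SimConfig(**{**small_config.to_dict(), "growth_rate": 1.0})
        r0 = cs.generate_population(cfg, day=0).cells["radius"]
        r5 = cs.generate_population(cfg, day=5).cells["radius"]
        assert np.allclose(np.sort(r0), np.sort(r5))

    def test_mean_radius_monotone_in_day(self, small_config):
        radii = [cs.generate_population(small_config, day=d).mean_radius() for d in range(5)]
        assert all(a < b for a, b in zip(radii, radii[1:]))

    def test_invalid_density_rejected(self):
        with pytest.raises(ConfigurationError):
            cs.SimConfig(seeding_density=0)

    def test_negative_day_rejected(self, small_config):
        with pytest.raises(ConfigurationError):
            cs.generate_population(small_config, day=-1)

    def test_deterministic_given_seed(self, small_config):
        a = cs.generate_population(small_config, day=2, chip_id="c1")
        b = cs.generate_population(small_config, day=2, chip_id="c1")
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_centers_inside_channel(self, small_config):
        pop = cs.generate_population(small_config, day=8)
        assert pop.cells["x"].between(0, small_config.channel_width_px).all()
        assert pop.cells["y"].between(0, small_config.channel_height_px).all()


class TestApplyDrug:
    def test_zero_dose_no_deaths(self, small_config):
        pop = cs.generate_population(small_config, day=0)
        out = cs.apply_drug(pop, 0.0, small_config, seed=1)
        assert out.live_fraction == 1.0

    def test_ic50_live_fraction_matches_binomial(self):
        cfg = cs.SimConfig(
            channel_width_px=2000, channel_height_px=600, seeding_density=10_000,
            baseline_death_fraction=0.0, drug_bottom=0.0, drug_top=1.0,
            drug_ic50=1.0, drug_hill=1.5, seed=3,
        )
        pop = cs.generate_population(cfg, day=0)
        out = cs.apply_drug(pop, cfg.drug_ic50, cfg, seed=9)
        expected = (cfg.drug_bottom + cfg.drug_top) / 2
        sd = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(out.live_fraction - expected) < 3 * sd

    def test_saturating_dose_approaches_bottom(self):
        cfg = cs.SimConfig(seeding_density=5000, baseline_death_fraction=0.0,
                           drug_bottom=0.1, channel_width_px=2000, channel_height_px=600)
        pop = cs.generate_population(cfg, day=0)
        out = cs.apply_drug(pop, 1e6, cfg, seed=2)
        assert out.live_fraction == pytest.approx(0.1, abs=0.02)

    def test_negative_dose_rejected(self, small_config):
        pop = cs.generate_population(small_config, day=0)
        with pytest.raises(ConfigurationError):
            cs.apply_drug(pop, -1.0, small_config, seed=0)

    def test_deaths_never_reverse(self, small_config):
        pop = cs.generate_population(small_config, day=0)
        first = cs.apply_drug(pop, 10.0, small_config, seed=4)
        second = cs.apply_drug(first, 0.5, small_config, seed=5)
        was_dead = ~first.cells["live"].to_numpy()
        assert (~second.cells["live"].to_numpy()[was_dead]).all()

    def test_expected_live_fraction_monotone_in_dose(self, small_config):
        doses = [0.0, 0.01, 0.1, 1.0, 10.0, 100.0]
        v = [four_pl_viability(d, small_config) for d in doses]
        assert all(a >= b for a, b in zip(v, v[1:]))


class TestRenderChannels:
    def test_empty_population_background_only(self, small_config):
        bf, dapi, tritc = render_channels(empty_population(), small_config)
        # flat background carries no stain foreground
        assert dapi.pixels.max() <= 0.03 * small_config.max_value
        assert not postprocess(dapi, Channel.DAPI).qc_ok
        assert postprocess(dapi, Channel.DAPI).sum_area == 0

    def test_live_cells_carry_no_tritc(self):
        cfg = cs.SimConfig(channel_width_px=96, channel_height_px=64, seeding_density=1,
                           baseline_death_fraction=0.0, noise_sd=100.0, seed=5)
        pop = cs.generate_population(cfg, day=0)
        assert pop.live_fraction == 1.0
        _, _, tritc = render_channels(pop, cfg)
        noise_floor = 0.02 * cfg.max_value + 5 * cfg.noise_sd
        assert (tritc.pixels.astype(float) <= noise_floor).all()

    def test_dapi_present_at_every_cell(self, small_config):
        pop = cs.generate_population(small_config, day=0)
        _, dapi, _ = render_channels(pop, small_config)
        px = dapi.pixels.astype(float)
        for _, cell in pop.cells.iterrows():
            assert px[int(round(cell.y)), int(round(cell.x))] > 0.3 * small_config.max_value

    def test_unevenness_moves_fluorescence_not_bf(self, small_config):
        cfg_flat = small_config
        cfg_uneven = cs.SimConfig(
            **{**small_config.to_dict(), "stain_unevenness_amplitude": 0.5}
        )
        pop = cs.generate_population(cfg_flat, day=0)
        bf0, dapi0, _ = render_channels(pop, cfg_flat)
        bf1, dapi1, _ = render_channels(pop, cfg_uneven)
        assert np.array_equal(bf0.pixels, bf1.pixels)
        # the multiplicative stain field varies smoothly across the chip:
        # the per-pixel ratio on bright stain pixels spans a wide range
        strong = dapi0.pixels.astype(float) > 0.3 * small_config.max_value
        ratio = dapi1.pixels[strong].astype(float) / dapi0.pixels[strong].astype(float)
        assert not np.array_equal(dapi0.pixels, dapi1.pixels)
        assert ratio.max() - ratio.min() > 0.2

    def test_render_deterministic(self, small_config):
        pop = cs.generate_population(small_config, day=1)
        imgs_a = render_channels(pop, small_config)
        imgs_b = render_channels(pop, small_config)
        for a, b in zip(imgs_a, imgs_b):
            assert np.array_equal(a.pixels, b.pixels)

    def test_out_of_bounds_population_rejected(self, small_config):
        cells = pd.DataFrame(
            {"x": [1e4], "y": [10.0], "radius": [4.0], "live": [True], "aggregate_id": [-1]}
        )
        pop = CellPopulation(cells=cells)
        with pytest.raises(ValueError):
            render_channels(pop, small_config)

    def test_tiles_cover_chip_with_overlap(self, small_config):
        pop = cs.generate_population(small_config, day=0)
        tiles = render_tiles(pop, small_config, Channel.DAPI, n_tiles=2, overlap_fraction=0.1)
        assert len(tiles) == 2
        assert tiles[0].shape[0] == small_config.channel_height_px
        total = sum(t.shape[1] for t in tiles)
        assert total >= small_config.channel_width_px  # overlap ⇒ union covers

    def test_zstack_projection_recovers_in_focus_render(self, small_config):
        pop = cs.generate_population(small_config, day=0)
        stack = render_zstack(pop, small_config, Channel.DAPI, n_slices=7)
        _, dapi, _ = render_channels(pop, small_config)
        proj = max_project(stack)
        # projection dominated by the in-focus slice; defocused light only adds
        assert (proj.pixels >= dapi.pixels.astype(np.float64) - 1e-9).all()
        bright = dapi.pixels.astype(float) > 0.3 * small_config.max_value
        excess = proj.pixels[bright] / dapi.pixels[bright].astype(float) - 1.0
        # blob edges gain a little defocused light; the bulk is unchanged
        assert np.median(excess) < 0.02
        assert np.percentile(excess, 95) < 0.10

    def test_viable_area_conservation_against_masks(self):
        """Rendered DAPI-minus-TRITC area tracks the ground truth within 5%.

        Checked at the day-8 endpoint (zero noise, zero unevenness) with
        substantial drug-induced death, the regime the viability metrics
        are used in.
        """
        for seed in (0, 1, 2):
            cfg = cs.SimConfig(
                channel_width_px=256, channel_height_px=192, seeding_density=30,
                noise_sd=0.0, stain_unevenness_amplitude=0.0, seed=seed,
            )
            pop = cs.generate_population(cfg, day=8)
            pop = cs.apply_drug(pop, cfg.drug_ic50, cfg, seed=seed)
            _, dapi, tritc = render_channels(pop, cfg)
            feats = cs.chip_features(
                dapi, tritc,
                params=cs.segment.SegmentationParams(smooth_sigma_px=0.5),
            )
            truth = true_viable_area(pop, cfg)
            assert feats.viable_area == pytest.approx(
                truth["true_viable_area_px"], rel=0.05
            )


class TestGenerateDataset:
    def test_split_ratio_7_2_1(self):
        splits = assign_splits(10)
        assert splits.count("train") == 7
        assert splits.count("val") == 2
        assert splits.count("test") == 1

    def test_split_rejects_small_runs(self):
        with pytest.raises(ConfigurationError):
            assign_splits(9)

    def test_manifest_bookkeeping_and_determinism(self, tmp_path, small_config):
        cfg = cs.SimConfig(**{**small_config.to_dict(), "channel_width_px": 96,
                              "channel_height_px": 64, "seeding_density": 10})
        days, doses = [0, 8], [0.0, 1.0]
        m1 = cs.generate_dataset(cfg, 10, days, doses, tmp_path / "a")
        m2 = cs.generate_dataset(cfg, 10, days, doses, tmp_path / "b")
        assert len(m1) == 10 * len(days)
        # no chip in two splits
        per_chip = m1.groupby("chip_id")["split"].nunique()
        assert (per_chip == 1).all()
        # byte-identical outputs at fixed seed
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == (
            tmp_path / "b" / "manifest.csv"
        ).read_bytes()
        rel = m1.iloc[0]["dapi_path"]
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_truth_table_written(self, tmp_path, small_config):
        cfg = cs.SimConfig(**{**small_config.to_dict(), "channel_width_px": 96,
                              "channel_height_px": 64, "seeding_density": 10})
        cs.generate_dataset(cfg, 10, [8], [0.0, 10.0], tmp_path)
        truth = pd.read_csv(tmp_path / "truth.csv")
        assert len(truth) == 10
        assert (truth["true_viable_area_px"] <= truth["true_total_area_px"]).all()
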
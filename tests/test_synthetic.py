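"""Forward-model generators: known ground truth, determinism, validation."""

import math

import numpy as np
import pandas as pd
import pytest

from spiscreen.synthetic import (
    CapacityError,
    Nucleus,
    PlacementError,
    ScreenSimConfig,
    StackSimConfig,
    generate_counts,
    generate_screen,
    generate_stack,
    render_plate_image,
)

from conftest import brute_force_sphere_count


class TestGenerateScreen:
    def test_noiseless_null_gives_exact_baseline(self, small_noiseless_config):
        _, tables, _ = generate_screen(small_noiseless_config)
        for tbl in tables.values():
            assert (tbl["size"] == small_noiseless_config.baseline_size).all()

    def test_planted_lgr_one_attenuates_to_37_percent(self, small_noiseless_config):
        import dataclasses

        cfg = dataclasses.replace(small_noiseless_config, hit_lgr={"strain-0003": 1.0})
        _, tables, _ = generate_screen(cfg)
        exp = tables[cfg.experimental]
        hit_sizes = exp.loc[exp["strain"] == "strain-0003", "size"]
        assert np.allclose(hit_sizes, math.exp(-1.0) * cfg.baseline_size)
        # 0.3679 x baseline, i.e. ~37 % of an unattenuated control colony
        assert hit_sizes.iloc[0] / cfg.baseline_size == pytest.approx(0.3679, abs=1e-4)
        ctrl = tables[cfg.controls[0]]
        assert (ctrl.loc[ctrl["strain"] == "strain-0003", "size"] == cfg.baseline_size).all()

    def test_replicates_form_contiguous_square_blocks(self, small_noiseless_config):
        layout, _, _ = generate_screen(small_noiseless_config)
        b = small_noiseless_config.block_side
        for _, grp in layout.groupby("strain"):
            assert len(grp) == small_noiseless_config.replicates_per_strain
            assert grp["plate"].nunique() == 1
            assert grp["row"].max() - grp["row"].min() == b - 1
            assert grp["col"].max() - grp["col"].min() == b - 1

    def test_identical_layout_across_plasmids(self, planted_screen):
        _, _, tables, _ = planted_screen
        ref = None
        for tbl in tables.values():
            cur = tbl[["plate", "row", "col", "strain"]]
            if ref is None:
                ref = cur
            else:
                pd.testing.assert_frame_equal(ref, cur)

    def test_seed_determinism_bit_identical(self):
        cfg = ScreenSimConfig(n_strains=96, replicates_per_strain=4, seed=42)
        _, t1, _ = generate_screen(cfg)
        _, t2, _ = generate_screen(cfg)
        for p in cfg.plasmids:
            assert (t1[p]["size"].to_numpy() == t2[p]["size"].to_numpy()).all()

    def test_capacity_and_validation_errors(self):
        with pytest.raises(CapacityError):
            generate_screen(
                ScreenSimConfig(
                    n_strains=30, replicates_per_strain=4,
                    plate_rows=8, plate_cols=12, max_plates=1,
                )
            )
        with pytest.raises(ValueError):
            ScreenSimConfig(colony_noise_cv=-0.1)
        with pytest.raises(ValueError):
            ScreenSimConfig(replicates_per_strain=9)
        with pytest.raises(ValueError):
            ScreenSimConfig(hit_lgr={"strain-0001": -0.5})

    def test_ground_truth_forward_model(self, planted_screen):
        cfg, layout, tables, truth = planted_screen
        # realized size = baseline * plate factor * exp(-lgr) * noise; back out
        # the noise for one hit strain and confirm it is lognormal-positive
        exp = tables[cfg.experimental]
        factors = truth.plate_factors.query("plasmid == @cfg.experimental").set_index("plate")["factor"]
        strain = "strain-0005"
        sub = exp[exp["strain"] == strain]
        noise = sub["size"].to_numpy() / (
            cfg.baseline_size
            * factors.loc[sub["plate"]].to_numpy()
            * math.exp(-truth.true_lgr[strain])
        )
        assert (noise > 0).all()
        assert np.log(noise).std() == pytest.approx(math.sqrt(math.log1p(0.04)), rel=0.5)


class TestRenderPlateImage:
    def test_equal_sizes_render_equal_disc_areas(self):
        tbl = pd.DataFrame(
            {"plate": 0, "row": [0, 0, 1, 1], "col": [0, 1, 0, 1], "size": 50.0}
        )
        img, geom = render_plate_image(tbl)
        from spiscreen.colony import measure_colonies

        meas = measure_colonies(img, geom)
        areas = meas["pixel_area"].to_numpy()
        assert areas.max() - areas.min() <= 1

    def test_zero_size_renders_no_foreground(self):
        tbl = pd.DataFrame({"plate": 0, "row": [0, 0], "col": [0, 1], "size": [60.0, 0.0]})
        img, geom = render_plate_image(tbl)
        cy, cx = geom.center(0, 1)
        half = int(geom.pitch[0] / 2)
        cell = img[int(cy) - half : int(cy) + half, int(cx) - half : int(cx) + half]
        assert (cell == cell.min()).all()  # uniform background, no disc pixels

    def test_two_to_one_size_ratio_in_pixel_area(self):
        tbl = pd.DataFrame({"plate": 0, "row": [0, 0], "col": [0, 1], "size": [100.0, 50.0]})
        img, geom = render_plate_image(tbl)
        fg = img > img.min()
        half = int(geom.pitch[0] / 2)

        def cell_area(r, c):
            cy, cx = geom.center(r, c)
            return fg[int(cy) - half : int(cy) + half, int(cx) - half : int(cx) + half].sum()

        ratio = cell_area(0, 0) / cell_area(0, 1)
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestGenerateStack:
    def test_single_sphere_truth_and_voxel_oracle(self):
        shape = (10, 40, 40)
        nuc = Nucleus((1.5, 4.0, 4.0), 1.0, marker_intensity=200, measure_intensity=200)
        cfg = StackSimConfig(shape=shape, nuclei=[nuc], background=50.0, noise_sd=0.0)
        stack, truth = generate_stack(cfg)
        assert truth.loc[0, "true_corrected"] == 150.0
        oracle = brute_force_sphere_count(shape, (1.5, 4.0, 4.0), 1.0, 300.0, 205.0)
        assert truth.loc[0, "voxel_count"] == oracle

    def test_zero_nuclei_gives_empty_truth_and_flat_marker(self):
        cfg = StackSimConfig(shape=(5, 16, 16), nuclei=[], noise_sd=0.0)
        stack, truth = generate_stack(cfg)
        assert truth.empty
        assert (stack[0] == cfg.marker_background).all()
        assert (stack[1] == cfg.background).all()

    def test_edge_nucleus_raises_placement_error(self):
        nuc = Nucleus((0.1, 1.0, 1.0), 1.0)
        with pytest.raises(PlacementError):
            generate_stack(StackSimConfig(shape=(10, 64, 64), nuclei=[nuc]))

    def test_seed_determinism(self):
        nuc = Nucleus((1.5, 4.0, 4.0), 1.0)
        cfg = StackSimConfig(shape=(10, 40, 40), nuclei=[nuc], noise_sd=10.0, seed=3)
        s1, _ = generate_stack(cfg)
        s2, _ = generate_stack(cfg)
        assert (s1 == s2).all()

    def test_intensity_above_dynamic_range_rejected(self):
        nuc = Nucleus((1.5, 4.0, 4.0), 1.0, marker_intensity=5000)
        with pytest.raises(ValueError):
            StackSimConfig(shape=(10, 40, 40), nuclei=[nuc], dynamic_range=3000)


class TestGenerateCounts:
    @pytest.mark.parametrize("p,expect", [(0.0, 0), (1.0, 250)])
    def test_degenerate_proportions(self, p, expect):
        df = generate_counts([250], [p], seed=1)
        assert df.loc[0, "positive"] == expect

    def test_binomial_mean_matches_moments(self):
        # 1000 draws of Binomial(500, 0.3): mean within 3 sd of np = 150
        df = generate_counts([500] * 1000, [0.3] * 1000, seed=9)
        sd = math.sqrt(500 * 0.3 * 0.7)
        assert abs(df["positive"].mean() - 150.0) <= 3 * sd / math.sqrt(1000)

    def test_invalid_proportion_rejected(self):
        with pytest.raises(ValueError):
            generate_counts([10], [1.5])
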
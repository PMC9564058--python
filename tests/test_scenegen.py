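"""The synthetic scene generator: placement, kinetics, rendering, determinism."""

import numpy as np
import pytest

from mastreg.imgproc import max_z_project
from mastreg.stackio import StackMeta
from mastreg.scenegen import (
    NoiseConfig,
    ScenarioConfig,
    mc_repopulation_density,
    sample_cell_positions,
    simulate_scene,
    simulate_treg_tracks,
)


class TestSampleCellPositions:
    def test_zero_density_gives_no_points(self):
        pts = sample_cell_positions(0.0, (1.0, 1.0), 15.0, np.random.default_rng(0))
        assert pts.shape == (0, 2)

    def test_fixed_count_and_hard_core(self):
        pts = sample_cell_positions(360.0, (1.0, 1.0), 15.0, np.random.default_rng(1))
        assert len(pts) == 360
        d = np.hypot(pts[:, 0, None] - pts[None, :, 0],
                     pts[:, 1, None] - pts[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 15.0

    def test_count_rounding_rule(self):
        pts = sample_cell_positions(100.0, (0.45, 0.45), 15.0,
                                    np.random.default_rng(2))
        assert len(pts) == 20  # round(100 × 0.2025)

    def test_infeasible_packing_raises(self):
        with pytest.raises(RuntimeError, match="infeasible"):
            sample_cell_positions(5000.0, (0.1, 0.1), 50.0, np.random.default_rng(3))

    def test_forbidden_zones_respected(self):
        forb = np.array([[100.0, 100.0]])
        pts = sample_cell_positions(200.0, (0.2, 0.2), 10.0,
                                    np.random.default_rng(4),
                                    forbidden_centers=forb, forbidden_radius_um=40.0)
        d = np.hypot(pts[:, 0] - 100.0, pts[:, 1] - 100.0)
        assert d.min() >= 40.0


class TestRepopulationKinetics:
    def test_day_zero_returns_baseline(self):
        assert mc_repopulation_density(0.0, 360.0) == 360.0

    def test_three_month_recovery(self):
        assert mc_repopulation_density(90.0, 360.0) == 150.0

    def test_linear_interpolation_midpoint(self):
        assert mc_repopulation_density(50.5, 360.0) == pytest.approx(90.0)

    def test_flat_after_day_90(self):
        assert mc_repopulation_density(120.0, 360.0) == 150.0

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError):
            mc_repopulation_density(-1.0, 360.0)


class TestTregTracks:
    def test_zero_speed_without_contacts_freezes_tracks(self):
        cfg = ScenarioConfig(field_size_mm=(0.3, 0.3), n_frames=10,
                             treg_speed_um_min=0.0, contact_model=None,
                             episodes_per_treg=0, mc_density_per_mm2=0,
                             noise=NoiseConfig.off(), rng_seed=5)
        tracks, _ = simulate_treg_tracks(cfg, [], np.random.default_rng(5))
        assert tracks
        for tr in tracks:
            assert np.ptp(tr.positions_um, axis=0).max() == 0.0

    def test_contact_demand_without_mast_cells_is_an_error(self):
        cfg = ScenarioConfig(field_size_mm=(0.3, 0.3), n_frames=10, rng_seed=6,
                             noise=NoiseConfig.off())
        with pytest.raises(ValueError, match="no mast cells"):
            simulate_treg_tracks(cfg, [], np.random.default_rng(6))

    def test_episode_duration_to_frame_conversion(self, pca_scene):
        cfg, _, truth = pca_scene
        dt = cfg.meta.frame_interval_min
        # a duration of g frames corresponds to (end - start + 1) frames
        for c in truth.contacts:
            assert 0 <= c.start_frame <= c.end_frame < cfg.n_frames

    def test_contact_adjacency_during_episodes(self, pca_scene):
        cfg, _, truth = pca_scene
        for c in truth.contacts:
            mc = truth.mc_cells[c.mc_id]
            pts = mc.boundary_samples(256)
            pos = truth.treg_tracks[c.treg_id].positions_um
            for f in range(c.start_frame, c.end_frame + 1):
                d = np.hypot(pts[:, 0] - pos[f, 0], pts[:, 1] - pos[f, 1]).min()
                assert d <= 2.0 + 0.1

    def test_episodes_never_overlap_per_treg(self, pca_scene):
        _, _, truth = pca_scene
        by_treg = {}
        for c in truth.contacts:
            by_treg.setdefault(c.treg_id, []).append((c.start_frame, c.end_frame))
        for spans in by_treg.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2


class TestSceneInvariants:
    def test_determinism_bit_identical(self):
        cfg = ScenarioConfig(field_size_mm=(0.15, 0.15), n_frames=4, rng_seed=11)
        stack_a, truth_a = simulate_scene(cfg)
        stack_b, truth_b = simulate_scene(cfg)
        np.testing.assert_array_equal(stack_a.data, stack_b.data)
        assert len(truth_a.mc_cells) == len(truth_b.mc_cells)
        for ta, tb in zip(truth_a.treg_tracks, truth_b.treg_tracks):
            np.testing.assert_array_equal(ta.positions_um, tb.positions_um)
        assert truth_a.contacts == truth_b.contacts

    def test_seeded_density_is_exact(self):
        cfg = ScenarioConfig(field_size_mm=(0.5, 0.5), n_frames=1, rng_seed=12,
                             noise=NoiseConfig.off(), contact_model=None,
                             episodes_per_treg=0)
        _, truth = simulate_scene(cfg)
        assert len(truth.mc_cells) == round(360.0 * 0.25)
        assert truth.densities_seeded["red_tdt"] == len(truth.mc_cells) / 0.25

    def test_pca_arm_treg_count_ratio(self):
        kw = dict(field_size_mm=(1.0, 1.0), n_frames=1, rng_seed=13,
                  noise=NoiseConfig.off(), contact_model=None, episodes_per_treg=0)
        _, ctrl = simulate_scene(ScenarioConfig(pca=False, **kw))
        _, pca = simulate_scene(ScenarioConfig(pca=True, **kw))
        assert len(ctrl.treg_tracks) == round(18.0)
        assert len(pca.treg_tracks) == round(18.0 * 15.0)

    def test_mast_cells_are_sessile_by_construction(self, tiny_scene):
        cfg, stack, _ = tiny_scene
        red = max_z_project(stack).channel("red_tdt")
        for t in range(1, cfg.n_frames):
            np.testing.assert_array_equal(red[t], red[0])

    def test_mc_centroid_hard_core(self, pca_scene):
        cfg, _, truth = pca_scene
        pos = np.array([[m.y_um, m.x_um] for m in truth.mc_cells])
        d = np.hypot(pos[:, 0, None] - pos[None, :, 0],
                     pos[:, 1, None] - pos[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= cfg.min_separation_um


class TestRendering:
    def test_empty_scene_renders_pure_background(self):
        cfg = ScenarioConfig(field_size_mm=(0.1, 0.1), n_frames=2, rng_seed=14,
                             mc_density_per_mm2=0, treg_baseline_per_mm2=0,
                             follicle_density_per_mm2=0, contact_model=None,
                             episodes_per_treg=0,
                             noise=NoiseConfig(background=0.07, gaussian_sd=0.0))
        stack, _ = simulate_scene(cfg)
        np.testing.assert_allclose(stack.data, 0.07, atol=1e-6)

    def test_follicles_are_yellow_never_green(self):
        cfg = ScenarioConfig(field_size_mm=(0.3, 0.3), n_frames=1, rng_seed=15,
                             mc_density_per_mm2=0, treg_baseline_per_mm2=0,
                             follicle_density_per_mm2=30.0, contact_model=None,
                             episodes_per_treg=0, noise=NoiseConfig.off(),
                             meta=StackMeta(channel_roles=("red_tdt", "green_egfp",
                                                           "blue_auto")))
        stack, truth = simulate_scene(cfg)
        assert truth.follicles
        proj = max_z_project(stack)
        px = cfg.meta.pixel_size_um
        for fol in truth.follicles:
            iy, ix = int(fol.y_um / px), int(fol.x_um / px)
            assert proj.frame(0, "red_tdt")[iy, ix] > 0.1
            assert proj.frame(0, "blue_auto")[iy, ix] > 0.1
            assert proj.frame(0, "green_egfp")[iy, ix] == 0.0

    def test_every_treg_has_a_green_peak_at_its_centroid(self, tiny_scene):
        cfg, stack, truth = tiny_scene
        green = max_z_project(stack).channel("green_egfp")
        px = cfg.meta.pixel_size_um
        for tr in truth.treg_tracks:
            for f in (0, cfg.n_frames - 1):
                iy, ix = int(round(tr.positions_um[f, 0] / px)), int(
                    round(tr.positions_um[f, 1] / px))
                window = green[f][max(iy - 3, 0):iy + 4, max(ix - 3, 0):ix + 4]
                peak_y, peak_x = np.unravel_index(window.argmax(), window.shape)
                assert abs(peak_y + max(iy - 3, 0) - iy) <= 3
                assert abs(peak_x + max(ix - 3, 0) - ix) <= 3
                assert window.max() > 0.5

    def test_lc_layer_renders_in_green_at_distinct_z(self):
        cfg = ScenarioConfig(field_size_mm=(0.15, 0.15), n_frames=4, rng_seed=16,
                             mc_density_per_mm2=0, treg_baseline_per_mm2=0,
                             follicle_density_per_mm2=0, include_lc_layer=True,
                             lc_density_per_mm2=80.0, contact_model=None,
                             episodes_per_treg=0, noise=NoiseConfig.off())
        stack, truth = simulate_scene(cfg)
        assert truth.lc_cells
        assert stack.n_slices == 3
        green_c = stack.meta.channel_index("green_egfp")
        assert stack.data[:, 2, green_c].max() > 0.5  # somata in the LC slab
        assert stack.data[:, 0, green_c].max() == 0.0  # dermal slab has no LCs
        # dendrite tips move between frames while somata stay put
        assert not np.array_equal(stack.data[0, 2, green_c],
                                  stack.data[2, 2, green_c])
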
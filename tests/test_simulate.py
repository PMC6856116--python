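"""Synthetic colony-assay generator: division model, rendering, determinism."""

import warnings

import numpy as np
import pytest

import colonytrack as ct
from colonytrack.simulate import ConfigurationError


def no_division_config(**kw):
    inf = {"large": np.inf, "medium": np.inf, "small": np.inf}
    return ct.SimulationConfig(division_interval_h=inf, **kw)


class TestGrowthCurves:
    def test_no_divisions_gives_all_ones(self):
        cfg = no_division_config(n_colonies=8, seed=3, duration_days=5)
        matrix, _ = ct.simulate_growth_curves(cfg)
        assert matrix.shape == (8, 5)
        assert np.all(matrix == 1)

    def test_deterministic_daily_doubling(self):
        cfg = ct.SimulationConfig(
            n_colonies=1,
            seed=0,
            duration_days=4,
            deterministic_divisions=True,
            group_mix={"large": 1.0},
            division_interval_h={"large": 24.0, "medium": 96.0, "small": 168.0},
            lag_h={"large": 0.0, "medium": 0.0, "small": 0.0},
        )
        matrix, labels = ct.simulate_growth_curves(cfg)
        assert labels == ["large"]
        assert matrix[0].tolist() == [2, 4, 8, 16]

    def test_seed_determinism_of_matrix(self):
        cfg = ct.SimulationConfig(n_colonies=140, seed=1)
        m1, l1 = ct.simulate_growth_curves(cfg)
        m2, l2 = ct.simulate_growth_curves(ct.SimulationConfig(n_colonies=140, seed=1))
        assert np.array_equal(m1, m2)
        assert l1 == l2

    def test_counts_non_decreasing_without_death(self):
        cfg = ct.SimulationConfig(n_colonies=30, seed=5)
        matrix, _ = ct.simulate_growth_curves(cfg)
        assert np.all(np.diff(matrix, axis=1) >= 0)
        assert np.all(matrix[:, 0] >= 1)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ConfigurationError):
            ct.SimulationConfig(group_mix={"large": 0.5, "medium": 0.2, "small": 0.2})

    def test_interval_must_divide_day(self):
        with pytest.raises(ConfigurationError):
            ct.SimulationConfig(frame_interval_h=7.0)


class TestGroundTruth:
    def test_cell_records_conserve_daily_counts(self, small_truth, small_cfg):
        for day in range(1, small_cfg.duration_days + 1):
            f = small_cfg.day_reference_frame(day)
            per_colony = {}
            for c in small_truth.cells_by_frame[f]:
                per_colony[c.colony_id] = per_colony.get(c.colony_id, 0) + 1
            for cid, counts in small_truth.daily_counts.items():
                assert per_colony.get(cid, 0) == counts[day - 1]

    def test_every_cell_has_one_colony(self, small_truth):
        owner = {}
        for frame in small_truth.cells_by_frame:
            for c in frame:
                assert owner.setdefault(c.cell_id, c.colony_id) == c.colony_id

    def test_debris_jump_at_least_minimum(self, small_truth, small_cfg):
        prev = {}
        for frame in small_truth.debris_by_frame:
            for d in frame:
                if d.debris_id in prev:
                    px, py = prev[d.debris_id]
                    assert np.hypot(d.x_px - px, d.y_px - py) >= small_cfg.debris_jump_px
                prev[d.debris_id] = (d.x_px, d.y_px)

    def test_truth_deterministic_given_seed(self, small_cfg, small_truth):
        again = ct.simulate_ground_truth(small_cfg)
        assert np.array_equal(again.counts_matrix(), small_truth.counts_matrix())
        a = [(c.cell_id, c.x_px, c.y_px) for c in again.cells_by_frame[-1]]
        b = [(c.cell_id, c.x_px, c.y_px) for c in small_truth.cells_by_frame[-1]]
        assert a == b


class TestRendering:
    def test_zero_cells_is_background_only(self):
        cfg = no_division_config(
            n_colonies=0, seed=2, duration_days=1, frame_shape=(128, 128),
            debris_count=0, noise_sigma=0.0,
        )
        truth = ct.simulate_ground_truth(cfg)
        seq = ct.render_sequence(truth)
        # all frames identical (static background, no objects, no noise)
        for f in seq.frames[1:]:
            assert np.array_equal(f, seq.frames[0])
        # smooth gradient spans roughly the configured amplitude
        assert np.ptp(seq.frames[0].astype(float)) <= cfg.background_gradient_amplitude + 1

    def test_render_deterministic(self, small_cfg, small_truth):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = ct.render_sequence(small_truth, small_cfg)
            s2 = ct.render_sequence(ct.simulate_ground_truth(small_cfg), small_cfg)
        for f1, f2 in zip(s1.frames, s2.frames):
            assert np.array_equal(f1, f2)

    def test_interiors_darker_rims_brighter_than_local_background(self):
        cfg = no_division_config(
            n_colonies=3, seed=9, duration_days=1, frame_shape=(256, 256),
            debris_count=0, noise_sigma=0.0, min_colony_separation_px=60.0,
        )
        truth = ct.simulate_ground_truth(cfg)
        rendered = ct.render_sequence(truth).frames[0].astype(float)
        bg_cfg = no_division_config(
            n_colonies=0, seed=9, duration_days=1, frame_shape=(256, 256),
            debris_count=0, noise_sigma=0.0,
        )
        bg = ct.render_sequence(ct.simulate_ground_truth(bg_cfg)).frames[0].astype(float)
        diff = rendered - bg
        for c in truth.cells_by_frame[0]:
            y, x = int(round(c.y_px)), int(round(c.x_px))
            patch = diff[max(y - 10, 0) : y + 11, max(x - 10, 0) : x + 11]
            assert diff[y, x] < 0  # interior darker than local background
            assert patch.max() > 0  # rim brighter than local background
            assert patch.min() < -cfg.cell_interior_contrast + 2

    def test_stationary_cell_centroid_recoverable(self):
        cfg = no_division_config(
            n_colonies=1, seed=4, duration_days=2, frame_shape=(256, 256),
            debris_count=0, noise_sigma=0.0,
        )
        truth = ct.simulate_ground_truth(cfg)
        seq = ct.render_sequence(truth)
        bg_cfg = no_division_config(
            n_colonies=0, seed=4, duration_days=2, frame_shape=(256, 256),
            debris_count=0, noise_sigma=0.0,
        )
        bg = ct.render_sequence(ct.simulate_ground_truth(bg_cfg)).frames[0].astype(float)
        cell = truth.cells_by_frame[0][0]
        for frame in seq.frames:
            # oracle: centroid of the strongly darkened pixels
            dark = (bg - frame.astype(float)) > 10
            rr, cc = np.nonzero(dark)
            assert np.hypot(cc.mean() - cell.x_px, rr.mean() - cell.y_px) <= 2.0

    def test_out_of_frame_cell_clipped_with_warning(self):
        cfg = no_division_config(
            n_colonies=1, seed=6, duration_days=1, frame_shape=(128, 128),
            debris_count=0, noise_sigma=0.0,
        )
        truth = ct.simulate_ground_truth(cfg)
        for frame in truth.cells_by_frame:
            for c in frame:
                c.x_px, c.y_px = 1.0, 1.0  # push the cell onto the frame edge
        with pytest.warns(UserWarning, match="clipped"):
            ct.render_sequence(truth, cfg)
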
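"""The generators must be deterministic and their ground truth exact."""

import math

import numpy as np
import pytest

import cardiogate as cg
from cardiogate.core import PackingError, ParameterError

TWO_PI = 2 * math.pi


class TestHeartVideo:
    def test_phase_advances_by_period_over_fps(self, heart_video):
        _, truth = heart_video
        # 400 ms at 30 fps: 2*pi * (1000/400) / 30 rad per frame
        expected = TWO_PI * (1000 / 400) / 30
        steps = np.diff(truth.timeline.unwrapped_phase_at(
            np.arange(10) * 1000 / 30))
        assert np.allclose(steps, expected, atol=1e-12)

    def test_unwrapped_phase_affine_in_time_without_pause(self, heart_video):
        video, truth = heart_video
        t = video.timestamps_ms
        phi = truth.timeline.unwrapped_phase_at(t)
        slope = np.polyfit(t, phi, 1)[0]
        assert np.isclose(slope, TWO_PI / 400.0, rtol=1e-12)
        assert np.allclose(phi, np.polyval(np.polyfit(t, phi, 1), t), atol=1e-9)

    def test_zero_ef_gives_constant_area(self):
        _, truth = cg.generate_heart_video(cg.HeartSimParams(ef_true_pct=0.0))
        assert np.ptp(truth.area_per_frame_um2) == 0.0
        assert np.allclose(truth.area_per_frame_um2, 10_100.0)

    def test_pause_freezes_phase_and_blocks_crossings(self):
        params = cg.HeartSimParams(n_frames=200, pause_onset_frame=60,
                                   pause_duration_ms=2000.0)
        video, truth = cg.generate_heart_video(params)
        t_pause = 60 * 1000 / 30
        crossings = truth.target_phase_times_ms
        inside = (crossings > t_pause) & (crossings < t_pause + 2000.0)
        assert not inside.any()
        # phase is constant during the pause
        frozen = truth.phase_per_frame[61:int((t_pause + 2000) * 30 / 1000)]
        assert np.ptp(frozen) == 0.0

    def test_post_pause_period_switches(self):
        params = cg.HeartSimParams(n_frames=300, pause_onset_frame=60,
                                   pause_duration_ms=2000.0,
                                   post_pause_period_ms=512.0)
        _, truth = cg.generate_heart_video(params)
        (r0, hr0), (_, hr_pause), (_, hr2) = truth.hr_bpm_piecewise
        assert hr0 == pytest.approx(150.0)
        assert hr_pause == 0.0
        assert hr2 == pytest.approx(60_000 / 512)

    def test_deterministic_given_seed(self):
        p = cg.HeartSimParams(noise_sigma=0.05, seed=3, n_frames=20)
        v1, _ = cg.generate_heart_video(p)
        v2, _ = cg.generate_heart_video(p)
        assert np.array_equal(v1.frames, v2.frames)

    @pytest.mark.parametrize("bad", [
        dict(period_ms=0.0), dict(fps=-1.0), dict(ef_true_pct=100.0),
        dict(pause_onset_frame=1000), dict(noise_sigma=-0.1),
    ])
    def test_invalid_params_raise(self, bad):
        with pytest.raises(ParameterError):
            cg.HeartSimParams(**bad)


class TestVesselVideo:
    def test_interframe_displacement_is_velocity_over_fps(self):
        p = cg.VesselSimParams(velocity_um_s=300.0, fps=30.0, pixel_size_um=1.0,
                               n_frames=10)
        video, v_true = cg.generate_vessel_video(p)
        assert v_true == 300.0
        dx = np.diff(video.true_positions_px[:, :, 1], axis=1)
        assert np.allclose(np.abs(dx), 10.0)  # 300/30/1 = 10 px per frame

    def test_zero_velocity_gives_identical_frames(self):
        video, _ = cg.generate_vessel_video(
            cg.VesselSimParams(velocity_um_s=0.0, n_frames=5))
        assert np.ptp(video.frames, axis=0).max() == 0.0

    def test_truth_records_one_trajectory_per_cell(self):
        video, _ = cg.generate_vessel_video(
            cg.VesselSimParams(n_cells=4, n_frames=10))
        assert video.true_positions_px.shape == (4, 10, 2)

    def test_oversized_cell_raises(self):
        with pytest.raises(ParameterError):
            cg.VesselSimParams(cell_radius_um=500.0)


class TestHeartStack:
    def test_truth_counts_match_construction(self):
        _, truth = cg.generate_heart_stack(cg.StackSimParams(
            n_nuclei_in_mask=50, n_nuclei_out_mask=10, phh3_fraction=0.0))
        assert truth["vct"] == 50
        assert truth["vcm"] == 0

    def test_full_phh3_fraction_copies_every_centroid(self):
        _, truth = cg.generate_heart_stack(cg.StackSimParams(
            n_nuclei_in_mask=10, n_nuclei_out_mask=0, phh3_fraction=1.0))
        assert truth["vcm"] == 10
        assert np.array_equal(np.sort(truth["phh3_centers_um"], axis=0),
                              np.sort(truth["centers_in_um"], axis=0))

    @pytest.mark.parametrize("n_tunel", [1, 5])
    def test_requested_puncta_are_rendered(self, n_tunel):
        scene, truth = cg.generate_heart_stack(cg.StackSimParams(
            n_nuclei_in_mask=20, n_nuclei_out_mask=0, n_tunel_puncta=n_tunel))
        assert truth["tunel"] == n_tunel
        assert len(truth["tunel_centers_um"]) == n_tunel
        assert (scene.channels["tunel"] > 0.5).any()

    def test_rendered_nucleus_count_conserved_before_noise(self):
        from scipy import ndimage
        scene, truth = cg.generate_heart_stack(cg.StackSimParams(
            n_nuclei_in_mask=40, n_nuclei_out_mask=10, seed=2))
        _, n = ndimage.label(scene.channels["dapi"] > 0.5,
                             structure=np.ones((3, 3, 3)))
        assert n == 50

    def test_min_separation_respected(self):
        _, truth = cg.generate_heart_stack(cg.StackSimParams(
            n_nuclei_in_mask=60, n_nuclei_out_mask=20, seed=5))
        centers = np.vstack([truth["centers_in_um"], truth["centers_out_um"]])
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 9.0

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            cg.generate_heart_stack(cg.StackSimParams(
                shape_zyx=(6, 32, 32), n_nuclei_in_mask=500))

    def test_stack_deterministic_given_seed(self):
        p = cg.StackSimParams(n_nuclei_in_mask=30, n_nuclei_out_mask=5,
                              noise_sigma=0.05, seed=11)
        s1, _ = cg.generate_heart_stack(p)
        s2, _ = cg.generate_heart_stack(p)
        assert all(np.array_equal(s1.channels[c], s2.channels[c])
                   for c in s1.channels)
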
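import numpy as np
import pytest

from vitreoquant import (
    BScan,
    GatedVolumeError,
    OCTVolume,
    SegmentationError,
    SyntheticConfig,
    VIParams,
    compute_vi,
    compute_volume_vi,
    generate_volume,
    preprocess_bscan,
    segment_retina,
)
from vitreoquant.errors import DegenerateImageWarning

from conftest import small_config


class TestPreprocess:
    def test_constant_image_returns_zeros_with_warning(self):
        with pytest.warns(DegenerateImageWarning):
            prep = preprocess_bscan(np.zeros((50, 40)))
        assert prep.degenerate and not prep.image.any()

    def test_single_bright_pixel_removed_by_opening(self):
        img = np.zeros((60, 60))
        img[10, 10] = 1.0
        with pytest.warns(DegenerateImageWarning):
            prep = preprocess_bscan(img)
        assert not prep.image.any()

    def test_particles_survive_opening(self):
        cfg = small_config(particle_radius_px=3.0, inflammation_level=3.0)
        vol, gt = generate_volume(cfg)
        prep = preprocess_bscan(vol.scans[0])
        rows = np.arange(prep.image.shape[0])[:, None]
        vitreous = prep.image[rows < gt.ilm_rows[0][None, :]]
        assert vitreous.sum() > 0

    def test_output_range_is_unit_interval(self, small_volume):
        vol, _ = small_volume
        prep = preprocess_bscan(vol.scans[0])
        assert prep.image.min() >= 0.0 and prep.image.max() == 1.0


class TestSegmentation:
    def test_ilm_matches_ground_truth_noiseless(self):
        vol, gt = generate_volume(SyntheticConfig(speckle_sigma=0.0, seed=3, n_scans=1))
        seg = segment_retina(preprocess_bscan(vol.scans[0]))
        valid = seg.valid_columns
        err = np.abs(seg.ilm_row_per_column[valid] - gt.ilm_rows[0][valid])
        assert (err <= 2).mean() >= 0.99

    def test_boundary_recovery_on_noisy_default_generator(self):
        vol, gt = generate_volume(SyntheticConfig(seed=11, n_scans=1))
        seg = segment_retina(preprocess_bscan(vol.scans[0]))
        valid = seg.valid_columns
        ilm_mae = np.abs(seg.ilm_row_per_column[valid] - gt.ilm_rows[0][valid]).mean()
        rpe_mae = np.abs(seg.rpe_top_per_column[valid] - gt.rpe_rows[0][valid]).mean()
        assert ilm_mae <= 3.0 and rpe_mae <= 3.0

    def test_translation_equivariance(self):
        # absolute threshold keeps the global adjustment identical, so
        # boundaries must move exactly with the retina
        params = VIParams(threshold_mode="absolute", absolute_threshold=0.05)
        vol, _ = generate_volume(small_config(n_scans=1, ilm_row_frac=0.45, rpe_row_frac=0.7))
        px = vol.scans[0].pixels
        base = segment_retina(preprocess_bscan(px, params), params)
        shifted = np.vstack([np.zeros((30, px.shape[1])), px[:-30]])
        moved = segment_retina(preprocess_bscan(shifted, params), params)
        both = base.valid_columns & moved.valid_columns
        assert both.mean() > 0.9
        np.testing.assert_array_equal(
            moved.ilm_row_per_column[both], base.ilm_row_per_column[both] + 30
        )

    def test_pure_noise_raises_segmentation_error(self, rng):
        noise = rng.random((200, 160))
        with pytest.raises(SegmentationError) as err:
            segment_retina(preprocess_bscan(noise))
        assert err.value.diagnostics["n_invalid"] > 0

    def test_vitreous_mask_strictly_above_ilm(self, small_volume):
        vol, _ = small_volume
        seg = segment_retina(preprocess_bscan(vol.scans[0]))
        rows = np.arange(seg.vitreous_mask.shape[0])[:, None]
        expected = seg.valid_columns[None, :] & (rows < seg.ilm_row_per_column[None, :])
        np.testing.assert_array_equal(seg.vitreous_mask, expected)


class TestVIScore:
    def test_zero_particles_noiseless_gives_zero_vi(self):
        vol, _ = generate_volume(small_config(inflammation_level=0.0))
        assert compute_vi(vol.scans[0]).vi == 0.0

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 0.75])
    def test_media_opacity_invariance(self, alpha, small_volume):
        """Global multiplicative attenuation leaves VI unchanged."""
        vol, _ = small_volume
        scan = vol.scans[2]
        base = compute_vi(scan).vi
        scaled = compute_vi(
            BScan(scan.pixels * alpha, scan.quality, scan.index_in_volume, scan.y_position_um)
        ).vi
        assert base > 0
        assert abs(scaled - base) <= 1e-9 * base

    def test_vi_increases_with_density(self):
        means = []
        for level in (0.5, 4.0):
            vis = [
                compute_vi(generate_volume(small_config(inflammation_level=level, seed=s, n_scans=1))[0].scans[0]).vi
                for s in range(10)
            ]
            means.append(np.mean(vis))
        assert means[1] > means[0]

    def test_absolute_threshold_mode_available(self, small_volume):
        vol, _ = small_volume
        params = VIParams(threshold_mode="absolute", absolute_threshold=0.1)
        assert compute_vi(vol.scans[0], params).vi >= 0.0


def _replicated_volume(scan, n):
    scans = [
        BScan(scan.pixels.copy(), 30.0, i, float(i + 1) * 100.0) for i in range(n)
    ]
    return OCTVolume(scans, 100.0, "rep")


class TestVolumeVI:
    def test_nineteen_scans_yield_nine_scores(self):
        vol, _ = generate_volume(small_config(n_scans=19))
        scores = compute_volume_vi(vol)
        assert len(scores) == 9
        assert all(s is not None for s in scores)

    def test_identical_scans_identical_scores(self):
        vol, _ = generate_volume(small_config(n_scans=1))
        rep = _replicated_volume(vol.scans[0], 19)
        scores = compute_volume_vi(rep)
        vis = np.array([s.vi for s in scores])
        assert vis.mean() > 0
        assert np.ptp(vis) <= 1e-6 * vis.mean()

    def test_linear_gradient_gives_monotone_scores(self):
        # gradient spans the score's sensitivity range; extreme densities
        # saturate the vitreous and compress the score
        gradient = np.linspace(0.25, 2.0, 19)
        cfg = SyntheticConfig(
            speckle_sigma=0.0, inflammation_level=4.0, inflammation_gradient=gradient, seed=4
        )
        vol, _ = generate_volume(cfg)
        vis = [s.vi for s in compute_volume_vi(vol)]
        assert all(b > a for a, b in zip(vis, vis[1:]))

    def test_low_quality_volume_is_gated(self):
        vol, _ = generate_volume(small_config(n_scans=19))
        bad = OCTVolume(
            [BScan(s.pixels, 10.0, s.index_in_volume, s.y_position_um) for s in vol.scans],
            vol.inter_scan_um,
            vol.eye_id,
        )
        with pytest.raises(GatedVolumeError):
            compute_volume_vi(bad)

    def test_segmentation_failure_recorded_as_missing(self, rng):
        vol, _ = generate_volume(small_config(n_scans=19))
        scans = [BScan(s.pixels, 30.0, s.index_in_volume, s.y_position_um) for s in vol.scans]
        scans[3] = BScan(rng.random(scans[3].pixels.shape), 30.0, 3, scans[3].y_position_um)
        broken = OCTVolume(scans, vol.inter_scan_um, vol.eye_id)
        scores = compute_volume_vi(broken)
        assert scores[1] is None  # analysable position of original scan 3
        assert sum(s is not None for s in scores) == 8
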
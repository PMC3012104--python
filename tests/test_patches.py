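"""Masks, patch extraction/sampling, and PCA whitening."""

import numpy as np
import pytest

from ctxsal import (
    ImageGrid,
    PatchConfig,
    apply_whitening,
    extract_patch_at,
    fit_whitening,
    make_masks,
    sample_patches,
)
from ctxsal.patches import PatchBatch, augment_mirror, unapply_whitening
from ctxsal.synth import gen_moving_dot_sequence


def brute_force_lattice_count(radius: float) -> int:
    r = int(np.ceil(radius))
    return sum(
        1
        for x in range(-r, r + 1)
        for y in range(-r, r + 1)
        if x * x + y * y <= radius * radius
    )


class TestMasks:
    @pytest.mark.parametrize(
        "diameters,center_px,surround_px",
        [((15, 45), 149, 1368), ((7, 23), 29, 348), ((7, 31), 29, 680)],
    )
    def test_pixel_counts_match_lattice(self, diameters, center_px, surround_px):
        cfg = PatchConfig(*diameters)
        center, surround = make_masks(cfg)
        assert int(center.sum()) == center_px
        assert int(surround.sum()) == surround_px
        # cross-check against brute-force lattice enumeration
        r_c, r_s = (diameters[0] - 1) / 2, (diameters[1] - 1) / 2
        assert center_px == brute_force_lattice_count(r_c)
        assert center_px + surround_px == brute_force_lattice_count(r_s)

    def test_color_dimensionalities(self):
        cfg = PatchConfig(7, 23, channels=3)
        assert cfg.d_center == 87
        assert cfg.d_context == 1044

    def test_video_volume_dimensionalities(self):
        cfg = PatchConfig(11, 13, channels=3, temporal_depth=4)
        assert cfg.d_center == 363
        assert cfg.d_context == 1089

    def test_masks_disjoint_and_monotone(self):
        cfg = PatchConfig(15, 45)
        center, surround = make_masks(cfg)
        assert not np.any(center & surround)
        counts = [brute_force_lattice_count(r) for r in (3, 7, 11, 22)]
        assert counts == [29, 149, 377, 1517]
        assert np.all(np.diff(counts) > 0)

    def test_even_diameter_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            PatchConfig(14, 45)

    def test_explicit_radii_override(self):
        cfg = PatchConfig(15, 45, explicit_radii=(3.0, 11.0))
        center, surround = make_masks(cfg)
        assert int(center.sum()) == 29
        assert int(surround.sum()) == 348


class TestExtract:
    def test_constant_image_gives_constant_vectors(self):
        cfg = PatchConfig(7, 23)
        img = ImageGrid(np.full((30, 30, 1), 0.4))
        x_c, x_s = extract_patch_at(img, 15, 15, cfg)
        assert x_c.shape == (29,) and x_s.shape == (348,)
        assert np.all(x_c == 0.4) and np.all(x_s == 0.4)

    def test_vector_lengths_for_default_config(self):
        cfg = PatchConfig(15, 45)
        img = ImageGrid(np.zeros((45, 45, 1)))
        x_c, x_s = extract_patch_at(img, 22, 22, cfg)
        assert (len(x_c), len(x_s)) == (149, 1368)

    def test_write_then_extract_is_identity(self):
        cfg = PatchConfig(7, 23)
        center, surround = make_masks(cfg)
        rng = np.random.default_rng(0)
        img = np.zeros((23, 23, 1))
        vc = rng.random(int(center.sum()))
        vs = rng.random(int(surround.sum()))
        img[center, 0] = vc
        img[surround, 0] = vs
        x_c, x_s = extract_patch_at(ImageGrid(img), 11, 11, cfg)
        np.testing.assert_array_equal(x_c, vc)
        np.testing.assert_array_equal(x_s, vs)

    def test_out_of_bounds_raises(self):
        cfg = PatchConfig(7, 23)
        img = ImageGrid(np.zeros((30, 30, 1)))
        with pytest.raises(IndexError):
            extract_patch_at(img, 5, 15, cfg)

    def test_video_extraction_orders_context_oldest_first(self):
        cfg = PatchConfig(11, 13, temporal_depth=3)
        seq, _ = gen_moving_dot_sequence(n_frames=5)
        x_c, x_s = extract_patch_at(seq, 20, 20, cfg, frame=4)
        direct_c, _ = extract_patch_at(seq[4], 20, 20, PatchConfig(11, 13))
        # target equals the current frame's square window regardless of config kind
        ref = seq[4].values[15:26, 15:26, 0].ravel()
        np.testing.assert_array_equal(x_c, ref)
        old = seq[2].values[15:26, 15:26, 0].ravel()
        np.testing.assert_array_equal(x_s[:121], old)

    def test_video_needs_enough_preceding_frames(self):
        cfg = PatchConfig(11, 13, temporal_depth=3)
        seq, _ = gen_moving_dot_sequence(n_frames=5)
        with pytest.raises(IndexError):
            extract_patch_at(seq, 20, 20, cfg, frame=1)


class TestSampling:
    def test_single_valid_position(self):
        cfg = PatchConfig(15, 45)
        img = ImageGrid(np.random.default_rng(0).random((45, 45, 1)))
        batch = sample_patches([("only", img)], cfg, 3, seed=0)
        assert all(p[1:3] == (22, 22) for p in batch.provenance)

    def test_same_seed_reproduces_batch(self):
        cfg = PatchConfig(7, 23)
        img = ImageGrid(np.random.default_rng(1).random((64, 64, 1)))
        b1 = sample_patches([("a", img)], cfg, 50, seed=9)
        b2 = sample_patches([("a", img)], cfg, 50, seed=9)
        np.testing.assert_array_equal(b1.X_c, b2.X_c)
        assert b1.provenance == b2.provenance

    def test_provenance_within_valid_bounds(self):
        cfg = PatchConfig(7, 23)
        rng = np.random.default_rng(2)
        scenes = [(f"s{i}", ImageGrid(rng.random((40, 50, 1)))) for i in range(3)]
        batch = sample_patches(scenes, cfg, 200, seed=4)
        for _, r, c, _ in batch.provenance:
            assert 11 <= r <= 40 - 12 and 11 <= c <= 50 - 12

    def test_no_valid_window_raises(self):
        cfg = PatchConfig(15, 45)
        img = ImageGrid(np.zeros((20, 20, 1)))
        with pytest.raises(ValueError, match="valid window"):
            sample_patches([("tiny", img)], cfg, 1, seed=0)

    def test_mismatched_rows_rejected(self):
        with pytest.raises(ValueError, match="row counts"):
            PatchBatch(np.zeros((3, 4)), np.zeros((2, 5)))


class TestWhitening:
    def test_projected_covariance_is_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10_000, 6)) @ rng.standard_normal((6, 6))
        t = fit_whitening(X, 6)
        Z = apply_whitening(t, X)
        cov = np.cov(Z, rowvar=False)
        assert np.max(np.abs(cov - np.eye(6))) < 1e-6
        assert np.max(np.abs(Z.mean(axis=0))) < 1e-10
        assert np.all(np.diff(t.explained_variance) <= 1e-12)  # decreasing variance

    def test_forward_inverse_identity_on_k_space(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 5))
        t = fit_whitening(X, 3)
        assert np.max(np.abs(t.forward @ t.inverse - np.eye(3))) < 1e-8

    def test_rank_one_data_reconstructs_perfectly(self):
        x = np.random.default_rng(2).standard_normal(300)
        X = np.column_stack([x, 2 * x])
        t = fit_whitening(X, 1)
        back = unapply_whitening(t, apply_whitening(t, X))
        np.testing.assert_allclose(back, X, atol=1e-10)

    def test_k_beyond_rank_names_achievable_rank(self):
        x = np.random.default_rng(3).standard_normal(100)
        X = np.column_stack([x, 2 * x, -x])
        with pytest.raises(ValueError, match="rank 1"):
            fit_whitening(X, 2)

    def test_constant_column_never_selected(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.standard_normal(200), np.full(200, 3.0),
                             rng.standard_normal(200)])
        t = fit_whitening(X, 2)
        # a constant column contributes nothing to any retained component
        assert np.max(np.abs(t.forward[:, 1])) < 1e-8

    def test_scale_invariant_output(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((1000, 4))
        Z1 = apply_whitening(fit_whitening(X, 4), X)
        Z2 = apply_whitening(fit_whitening(10.0 * X, 4), 10.0 * X)
        np.testing.assert_allclose(np.abs(Z1), np.abs(Z2), atol=1e-8)


class TestMirrorAugmentation:
    def test_quadruples_batch_and_flips_are_involutions(self):
        from ctxsal.patches import _mirror_permutation

        cfg = PatchConfig(7, 23)
        for fr, fc in ((True, False), (False, True), (True, True)):
            pc, ps = _mirror_permutation(cfg, fr, fc)
            np.testing.assert_array_equal(pc[pc], np.arange(pc.size))
            np.testing.assert_array_equal(ps[ps], np.arange(ps.size))
        rng = np.random.default_rng(0)
        batch = PatchBatch(rng.random((10, cfg.d_center)), rng.random((10, cfg.d_context)))
        aug = augment_mirror(batch, cfg)
        assert aug.n == 40
        np.testing.assert_array_equal(aug.X_c[:10], batch.X_c)

    def test_flip_matches_flipping_the_image(self):
        cfg = PatchConfig(7, 23)
        rng = np.random.default_rng(1)
        img = rng.random((23, 23, 1))
        x_c, x_s = extract_patch_at(ImageGrid(img), 11, 11, cfg)
        xf_c, xf_s = extract_patch_at(ImageGrid(img[::-1].copy()), 11, 11, cfg)
        from ctxsal.patches import _mirror_permutation

        pc, ps = _mirror_permutation(cfg, True, False)
        np.testing.assert_allclose(x_c[pc], xf_c)
        np.testing.assert_allclose(x_s[ps], xf_s)
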
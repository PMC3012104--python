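"""Sliding-window saliency maps for still scenes and frame sequences."""

import numpy as np
import pytest

from ctxsal import (
    GGParams,
    ImageGrid,
    PatchConfig,
    SaliencyMap,
    compute_map,
    compute_video_maps,
    gen_moving_dot_sequence,
    gen_popout_image,
    render_map,
)
from ctxsal.model import SaliencyModel
from ctxsal.patches import WhitenTransform, make_masks
from ctxsal.scene_io import FrameSequence
from ctxsal.structured_ica import ICAModel


def toy_linear_model(mean_value: float = 0.5) -> SaliencyModel:
    """A minimal handmade model: identity-ish filters around a known mean.

    With the training mean planted at a constant, a constant scene at that
    value yields exactly zero amplitudes and zero saliency everywhere.
    """
    cfg = PatchConfig(3, 7)
    d_c, d_s = cfg.d_center, cfg.d_context
    k_c, k_s = 4, 6
    rng = np.random.default_rng(0)

    def fake_whiten(d, k):
        q, _ = np.linalg.qr(rng.standard_normal((d, k)))
        return WhitenTransform(np.full(d, mean_value), q.T, q, k)

    wc, ws = fake_whiten(d_c, k_c), fake_whiten(d_s, k_s)
    k_u = k_c
    A_cs = np.zeros((k_c, k_s))
    F = np.eye(k_u)
    ica = ICAModel(
        whiten_c=wc, whiten_s=ws, k_s=k_s, k_u=k_u,
        W_s=np.eye(k_s), A_ss=np.eye(k_s), A_cs=A_cs,
        A_cu=np.eye(k_c), W_u_joint=np.hstack([F, -F @ A_cs]),
    )
    gg = GGParams(np.ones(k_u), np.full(k_u, 2.0))
    return SaliencyModel(config=cfg, ica=ica, gg=gg)


class TestComputeMap:
    def test_constant_scene_scores_zero(self):
        model = toy_linear_model(mean_value=0.5)
        scene = ImageGrid(np.full((20, 24, 1), 0.5))
        m = compute_map(scene, model)
        assert np.all(m.scores == 0.0)

    def test_map_shape_follows_window_arithmetic(self):
        model = toy_linear_model()
        m = compute_map(ImageGrid(np.random.default_rng(1).random((20, 24, 1))), model)
        assert m.shape == (20 - 7 + 1, 24 - 7 + 1)
        assert m.offset == (3, 3)

    def test_translation_covariance(self):
        model = toy_linear_model()
        rng = np.random.default_rng(2)
        big = rng.random((26, 30, 1))
        m1 = compute_map(ImageGrid(big[:-1, :-1]), model)
        m2 = compute_map(ImageGrid(big[1:, 1:]), model)
        np.testing.assert_allclose(m1.scores[1:, 1:], m2.scores[:-1, :-1], atol=1e-10)

    def test_deterministic(self, static_model):
        scene = ImageGrid(np.random.default_rng(3).random((40, 40, 1)))
        m1 = compute_map(scene, static_model, stride=2)
        m2 = compute_map(scene, static_model, stride=2)
        np.testing.assert_array_equal(m1.scores, m2.scores)

    def test_scene_too_small_and_channel_mismatch(self, static_model):
        with pytest.raises(ValueError, match="smaller"):
            compute_map(ImageGrid(np.zeros((10, 10, 1))), static_model)
        with pytest.raises(ValueError, match="channels"):
            compute_map(ImageGrid(np.zeros((40, 40, 3))), static_model)

    def test_planted_unpaired_burst_dominates_map(self, static_model):
        # write a strongly unpaired center pattern into an otherwise
        # training-mean scene: the map maximum must sit on it
        ica = static_model.ica
        rng = np.random.default_rng(4)
        s_u = 8.0 * np.sign(rng.standard_normal(ica.k_u))
        x_c, _ = ica.generate_pairs(np.zeros(ica.k_s), s_u)
        cfg = static_model.config
        center_mask, _ = make_masks(cfg)
        half = (cfg.window - 1) // 2
        scene = np.tile(ica.whiten_c.mean.mean(), (100, 100, 1))
        target = (50, 50)
        block = scene[
            target[0] - half : target[0] + half + 1,
            target[1] - half : target[1] + half + 1,
            0,
        ]
        # center mask sits in the middle of the full window grid
        block[center_mask] = x_c[0] if x_c.ndim > 1 else x_c
        m = compute_map(ImageGrid(scene), static_model)
        am = np.unravel_index(np.argmax(m.scores), m.shape)
        loc = (m.offset[0] + am[0], m.offset[1] + am[1])
        # argmax must be a window whose center mask sees the burst (two
        # center radii), and far windows must score far below it
        assert np.hypot(loc[0] - target[0], loc[1] - target[1]) <= 6
        rr = np.arange(m.shape[0])[:, None] + m.offset[0]
        cc = np.arange(m.shape[1])[None, :] + m.offset[1]
        far = np.hypot(rr - target[0], cc - target[1]) > cfg.window
        assert m.scores[far].max() < 0.2 * m.scores.max()


class TestPopOut:
    @pytest.mark.parametrize("kind", ["intensity", "orientation"])
    def test_singleton_attracts_global_argmax(self, static_model, kind):
        img, pos = gen_popout_image(kind, seed=4)
        m = compute_map(img, static_model)
        am = np.unravel_index(np.argmax(m.scores), m.shape)
        loc = (m.offset[0] + am[0] * m.stride, m.offset[1] + am[1] * m.stride)
        # within the singleton's center-mask footprint (radius 3)
        assert np.hypot(loc[0] - pos[0], loc[1] - pos[1]) <= 3.0


class TestVideoMaps:
    def test_first_context_frames_produce_no_map(self, video_model):
        seq, _ = gen_moving_dot_sequence(n_frames=6)
        maps = compute_video_maps(seq, video_model)
        depth = video_model.config.temporal_context
        assert len(maps) == 6 - depth
        assert maps[0].frame == depth

    def test_static_frames_give_identical_maps(self, video_model):
        frame = ImageGrid(np.random.default_rng(5).random((32, 40, 1)))
        seq = FrameSequence((frame,) * 4)
        maps = compute_video_maps(seq, video_model)
        for m in maps[1:]:
            np.testing.assert_array_equal(m.scores, maps[0].scores)

    def test_motion_onset_outscores_static_scene(self, video_model):
        rng = np.random.default_rng(6)
        a = ImageGrid(0.5 + 0.1 * rng.standard_normal((32, 40, 1)).clip(-2, 2))
        b = ImageGrid(np.roll(a.values, 4, axis=1))
        static = compute_video_maps(FrameSequence((a, a)), video_model)[0]
        onset = compute_video_maps(FrameSequence((a, b)), video_model)[0]
        assert onset.scores.max() > static.scores.max()

    def test_moving_dot_argmax_tracks_within_two_pixels(self, video_model):
        seq, truth = gen_moving_dot_sequence()
        for m in compute_video_maps(seq, video_model):
            am = np.unravel_index(np.argmax(m.scores), m.shape)
            loc = (m.offset[0] + am[0], m.offset[1] + am[1])
            tr = truth[m.frame]
            assert np.hypot(loc[0] - tr[0], loc[1] - tr[1]) <= 2.0

    def test_too_few_frames_rejected(self, video_model):
        seq, _ = gen_moving_dot_sequence(n_frames=2)
        with pytest.raises(ValueError, match="shorter"):
            compute_video_maps(FrameSequence(seq.frames[:1]), video_model)

    def test_static_model_and_video_model_are_not_interchangeable(
        self, static_model, video_model
    ):
        seq, _ = gen_moving_dot_sequence(n_frames=4)
        with pytest.raises(ValueError):
            compute_video_maps(seq, static_model)
        with pytest.raises(ValueError):
            compute_map(seq[0], video_model)


class TestRenderMap:
    def test_constant_map_renders_all_zero(self):
        assert np.all(render_map(np.full((4, 4), 7.0)) == 0)

    def test_monotone_rank_preservation(self):
        rng = np.random.default_rng(7)
        s = rng.random((6, 6)) * 50
        out = render_map(s, mode="minmax").astype(float)
        flat_s, flat_o = s.ravel(), out.ravel()
        order = np.argsort(flat_s)
        assert np.all(np.diff(flat_o[order]) >= 0)

    def test_percentile_mode_bounds_outliers(self):
        s = np.ones((10, 10))
        s[0, 0] = 1e6
        out = render_map(s, mode="percentile")
        assert out.max() == 255 and np.median(out) == 0

    def test_empty_and_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            render_map(np.zeros((0, 0)))
        with pytest.raises(ValueError):
            render_map(np.ones((2, 2)), mode="nope")


class TestSaliencyMapType:
    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            SaliencyMap(np.array([[-1.0]]), (0, 0), 1)

    def test_score_at_clamps_to_nearest_window(self):
        m = SaliencyMap(np.arange(12.0).reshape(3, 4), (5, 5), 2)
        assert m.score_at(0, 0) == 0.0  # clamped to first window
        assert m.score_at(9, 11) == 11.0  # clamped to last
        assert m.score_at(7, 7) == m.scores[1, 1]
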
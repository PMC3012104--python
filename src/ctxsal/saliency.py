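"""Dense saliency maps by sliding the target–context window over a scene.

For every valid window center on the stride grid the model computes the
unpaired amplitudes of the center patch given its surround (or preceding
frames) and converts them to the closed-form saliency score.  No smoothing
or normalization is applied to the map of record; an optional Gaussian
blur exists only for side-by-side comparison and is off by default.

Border policy is valid-only: the map is smaller than the scene and carries
the (row, col) offset of its first window center plus the stride, so
evaluation can map scene-coordinate fixations to the nearest scored window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import saliency_score
from .model import SaliencyModel
from .patches import apply_whitening, make_masks
from .scene_io import FrameSequence, ImageGrid

__all__ = ["SaliencyMap", "compute_map", "compute_video_maps", "render_map"]


@dataclass
class SaliencyMap:
    """A nonnegative score grid with enough metadata to index it from scene coords."""

    scores: np.ndarray  # h x w, >= 0, finite
    offset: tuple[int, int]  # scene coords of the first window center
    stride: int
    scene_id: str = ""
    frame: int | None = None

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ValueError("saliency scores must be finite and nonnegative")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        self.scores = s

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def score_at(self, row: int, col: int) -> float:
        """Score of the window nearest a scene-coordinate location.

        Locations outside the valid region take the nearest valid window's
        score (border fixations are never dropped).
        """
        r = int(np.clip(round((row - self.offset[0]) / self.stride), 0, self.shape[0] - 1))
        c = int(np.clip(round((col - self.offset[1]) / self.stride), 0, self.shape[1] - 1))
        return float(self.scores[r, c])


def _window_vectors(
    values: np.ndarray, centers_r: np.ndarray, centers_c: np.ndarray, mask: np.ndarray, half: int
) -> np.ndarray:
    """Gather masked window pixels for every center, channel-major columns."""
    mr, mc = np.nonzero(mask)
    dr, dc = mr - half, mc - half
    rows = centers_r[:, None] + dr[None, :]
    cols = centers_c[:, None] + dc[None, :]
    gathered = values[rows, cols, :]  # m x p x C
    m, p, c = gathered.shape
    return gathered.transpose(0, 2, 1).reshape(m, p * c)


def _score_grid(model: SaliencyModel, x_c: np.ndarray, x_s: np.ndarray, shape) -> np.ndarray:
    z = np.hstack(
        [apply_whitening(model.ica.whiten_c, x_c), apply_whitening(model.ica.whiten_s, x_s)]
    )
    u = z @ model.ica.W_u_joint.T + model.ica.diagnostics.get("residual_offset", 0.0)
    return np.asarray(saliency_score(u, model.gg)).reshape(shape)


def _center_grid(h: int, w: int, window: int, stride: int) -> tuple[np.ndarray, np.ndarray, int]:
    half = (window - 1) // 2
    if h < window or w < window:
        raise ValueError(f"scene {h}x{w} smaller than the {window}-pixel window")
    rs = np.arange(half, h - half, stride)
    cs = np.arange(half, w - half, stride)
    return rs, cs, half


def compute_map(
    scene: ImageGrid, model: SaliencyModel, stride: int = 1, scene_id: str = ""
) -> SaliencyMap:
    """Saliency map of a still scene: one score per valid window center."""
    cfg = model.config
    if not cfg.is_static:
        raise ValueError("model was trained on video volumes; use compute_video_maps")
    if scene.n_channels != cfg.channels:
        raise ValueError(
            f"scene has {scene.n_channels} channels, model expects {cfg.channels}"
        )
    h, w, _ = scene.shape
    rs, cs, half = _center_grid(h, w, cfg.window, stride)
    center_mask, surround_mask = make_masks(cfg)
    rr, cc = np.meshgrid(rs, cs, indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    x_c = _window_vectors(scene.values, rr, cc, center_mask, half)
    x_s = _window_vectors(scene.values, rr, cc, surround_mask, half)
    scores = _score_grid(model, x_c, x_s, (rs.size, cs.size))
    return SaliencyMap(scores, (int(rs[0]), int(cs[0])), stride, scene_id=scene_id)


def compute_video_maps(
    seq: FrameSequence, model: SaliencyModel, stride: int = 1, scene_id: str = ""
) -> list[SaliencyMap]:
    """One map per frame t >= temporal_context, preceding frames as context."""
    cfg = model.config
    if cfg.is_static:
        raise ValueError("model was trained on static patches; use compute_map")
    depth = cfg.temporal_context
    if len(seq) < cfg.temporal_depth:
        raise ValueError(
            f"sequence of {len(seq)} frames is shorter than temporal depth {cfg.temporal_depth}"
        )
    if seq.shape[2] != cfg.channels:
        raise ValueError(f"frames have {seq.shape[2]} channels, model expects {cfg.channels}")
    h, w, _ = seq.shape
    rs, cs, half = _center_grid(h, w, cfg.window, stride)
    center_mask, _ = make_masks(cfg)  # full square for video
    rr, cc = np.meshgrid(rs, cs, indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    maps = []
    for t in range(depth, len(seq)):
        x_c = _window_vectors(seq[t].values, rr, cc, center_mask, half)
        ctx = [
            _window_vectors(seq[t - depth + i].values, rr, cc, center_mask, half)
            for i in range(depth)
        ]  # oldest frame first, matching training order
        x_s = np.hstack(ctx)
        scores = _score_grid(model, x_c, x_s, (rs.size, cs.size))
        maps.append(
            SaliencyMap(scores, (int(rs[0]), int(cs[0])), stride, scene_id=scene_id, frame=t)
        )
    return maps


def render_map(map_or_scores, mode: str = "minmax") -> np.ndarray:
    """Monotone 8-bit rendering of a score grid for inspection.

    ``raw`` clips [0, 1] scores; ``minmax`` scales the full range (a
    constant map renders all-zero by convention); ``percentile`` clips at
    the 99th percentile before scaling, bounding outliers.
    """
    s = map_or_scores.scores if isinstance(map_or_scores, SaliencyMap) else map_or_scores
    s = np.atleast_2d(np.asarray(s, dtype=float))
    if s.size == 0:
        raise ValueError("empty saliency map")
    if mode == "raw":
        out = np.clip(s, 0.0, 1.0)
    elif mode == "minmax":
        lo, hi = s.min(), s.max()
        out = np.zeros_like(s) if hi == lo else (s - lo) / (hi - lo)
    elif mode == "percentile":
        lo, hi = s.min(), np.percentile(s, 99)
        clipped = np.minimum(s, hi)
        out = np.zeros_like(s) if hi == lo else (clipped - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown render mode {mode!r}")
    return np.round(out * 255).astype(np.uint8)
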
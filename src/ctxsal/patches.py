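"""Center–surround masks, target–context patch sampling, and PCA whitening.

The static configuration pairs a circular *center* (the target) with the
annular *surround* (the context) around it.  A pixel belongs to the center
iff its Euclidean distance from the central pixel is at most
``(center_diameter - 1) / 2``; the surround is the annulus out to
``(surround_diameter - 1) / 2``.  On the integer lattice this rule yields
149 center and 1368 surround pixels for diameters (15, 45), and 29 / 348
pixels (87 / 1044 values over three channels) for diameters (7, 23).

The spatiotemporal configuration takes full square windows: the current
frame is the target and the ``temporal_depth - 1`` preceding frames are the
context (11x11x4 volumes give a 363-dimensional target and 1089-dimensional
context for color video).

Vectorization order is fixed and channel-major: all masked pixels of
channel 0 in row-major order, then channel 1, then channel 2; video context
frames are stacked oldest first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scene_io import FrameSequence, ImageGrid

__all__ = [
    "PatchConfig",
    "PatchBatch",
    "WhitenTransform",
    "make_masks",
    "extract_patch_at",
    "sample_patches",
    "augment_mirror",
    "fit_whitening",
    "apply_whitening",
    "unapply_whitening",
]


@dataclass(frozen=True)
class PatchConfig:
    """Geometry of the target–context window.

    ``temporal_depth`` = 1 selects the static center/surround layout;
    depth >= 2 selects the video layout (square windows, preceding frames
    as context, ``surround_diameter`` unused).  ``explicit_radii`` overrides
    the default half-diameter-minus-half mask rule with given
    (center_radius, surround_radius).
    """

    center_diameter: int = 15
    surround_diameter: int = 45
    channels: int = 1
    temporal_depth: int = 1
    explicit_radii: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        if self.temporal_depth < 1:
            raise ValueError("temporal_depth must be >= 1")
        if self.center_diameter % 2 == 0 or self.surround_diameter % 2 == 0:
            raise ValueError("diameters must be odd")
        if self.is_static and self.surround_diameter <= self.center_diameter:
            raise ValueError("surround_diameter must exceed center_diameter")

    @property
    def is_static(self) -> bool:
        return self.temporal_depth == 1

    @property
    def temporal_context(self) -> int:
        return self.temporal_depth - 1

    @property
    def window(self) -> int:
        """Spatial extent of the full window in pixels."""
        return self.surround_diameter if self.is_static else self.center_diameter

    @property
    def d_center(self) -> int:
        if self.is_static:
            return int(make_masks(self)[0].sum()) * self.channels
        return self.center_diameter**2 * self.channels

    @property
    def d_context(self) -> int:
        if self.is_static:
            return int(make_masks(self)[1].sum()) * self.channels
        return self.center_diameter**2 * self.channels * self.temporal_context


@dataclass
class PatchBatch:
    """Paired matrices of vectorized target (X_c) and context (X_s) patches."""

    X_c: np.ndarray
    X_s: np.ndarray
    provenance: list[tuple[str, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X_c = np.atleast_2d(np.asarray(self.X_c, dtype=float))
        self.X_s = np.atleast_2d(np.asarray(self.X_s, dtype=float))
        if self.X_c.shape[0] != self.X_s.shape[0]:
            raise ValueError(
                f"target and context row counts differ: {self.X_c.shape[0]} vs {self.X_s.shape[0]}"
            )
        if not (np.all(np.isfinite(self.X_c)) and np.all(np.isfinite(self.X_s))):
            raise ValueError("patch batch contains non-finite values")

    @property
    def n(self) -> int:
        return self.X_c.shape[0]


def make_masks(cfg: PatchConfig) -> tuple[np.ndarray, np.ndarray]:
    """Boolean center and surround masks on a ``window x window`` grid.

    Masks are disjoint by construction; for video configurations the center
    mask is the full square and the surround mask is empty (context comes
    from preceding frames instead).
    """
    w = cfg.window
    if not cfg.is_static:
        full = np.ones((w, w), dtype=bool)
        return full, np.zeros((w, w), dtype=bool)
    if cfg.explicit_radii is not None:
        r_c, r_s = cfg.explicit_radii
    else:
        r_c = (cfg.center_diameter - 1) / 2.0
        r_s = (cfg.surround_diameter - 1) / 2.0
    mid = (w - 1) // 2
    yy, xx = np.mgrid[0:w, 0:w]
    d2 = (yy - mid) ** 2 + (xx - mid) ** 2
    center = d2 <= r_c**2
    surround = (d2 > r_c**2) & (d2 <= r_s**2)
    return center, surround


def _vectorize(patch: np.ndarray, mask: np.ndarray) -> np.ndarray:
    # channel-major: all masked pixels of channel 0, then 1, then 2
    return patch[mask].T.reshape(-1)


def extract_patch_at(
    scene: ImageGrid | FrameSequence,
    row: int,
    col: int,
    cfg: PatchConfig,
    frame: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the (target, context) vector pair for a window centered at (row, col).

    ``(row, col)`` is the central pixel; the full window must fit inside the
    scene.  For video, ``frame`` indexes the target frame and must leave
    ``temporal_depth - 1`` preceding frames available.
    """
    half = (cfg.window - 1) // 2
    if cfg.is_static:
        if not isinstance(scene, ImageGrid):
            raise TypeError("static configuration requires an ImageGrid")
        v = scene.values
    else:
        if not isinstance(scene, FrameSequence):
            raise TypeError("video configuration requires a FrameSequence")
        if frame is None:
            raise ValueError("video extraction requires a target frame index")
        if frame < cfg.temporal_context or frame >= len(scene):
            raise IndexError(
                f"target frame {frame} needs {cfg.temporal_context} preceding frames"
            )
        v = scene[frame].values
    h, w, c = v.shape
    if c != cfg.channels:
        raise ValueError(f"scene has {c} channels, config expects {cfg.channels}")
    if not (half <= row < h - half and half <= col < w - half):
        raise IndexError(f"window at ({row}, {col}) exceeds scene bounds {h}x{w}")
    sl = np.s_[row - half : row + half + 1, col - half : col + half + 1]
    center_mask, surround_mask = make_masks(cfg)
    x_c = _vectorize(v[sl], center_mask)
    if cfg.is_static:
        x_s = _vectorize(v[sl], surround_mask)
    else:
        ctx = [
            _vectorize(scene[frame - cfg.temporal_context + i].values[sl], center_mask)
            for i in range(cfg.temporal_context)
        ]  # oldest frame first
        x_s = np.concatenate(ctx)
    return x_c, x_s


def sample_patches(
    scenes: list[tuple[str, ImageGrid | FrameSequence]],
    cfg: PatchConfig,
    n: int,
    seed: int,
) -> PatchBatch:
    """Draw ``n`` patch pairs uniformly over all valid window positions.

    Windows overlapping the scene border (or lacking temporal context) are
    excluded; no padding is used during training.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    half = (cfg.window - 1) // 2
    valid: list[tuple[int, int, int, int, int]] = []  # scene idx, row lo/hi, col lo/hi
    frames: list[tuple[int, int]] = []  # frame lo/hi per scene
    for idx, (_, scene) in enumerate(scenes):
        if cfg.is_static:
            h, w, _ = scene.shape
            f_lo, f_hi = 0, 0
        else:
            h, w, _ = scene.shape
            f_lo, f_hi = cfg.temporal_context, len(scene) - 1
            if f_hi < f_lo:
                continue
        if h < cfg.window or w < cfg.window:
            continue
        valid.append((idx, half, h - half - 1, half, w - half - 1))
        frames.append((f_lo, f_hi))
    if not valid:
        raise ValueError("no scene admits a valid window for this configuration")

    # uniform over (scene, row, col[, frame]) triples, weighted by window count
    counts = np.array(
        [
            (r1 - r0 + 1) * (c1 - c0 + 1) * (f[1] - f[0] + 1)
            for (_, r0, r1, c0, c1), f in zip(valid, frames)
        ],
        dtype=float,
    )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(valid), size=n, p=counts / counts.sum())
    xcs, xss, prov = [], [], []
    for p in picks:
        idx, r0, r1, c0, c1 = valid[p]
        f0, f1 = frames[p]
        row = int(rng.integers(r0, r1 + 1))
        col = int(rng.integers(c0, c1 + 1))
        frm = int(rng.integers(f0, f1 + 1))
        scene_id, scene = scenes[idx]
        x_c, x_s = extract_patch_at(scene, row, col, cfg, frame=None if cfg.is_static else frm)
        xcs.append(x_c)
        xss.append(x_s)
        prov.append((scene_id, row, col, frm))
    return PatchBatch(np.array(xcs), np.array(xss), prov)


def _mirror_permutation(cfg: PatchConfig, flip_r: bool, flip_c: bool) -> tuple[np.ndarray, np.ndarray]:
    """Index permutations realizing a spatial flip on (x_c, x_s) vectors.

    Both masks are mirror symmetric, so a flip permutes the vectorized
    layout; the permutation respects the channel-major (and frame-major)
    stacking order.
    """
    center_mask, surround_mask = make_masks(cfg)

    def mask_perm(mask: np.ndarray) -> np.ndarray:
        coords = np.argwhere(mask)
        lookup = {tuple(rc): i for i, rc in enumerate(coords)}
        w = mask.shape[0] - 1
        return np.array(
            [
                lookup[(w - r if flip_r else r, w - c if flip_c else c)]
                for r, c in coords
            ]
        )

    def tile(perm: np.ndarray, blocks: int) -> np.ndarray:
        p = perm.size
        return np.concatenate([perm + b * p for b in range(blocks)])

    perm_c = tile(mask_perm(center_mask), cfg.channels)
    if cfg.is_static:
        perm_s = tile(mask_perm(surround_mask), cfg.channels)
    else:
        perm_s = tile(mask_perm(center_mask), cfg.channels * cfg.temporal_context)
    return perm_c, perm_s


def augment_mirror(batch: PatchBatch, cfg: PatchConfig) -> PatchBatch:
    """Quadruple a batch with its left-right, up-down and 180-degree flips.

    Enforces the mirror symmetry of the scene ensemble exactly in the
    training sample, so fitted filters respond symmetrically to symmetric
    stimuli instead of inheriting sampling noise.
    """
    perms = [_mirror_permutation(cfg, fr, fc) for fr, fc in ((True, False), (False, True), (True, True))]
    X_c = np.vstack([batch.X_c] + [batch.X_c[:, pc] for pc, _ in perms])
    X_s = np.vstack([batch.X_s] + [batch.X_s[:, ps] for _, ps in perms])
    return PatchBatch(X_c, X_s, list(batch.provenance) * 4)


@dataclass(frozen=True)
class WhitenTransform:
    """PCA whitening: x -> forward @ (x - mean), with pseudo-inverse back-map.

    ``forward`` rows are ordered by decreasing explained variance; projected
    training data has identity covariance (sample covariance, ddof=1).
    """

    mean: np.ndarray
    forward: np.ndarray  # k x d
    inverse: np.ndarray  # d x k
    retained_k: int
    explained_variance: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.forward.shape[1]


def fit_whitening(X: np.ndarray, k: int) -> WhitenTransform:
    """Fit a rank-``k`` PCA whitening transform to the rows of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}]")
    if n <= k:
        raise ValueError("need more samples than retained components")
    mean = X.mean(axis=0)
    _, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    var = s**2 / (n - 1)
    rank = int(np.sum(s > s[0] * 1e-10)) if s[0] > 0 else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds the achievable rank {rank} of the centered data")
    scale = np.sqrt(var[:k])
    forward = Vt[:k] / scale[:, None]
    inverse = Vt[:k].T * scale[None, :]
    return WhitenTransform(mean, forward, inverse, k, var[:k])


def apply_whitening(t: WhitenTransform, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        return t.forward @ (X - t.mean)
    return (X - t.mean) @ t.forward.T


def unapply_whitening(t: WhitenTransform, Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        return t.inverse @ Z + t.mean
    return Z @ t.inverse.T + t.mean
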
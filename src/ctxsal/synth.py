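"""Synthetic inputs for building and testing the whole pipeline offline.

Three families of generators:

* samples from the planted block-triangular source model (ground-truth
  mixings and sources returned for parameter-recovery oracles);
* rendered stimuli — Gabor-texture scenes for training toy models,
  pop-out singleton arrays, and moving-dot frame sequences with known
  ground-truth locations;
* map-proportional synthetic fixations, the evaluation oracle: observers
  that fixate exactly where a map says they should.

Everything is deterministic under a seed and rendered analytically — no
texture files, no downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patches import PatchBatch
from .saliency import SaliencyMap
from .scene_io import FixationRecord, FixationSet, FrameSequence, ImageGrid

__all__ = [
    "PlantedModel",
    "gen_structured_samples",
    "gen_popout_image",
    "gen_moving_dot_sequence",
    "gen_fixations_from_map",
    "gen_texture_scene",
    "gen_translating_sequence",
    "gen_anomaly_scene",
    "make_demo_static_model",
    "make_demo_video_model",
]


@dataclass(frozen=True)
class PlantedModel:
    """Ground-truth mixing blocks and source families for the planted model.

    x_s = A_ss s_s and x_c = A_cs s_s + A_cu s_u, with every source group
    i.i.d. from a stated generalized-Gaussian family.  Laplace (beta = 1)
    is the default: sharply peaked at zero with long tails, the regime
    where ICA is well identified.
    """

    d_c: int
    d_s: int
    k_s: int
    k_u: int
    A_ss: np.ndarray
    A_cs: np.ndarray
    A_cu: np.ndarray
    context_beta: float = 1.0
    unpaired_beta: float = 1.0
    source_scale: float = 1.0

    @classmethod
    def random(
        cls,
        d_c: int = 12,
        d_s: int = 16,
        k_s: int = 8,
        k_u: int = 4,
        seed: int = 0,
        context_beta: float = 1.0,
        unpaired_beta: float = 1.0,
        paired_strength: float = 1.0,
    ) -> "PlantedModel":
        rng = np.random.default_rng(seed)
        A_ss = rng.standard_normal((d_s, k_s))
        A_cs = paired_strength * rng.standard_normal((d_c, k_s))
        A_cu = rng.standard_normal((d_c, k_u))
        pm = cls(d_c, d_s, k_s, k_u, A_ss, A_cs, A_cu,
                 context_beta=context_beta, unpaired_beta=unpaired_beta)
        pm.validate()
        return pm

    def validate(self) -> None:
        if np.linalg.matrix_rank(self.A_ss) < self.k_s:
            raise ValueError("A_ss is rank deficient")
        if np.linalg.matrix_rank(self.A_cu) < self.k_u:
            raise ValueError("A_cu is rank deficient")


def _gg_samples(rng: np.random.Generator, beta: float, scale: float, size) -> np.ndarray:
    # standard generalized Gaussian via gamma variates: |u|^beta ~ Gamma(1/beta)
    g = rng.gamma(1.0 / beta, 1.0, size=size)
    signs = rng.choice([-1.0, 1.0], size=size)
    return scale * signs * g ** (1.0 / beta)


def gen_structured_samples(
    pm: PlantedModel, n: int, seed: int = 0
) -> tuple[PatchBatch, np.ndarray, np.ndarray]:
    """Draw n pairs from the planted model; returns (batch, s_s, s_u)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pm.validate()
    rng = np.random.default_rng(seed)
    s_s = _gg_samples(rng, pm.context_beta, pm.source_scale, (n, pm.k_s))
    s_u = _gg_samples(rng, pm.unpaired_beta, pm.source_scale, (n, pm.k_u))
    X_s = s_s @ pm.A_ss.T
    X_c = s_s @ pm.A_cs.T + s_u @ pm.A_cu.T
    prov = [("planted", i, 0, 0) for i in range(n)]
    return PatchBatch(X_c, X_s, prov), s_s, s_u


def _gabor(size: int, theta: float, wavelength: float, sigma: float, phase: float = 0.0):
    half = (size - 1) / 2.0
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    xr = x * np.cos(theta) + y * np.sin(theta)
    env = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    return env * np.cos(2.0 * np.pi * xr / wavelength + phase)


# Shared texture-array geometry: element footprint and grid pitch chosen so
# that a 31-pixel surround annulus around any element contains its neighbors
# — the context must see the neighbors for orientation contrast to exist.
ELEMENT_SIZE = 9
SPACING = 12


def _place_gabor(img: np.ndarray, r: int, c: int, theta: float, amp: float) -> None:
    img[r : r + ELEMENT_SIZE, c : c + ELEMENT_SIZE] += amp * _gabor(
        ELEMENT_SIZE, theta, ELEMENT_SIZE / 1.8, ELEMENT_SIZE / 4.0
    )


def gen_texture_scene(
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    orientation_coherence: float = 0.9,
    jitter: int = 2,
    channels: int = 1,
    base_theta: float | None = None,
) -> ImageGrid:
    """A jittered grid of oriented Gabor elements on mid-grey.

    Orientations follow a smooth global field with occasional random
    outliers, so the orientation of an element's neighbors statistically
    predicts its own — the structure the paired target components latch
    onto.  Random amplitudes and signs keep the patch statistics
    heavy-tailed, the regime in which kurtosis-based ICA is identified.
    """
    h, w = shape
    rng = np.random.default_rng(seed)
    img = np.zeros((h, w))
    if base_theta is None:
        base_theta = rng.uniform(0, np.pi)
    else:
        rng.uniform(0, np.pi)  # keep the stream aligned with the random-base case
    freq_r, freq_c = rng.uniform(0.3, 1.5, size=2)
    for i in range(0, (h - ELEMENT_SIZE) // SPACING + 1):
        for j in range(0, (w - ELEMENT_SIZE) // SPACING + 1):
            r = int(np.clip(i * SPACING + rng.integers(-jitter, jitter + 1), 0, h - ELEMENT_SIZE))
            c = int(np.clip(j * SPACING + rng.integers(-jitter, jitter + 1), 0, w - ELEMENT_SIZE))
            theta = base_theta + 0.6 * np.sin(2 * np.pi * (freq_r * r / h + freq_c * c / w))
            if rng.random() > orientation_coherence:
                theta = rng.uniform(0, np.pi)
            amp = rng.uniform(0.25, 0.45) * rng.choice([-1.0, 1.0])
            _place_gabor(img, r, c, theta, amp)
    img = np.clip(0.5 + img, 0.0, 1.0)
    if channels == 3:
        img = np.repeat(img[:, :, None], 3, axis=2)
    return ImageGrid(img)


def gen_popout_image(
    kind: str,
    grid_shape: tuple[int, int] = (9, 9),
    singleton_pos: tuple[int, int] | None = None,
    seed: int = 0,
    margin: int = 2,
) -> tuple[ImageGrid, tuple[int, int]]:
    """An array of identical elements with one differing in a single attribute.

    ``kind`` is ``orientation`` (one element rotated 90 degrees),
    ``intensity`` (one bright dot among dim dots) or ``color`` (one
    red-tinted element among green).  Returns the image and the scene
    coordinates of the singleton's center — the ground truth a saliency
    map should point at.  Element size and pitch match
    :func:`gen_texture_scene`, keeping the background in-distribution for
    a model trained on those textures; elements fill the canvas to the
    border so the singleton, not the array boundary, is the only anomaly,
    and the singleton sits well inside the array.
    """
    if kind not in ("orientation", "intensity", "color"):
        raise ValueError(f"unknown pop-out kind {kind!r}")
    rows, cols = grid_shape
    rng = np.random.default_rng(seed)
    if singleton_pos is None:
        singleton_pos = (int(rng.integers(3, rows - 3)), int(rng.integers(3, cols - 3)))
    sr, sc = singleton_pos
    if not (0 <= sr < rows and 0 <= sc < cols):
        raise ValueError("singleton position outside the element grid")
    es = ELEMENT_SIZE
    h = 2 * margin + (rows - 1) * SPACING + es
    w = 2 * margin + (cols - 1) * SPACING + es
    channels = 3 if kind == "color" else 1
    img = np.full((h, w, channels), 0.5)

    base_theta = np.pi / 4.0
    for i in range(rows):
        for j in range(cols):
            r0 = margin + i * SPACING
            c0 = margin + j * SPACING
            is_singleton = (i, j) == (sr, sc)
            if kind == "orientation":
                theta = base_theta + (np.pi / 2.0 if is_singleton else 0.0)
                _place_gabor(img[:, :, 0], r0, c0, theta, 0.35)
            elif kind == "intensity":
                level = 0.45 if is_singleton else 0.12
                half = (es - 1) / 2.0
                y, x = np.mgrid[-half : half + 1, -half : half + 1]
                dot = level * np.exp(-(x**2 + y**2) / (2.0 * (es / 6.0) ** 2))
                img[r0 : r0 + es, c0 : c0 + es, 0] += dot
            else:  # color
                patch = 0.35 * np.abs(_gabor(es, base_theta, es / 1.8, es / 4.0))
                ch = 0 if is_singleton else 1  # red singleton among green
                img[r0 : r0 + es, c0 : c0 + es, ch] += patch
    img = np.clip(img, 0.0, 1.0)
    center = (margin + sr * SPACING + (es - 1) // 2, margin + sc * SPACING + (es - 1) // 2)
    return ImageGrid(img), center


def gen_translating_sequence(
    n_frames: int = 10,
    shape: tuple[int, int] = (64, 80),
    seed: int = 0,
    max_speed: int = 2,
    channels: int = 1,
) -> FrameSequence:
    """A texture scene drifting rigidly at a constant random velocity.

    Crops a moving window out of one large texture, so preceding frames
    predict the current frame up to the drift — the temporal analogue of
    the surround predicting the center.
    """
    rng = np.random.default_rng(seed)
    vr, vc = rng.integers(-max_speed, max_speed + 1, size=2)
    h, w = shape
    big = gen_texture_scene(
        (h + abs(int(vr)) * n_frames + 2, w + abs(int(vc)) * n_frames + 2),
        seed=seed + 1,
        channels=channels,
    )
    r0 = 0 if vr >= 0 else abs(int(vr)) * (n_frames - 1)
    c0 = 0 if vc >= 0 else abs(int(vc)) * (n_frames - 1)
    frames = []
    for t in range(n_frames):
        r = r0 + int(vr) * t
        c = c0 + int(vc) * t
        frames.append(ImageGrid(big.values[r : r + h, c : c + w]))
    return FrameSequence(tuple(frames))


def gen_moving_dot_sequence(
    n_frames: int = 12,
    shape: tuple[int, int] = (48, 64),
    start: tuple[int, int] = (24, 10),
    velocity: tuple[float, float] = (0.0, 3.0),
    dot_sigma: float = 1.5,
    amplitude: float = 0.45,
    frame_rate: float = 30.0,
) -> tuple[FrameSequence, list[tuple[int, int]]]:
    """A bright Gaussian dot translating at constant velocity on mid-grey.

    Returns the sequence and the dot's integer center per frame (the
    tracking oracle for video saliency maps).
    """
    h, w = shape
    frames = []
    truth = []
    yy, xx = np.mgrid[0:h, 0:w]
    for t in range(n_frames):
        r = start[0] + velocity[0] * t
        c = start[1] + velocity[1] * t
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("dot leaves the frame; shorten the sequence or slow it down")
        img = 0.5 + amplitude * np.exp(
            -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * dot_sigma**2)
        )
        frames.append(ImageGrid(np.clip(img, 0.0, 1.0)[:, :, None]))
        truth.append((int(round(r)), int(round(c))))
    return FrameSequence(tuple(frames), frame_rate=frame_rate), truth


def gen_fixations_from_map(
    smap: SaliencyMap, n: int, seed: int = 0, scene_id: str | None = None
) -> FixationSet:
    """Sample n fixations with probability proportional to map scores.

    The synthetic observer realizes the hypothesis the metrics test: gaze
    lands where the model says saliency is high.  Coordinates are reported
    in scene coordinates (map offset and stride applied).
    """
    scores = smap.scores.ravel()
    total = scores.sum()
    if total <= 0:
        raise ValueError("map has no positive mass to sample fixations from")
    rng = np.random.default_rng(seed)
    idx = rng.choice(scores.size, size=n, p=scores / total)
    rr, cc = np.unravel_index(idx, smap.shape)
    sid = scene_id if scene_id is not None else smap.scene_id
    return FixationSet(
        [
            FixationRecord(
                sid,
                int(smap.offset[0] + r * smap.stride),
                int(smap.offset[1] + c * smap.stride),
                smap.frame,
            )
            for r, c in zip(rr, cc)
        ]
    )


def gen_anomaly_scene(
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
    n_anomalies: int = 4,
) -> tuple[ImageGrid, list[tuple[int, int]]]:
    """A coherent texture scene with a few planted orientation anomalies.

    Like :func:`gen_texture_scene` but with ``n_anomalies`` elements
    rotated 90 degrees and slightly brightened — localized deviations a
    context-mediated model should flag.  Returns the scene and the anomaly
    centers, the ground truth for evaluation harnesses where synthetic
    observers should concentrate.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.zeros((h, w))
    base = rng.uniform(0, np.pi)
    freq_r, freq_c = rng.uniform(0.3, 1.5, size=2)
    cells = [
        (i, j)
        for i in range(0, (h - ELEMENT_SIZE) // SPACING + 1)
        for j in range(0, (w - ELEMENT_SIZE) // SPACING + 1)
    ]
    anom = set(
        map(tuple, np.array(cells)[rng.choice(len(cells), n_anomalies, replace=False)])
    )
    centers = []
    for i, j in cells:
        r = int(np.clip(i * SPACING + rng.integers(-2, 3), 0, h - ELEMENT_SIZE))
        c = int(np.clip(j * SPACING + rng.integers(-2, 3), 0, w - ELEMENT_SIZE))
        theta = base + 0.6 * np.sin(2 * np.pi * (freq_r * r / h + freq_c * c / w))
        amp = rng.uniform(0.25, 0.45) * rng.choice([-1.0, 1.0])
        if (i, j) in anom:
            theta += np.pi / 2.0
            amp = 0.5 * np.sign(amp)
            centers.append((r + (ELEMENT_SIZE - 1) // 2, c + (ELEMENT_SIZE - 1) // 2))
        _place_gabor(img, r, c, theta, amp)
    return ImageGrid(np.clip(0.5 + img, 0.0, 1.0)[:, :, None]), centers


def make_demo_static_model(seed: int = 0, n_scenes: int = 12, n_patches: int = 25000):
    """Train the reference static toy model on Gabor-texture scenes.

    The study conditions for the desk-scale harness: center/surround
    diameters 7/31 (so the surround annulus covers neighboring texture
    elements), 20/50 retained principal components, 15 unpaired
    components, 25k patches from 12 scenes of 128x128.  Scene base
    orientations are stratified over [0, pi) so the ensemble is
    orientation-balanced — a model trained on a lopsided orientation diet
    cannot judge orientation contrast.  Returns (model, scenes) with
    scenes as (scene_id, ImageGrid) pairs.
    """
    from .model import train_model
    from .patches import PatchConfig, sample_patches

    cfg = PatchConfig(center_diameter=7, surround_diameter=31, channels=1)
    rng = np.random.default_rng(seed)
    scenes = [
        (
            f"tex{i:02d}",
            gen_texture_scene(
                (128, 128),
                seed=seed * 1000 + i,
                base_theta=(i + rng.random()) * np.pi / n_scenes,
            ),
        )
        for i in range(n_scenes)
    ]
    batch = sample_patches(scenes, cfg, n_patches, seed=seed + 11)
    model = train_model(batch, cfg, k_c=20, k_s=50, k_u=15, seed=seed + 2)
    return model, scenes


def make_demo_video_model(seed: int = 0, n_sequences: int = 8, n_patches: int = 20000):
    """Train the reference spatiotemporal toy model on drifting textures.

    Conditions: 11x11 windows, temporal depth 2 (one context frame),
    textures drifting at up to 1 px/frame — a mostly-static world in which
    faster motion is the unexplained, salient deviation.  Training patches
    are mirror-augmented so filters respond symmetrically.  Returns
    (model, sequences).
    """
    from .model import train_model
    from .patches import PatchConfig, augment_mirror, sample_patches

    cfg = PatchConfig(
        center_diameter=11, surround_diameter=13, channels=1, temporal_depth=2
    )
    seqs = [
        (
            f"clip{i:02d}",
            gen_translating_sequence(
                n_frames=10, shape=(64, 80), seed=seed * 1000 + i, max_speed=1
            ),
        )
        for i in range(n_sequences)
    ]
    batch = augment_mirror(sample_patches(seqs, cfg, n_patches, seed=seed + 11), cfg)
    model = train_model(batch, cfg, k_c=25, k_s=25, k_u=25, seed=seed + 2)
    return model, seqs
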
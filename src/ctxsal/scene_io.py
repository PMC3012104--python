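"""Image, frame-sequence, fixation and saliency-map I/O plus intensity preprocessing.

Scenes are held as :class:`ImageGrid` — an ``H x W x C`` float array in
either linear intensity (as decoded from disk, scaled to [0, 1]) or
log intensity (after :func:`to_log_luminance`).  Videos are directories of
frame images, read into a :class:`FrameSequence`; no codec handling is done.
Fixations travel as CSV with columns ``scene_id,frame,row,col`` (frame empty
for still images), coordinates 0-based with origin at the top-left pixel.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "ImageGrid",
    "FrameSequence",
    "FixationRecord",
    "FixationSet",
    "load_image",
    "to_log_luminance",
    "block_average",
    "read_fixations",
    "write_fixations",
    "save_map_csv",
    "load_map_csv",
    "save_map_png",
]

LINEAR = "linear-intensity"
LOG = "log-intensity"


@dataclass(frozen=True)
class ImageGrid:
    """A scene held as an H x W x C array of finite reals.

    ``pixel_unit`` records whether values are linear intensities in [0, 1]
    or natural-log intensities, so that the preprocessing order
    (block-average first, then log) can be asserted downstream.
    """

    values: np.ndarray
    pixel_unit: str = LINEAR

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 2:
            v = v[:, :, None]
        if v.ndim != 3 or v.shape[2] not in (1, 3):
            raise ValueError(f"expected H x W x C with C in {{1,3}}, got shape {v.shape}")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("empty image")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        if self.pixel_unit not in (LINEAR, LOG):
            raise ValueError(f"unknown pixel unit {self.pixel_unit!r}")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class FrameSequence:
    """An ordered, uniformly shaped list of frames with a nominal frame rate."""

    frames: tuple[ImageGrid, ...]
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise ValueError("empty frame sequence")
        shape = frames[0].shape
        for f in frames:
            if f.shape != shape:
                raise ValueError("all frames must share one shape")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> ImageGrid:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames[0].shape

    def subsample(self, step: int) -> "FrameSequence":
        """Keep every ``step``-th frame (temporal decimation before sampling)."""
        if step < 1:
            raise ValueError("step must be >= 1")
        return FrameSequence(self.frames[::step], frame_rate=self.frame_rate / step)


@dataclass(frozen=True)
class FixationRecord:
    scene_id: str
    row: int
    col: int
    frame: int | None = None


@dataclass
class FixationSet:
    """Gaze coordinates grouped by scene (and optionally frame)."""

    records: list[FixationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FixationSet) and self.records == other.records

    def scene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.scene_id, None)
        return list(seen)

    def for_scene(self, scene_id: str) -> list[FixationRecord]:
        return [r for r in self.records if r.scene_id == scene_id]


def load_image(path: str | os.PathLike) -> ImageGrid:
    """Read a PNG/PGM/PPM image and scale it to [0, 1] linear intensity."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface decoder failures with the path
        raise IOError(f"cannot decode image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(float) / scale
    else:
        arr = arr.astype(float)
    return ImageGrid(arr, LINEAR)


def save_image(img: ImageGrid, path: str | os.PathLike) -> None:
    """Write an 8-bit rendering of a linear-intensity grid."""
    v = np.clip(img.values, 0.0, 1.0)
    out = np.round(v * 255).astype(np.uint8)
    if out.shape[2] == 1:
        out = out[:, :, 0]
    iio.imwrite(Path(path), out)


def load_frame_dir(path: str | os.PathLike, frame_rate: float = 30.0) -> FrameSequence:
    """Read a directory of frame images, sorted by filename."""
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".png", ".pgm", ".ppm"))
    if not files:
        raise IOError(f"no frame images found in {path}")
    return FrameSequence(tuple(load_image(p) for p in files), frame_rate=frame_rate)


def to_log_luminance(img: ImageGrid, epsilon: float = 1.0 / 255.0) -> ImageGrid:
    """Map each linear intensity v to ln(v + epsilon).

    The offset keeps the transform defined at v = 0 while preserving
    monotonicity; it approximates one quantization step of 8-bit data.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if img.pixel_unit != LINEAR:
        raise ValueError("to_log_luminance expects linear-intensity input")
    return ImageGrid(np.log(img.values + epsilon), LOG)


def block_average(img: ImageGrid, factor: int, crop: bool = False) -> ImageGrid:
    """Downsample by averaging disjoint ``factor x factor`` blocks.

    Applied before the log transform when emulating the reduced-resolution
    training pipeline (1536x1024 -> 768x512 at factor 2).
    """
    if not isinstance(factor, (int, np.integer)) or factor <= 0:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return img
    h, w, c = img.shape
    if (h % factor or w % factor) and not crop:
        raise ValueError(
            f"image {h}x{w} not divisible by factor {factor}; pass crop=True to trim"
        )
    h2, w2 = h // factor, w // factor
    v = img.values[: h2 * factor, : w2 * factor]
    v = v.reshape(h2, factor, w2, factor, c).mean(axis=(1, 3))
    return ImageGrid(v, img.pixel_unit)


def write_fixations(fs: FixationSet, path: str | os.PathLike) -> None:
    rows = [
        {
            "scene_id": r.scene_id,
            "frame": "" if r.frame is None else int(r.frame),
            "row": int(r.row),
            "col": int(r.col),
        }
        for r in fs.records
    ]
    df = pd.DataFrame(rows, columns=["scene_id", "frame", "row", "col"])
    df.to_csv(path, index=False)


def read_fixations(path: str | os.PathLike) -> FixationSet:
    try:
        df = pd.read_csv(path, dtype={"scene_id": str}, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read fixation CSV {path}: {exc}") from exc
    expected = ["scene_id", "frame", "row", "col"]
    if list(df.columns) != expected:
        raise ValueError(f"fixation CSV must have header {expected}, got {list(df.columns)}")
    records: list[FixationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        frame_raw = str(row.frame).strip()
        try:
            frame = None if frame_raw == "" else int(frame_raw)
            r, c = int(str(row.row)), int(str(row.col))
        except ValueError as exc:
            raise ValueError(f"malformed fixation row at line {i}: {exc}") from exc
        if r < 0 or c < 0 or (frame is not None and frame < 0):
            raise ValueError(f"negative coordinate at line {i}")
        records.append(FixationRecord(str(row.scene_id), r, c, frame))
    return FixationSet(records)


def save_map_csv(scores: np.ndarray, path: str | os.PathLike) -> None:
    """Persist a saliency score grid as a plain float CSV (format of record)."""
    np.savetxt(path, np.asarray(scores, dtype=float), delimiter=",")


def load_map_csv(path: str | os.PathLike) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def save_map_png(scores: np.ndarray, path: str | os.PathLike, mode: str = "minmax") -> None:
    """Write an 8-bit rendering of a score grid for visual inspection."""
    from .saliency import render_map  # local import to avoid a cycle

    iio.imwrite(Path(path), render_map(scores, mode=mode))
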
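"""Video decoding and frame-clock arithmetic.

A :class:`VideoClip` is the pipeline's raw input: an ordered stack of 2-D
grayscale rasters plus a trustworthy frame rate.  Helpers here convert
color frames to luminance, compute the per-frame duration (with an optional
truncated-constant compatibility mode), the slow-motion rescaling factor
used when intervals are measured on re-rendered footage, and nearest-frame
resampling to a lower rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import avi
from .errors import EmptyVideoError, MetadataError, VideoDecodeError


@dataclass
class VideoClip:
    """Decoded grayscale frame stack with fps metadata.

    frames is a (n_frames, height, width) uint8 array; values are grey
    levels in [0, 255].  Frame i's timestamp is ``i / fps`` (first frame at
    t = 0).
    """

    frames: np.ndarray
    fps: float
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n, h, w) stack")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB raster to grayscale via BT.601 luminance.

    Y = 0.299 R + 0.587 G + 0.114 B, rounded to the nearest integer.
    Already-grayscale (2-D or single-channel) input passes through unchanged.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] == 1:
        return frame[..., 0]
    if frame.ndim == 3 and frame.shape[2] == 3:
        lum = 0.299 * frame[..., 0] + 0.587 * frame[..., 1] + 0.114 * frame[..., 2]
        return np.round(lum).astype(np.uint8)
    raise ValueError(f"expected a 2-D or 1/3-channel raster, got shape {frame.shape}")


def frame_duration(fps: float, paper_compat: bool = False) -> float:
    """Seconds per frame.

    Exact mode returns 1/fps.  ``paper_compat`` truncates 1/fps to three
    decimal places, reproducing the constants used in the original
    acquisition protocol (200 fps -> 0.005 s, 60 fps -> 0.016 s; note that
    0.016 is a truncation of 0.01666..., not a round).  The truncated
    constants bias bpm by about 0.4% at 60 fps, so exact mode is the
    default computation path.
    """
    if fps <= 0:
        raise ValueError(f"fps must be positive, got {fps}")
    if paper_compat:
        return math.floor(1000.0 / fps) / 1000.0
    return 1.0 / fps


def slowdown_factor(acquisition_fps: float, playback_fps: float) -> float:
    """Slow-motion multiplier, truncated to one decimal place.

    Footage acquired at ``acquisition_fps`` but re-rendered at
    ``playback_fps`` plays back slowed by this factor (200 -> 30 fps gives
    6.6); intervals measured on the slow clock are multiplied by it to
    recover real time.  Truncation (not rounding) to one decimal reproduces
    the 6.6 constant (200/30 = 6.67 rounds to 6.7).
    """
    if acquisition_fps <= 0 or playback_fps <= 0:
        raise ValueError("frame rates must be positive")
    return math.floor(acquisition_fps / playback_fps * 10.0) / 10.0


def resample(clip: VideoClip, new_fps: float) -> VideoClip:
    """Downsample a clip to ``new_fps`` by nearest-timestamp frame selection.

    Output frame k carries the source frame whose timestamp is closest to
    k/new_fps; n_frames = floor(duration * new_fps).  Upsampling is not
    supported (it would fabricate frames).
    """
    if new_fps <= 0:
        raise ValueError(f"new_fps must be positive, got {new_fps}")
    if new_fps > clip.fps:
        raise ValueError(
            f"upsampling not supported: new_fps {new_fps} > clip fps {clip.fps}"
        )
    n_out = int(math.floor(clip.duration_s * new_fps))
    n_out = max(n_out, 1)
    src = np.round(np.arange(n_out) / new_fps * clip.fps).astype(int)
    src = np.clip(src, 0, clip.n_frames - 1)
    return VideoClip(frames=clip.frames[src], fps=new_fps, source=clip.source)


def load_video(path: str | Path, fps_override: float | None = None) -> VideoClip:
    """Decode an mp4 or AVI file into a grayscale :class:`VideoClip`.

    Uncompressed AVI is decoded natively.  Other containers (mp4, compressed
    AVI) are routed through imageio, which requires an ffmpeg backend; when
    none is importable a decode error explains what is missing.  ``fps_override``
    replaces (or supplies, if absent) the container's frame-rate metadata.
    """
    path = Path(path)
    if not path.exists():
        raise VideoDecodeError(f"video file not found: {path}")

    frames = None
    meta_fps: float | None = None
    if path.suffix.lower() == ".avi":
        try:
            frames, meta_fps = avi.read_avi(path)
        except VideoDecodeError:
            raise
    else:
        frames, meta_fps = _load_via_imageio(path)

    if frames is None or len(frames) == 0:
        raise EmptyVideoError(f"no decodable frames in {path}")

    fps = fps_override if fps_override is not None else meta_fps
    if fps is None or fps <= 0:
        raise MetadataError(
            f"{path} carries no usable fps metadata; pass an fps override "
            "(load_video(..., fps_override=...) or --fps on the CLI)"
        )
    return VideoClip(frames=np.asarray(frames), fps=float(fps), source=str(path))


def _load_via_imageio(path: Path) -> tuple[np.ndarray, float | None]:
    try:
        import imageio.v2 as iio
    except ImportError as exc:  # pragma: no cover - imageio is a hard dep
        raise VideoDecodeError(f"imageio unavailable to decode {path}: {exc}") from exc
    try:
        reader = iio.get_reader(str(path))
    except Exception as exc:
        raise VideoDecodeError(
            f"cannot decode {path}: {exc}. Compressed containers (mp4) need an "
            "ffmpeg backend (imageio-ffmpeg); uncompressed AVI is decoded natively."
        ) from exc
    try:
        meta = reader.get_meta_data()
        meta_fps = meta.get("fps")
        frames = [to_grayscale(np.asarray(f)) for f in reader]
    finally:
        reader.close()
    if not frames:
        raise EmptyVideoError(f"no decodable frames in {path}")
    return np.stack(frames), meta_fps
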
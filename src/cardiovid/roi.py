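"""Region-of-interest definition and mean-intensity signal extraction.

Each heart chamber (atrium, ventricle) is covered by a static rectangular
bounding box; the chamber's activity signal is the arithmetic mean of the
grey levels inside the box, frame by frame.  The two chamber signals can be
extracted concurrently — the results are bitwise identical to sequential
extraction.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np

from .errors import BoundsError, ConfigError, FlatSignalError, TooFewFramesError
from .video import VideoClip

MIN_FRAMES = 10
MAX_FRAMES = 2000


class ChamberLabel(str, Enum):
    ATRIUM = "atrium"
    VENTRICLE = "ventricle"


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel rectangle, half-open [x, x+w) x [y, y+h), 0-based,
    origin at the top-left of the frame."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise BoundsError(f"box extent must be >= 1 pixel, got w={self.w}, h={self.h}")
        if self.x < 0 or self.y < 0:
            raise BoundsError(f"box corner must be non-negative, got x={self.x}, y={self.y}")

    def validate(self, width: int, height: int) -> "BoundingBox":
        if self.x + self.w > width or self.y + self.h > height:
            raise BoundsError(
                f"box x={self.x}, y={self.y}, w={self.w}, h={self.h} exceeds "
                f"frame bounds {width}x{height}"
            )
        return self

    @classmethod
    def parse(cls, text: str) -> "BoundingBox":
        """Parse 'x,y,w,h'."""
        parts = [p.strip() for p in str(text).split(",")]
        if len(parts) != 4:
            raise ConfigError(f"expected 'x,y,w,h', got {text!r}")
        try:
            x, y, w, h = (int(p) for p in parts)
        except ValueError as exc:
            raise ConfigError(f"non-integer ROI coordinate in {text!r}") from exc
        return cls(x, y, w, h)


@dataclass
class ROISignal:
    """Per-frame mean grayscale intensity of one chamber's bounding box."""

    label: ChamberLabel
    values: np.ndarray
    fps: float
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if len(self.values) != len(self.frame_indices) or len(self.values) < 1:
            raise ValueError("values and frame_indices must be equal length >= 1")


def select_rois(
    clip: VideoClip,
    spec: Mapping[str, str] | Mapping[ChamberLabel, BoundingBox] | None = None,
    interactive: bool = False,
) -> dict[ChamberLabel, BoundingBox]:
    """Resolve both chamber boxes from config entries or an interactive prompt.

    Config mode expects entries for both chambers as ``x,y,w,h`` strings (or
    ready BoundingBox values).  Interactive mode prompts on the terminal with
    the same syntax, so both modes produce identical boxes from identical
    coordinates.  Boxes may overlap; both are validated against frame bounds.
    """
    if interactive:
        spec = _prompt_rois()
    if spec is None:
        raise ConfigError("no ROI specification given (need atrium and ventricle boxes)")

    boxes: dict[ChamberLabel, BoundingBox] = {}
    for label in ChamberLabel:
        entry = None
        for key in (label, label.value):
            if key in spec:
                entry = spec[key]  # type: ignore[index]
                break
        if entry is None:
            raise ConfigError(f"missing ROI for chamber '{label.value}'")
        box = entry if isinstance(entry, BoundingBox) else BoundingBox.parse(entry)
        boxes[label] = box.validate(clip.width, clip.height)
    return boxes


def _prompt_rois() -> dict[str, str]:
    spec = {}
    for name in ("atrium", "ventricle"):
        spec[name] = input(f"{name} ROI as x,y,w,h: ")
    return spec


def extract_signal(clip: VideoClip, box: BoundingBox, label: ChamberLabel) -> ROISignal:
    """Mean grey level inside ``box`` for every frame of the clip."""
    box.validate(clip.width, clip.height)
    patch = clip.frames[:, box.y : box.y + box.h, box.x : box.x + box.w]
    values = patch.mean(axis=(1, 2), dtype=np.float64)
    return ROISignal(
        label=label,
        values=values,
        fps=clip.fps,
        frame_indices=np.arange(clip.n_frames),
    )


def extract_signals(
    clip: VideoClip,
    boxes: Mapping[ChamberLabel, BoundingBox],
    parallel: bool = True,
) -> dict[ChamberLabel, ROISignal]:
    """Extract all chamber signals, concurrently by default.

    Concurrent extraction is bitwise identical to sequential extraction:
    each chamber reduces its own read-only view of the frame stack.
    """
    items = list(boxes.items())
    if parallel and len(items) > 1:
        with ThreadPoolExecutor(max_workers=len(items)) as pool:
            results = list(
                pool.map(lambda lb: extract_signal(clip, lb[1], lb[0]), items)
            )
    else:
        results = [extract_signal(clip, box, label) for label, box in items]
    return {sig.label: sig for sig in results}


def normalize(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Center to zero mean and scale to unit standard deviation.

    Uses the sample (n-1) convention by default; ``ddof=0`` selects the
    population convention.  A flat series has no cardiac information and is
    rejected.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 samples to normalize")
    sd = values.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise FlatSignalError("no cardiac motion detected in ROI (flat signal)")
    return (values - values.mean()) / sd


def gate_frame_count(n_frames: int) -> tuple[int, int]:
    """Frame-count gate: the accepted analysis window [start, end).

    Clips under 10 frames are rejected as unanalyzable; clips over 2000
    frames (the 10 s x 200 fps protocol ceiling) are truncated to their
    first 2000 frames with a warning, keeping long videos usable.
    """
    if n_frames < MIN_FRAMES:
        raise TooFewFramesError(
            f"clip has {n_frames} frames; at least {MIN_FRAMES} are required"
        )
    if n_frames > MAX_FRAMES:
        warnings.warn(
            f"clip has {n_frames} frames; analysis window clipped to the first "
            f"{MAX_FRAMES}",
            stacklevel=2,
        )
        return (0, MAX_FRAMES)
    return (0, n_frames)
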
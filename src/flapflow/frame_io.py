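"""Fluorescence frame-stack container, TIFF I/O and duration standardization.

A recording is a stack of grayscale frames in absolute perfusion units (APU),
sampled uniformly from the moment of dye injection (t = 0).  Stacks are stored
as multi-page 32-bit float TIFF with a JSON sidecar carrying the acquisition
metadata (frame rate, start time, APU ceiling).  Recordings of different
lengths are standardized by cutting every video a fixed number of seconds
after the start so that regional parameters are comparable across flaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, MetadataError, QualityCriteriaError

__all__ = [
    "FrameStack",
    "read_frame_stack",
    "write_frame_stack",
    "trim_to_duration",
]

#: Default APU ceiling; fluorescence values are clipped to [0, APU_MAX].
APU_MAX = 255.0

#: Standard video length in seconds after the recording start.
STANDARD_DURATION_S = 20.0


@dataclass
class FrameStack:
    """A grayscale fluorescence video.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)`` in APU; page order is time order.
    frame_rate
        Acquisition rate in Hz (uniform sampling).
    apu_max
        Upper bound of the APU scale; values must lie in ``[0, apu_max]``.
    start_time
        Time of the first frame relative to dye injection, in seconds.
    """

    frames: np.ndarray
    frame_rate: float
    apu_max: float = APU_MAX
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(f"expected a (T, H, W) stack, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise FormatError("a frame stack needs at least two frames")
        if self.frame_rate <= 0:
            raise MetadataError("frame rate must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise FormatError("frame stack contains non-finite values")
        lo = float(self.frames.min())
        hi = float(self.frames.max())
        if lo < -1e-6 or hi > self.apu_max + 1e-6:
            raise FormatError(
                f"pixel values [{lo:.3g}, {hi:.3g}] outside APU range [0, {self.apu_max}]"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape (H, W)."""
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, uniform from ``start_time``."""
        return self.start_time + np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        """Covered duration in seconds (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_frame_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack as multi-page float32 TIFF plus a JSON metadata sidecar.

    Returns the sidecar path.  float32 storage is lossless for simulated APU
    values; 8-bit export is intentionally not the default.
    """
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {
        "frame_rate_hz": stack.frame_rate,
        "start_time_s": stack.start_time,
        "apu_max": stack.apu_max,
        "n_frames": stack.n_frames,
    }
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_frame_stack(path: str | Path) -> FrameStack:
    """Read a multi-page TIFF + JSON sidecar into a validated :class:`FrameStack`.

    Raises
    ------
    MetadataError
        If the sidecar is missing or its frame count disagrees with the TIFF.
    FormatError
        If the TIFF pages do not form a uniform (T, H, W) stack.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("frame_rate_hz", "n_frames"):
        if key not in meta:
            raise MetadataError(f"sidecar {sidecar} lacks required key {key!r}")
    try:
        frames = tifffile.imread(path)
    except (ValueError, tifffile.TiffFileError) as exc:  # pragma: no cover - backend detail
        raise FormatError(f"cannot read {path} as a uniform stack: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.dtype == object:
        raise FormatError(f"{path} does not contain a uniform page stack")
    if frames.shape[0] != int(meta["n_frames"]):
        raise MetadataError(
            f"{path} has {frames.shape[0]} pages but metadata declares {meta['n_frames']}"
        )
    return FrameStack(
        frames=frames,
        frame_rate=float(meta["frame_rate_hz"]),
        apu_max=float(meta.get("apu_max", APU_MAX)),
        start_time=float(meta.get("start_time_s", 0.0)),
    )


def trim_to_duration(stack: FrameStack, duration: float = STANDARD_DURATION_S) -> FrameStack:
    """Cut a stack ``duration`` seconds after the recording start.

    Frames with time in the half-open interval ``[start, start + duration)``
    are retained, so a 25 s stack at 4 Hz keeps exactly 80 frames.  Retained
    pixel values are untouched and the operation is idempotent.

    Raises
    ------
    QualityCriteriaError
        If the stack covers less than ``duration`` seconds — such recordings
        do not meet the inclusion criteria and cannot be standardized.
    """
    if duration <= 0:
        raise QualityCriteriaError("trim duration must be positive")
    if stack.duration < duration - 1e-9:
        raise QualityCriteriaError(
            f"recording covers {stack.duration:.2f} s < required {duration:.2f} s"
        )
    rel = stack.times - stack.start_time
    n_keep = int(np.searchsorted(rel, duration - 1e-9, side="left"))
    if n_keep >= stack.n_frames:
        return stack
    return FrameStack(
        frames=stack.frames[:n_keep],
        frame_rate=stack.frame_rate,
        apu_max=stack.apu_max,
        start_time=stack.start_time,
    )
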
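"""Frame-differencing of ultrasound frame stacks into movement-magnitude traces.

The central quantity is the Euclidean distance between the pixel-intensity
vectors of consecutive grayscale frames ("delta"), which yields one
nonnegative change magnitude per frame pair and hence a time series of
relative image change for each trial.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Literal

import numpy as np
import tifffile

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import TrialEvents

Normalization = Literal["none", "per_pixel_rms"]

__all__ = [
    "FrameStack",
    "DeltaTrace",
    "frame_delta",
    "extract_delta_trace",
    "align_to_events",
    "read_frame_stack",
    "write_frame_stack",
]


class ShapeMismatchError(ValueError):
    """Raised when two frames (or stacks) disagree in pixel dimensions."""


class TrialMismatchError(ValueError):
    """Raised when a trace and an event record belong to different trials."""


@dataclass
class FrameStack:
    """One trial's ordered grayscale frames plus timing metadata.

    ``sync_frame_index`` marks the frame recorded at the moment of the
    synchronization pulse, i.e. at question onset on the trial clock.
    """

    frames: np.ndarray  # (n_frames, H, W), integer intensities in [0, 255]
    frame_rate_hz: float
    sync_frame_index: int
    participant_id: int
    item_id: int
    condition: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ShapeMismatchError(
                f"frames must be a (n, H, W) array, got shape {self.frames.shape}"
            )
        if not 0 <= self.sync_frame_index < len(self.frames):
            raise ValueError(
                f"sync_frame_index {self.sync_frame_index} outside "
                f"[0, {len(self.frames)})"
            )
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class DeltaTrace:
    """Per-trial time series of frame-to-frame change magnitudes.

    Each value is the delta between frames k and k+1 and is timestamped at
    the temporal midpoint of the two frames.  Until :func:`align_to_events`
    is applied, time 0 is the sync pulse (question onset).
    """

    timestamps: np.ndarray  # seconds, strictly increasing, step 1/frame_rate_hz
    values: np.ndarray  # nonnegative, length n_frames - 1
    frame_rate_hz: float
    normalization: Normalization
    participant_id: int
    item_id: int
    condition: str
    sync_time: float = 0.0  # trial-clock time of the sync pulse

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)


def frame_delta(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    normalization: Normalization = "none",
) -> float:
    """Euclidean distance between the pixel intensities of two frames.

    With ``normalization="none"`` this is ``sqrt(sum((a - b)**2))`` over all
    pixels; ``"per_pixel_rms"`` divides by ``sqrt(H * W)`` so values are
    comparable across image sizes.  Intensities are promoted to float before
    differencing to avoid unsigned-integer wraparound.
    """
    a = np.asarray(frame_a)
    b = np.asarray(frame_b)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"frame shapes differ: {a.shape} vs {b.shape}")
    diff = a.astype(np.float64) - b.astype(np.float64)
    dist = float(np.sqrt(np.sum(diff * diff)))
    if normalization == "per_pixel_rms":
        dist /= np.sqrt(a.size)
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return dist


def extract_delta_trace(
    stack: FrameStack, normalization: Normalization = "none"
) -> DeltaTrace:
    """Compute the delta trace of a frame stack.

    Value k is the delta between frames k and k+1, timestamped at the
    midpoint of the two frame times; the sync frame defines time 0.
    """
    if stack.n_frames < 2:
        raise ValueError("frame stack must contain at least 2 frames")
    x = stack.frames.astype(np.float64)
    diffs = np.diff(x, axis=0)
    values = np.sqrt(np.einsum("khw,khw->k", diffs, diffs))
    if normalization == "per_pixel_rms":
        values = values / np.sqrt(x.shape[1] * x.shape[2])
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    dt = 1.0 / stack.frame_rate_hz
    frame_times = (np.arange(stack.n_frames) - stack.sync_frame_index) * dt
    timestamps = 0.5 * (frame_times[:-1] + frame_times[1:])
    return DeltaTrace(
        timestamps=timestamps,
        values=values,
        frame_rate_hz=stack.frame_rate_hz,
        normalization=normalization,
        participant_id=stack.participant_id,
        item_id=stack.item_id,
        condition=stack.condition,
        sync_time=0.0,
    )


def align_to_events(trace: DeltaTrace, events: "TrialEvents") -> DeltaTrace:
    """Re-express trace timestamps on the trial clock of ``events``.

    The sync time is mapped onto ``events.question_onset``; afterwards all
    three lock points should fall within (or adjacent to) the trace span —
    a warning is emitted for any that does not.
    """
    if (trace.participant_id, trace.item_id) != (events.participant_id, events.item_id):
        raise TrialMismatchError(
            f"trace is P{trace.participant_id}/I{trace.item_id} but events are "
            f"P{events.participant_id}/I{events.item_id}"
        )
    shift = events.question_onset - trace.sync_time
    new_ts = trace.timestamps + shift
    dt = 1.0 / trace.frame_rate_hz
    lo, hi = new_ts[0] - dt, new_ts[-1] + dt
    for name, t in [
        ("TL1 (question offset)", events.question_offset),
        ("TL2 (critical word onset)", events.critical_word_onset),
        ("TL3 (response onset)", events.response_onset),
    ]:
        if not lo <= t <= hi:
            warnings.warn(
                f"lock point {name} at {t:.3f}s lies outside trace span "
                f"[{new_ts[0]:.3f}, {new_ts[-1]:.3f}]s",
                stacklevel=2,
            )
    return replace(trace, timestamps=new_ts, sync_time=events.question_onset)


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF and a simple raw binary format
# ---------------------------------------------------------------------------

_RAW_MAGIC_LEN = 16  # H, W, n_frames, frame_rate*1000 as little-endian int32


def write_frame_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack as 8-bit grayscale multi-page TIFF (.tif) or raw (.bin)."""
    path = Path(path)
    frames = np.clip(stack.frames, 0, 255).astype(np.uint8)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, frames, photometric="minisblack")
    elif path.suffix == ".bin":
        n, h, w = frames.shape
        header = struct.pack("<4i", h, w, n, int(round(stack.frame_rate_hz * 1000)))
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(frames.tobytes())
    else:
        raise ValueError(f"unsupported frame-stack extension {path.suffix!r}")
    return path


def read_frame_stack(
    path: str | Path,
    frame_rate_hz: float | None = None,
    sync_frame_index: int = 0,
    participant_id: int = -1,
    item_id: int = -1,
    condition: str = "",
) -> FrameStack:
    """Read a multi-page TIFF or raw binary stack written by this module.

    TIFF files carry no timing metadata, so ``frame_rate_hz`` must be given;
    the raw format stores it in its 16-byte header.
    """
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        if frame_rate_hz is None:
            raise ValueError("frame_rate_hz is required when reading TIFF stacks")
    elif path.suffix == ".bin":
        with open(path, "rb") as fh:
            h, w, n, fr_milli = struct.unpack("<4i", fh.read(_RAW_MAGIC_LEN))
            frames = np.frombuffer(fh.read(n * h * w), dtype=np.uint8)
        frames = frames.reshape(n, h, w)
        frame_rate_hz = fr_milli / 1000.0
    else:
        raise ValueError(f"unsupported frame-stack extension {path.suffix!r}")
    return FrameStack(
        frames=frames,
        frame_rate_hz=frame_rate_hz,
        sync_frame_index=sync_frame_index,
        participant_id=participant_id,
        item_id=item_id,
        condition=condition,
    )
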
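"""Frame stacks, beat times and cardiac phase.

A recording is a short fundus video (nominally 25 fps, three cardiac
cycles) stored either as a multi-page TIFF or as a lexicographically
ordered ``frame_%04d.png``/``.tif`` sequence, together with a CSV of
cardiac beat-onset times from a pulse oximeter.  Every frame is assigned
a cardiac phase in [0, 1): the fractional position between the two beat
onsets that bracket it.  Phase is normalised per cycle, so a varying
heart rate does not smear the waveform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FrameStack",
    "BeatTimes",
    "PhaseVector",
    "read_stack",
    "write_stack",
    "read_beats",
    "write_beats",
    "extract_green",
    "compute_phase",
]

_SEQ_PATTERN = re.compile(r"\.(png|tif|tiff)$", re.IGNORECASE)


@dataclass
class FrameStack:
    """Time-ordered RGB frames with uniform geometry.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, H, W, 3)
        Integer camera intensities (nominally 8-bit).  Aligned stacks may
        hold interpolated float values.
    fps : float
        Frame rate in frames per second.
    timestamps : ndarray, shape (n_frames,), optional
        Seconds per frame; defaults to ``arange(n) / fps``.
    valid : ndarray of bool, shape (n_frames, H, W), optional
        Per-pixel validity flags.  Warping during alignment marks pixels
        that fell outside the camera view; ``None`` means all valid.
    """

    frames: np.ndarray
    fps: float
    timestamps: np.ndarray = None
    valid: np.ndarray = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[3] != 3:
            raise ValueError(
                f"frames must have shape (n, H, W, 3); got {self.frames.shape}"
            )
        if self.n_frames < 2:
            raise ValueError("a stack needs at least 2 frames")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(self.n_frames, dtype=float) / self.fps
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.n_frames,):
                raise ValueError("one timestamp per frame required")
            if np.any(np.diff(self.timestamps) <= 0):
                raise ValueError("timestamps must be strictly increasing")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.frames.shape[:3]:
                raise ValueError("valid mask shape must match frames")

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
    def bit_max(self) -> int:
        """Maximum representable intensity for the stack's dtype (255 for 8-bit)."""
        if np.issubdtype(self.frames.dtype, np.integer):
            return int(np.iinfo(self.frames.dtype).max)
        return 255


@dataclass
class BeatTimes:
    """Cardiac beat-onset times in seconds, one per cycle start."""

    onsets: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float).ravel()
        if self.onsets.size < 4:
            raise ValueError("need >=4 beat onsets (>=3 complete cycles)")
        gaps = np.diff(self.onsets)
        if np.any(gaps <= 0):
            raise ValueError("beat onsets must be strictly increasing")
        if np.any(gaps <= 0.2):
            raise ValueError("cycle lengths must exceed 0.2 s")

    @property
    def n_cycles(self) -> int:
        return self.onsets.size - 1


@dataclass
class PhaseVector:
    """Per-frame cardiac phase.

    ``phase[i]`` is in [0, 1) for frames inside a complete cycle;
    ``included[i]`` is False for frames before the first or at/after the
    last onset, which are excluded from regression.  ``cycle_index`` is
    -1 for excluded frames.
    """

    phase: np.ndarray
    cycle_index: np.ndarray
    included: np.ndarray
    time: np.ndarray = field(default=None)


def read_stack(path: str | Path, fps: float = 25.0) -> FrameStack:
    """Read a frame stack from a multi-page TIFF or an image-sequence directory.

    Frame order follows page order (TIFF) or lexicographic filename order
    (directory of PNG/TIFF files).  Timestamps are ``i / fps``.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if _SEQ_PATTERN.search(p.name))
        if len(files) < 2:
            raise ValueError(f"need >=2 frames, found {len(files)} in {path}")
        frames = [np.asarray(iio.imread(f)) for f in files]
    else:
        data = tifffile.imread(path)
        if data.ndim == 3 and data.shape[2] in (3, 4):
            raise ValueError("single-page file: a stack needs >=2 frames")
        if data.ndim != 4:
            raise ValueError(f"expected pages of RGB frames, got shape {data.shape}")
        frames = list(data)
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames have mixed sizes: {sorted(shapes)}")
    arr = np.stack(frames)
    if arr.ndim != 4 or arr.shape[3] < 3:
        raise ValueError("frames must be RGB")
    return FrameStack(frames=arr[..., :3], fps=fps)


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF (``.tif``) or a PNG sequence (directory)."""
    path = Path(path)
    frames = stack.frames
    if not np.issubdtype(frames.dtype, np.integer):
        frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frames, photometric="rgb")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:04d}.png", frame)


def read_beats(path: str | Path) -> BeatTimes:
    """Read beat-onset times from a CSV with a ``time_s`` column."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"beat file {path} lacks a 'time_s' column")
    return BeatTimes(onsets=df["time_s"].to_numpy())


def write_beats(beats: BeatTimes, path: str | Path) -> None:
    pd.DataFrame({"time_s": beats.onsets}).to_csv(path, index=False)


def extract_green(stack: FrameStack) -> np.ndarray:
    """Return the green channel of every frame, values unchanged.

    Haemoglobin absorbs strongly near 550 nm, so the green channel
    carries the blood-volume signal; channel convention is RGB.
    """
    return stack.frames[..., 1]


def compute_phase(stack: FrameStack, beats: BeatTimes) -> PhaseVector:
    """Map each frame time to a cardiac phase in [0, 1).

    For a frame at time t in [onset_k, onset_{k+1}):
    ``phase = (t - onset_k) / (onset_{k+1} - onset_k)`` and
    ``cycle_index = k``.  Frames outside [first onset, last onset) are
    flagged excluded.  Raises if fewer than 3 complete cycles contain
    frames.
    """
    t = stack.timestamps
    onsets = beats.onsets
    k = np.searchsorted(onsets, t, side="right") - 1
    included = (k >= 0) & (k < beats.n_cycles)
    phase = np.zeros_like(t)
    cycle = np.full(t.shape, -1, dtype=int)
    ki = k[included]
    phase[included] = (t[included] - onsets[ki]) / (onsets[ki + 1] - onsets[ki])
    cycle[included] = ki
    n_covered = np.unique(cycle[included]).size
    if n_covered < 3:
        raise ValueError(
            f"only {n_covered} complete cardiac cycles overlap the stack; need >=3"
        )
    return PhaseVector(phase=phase, cycle_index=cycle, included=included, time=t)
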
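"""Movie containers, TIFF round-trip, spatial filtering, and beat segmentation.

A recording is a single-channel fluorescence movie (time x rows x cols) with
acquisition metadata: frame rate, pixel pitch, channel name, and the stimulus
times of the pacing protocol (empty for sinus rhythm).  On disk a movie is a
multi-page TIFF next to a JSON sidecar carrying the metadata, so nothing about
the acquisition is baked into the pixel data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .errors import DegenerateSignalError, FormatError, InvalidParameterError

#: canonical discrete 3x3 Gaussian: binomial [1 2 1] outer [1 2 1], normalized
GAUSSIAN3_KERNEL = np.outer([1.0, 2.0, 1.0], [1.0, 2.0, 1.0]) / 16.0

VALID_CHANNELS = ("voltage", "calcium")


@dataclass
class Movie:
    """Single-channel fluorescence movie plus acquisition metadata.

    Parameters
    ----------
    frames
        Intensity array of shape ``(n_frames, rows, cols)``; finite values.
    frame_rate
        Sampling rate in Hz (default acquisition runs at 900 Hz).
    pixel_pitch
        Physical pixel size in mm.
    channel
        ``"voltage"`` or ``"calcium"``.
    stimulus_times
        Pacing stimulus times in ms from the start of the recording; empty
        for unstimulated (sinus) recordings.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_pitch: float
    channel: str = "voltage"
    stimulus_times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidParameterError(
                f"frames must be 3-D (time, rows, cols), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise InvalidParameterError("a movie needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise InvalidParameterError("movie intensities must be finite")
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")
        if self.pixel_pitch <= 0:
            raise InvalidParameterError("pixel_pitch must be positive")
        if self.channel not in VALID_CHANNELS:
            raise InvalidParameterError(
                f"channel must be one of {VALID_CHANNELS}, got {self.channel!r}"
            )
        self.stimulus_times = [float(t) for t in self.stimulus_times]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def frame_period(self) -> float:
        """Frame period in ms."""
        return 1000.0 / self.frame_rate

    @property
    def duration(self) -> float:
        """Recording length in ms."""
        return self.n_frames * self.frame_period

    def times(self) -> np.ndarray:
        """Frame timestamps in ms (frame k is sampled at k * frame_period)."""
        return np.arange(self.n_frames) * self.frame_period

    def pixel_trace(self, row: int, col: int) -> np.ndarray:
        return self.frames[:, row, col]


@dataclass
class Mask:
    """Boolean grid of analyzable pixels (same rows/cols as the movie)."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise InvalidParameterError("mask must be 2-D")
        if not self.grid.any():
            raise InvalidParameterError("mask must contain at least one pixel")

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "Mask":
        return cls(np.ones(shape, dtype=bool))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Mask":
        return cls(np.loadtxt(path, delimiter=",") > 0.5)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.grid.astype(int), fmt="%d", delimiter=",")


@dataclass(frozen=True)
class BeatWindow:
    """One beat of one pixel trace: frame span plus its reference time.

    ``start``/``end`` are frame indices (half-open interval) and ``ref_time``
    is the stimulus time (paced data) or the detected upstroke time (sinus
    data) in ms.
    """

    start: int
    end: int
    ref_time: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidParameterError("BeatWindow end must exceed start")

    def slice(self) -> slice:
        return slice(self.start, self.end)


# ---------------------------------------------------------------------------
# disk round-trip


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(movie: Movie, path: str | Path) -> Path:
    """Write a movie as a multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    meta = {
        "frame_rate_hz": movie.frame_rate,
        "pixel_pitch_mm": movie.pixel_pitch,
        "channel": movie.channel,
        "stimulus_times_ms": list(movie.stimulus_times),
        "n_frames": movie.n_frames,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_movie(path: str | Path) -> Movie:
    """Read a movie written by :func:`write_movie`.

    Raises
    ------
    FormatError
        If the sidecar is missing, lacks required keys, or its frame count
        disagrees with the TIFF stack.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FormatError(f"movie stack not found: {path}")
    if not sidecar.exists():
        raise FormatError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("frame_rate_hz", "pixel_pitch_mm"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} missing required key {key!r}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if "n_frames" in meta and int(meta["n_frames"]) != frames.shape[0]:
        raise FormatError(
            f"sidecar declares {meta['n_frames']} frames, stack has {frames.shape[0]}"
        )
    return Movie(
        frames=np.asarray(frames, dtype=float),
        frame_rate=float(meta["frame_rate_hz"]),
        pixel_pitch=float(meta["pixel_pitch_mm"]),
        channel=meta.get("channel", "voltage"),
        stimulus_times=list(meta.get("stimulus_times_ms", [])),
    )


# ---------------------------------------------------------------------------
# preprocessing


def spatial_gaussian3(movie: Movie) -> Movie:
    """Apply the canonical 3x3 Gaussian spatial filter to every frame.

    The kernel is the binomial ``[1 2 1]^T [1 2 1] / 16`` approximation to a
    Gaussian; borders are handled by edge replication so the filter preserves
    constants exactly.
    """
    rows, cols = movie.shape
    if rows < 3 or cols < 3:
        raise InvalidParameterError("spatial filtering needs a grid of at least 3x3")
    filtered = ndimage.convolve(
        movie.frames, GAUSSIAN3_KERNEL[None, :, :], mode="nearest"
    )
    return replace(movie, frames=filtered)


def normalize_beat(trace: np.ndarray, window: BeatWindow | None = None) -> np.ndarray:
    """Min-max normalize a beat segment to [0, 1].

    Operates on ``trace[window.start:window.end]`` when a window is given,
    otherwise on the full trace.  A flat segment has no amplitude to define
    repolarization levels against and raises :class:`DegenerateSignalError`.
    """
    seg = np.asarray(trace, dtype=float)
    if window is not None:
        seg = seg[window.slice()]
    lo, hi = float(np.min(seg)), float(np.max(seg))
    if hi - lo <= 0:
        raise DegenerateSignalError("flat trace: beat has no amplitude")
    return (seg - lo) / (hi - lo)


def _detect_upstrokes(
    trace: np.ndarray,
    frame_period: float,
    threshold_frac: float = 0.5,
    lockout_ms: float = 40.0,
) -> list[int]:
    """Indices of upward threshold crossings with a refractory lockout.

    Threshold is ``threshold_frac`` of the trace's full dynamic range; after
    each crossing, further crossings are ignored for ``lockout_ms`` (robust at
    rat heart rates).
    """
    x = np.asarray(trace, dtype=float)
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        return []
    # noise floor: a genuine upstroke must stand well above the frame-to-frame
    # noise, estimated robustly from the first differences
    sigma_est = np.median(np.abs(np.diff(x))) / (0.6745 * math.sqrt(2.0))
    if sigma_est > 0 and (hi - lo) < 10.0 * sigma_est:
        return []
    level = lo + threshold_frac * (hi - lo)
    above = x >= level
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    lockout = max(1, int(round(lockout_ms / frame_period)))
    kept: list[int] = []
    for idx in crossings:
        if not kept or idx - kept[-1] >= lockout:
            kept.append(int(idx))
    return kept


def segment_beats(
    movie: Movie,
    mask: Mask | None = None,
    *,
    threshold_frac: float = 0.5,
    lockout_ms: float = 40.0,
) -> dict[tuple[int, int], list[BeatWindow]]:
    """Split the recording into per-pixel beat windows.

    Paced recordings (``stimulus_times`` present) are segmented stimulus-
    locked: one window per stimulus, spanning to the next stimulus (or end of
    recording), identical across pixels.  Unstimulated recordings fall back to
    per-pixel threshold-crossing detection at 50% of the trace amplitude with
    a 40-ms lockout; windows then span between successive upstrokes, back-
    extended by a small pre-upstroke margin.

    Returns an empty window list (with no error) for pixels where nothing is
    detected, mirroring how an all-noise recording should degrade.
    """
    mask = mask or Mask.full(movie.shape)
    if mask.grid.shape != movie.shape:
        raise InvalidParameterError("mask shape must match movie frame shape")
    fp = movie.frame_period
    out: dict[tuple[int, int], list[BeatWindow]] = {}

    if movie.stimulus_times:
        # stimulus-locked windows, pulled back by a small pre-stimulus margin
        # so each window carries true diastolic baseline frames
        stims = sorted(movie.stimulus_times)
        margin = max(1, int(round(10.0 / fp)))
        bounds = [max(0, int(round(t / fp)) - margin) for t in stims] + [movie.n_frames]
        windows = [
            BeatWindow(start=bounds[i], end=bounds[i + 1], ref_time=stims[i])
            for i in range(len(stims))
            if bounds[i + 1] - bounds[i] >= 2
        ]
        for r, c in zip(*np.nonzero(mask.grid)):
            out[(int(r), int(c))] = list(windows)
        return out

    margin = max(1, int(round(10.0 / fp)))  # 10 ms pre-upstroke context
    for r, c in zip(*np.nonzero(mask.grid)):
        trace = movie.pixel_trace(int(r), int(c))
        ups = _detect_upstrokes(trace, fp, threshold_frac, lockout_ms)
        wins: list[BeatWindow] = []
        for i, idx in enumerate(ups):
            start = max(0, idx - margin)
            end = ups[i + 1] - margin if i + 1 < len(ups) else movie.n_frames
            if end - start >= 2:
                wins.append(BeatWindow(start=start, end=end, ref_time=idx * fp))
        out[(int(r), int(c))] = wins
    return out
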
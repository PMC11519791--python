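"""Beat-to-beat alternans: magnitude, spectral detection, phase, discordance.

Alternans is the period-2 large-small oscillation of APD or CaT amplitude at
fast pacing.  Its magnitude is 1 minus the ratio of the mean smaller-beat
value to the mean bigger-beat value (even/odd beat grouping, robust to slow
drift after detrending).  Detection uses the classical spectral method: the
beat-index magnitude spectrum is compared at 0.5 cycles/beat against a noise
band (0.33-0.48 cycles/beat), and the k-score counts how many noise standard
deviations the alternans peak stands above the noise mean.  Phase is anchored
to the stimulus train: long-short (or high-low) sequences are positive,
short-long negative.  Spatially discordant alternans - regions alternating
with opposite phase - is summarized by a discordance index in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

#: spectral noise band in cycles/beat (standard TWA convention; excludes the
#: alternans bin at 0.5)
NOISE_BAND = (0.33, 0.48)

#: default significance threshold on the k-score
K_THRESHOLD = 3.0


@dataclass
class SpectralAlternans:
    """Spectral-method result for one beat series."""

    alternans_power: float  # magnitude-spectrum amplitude at 0.5 cycles/beat
    k_score: float
    significant: bool


@dataclass
class AlternansResult:
    """Map-level alternans summary at one cycle length.

    ``magnitude`` in [0, 1); ``phase`` in {+1, -1, 0} with 0 meaning not
    significant; ``discordance`` is NaN when no pixel is significant.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    k_score: np.ndarray
    significant: np.ndarray
    discordance: float
    cycle_length: float | None = None

    @property
    def mean_magnitude(self) -> float:
        """Map-mean alternans magnitude over significant pixels (0 if none)."""
        if not self.significant.any():
            return 0.0
        return float(np.mean(self.magnitude[self.significant]))


def alternans_magnitude(series: np.ndarray) -> float:
    """1 - mean(smaller-beat group) / mean(bigger-beat group).

    Beats are split by even/odd index; whichever group has the larger mean is
    the "bigger" group.  The result lies in [0, 1) for positive series and is
    0 for a constant series.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise InvalidParameterError("alternans magnitude needs at least 4 beats")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("series must have no missing interior values")
    even, odd = x[0::2].mean(), x[1::2].mean()
    big, small = max(even, odd), min(even, odd)
    if big <= 0:
        raise InvalidParameterError("bigger-beat mean must be positive")
    return 1.0 - small / big


def _detrend(x: np.ndarray) -> np.ndarray:
    n = x.size
    t = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    return x - (slope * t + intercept)


def spectral_alternans(
    series: np.ndarray,
    noise_band: tuple[float, float] = NOISE_BAND,
    k_threshold: float = K_THRESHOLD,
) -> SpectralAlternans:
    """Spectral-method alternans detection on one beat series.

    The linearly detrended series is Fourier transformed over beat index; the
    alternans amplitude is the magnitude-spectrum value at 0.5 cycles/beat and
    the k-score is ``(alternans - mean(noise band)) / sd(noise band)``.  The
    series is truncated to an even number of beats so the 0.5 cycles/beat bin
    exists exactly.

    Raises on fewer than 8 beats: short series should fall back to the
    time-domain :func:`alternans_magnitude`.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 8:
        raise InvalidParameterError(
            "spectral detection needs >= 8 beats; use alternans_magnitude for short series"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("series must have no missing interior values")
    if x.size % 2:
        x = x[:-1]
    n = x.size
    x = _detrend(x)
    spec = np.abs(np.fft.rfft(x)) / n
    freqs = np.fft.rfftfreq(n)
    # the real-FFT bin at 0.5 cycles/beat has no imaginary counterpart and
    # carries twice the noise variance of interior bins; rescale so the null
    # distributions are comparable and k >= 3 retains its one-sided normal
    # false-positive bound
    alt = float(spec[-1]) / math.sqrt(2.0)
    band = (freqs >= noise_band[0]) & (freqs <= noise_band[1]) & (freqs < 0.5)
    if band.sum() < 3:  # short series: use all non-DC, non-alternans bins
        band = (freqs > 0) & (freqs < 0.5)
    noise = spec[band]
    sd = float(noise.std(ddof=1))
    if sd <= 0:
        k = math.inf if alt > noise.mean() else 0.0
    else:
        k = (alt - float(noise.mean())) / sd
    return SpectralAlternans(alternans_power=alt, k_score=k,
                             significant=k >= k_threshold)


def phase_map(
    series_stack: np.ndarray,
    significant: np.ndarray,
) -> np.ndarray:
    """Per-pixel alternans phase in {+1, -1, 0}, anchored to the first beat.

    ``series_stack`` has shape (n_beats, rows, cols) with beat indexing
    aligned across pixels (same stimulus train).  A pixel whose first
    analyzed beat starts the long/high group (long-short, high-low) is +1;
    short-long/low-high is -1; non-significant pixels are 0.
    """
    stack = np.asarray(series_stack, dtype=float)
    if stack.ndim != 3:
        raise InvalidParameterError("series_stack must be (n_beats, rows, cols)")
    if not np.all(np.isfinite(stack)):
        raise InvalidParameterError("beat series misaligned: missing values in stack")
    sig = np.asarray(significant, dtype=bool)
    if sig.shape != stack.shape[1:]:
        raise InvalidParameterError("significance mask shape must match the grid")
    even = stack[0::2].mean(axis=0)
    odd = stack[1::2].mean(axis=0)
    phase = np.where(even > odd, 1, -1).astype(int)
    phase[even == odd] = 0
    phase[~sig] = 0
    return phase


def discordance_index(phase: np.ndarray) -> float:
    """2 * min(N+, N-) / (N+ + N-) over significant pixels.

    0 for fully concordant alternans, 1 for balanced opposite-phase regions;
    NaN when no pixel is significant (discordance undefined).
    """
    p = np.asarray(phase)
    n_pos = int(np.sum(p == 1))
    n_neg = int(np.sum(p == -1))
    total = n_pos + n_neg
    if total == 0:
        return math.nan
    return 2.0 * min(n_pos, n_neg) / total


def alternans_analysis(
    series_stack: np.ndarray,
    cycle_length: float | None = None,
    *,
    noise_band: tuple[float, float] = NOISE_BAND,
    k_threshold: float = K_THRESHOLD,
) -> AlternansResult:
    """Full map-level alternans analysis of a per-pixel beat-series stack.

    Computes the time-domain magnitude, spectral k-score and significance per
    pixel, the stimulus-anchored phase map, and the discordance index over
    significant pixels.
    """
    stack = np.asarray(series_stack, dtype=float)
    if stack.ndim != 3:
        raise InvalidParameterError("series_stack must be (n_beats, rows, cols)")
    _, R, C = stack.shape
    mag = np.full((R, C), np.nan)
    k = np.full((R, C), np.nan)
    sig = np.zeros((R, C), dtype=bool)
    for r in range(R):
        for c in range(C):
            series = stack[:, r, c]
            if not np.all(np.isfinite(series)):
                continue
            mag[r, c] = alternans_magnitude(series)
            res = spectral_alternans(series, noise_band, k_threshold)
            k[r, c] = res.k_score
            sig[r, c] = res.significant
    phase = phase_map(np.nan_to_num(stack, nan=0.0), sig)
    return AlternansResult(
        magnitude=mag, phase=phase, k_score=k, significant=sig,
        discordance=discordance_index(phase), cycle_length=cycle_length,
    )
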
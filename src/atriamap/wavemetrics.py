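"""Per-beat AP/CaT feature extraction, maps, conduction, and heterogeneity.

The operational definitions mirror standard optical-mapping practice:
activation is the instant of maximal upstroke velocity (dF/dt max, refined to
sub-frame precision by quadratic interpolation); APD/CaT durations run from
activation to the linearly interpolated crossing of the requested
repolarization level; rise time is the 10-90% upstroke interval; the CaT
decay constant Tau comes from a monoexponential least-squares fit on the
segment between 30% below the peak and 90% recovery; conduction velocity is
the inverse gradient magnitude of a local second-order polynomial surface fit
to the activation map (Bayly-style, 5x5 neighborhoods).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateSignalError, InvalidParameterError
from .io import BeatWindow, Movie, Mask, normalize_beat, segment_beats


@dataclass
class ScalarMeasure:
    """A measured scalar with a reliability flag (set when the estimate is
    degenerate, tied, truncated, or poorly fit)."""

    value: float
    flagged: bool = False
    note: str = ""

    def __float__(self) -> float:
        return self.value


@dataclass
class BeatFeature:
    """Features of a single beat of a single pixel.

    Durations are ms, amplitude in normalized units, decay_tau in seconds.
    ``apd30 <= apd80 <= apd90`` holds whenever all three are measurable.
    """

    activation_time: float
    apd30: float | None = None
    apd80: float | None = None
    apd90: float | None = None
    rise_time: float | None = None
    amplitude: float | None = None
    decay_tau: float | None = None
    decay_r2: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class FeatureMap:
    """Per-pixel scalar grid with units; NaN marks unmasked/unmeasurable pixels."""

    values: np.ndarray
    units: str = "ms"
    beat_index: int | None = None

    def mean(self) -> float:
        return float(np.nanmean(self.values))

    def iqr(self) -> float:
        return heterogeneity_iqr(self)


@dataclass
class ConductionResult:
    """Local velocity field (mm/ms) and its summary over the masked interior."""

    speed: np.ndarray  # (R, C), NaN outside valid interior
    direction: np.ndarray  # (R, C, 2) unit vectors
    mean_speed: float
    direction_coherence: float  # |mean unit vector| in [0, 1]


# ---------------------------------------------------------------------------
# single-trace features


def _window_segment(trace: np.ndarray, window: BeatWindow | None) -> tuple[np.ndarray, int]:
    x = np.asarray(trace, dtype=float)
    if window is None:
        return x, 0
    return x[window.slice()], window.start


def upstroke_amplitude(segment: np.ndarray) -> float:
    """Beat amplitude as the maximum rise above the running minimum.

    Equals peak minus the preceding diastolic minimum for a clean beat, and
    ~0 for a window that only contains the decaying (monotone) tail of the
    previous transient - which is what fused, non-recovered beats at very
    fast pacing look like.
    """
    seg = np.asarray(segment, dtype=float)
    return float(np.max(seg - np.minimum.accumulate(seg)))


def activation_time(
    trace: np.ndarray, window: BeatWindow | None, frame_period: float
) -> ScalarMeasure:
    """Time (ms from recording start) of maximal upstroke velocity.

    The discrete first-difference argmax is refined by fitting a parabola
    through the three surrounding derivative samples.  Non-unique maxima
    (within a small tie tolerance, e.g. a perfectly linear ramp) resolve to
    the earliest frame and are flagged.
    """
    seg, offset = _window_segment(trace, window)
    if seg.size < 3:
        raise DegenerateSignalError("window too short for a derivative")
    d = np.diff(seg)
    i = int(np.argmax(d))
    tie_tol = 1e-9 * max(1.0, float(np.max(np.abs(d))))
    ties = np.flatnonzero(d >= d[i] - tie_tol)
    flagged = ties.size > 1
    if flagged:
        i = int(ties[0])
    # derivative sample k estimates the slope at frame centre k + 1/2
    t = (i + 0.5) * frame_period
    if not flagged and 0 < i < d.size - 1:
        denom = d[i - 1] - 2.0 * d[i] + d[i + 1]
        if denom < 0:
            t += 0.5 * (d[i - 1] - d[i + 1]) / denom * frame_period
    return ScalarMeasure(
        value=(offset * frame_period) + t,
        flagged=flagged,
        note="tied derivative maximum; earliest taken" if flagged else "",
    )


def _crossing_after(
    seg: np.ndarray, start_idx: int, level: float, frame_period: float
) -> float | None:
    """First downward crossing of ``level`` at or after ``start_idx``, ms
    (linearly interpolated)."""
    for k in range(max(start_idx, 0), seg.size - 1):
        if seg[k] >= level > seg[k + 1]:
            frac = (seg[k] - level) / (seg[k] - seg[k + 1])
            return (k + frac) * frame_period
    return None


def duration_at_level(
    trace: np.ndarray,
    window: BeatWindow | None,
    activation: float,
    level: float,
    frame_period: float,
) -> ScalarMeasure:
    """Duration (ms) from ``activation`` to the ``level`` recovery crossing.

    ``level`` is the repolarization fraction: 0.9 gives APD90, i.e. the time
    until the normalized trace falls through ``1 - level`` after its peak.
    Returns NaN flagged when the beat is cut off before reaching the level.
    """
    if not 0.0 < level < 1.0:
        raise InvalidParameterError("level must lie in (0, 1)")
    seg, offset = _window_segment(trace, window)
    # diastolic baseline: median of the frames before the upstroke foot
    # (unbiased under symmetric noise, exact on clean data); fall back to the
    # window minimum when no pre-foot frames exist
    nb = normalize_beat(seg)
    pk = int(np.argmax(nb))
    foot = 0
    for k in range(pk, -1, -1):
        if nb[k] <= 0.05:
            foot = k
            break
    lo = float(np.min(seg))
    if foot - 1 >= 2:
        lo = float(np.median(seg[: foot - 1]))
    hi = float(np.max(seg))
    if hi - lo <= 0:
        raise DegenerateSignalError("flat trace: beat has no amplitude")
    seg = (seg - lo) / (hi - lo)
    peak = int(np.argmax(seg))
    cross = _crossing_after(seg, peak, 1.0 - level, frame_period)
    if cross is None:
        return ScalarMeasure(value=math.nan, flagged=True, note="level never reached")
    t_cross = offset * frame_period + cross
    return ScalarMeasure(value=t_cross - activation)


def rise_time(
    trace: np.ndarray, window: BeatWindow | None, frame_period: float
) -> ScalarMeasure:
    """10-90% upstroke interval in ms (linear interpolation between frames)."""
    seg, _ = _window_segment(trace, window)
    try:
        seg = normalize_beat(seg)
    except DegenerateSignalError:
        return ScalarMeasure(value=math.nan, flagged=True, note="no amplitude")
    peak = int(np.argmax(seg))

    def up_cross(level: float) -> float:
        for k in range(peak, 0, -1):
            if seg[k - 1] <= level < seg[k]:
                frac = (level - seg[k - 1]) / (seg[k] - seg[k - 1])
                return (k - 1 + frac) * frame_period
        return 0.0

    return ScalarMeasure(value=up_cross(0.9) - up_cross(0.1))


def decay_tau(
    trace: np.ndarray,
    window: BeatWindow | None,
    frame_period: float,
    *,
    r2_floor: float = 0.9,
) -> ScalarMeasure:
    """Monoexponential decay constant of a CaT beat, in seconds.

    The fit runs on the decay segment from 30% below the peak down to 90%
    recovery of the normalized beat.  The value is returned flagged
    unreliable when the fit R-squared falls below ``r2_floor`` or when the
    log-scale residuals carry smooth curvature (a non-exponential shape such
    as a linear decay, which a 2-parameter exponential can otherwise shadow
    with deceptively high R-squared).
    """
    seg, _ = _window_segment(trace, window)
    seg = normalize_beat(seg)
    peak = int(np.argmax(seg))
    dec = seg[peak:]
    inside = np.flatnonzero((dec <= 0.7) & (dec >= 0.1))
    if inside.size < 10:
        return ScalarMeasure(value=math.nan, flagged=True,
                             note="fewer than 10 samples on the decay segment")
    i0, i1 = int(inside[0]), int(inside[-1]) + 1
    t = np.arange(i0, i1) * frame_period
    y = dec[i0:i1]

    def model(tt: np.ndarray, a: float, tau_ms: float) -> np.ndarray:
        return a * np.exp(-tt / tau_ms)

    try:
        popt, _ = curve_fit(
            model, t, y, p0=[float(y[0] * math.exp(t[0] / (t[-1] - t[0] + 1e-9))),
                             max(float(t[-1] - t[0]), frame_period)],
            maxfev=10000,
        )
    except RuntimeError:
        return ScalarMeasure(value=math.nan, flagged=True, note="fit failed")
    resid = y - model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    tau_s = float(popt[1]) / 1000.0
    # shape diagnostic: structured (smooth) log-residuals betray a
    # non-exponential decay even when R2 is high
    curved = False
    if popt[0] > 0 and np.all(y > 0):
        lresid = np.log(y) - np.log(model(t, *popt))
        ss_res = float(np.sum((lresid - lresid.mean()) ** 2))
        if ss_res > 1e-12:
            quad = np.polyval(np.polyfit(t, lresid, 2), t)
            reduction = 1.0 - float(np.sum((lresid - quad) ** 2)) / ss_res
            curved = reduction > 0.5
    flagged = r2 < r2_floor or tau_s <= 0 or curved
    return ScalarMeasure(
        value=tau_s,
        flagged=flagged,
        note=("non-exponential decay shape" if curved
              else f"R2={r2:.3f}" if r2 < r2_floor else ""),
    )


def transition_points(
    trace: np.ndarray, window: BeatWindow | None, frame_period: float
) -> dict[str, ScalarMeasure]:
    """CaT transition points t0, t_on, t30_off, t_off (ms from window start).

    t0 is the 5% upstroke crossing, t_on the peak time, t30_off/t_off the 30%
    and 90% recovery crossings.  ``t_off - t_on`` is the conventional
    calcium recovery time.
    """
    seg, offset = _window_segment(trace, window)
    seg = normalize_beat(seg)
    peak = int(np.argmax(seg))
    base = offset * frame_period

    t0 = None
    for k in range(peak, 0, -1):
        if seg[k - 1] <= 0.05 < seg[k]:
            frac = (0.05 - seg[k - 1]) / (seg[k] - seg[k - 1])
            t0 = (k - 1 + frac) * frame_period
            break
    out: dict[str, ScalarMeasure] = {}
    out["t0"] = (ScalarMeasure(base + t0) if t0 is not None
                 else ScalarMeasure(math.nan, True, "no onset"))
    out["t_on"] = ScalarMeasure(base + peak * frame_period)
    for name, lvl in (("t30_off", 0.7), ("t_off", 0.1)):
        cross = _crossing_after(seg, peak, lvl, frame_period)
        out[name] = (ScalarMeasure(base + cross) if cross is not None
                     else ScalarMeasure(math.nan, True, "recovery level never reached"))
    return out


# ---------------------------------------------------------------------------
# maps


def _nan_aware_smooth3(tmap: np.ndarray) -> np.ndarray:
    """3x3 binomial smoothing applied only where the full neighborhood is
    finite; other pixels keep their original value."""
    from .io import GAUSSIAN3_KERNEL

    out = tmap.copy()
    R, C = tmap.shape
    for r in range(1, R - 1):
        for c in range(1, C - 1):
            win = tmap[r - 1 : r + 2, c - 1 : c + 2]
            if np.all(np.isfinite(win)):
                out[r, c] = float(np.sum(win * GAUSSIAN3_KERNEL))
    return out


def conduction_velocity(
    activation_map: FeatureMap | np.ndarray,
    pixel_pitch: float,
    *,
    neighborhood: int = 5,
    max_speed: float | None = None,
    presmooth: bool = True,
) -> ConductionResult:
    """Velocity field from a local polynomial surface fit of activation time.

    In each ``neighborhood x neighborhood`` window a second-order polynomial
    surface ``T(x, y)`` is least-squares fitted to the activation times; the
    local conduction speed is the inverse of the gradient magnitude at the
    window centre, and the propagation direction follows the gradient.
    Pixels with singular fits (flat gradient, NaN neighbors) are excluded.

    ``presmooth`` applies a 3x3 binomial filter to the activation map first:
    exact on planar fronts, and it tempers the upward speed bias that
    activation-time jitter induces through the convex 1/|gradient| mapping.
    """
    tmap = activation_map.values if isinstance(activation_map, FeatureMap) else activation_map
    tmap = np.asarray(tmap, dtype=float)
    if presmooth and min(tmap.shape) >= 3:
        tmap = _nan_aware_smooth3(tmap)
    R, C = tmap.shape
    h = neighborhood // 2
    if R < neighborhood or C < neighborhood:
        raise InvalidParameterError(
            f"activation map must be at least {neighborhood}x{neighborhood}"
        )
    # design matrix over the window offsets, in mm
    ys, xs = np.meshgrid(
        np.arange(-h, h + 1) * pixel_pitch, np.arange(-h, h + 1) * pixel_pitch,
        indexing="ij",
    )
    A = np.column_stack([
        np.ones(ys.size), xs.ravel(), ys.ravel(),
        xs.ravel() ** 2, ys.ravel() ** 2, (xs * ys).ravel(),
    ])
    pinv = np.linalg.pinv(A)

    speed = np.full((R, C), np.nan)
    direction = np.full((R, C, 2), np.nan)
    for r in range(h, R - h):
        for c in range(h, C - h):
            win = tmap[r - h : r + h + 1, c - h : c + h + 1].ravel()
            if not np.all(np.isfinite(win)):
                continue
            coef = pinv @ win
            gx, gy = coef[1], coef[2]  # ms / mm along cols, rows
            gmag = math.hypot(gx, gy)
            if gmag <= 1e-12:
                continue
            s = 1.0 / gmag
            if max_speed is not None and s > max_speed:
                continue
            speed[r, c] = s
            direction[r, c] = (gy / gmag, gx / gmag)  # (row, col) components

    valid = np.isfinite(speed)
    if not valid.any():
        raise DegenerateSignalError("no valid conduction estimates on the interior")
    mean_speed = float(np.mean(speed[valid]))
    mean_vec = np.nanmean(direction[valid], axis=0)
    coherence = float(np.linalg.norm(mean_vec))
    return ConductionResult(speed=speed, direction=direction,
                            mean_speed=mean_speed, direction_coherence=coherence)


def heterogeneity_iqr(fmap: FeatureMap | np.ndarray) -> float:
    """75th minus 25th percentile over valid pixels (type-7 linear-interpolation
    quantiles), the standard spatial-heterogeneity statistic for duration maps."""
    values = fmap.values if isinstance(fmap, FeatureMap) else np.asarray(fmap, dtype=float)
    vals = values[np.isfinite(values)]
    if vals.size < 4:
        raise InvalidParameterError("IQR needs at least 4 valid pixels")
    q75, q25 = np.percentile(vals, [75.0, 25.0])  # numpy default = linear (type 7)
    return float(q75 - q25)


# ---------------------------------------------------------------------------
# movie-level extraction


def measure_beats(
    movie: Movie,
    mask: Mask | None = None,
    *,
    levels: tuple[float, ...] = (0.3, 0.8, 0.9),
    fit_decay: bool = False,
    temporal_smooth: int | None = None,
) -> dict[tuple[int, int], list[BeatFeature]]:
    """Per-pixel per-beat features for a whole recording.

    Beats are segmented stimulus-locked when the movie carries stimulus
    times, otherwise by threshold detection.  ``fit_decay`` adds the
    monoexponential Tau fit (calcium channel).  ``temporal_smooth`` applies a
    moving-average of that many frames to each pixel trace before feature
    extraction (off by default; useful at high sensor noise).
    """
    windows = segment_beats(movie, mask)
    fp = movie.frame_period
    kernel = None
    if temporal_smooth is not None and temporal_smooth > 1:
        kernel = np.ones(temporal_smooth) / temporal_smooth
    out: dict[tuple[int, int], list[BeatFeature]] = {}
    for (r, c), wins in windows.items():
        trace = movie.pixel_trace(r, c)
        if kernel is not None:
            trace = np.convolve(trace, kernel, mode="same")
        feats: list[BeatFeature] = []
        for w in wins:
            try:
                act = activation_time(trace, w, fp)
            except DegenerateSignalError:
                feats.append(BeatFeature(activation_time=math.nan, flags=["no-upstroke"]))
                continue
            seg = trace[w.slice()]
            feat = BeatFeature(activation_time=act.value,
                               amplitude=upstroke_amplitude(seg))
            if act.flagged:
                feat.flags.append("tied-activation")
            try:
                for lvl in levels:
                    dur = duration_at_level(trace, w, act.value, lvl, fp)
                    setattr(feat, f"apd{int(round(lvl * 100))}",
                            dur.value if not dur.flagged else None)
                    if dur.flagged:
                        feat.flags.append(f"apd{int(round(lvl * 100))}-missing")
                rt = rise_time(trace, w, fp)
                feat.rise_time = rt.value if not rt.flagged else None
                if fit_decay:
                    tau = decay_tau(trace, w, fp)
                    feat.decay_tau = tau.value if not tau.flagged else None
                    if tau.flagged:
                        feat.flags.append("tau-unreliable")
            except DegenerateSignalError:
                feat.flags.append("degenerate-beat")
            feats.append(feat)
        out[(r, c)] = feats
    return out


def feature_map(
    features: dict[tuple[int, int], list[BeatFeature]],
    shape: tuple[int, int],
    attr: str,
    beat: int,
    units: str = "ms",
) -> FeatureMap:
    """Assemble one beat's scalar feature into a grid (NaN where missing)."""
    grid = np.full(shape, np.nan)
    for (r, c), feats in features.items():
        if beat < len(feats):
            val = getattr(feats[beat], attr)
            if val is not None:
                grid[r, c] = val
    return FeatureMap(values=grid, units=units, beat_index=beat)


def feature_stack(
    features: dict[tuple[int, int], list[BeatFeature]],
    shape: tuple[int, int],
    attr: str,
) -> np.ndarray:
    """(n_beats, R, C) array of one scalar feature across all beats."""
    n_beats = max((len(v) for v in features.values()), default=0)
    stack = np.full((n_beats, *shape), np.nan)
    for (r, c), feats in features.items():
        for k, f in enumerate(feats):
            val = getattr(f, attr)
            if val is not None and not (isinstance(val, float) and math.isnan(val)):
                stack[k, r, c] = val
    return stack
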
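"""Stimulation-protocol analysis: Ca release restitution, AERP, SNRT, AF
episode metrics, and RyR2/SERCA rate constants.

The S1S2 extrastimulus protocol probes calcium-release refractoriness: a
drive train of S1 beats is followed by one premature S2 beat at a coupling
interval; the S2/S1 CaT amplitude ratio as a function of coupling interval is
the Ca release restitution curve, fitted here by a monoexponential with a
latency offset (ratios are undefined below the refractory period).  The same
protocol yields the atrial effective refractory period (AERP): the longest
coupling interval that fails to elicit a propagated response.  Overdrive
pacing yields the sinus-node recovery time (SNRT); irregular rapid activation
sequences are classified into AF-like episodes by cycle-length criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateSignalError, InvalidParameterError


@dataclass
class RestitutionFit:
    """Monoexponential Ca-release restitution fit.

    ratio(interval) = asymptote * (1 - exp(-(interval - latency) / tau_r));
    ``steepness`` is the maximum fitted slope over the tested interval range,
    expressed in percent per ms (x100).
    """

    asymptote: float
    tau_r: float
    latency: float
    steepness: float
    r2: float
    flagged: bool = False
    note: str = ""


@dataclass
class S2S1Result:
    """S2/S1 CaT amplitude ratios for one coupling interval."""

    interval: float
    ratio_map: np.ndarray  # (R, C)
    site_ratios: list[float]
    field_ratio: float
    captured: bool = True


@dataclass
class RefractoryResult:
    """AERP estimate with the drive-train APD context."""

    aerp: float | None
    lower_bound: float | None = None
    upper_bound: float | None = None
    apd90: float | None = None

    @property
    def aerp_apd_ratio(self) -> float | None:
        if self.aerp is None or not self.apd90:
            return None
        return self.aerp / self.apd90


@dataclass
class EctopyReport:
    """Detected AF-like episodes of one pacing run."""

    episodes: list[tuple[float, float]] = field(default_factory=list)
    total_duration_s: float = 0.0
    induced: bool = False

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)


@dataclass
class FluxRates:
    """Sarcoplasmic-reticulum flux estimates.

    ``ryr2_rate`` is the maximal release rate from the caffeine-transient
    upstroke (normalized amplitude per second); ``serca_rate_inv`` is the
    time constant of amplitude recovery with release blocked (seconds, an
    inverse-rate), with the polynomial-derivative estimate as a diagnostic.
    """

    ryr2_rate: float | None
    serca_rate_inv: float | None
    serca_poly_rate: float | None = None
    flagged: bool = False
    note: str = ""


# ---------------------------------------------------------------------------
# S2/S1 ratios and restitution


def s2s1_ratio(
    amplitudes: np.ndarray,
    beat_labels: Sequence[str],
    *,
    interval: float,
    sites: Sequence[tuple[int, int]] = (),
    n_reference: int = 3,
) -> S2S1Result:
    """S2/S1 CaT amplitude ratio per pixel, at configured sites, and field-wide.

    ``amplitudes`` is a (n_beats, rows, cols) stack of per-beat CaT amplitudes
    for one S1 train plus its S2; the S1 reference is the mean amplitude of
    the last ``n_reference`` S1 beats (steady state after the drive train).
    A missing S2 beat (all-NaN map) marks the interval non-captured.
    """
    amps = np.asarray(amplitudes, dtype=float)
    labels = list(beat_labels)
    if amps.shape[0] != len(labels):
        raise InvalidParameterError("one label per beat required")
    s2_idx = [i for i, l in enumerate(labels) if l == "s2"]
    if len(s2_idx) != 1:
        raise InvalidParameterError("exactly one S2 beat expected per train")
    s1_idx = [i for i, l in enumerate(labels) if l == "s1" and i < s2_idx[0]]
    if len(s1_idx) < n_reference:
        raise InvalidParameterError(f"need at least {n_reference} S1 beats before the S2")
    ref = np.nanmean(amps[s1_idx[-n_reference:]], axis=0)
    s2 = amps[s2_idx[0]]
    if not np.any(np.isfinite(s2)):
        nan_map = np.full(amps.shape[1:], np.nan)
        return S2S1Result(interval=interval, ratio_map=nan_map,
                          site_ratios=[math.nan] * len(sites),
                          field_ratio=math.nan, captured=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = s2 / ref
    site_ratios = [float(ratio[r, c]) for r, c in sites]
    return S2S1Result(interval=interval, ratio_map=ratio, site_ratios=site_ratios,
                      field_ratio=float(np.nanmean(ratio)), captured=True)


def fit_restitution(
    intervals: Sequence[float],
    ratios: Sequence[float],
    *,
    fix_latency: float | None = None,
) -> RestitutionFit:
    """Fit ratio(d) = A * (1 - exp(-(d - d0) / tau_r)) to a restitution curve.

    Degenerate curves (flat ratios, too few captured intervals after dropping
    NaNs) return a flagged fit rather than raising.  ``steepness`` is the
    maximum derivative over the tested intervals, x100 (percent per ms).
    """
    d = np.asarray(intervals, dtype=float)
    r = np.asarray(ratios, dtype=float)
    keep = np.isfinite(d) & np.isfinite(r)
    d, r = d[keep], r[keep]
    if d.size < 4:
        raise InvalidParameterError("restitution fit needs >= 4 captured intervals")
    if float(np.ptp(r)) < 1e-12:
        return RestitutionFit(asymptote=float(r.mean()), tau_r=math.nan,
                              latency=math.nan, steepness=0.0, r2=0.0,
                              flagged=True, note="flat curve: tau unidentifiable")

    def model(x: np.ndarray, a: float, tau: float, d0: float) -> np.ndarray:
        return a * (1.0 - np.exp(-np.maximum(x - d0, 0.0) / tau))

    span = float(d.max() - d.min())
    best = None
    for tau0 in (span / 4.0, span / 2.0, span):
        for d00 in ((0.0,) if fix_latency is None else (fix_latency,)) + (
            () if fix_latency is not None else (float(d.min()) / 2.0,)
        ):
            try:
                if fix_latency is not None:
                    popt, _ = curve_fit(
                        lambda x, a, tau: model(x, a, tau, fix_latency),
                        d, r, p0=[float(r.max()), tau0], maxfev=20000,
                    )
                    params = (float(popt[0]), float(popt[1]), fix_latency)
                else:
                    popt, _ = curve_fit(model, d, r,
                                        p0=[float(r.max()), tau0, d00], maxfev=20000)
                    params = tuple(float(v) for v in popt)
                sse = float(np.sum((model(d, *params) - r) ** 2))
                if best is None or sse < best[1]:
                    best = (params, sse)
            except RuntimeError:
                continue
    if best is None:
        return RestitutionFit(asymptote=math.nan, tau_r=math.nan, latency=math.nan,
                              steepness=math.nan, r2=math.nan, flagged=True,
                              note="fit did not converge")
    (a, tau, d0), sse = best
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
    # max derivative over tested range: A/tau * exp(-(d - d0)/tau), largest at
    # the smallest tested interval above the latency
    dd = np.linspace(max(float(d.min()), d0), float(d.max()), 200)
    steep = float(np.max(a / tau * np.exp(-(dd - d0) / tau))) * 100.0
    return RestitutionFit(asymptote=a, tau_r=tau, latency=d0, steepness=steep,
                          r2=r2, flagged=tau <= 0 or r2 < 0.8,
                          note="" if r2 >= 0.8 else f"poor fit R2={r2:.3f}")


# ---------------------------------------------------------------------------
# refractoriness / capture


def detect_capture(
    s2_amplitude: np.ndarray,
    s1_reference: np.ndarray,
    *,
    amplitude_frac: float = 0.5,
    pixel_frac: float = 0.5,
) -> bool:
    """Capture rule for a premature beat.

    The S2 is considered propagated when at least ``pixel_frac`` of the
    masked pixels show an upstroke of at least ``amplitude_frac`` of their
    steady-state S1 amplitude.
    """
    s2 = np.asarray(s2_amplitude, dtype=float)
    ref = np.asarray(s1_reference, dtype=float)
    valid = np.isfinite(ref) & (ref > 0)
    if not valid.any():
        raise DegenerateSignalError("no valid S1 reference amplitudes")
    frac = np.nan_to_num(s2[valid], nan=0.0) / ref[valid]
    return float(np.mean(frac >= amplitude_frac)) >= pixel_frac


def aerp_from_s1s2(
    capture_by_interval: Mapping[float, bool],
    *,
    apd90: float | None = None,
) -> RefractoryResult:
    """AERP = longest tested S2 interval that fails to elicit a response.

    When every interval captures, the AERP lies below the tested range and
    only an upper bound is reported; when none captures, only a lower bound.
    """
    if not capture_by_interval:
        raise InvalidParameterError("no S2 outcomes provided")
    intervals = sorted(capture_by_interval)
    failures = [i for i in intervals if not capture_by_interval[i]]
    if not failures:
        return RefractoryResult(aerp=None, upper_bound=min(intervals), apd90=apd90)
    if all(not capture_by_interval[i] for i in intervals):
        return RefractoryResult(aerp=None, lower_bound=max(intervals), apd90=apd90)
    return RefractoryResult(aerp=float(max(failures)), apd90=apd90)


def snrt(
    activation_times: Sequence[float],
    last_stimulus: float,
    baseline_cl: float,
    *,
    window_ms: float = 5000.0,
) -> tuple[float, float] | None:
    """Sinus-node recovery time after overdrive pacing.

    Raw SNRT is the delay from the last paced beat to the first spontaneous
    activation; corrected SNRT subtracts the baseline cycle length (the
    pause excess).  Returns None when no spontaneous beat occurs within the
    search window.
    """
    times = np.asarray(activation_times, dtype=float)
    after = times[(times > last_stimulus) & (times <= last_stimulus + window_ms)]
    if after.size == 0:
        return None
    raw = float(after[0] - last_stimulus)
    return raw, raw - baseline_cl


# ---------------------------------------------------------------------------
# AF episode detection


def detect_episodes(
    activation_times: Sequence[float],
    baseline_cl: float,
    *,
    min_cycles: int = 5,
    cl_factor: float = 0.6,
    cv_min: float = 0.1,
    candidate_factor: float = 0.75,
) -> EctopyReport:
    """Classify runs of rapid irregular cycles as AF-like episodes.

    An episode is at least ``min_cycles`` consecutive cycles, each shorter
    than ``candidate_factor`` x baseline, whose run additionally satisfies
    mean CL < ``cl_factor`` x baseline and coefficient of variation >
    ``cv_min``.  An empty report (regular rhythm) is a valid outcome, not an
    error.
    """
    times = np.asarray(activation_times, dtype=float)
    if times.size < 11:
        raise InvalidParameterError("episode detection needs at least 10 intervals")
    cls = np.diff(times)
    candidate = cls < candidate_factor * baseline_cl
    episodes: list[tuple[float, float]] = []
    i = 0
    n = cls.size
    while i < n:
        if not candidate[i]:
            i += 1
            continue
        j = i
        while j < n and candidate[j]:
            j += 1
        run = cls[i:j]
        if run.size >= min_cycles:
            mean_cl = float(run.mean())
            cv = float(run.std(ddof=0) / mean_cl) if mean_cl > 0 else 0.0
            if mean_cl < cl_factor * baseline_cl and cv > cv_min:
                episodes.append((float(times[i]), float(times[j])))
        i = j
    total_s = sum(b - a for a, b in episodes) / 1000.0
    return EctopyReport(episodes=episodes, total_duration_s=total_s,
                        induced=bool(episodes))


# ---------------------------------------------------------------------------
# RyR2 / SERCA flux rates


def _poly_max_derivative(t: np.ndarray, y: np.ndarray, order: int = 3) -> float:
    coefs = np.polyfit(t, y, order)
    dcoefs = np.polyder(coefs)
    grid = np.linspace(float(t[0]), float(t[-1]), 200)
    return float(np.max(np.polyval(dcoefs, grid)))


def flux_rates(
    caffeine_time: Sequence[float],
    caffeine_values: Sequence[float],
    recovery_time: Sequence[float],
    recovery_amplitude: Sequence[float],
) -> FluxRates:
    """RyR2 release rate and SERCA recovery constant from flux protocols.

    The RyR2 rate is the maximum first derivative of a 3rd-order polynomial
    fit to the caffeine-transient upstroke (from 5% of amplitude to the
    peak), in normalized amplitude per second.  The SERCA inverse rate is the
    time constant of an exponential fit ``A - B exp(-t/tau)`` to CaT
    amplitude recovery with release blocked (tetracaine), in seconds; the
    polynomial max-derivative estimate of the same series is reported as a
    diagnostic.  Degenerate inputs (flat transient, failed fits) flag the
    result instead of raising.
    """
    ct = np.asarray(caffeine_time, dtype=float)
    cv = np.asarray(caffeine_values, dtype=float)
    rt = np.asarray(recovery_time, dtype=float)
    ra = np.asarray(recovery_amplitude, dtype=float)

    ryr2: float | None = None
    flagged = False
    notes: list[str] = []
    amp = float(cv.max() - cv.min())
    if amp <= 0:
        flagged, notes = True, ["flat caffeine transient"]
    else:
        norm = (cv - cv.min()) / amp
        peak = int(np.argmax(norm))
        onset = 0
        for k in range(peak, 0, -1):
            if norm[k - 1] <= 0.05 < norm[k]:
                onset = k - 1
                break
        seg_t, seg_v = ct[onset : peak + 1], norm[onset : peak + 1]
        if seg_t.size < 5:
            flagged = True
            notes.append("caffeine upstroke shorter than 5 samples")
        elif np.any(np.diff(seg_v) < -0.05):
            flagged = True
            notes.append("non-monotone caffeine upstroke")
        else:
            ryr2 = _poly_max_derivative(seg_t, seg_v)

    serca: float | None = None
    serca_poly: float | None = None
    if rt.size < 5:
        flagged = True
        notes.append("recovery series shorter than 5 points")
    else:
        def rec_model(t: np.ndarray, a: float, b: float, tau: float) -> np.ndarray:
            return a - b * np.exp(-t / tau)

        try:
            popt, _ = curve_fit(
                rec_model, rt, ra,
                p0=[float(ra.max()), float(ra.max() - ra.min()),
                    max(float(rt[-1] - rt[0]) / 3.0, 1e-6)],
                maxfev=20000,
            )
            serca = float(popt[2])
            serca_poly = _poly_max_derivative(rt, ra)
            if serca <= 0:
                flagged = True
                notes.append("non-physical recovery constant")
        except RuntimeError:
            flagged = True
            notes.append("recovery fit did not converge")

    return FluxRates(ryr2_rate=ryr2, serca_rate_inv=serca, serca_poly_rate=serca_poly,
                     flagged=flagged, note="; ".join(notes))
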
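"""Ground-truth-labeled synthetic optical-mapping data.

This module emulates the statistical structure that the downstream analysis
assumes: paced 2-D wavefront propagation at a set conduction velocity, action
potential (AP) and calcium transient (CaT) waveforms with configurable
durations and decay constants, restitution-driven beat-to-beat alternans with
regional phase structure, premature-beat (S2) amplitude suppression governed
by release refractoriness, AF-like irregular activation episodes, and
additive Gaussian sensor noise.  Every emitted movie comes with a
:class:`GroundTruth` whose labels are consistent with the pixel data by
construction, which is what makes the analysis modules testable.

Waveform family
---------------
The AP upstroke is a raised-cosine sigmoid over ``rise_time`` (unique maximal
upstroke velocity at its midpoint) and repolarization is a cosine shoulder
scaled so that the 90%-recovery instant falls exactly ``apd90`` after the
upstroke-velocity maximum — the operational APD90 definition used by the
measurement code is therefore exact by construction, without solving an ionic
model.  The CaT shares the upstroke, holds a plateau, and decays as a single
exponential with time constant ``decay_tau`` so that a monoexponential Tau
refit recovers the truth.

Restitution dynamics
--------------------
Beat-to-beat APD dynamics follow the standard restitution iterated map

    APD_{n+1} = f(CL - APD_n),    f(DI) = apd_max * (1 - exp(-DI / tau_rest))

with the diastolic interval clipped below at ``DI_FLOOR`` (5 ms) so the map
stays total at aggressive cycle lengths.  Alternans appears when the slope of
``f`` at the fixed point exceeds 1 in magnitude, exactly as in the classical
linear-stability analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .io import Movie

#: diastolic-interval floor (ms) keeping the iterated map total
DI_FLOOR = 5.0

#: fraction of the cosine repolarization phase at which 90% recovery occurs
_C90 = math.acos(-0.8) / math.pi

#: measured 10-90% rise time of the raised-cosine upstroke, as a fraction of
#: the ``rise_time`` parameter (foot-to-peak duration)
RISE_CALIBRATION = (math.acos(-0.8) - math.acos(0.8)) / math.pi


def _cos_level_frac(level: float) -> float:
    """Fraction of the repolarization phase at which ``level`` recovery occurs."""
    return math.acos(1.0 - 2.0 * level) / math.pi


def ap_duration_truth(apd90: float, rise_time: float, level: float) -> float:
    """Exact duration from dF/dt-max to ``level`` recovery of the AP family."""
    t_rep = (apd90 - rise_time / 2.0) / _C90
    return rise_time / 2.0 + _cos_level_frac(level) * t_rep


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class RestitutionParams:
    """Per-region electrophysiology parameters of the generator.

    Parameters
    ----------
    apd_max
        Plateau (long-DI asymptote) of the APD restitution curve, ms.
    tau_rest
        Restitution time constant, ms; small values give a flat curve.
    cat_decay_tau
        CaT decay time constant, s (the quantity reported as Tau).
    cat_amp_tau_refr
        Recovery constant of CaT amplitude after a premature beat, ms; the
        S2/S1 amplitude ratio is ``1 - exp(-interval / cat_amp_tau_refr)``.
    rise_time
        Foot-to-peak upstroke duration, ms.
    cat90_offset
        CaT90 minus APD90 for the same beat, ms (CaT outlasts the AP).
    """

    apd_max: float = 40.0
    tau_rest: float = 15.0
    cat_decay_tau: float = 0.01
    cat_amp_tau_refr: float = 60.0
    rise_time: float = 12.5
    cat90_offset: float = 25.0

    def __post_init__(self) -> None:
        for name in ("apd_max", "tau_rest", "cat_decay_tau", "cat_amp_tau_refr",
                     "rise_time", "cat90_offset"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")

    def restitution(self, di: float | np.ndarray) -> float | np.ndarray:
        """APD restitution function f(DI) = apd_max * (1 - exp(-DI/tau_rest))."""
        return self.apd_max * (1.0 - np.exp(-np.asarray(di, dtype=float) / self.tau_rest))

    def restitution_slope(self, di: float) -> float:
        """Derivative f'(DI)."""
        return self.apd_max / self.tau_rest * math.exp(-di / self.tau_rest)


@dataclass(frozen=True)
class Region:
    """Spatial region with its own restitution parameters and alternans phase.

    ``phase_offset`` of 1 shifts the beat sequence by one beat relative to
    offset-0 regions, imposing spatially discordant alternans by construction.
    ``amp_alternans`` imposes a CaT-amplitude alternans of that magnitude
    (large beat 1.0, small beat ``1 - amp_alternans``): exact ground truth for
    testing.  ``amp_from_di`` instead couples CaT amplitude to the preceding
    diastolic interval through the release-restitution relation
    ``1 - exp(-DI / cat_amp_tau_refr)``, so amplitude alternans emerges
    mechanically from APD alternans at fast pacing.
    """

    mask: np.ndarray
    params: RestitutionParams = RestitutionParams()
    phase_offset: int = 0
    amp_alternans: float = 0.0
    amp_from_di: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.phase_offset not in (0, 1):
            raise InvalidParameterError("phase_offset must be 0 or 1")
        if not 0.0 <= self.amp_alternans < 1.0:
            raise InvalidParameterError("amp_alternans must lie in [0, 1)")
        if self.amp_alternans > 0 and self.amp_from_di:
            raise InvalidParameterError("choose either imposed or DI-coupled amplitudes")


@dataclass(frozen=True)
class TissueSpec:
    """Geometry and physiology of the synthetic 2-D tissue sheet."""

    grid_rows: int = 16
    grid_cols: int = 16
    pixel_pitch: float = 0.1  # mm / pixel
    conduction_velocity: float = 0.5  # mm / ms
    pacing_site: tuple[int, int] = (0, 0)
    regions: tuple[Region, ...] = ()
    aerp_ms: float = 45.0
    wave_geometry: str = "point"  # "point" (circular) or "plane"

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise InvalidParameterError("tissue grid must be at least 8x8")
        if self.conduction_velocity <= 0:
            raise InvalidParameterError("conduction_velocity must be positive")
        if self.wave_geometry not in ("point", "plane"):
            raise InvalidParameterError("wave_geometry must be 'point' or 'plane'")
        pr, pc = self.pacing_site
        if not (0 <= pr < self.grid_rows and 0 <= pc < self.grid_cols):
            raise InvalidParameterError("pacing_site must lie inside the grid")
        regions = self.regions or (
            Region(mask=np.ones((self.grid_rows, self.grid_cols), dtype=bool)),
        )
        object.__setattr__(self, "regions", tuple(regions))
        cover = np.zeros((self.grid_rows, self.grid_cols), dtype=int)
        for reg in self.regions:
            if reg.mask.shape != (self.grid_rows, self.grid_cols):
                raise InvalidParameterError("region mask shape must match the grid")
            cover += reg.mask.astype(int)
        if not np.all(cover == 1):
            raise InvalidParameterError("regions must partition the grid exactly")

    def propagation_delays(self) -> np.ndarray:
        """Per-pixel wavefront arrival delay from the pacing site, ms."""
        rr, cc = np.meshgrid(
            np.arange(self.grid_rows), np.arange(self.grid_cols), indexing="ij"
        )
        pr, pc = self.pacing_site
        if self.wave_geometry == "plane":
            dist = np.abs(cc - pc) * self.pixel_pitch
        else:
            dist = np.hypot(rr - pr, cc - pc) * self.pixel_pitch
        return dist / self.conduction_velocity


def four_region_layout(
    rows: int,
    cols: int,
    params: RestitutionParams,
    *,
    offset_quadrant: int = 0,
    amp_alternans: float = 0.0,
    offset_params: RestitutionParams | None = None,
) -> tuple[Region, ...]:
    """Quadrant partition with one quadrant in opposite alternans phase.

    Mirrors the observed phenotype of one area alternating out of phase with
    the other three; ``offset_quadrant`` selects which quadrant (0..3, row-
    major) carries ``phase_offset=1``.
    """
    hr, hc = rows // 2, cols // 2
    slices = [
        (slice(0, hr), slice(0, hc)),
        (slice(0, hr), slice(hc, cols)),
        (slice(hr, rows), slice(0, hc)),
        (slice(hr, rows), slice(hc, cols)),
    ]
    regions = []
    for i, (rs, cs) in enumerate(slices):
        mask = np.zeros((rows, cols), dtype=bool)
        mask[rs, cs] = True
        regions.append(
            Region(
                mask=mask,
                params=(offset_params if (offset_params is not None and i == offset_quadrant)
                        else params),
                phase_offset=1 if i == offset_quadrant else 0,
                amp_alternans=amp_alternans,
            )
        )
    return tuple(regions)


@dataclass(frozen=True)
class ProtocolSpec:
    """Stimulation protocol.

    Modes: ``sinus`` (intrinsic-like regular rhythm, stimulus times not
    recorded in the movie metadata), ``fixed_rate`` (recorded pacing train),
    ``S1S1_decremental`` (trains at progressively shorter cycle lengths), and
    ``S1S2_extrastimulus`` (drive train plus one premature beat per tested
    coupling interval).
    """

    mode: str = "fixed_rate"
    s1_cycle_length: float = 1000.0 / 6.0  # 6 Hz drive
    s1_count: int = 10
    s2_intervals: tuple[float, ...] = ()
    cl_sequence: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        modes = ("sinus", "fixed_rate", "S1S1_decremental", "S1S2_extrastimulus")
        if self.mode not in modes:
            raise InvalidParameterError(f"mode must be one of {modes}")
        if self.s1_cycle_length <= 0:
            raise InvalidParameterError("s1_cycle_length must be positive")
        if self.s1_count < 1:
            raise InvalidParameterError("s1_count must be at least 1")
        object.__setattr__(self, "s2_intervals", tuple(float(v) for v in self.s2_intervals))
        object.__setattr__(self, "cl_sequence", tuple(float(v) for v in self.cl_sequence))
        if self.mode == "S1S2_extrastimulus" and not self.s2_intervals:
            raise InvalidParameterError("S1S2 mode requires non-empty s2_intervals")
        if self.mode == "S1S1_decremental":
            if not self.cl_sequence:
                raise InvalidParameterError("S1S1_decremental requires cl_sequence")
            if any(b >= a for a, b in zip(self.cl_sequence, self.cl_sequence[1:])):
                raise InvalidParameterError("cl_sequence must be strictly decreasing")

    def schedule(self) -> tuple[list[float], list[str], dict[int, float]]:
        """Stimulus times (ms), beat labels, and {beat index: S2 interval}."""
        t0 = 10.0
        times: list[float] = []
        labels: list[str] = []
        s2_of: dict[int, float] = {}
        if self.mode in ("sinus", "fixed_rate"):
            times = [t0 + k * self.s1_cycle_length for k in range(self.s1_count)]
            labels = ["s1"] * self.s1_count
        elif self.mode == "S1S1_decremental":
            t = t0
            for cl in self.cl_sequence:
                for _ in range(self.s1_count):
                    times.append(t)
                    labels.append("s1")
                    t += cl
        else:  # S1S2_extrastimulus
            t = t0
            for s2 in self.s2_intervals:
                for _ in range(self.s1_count):
                    times.append(t)
                    labels.append("s1")
                    t += self.s1_cycle_length
                # last S1 fired at t - CL; S2 follows at the coupling interval
                s2_time = t - self.s1_cycle_length + s2
                times.append(s2_time)
                labels.append("s2")
                s2_of[len(times) - 1] = s2
                t = s2_time + 2.0 * self.s1_cycle_length  # rest gap before next train
        return times, labels, s2_of


@dataclass(frozen=True)
class NoiseSpec:
    """Additive i.i.d. Gaussian sensor noise, in fractional amplitude units."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError("noise sigma must be non-negative")


@dataclass
class GroundTruth:
    """Labels consistent with the emitted movie by construction."""

    activation_times: np.ndarray  # (n_beats, R, C) ms; NaN for missed beats
    apd90: np.ndarray
    apd30: np.ndarray
    apd80: np.ndarray
    cat90: np.ndarray
    cat_amplitudes: np.ndarray  # (n_beats, R, C)
    region_phase: np.ndarray  # (R, C): 0 or 1 beat offset
    region_amp_alternans: np.ndarray  # (R, C)
    stimulus_times: list[float]
    beat_labels: list[str]
    s2_interval_of_beat: dict[int, float]
    s2_captured: dict[float, bool]
    true_aerp: float
    af_episodes: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# single-beat waveforms


@dataclass(frozen=True)
class Waveform:
    """Sampled single-beat trace with its construction truth."""

    values: np.ndarray
    frame_period: float
    t_activation: float  # instant of maximal upstroke velocity, ms from sample 0

    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.frame_period


def _ap_value(t: np.ndarray, apd90: float, rise_time: float) -> np.ndarray:
    """Continuous AP waveform; foot of upstroke at t = 0, amplitude 1."""
    t_rep = (apd90 - rise_time / 2.0) / _C90
    v = np.zeros_like(t, dtype=float)
    up = (t >= 0) & (t < rise_time)
    v[up] = 0.5 * (1.0 - np.cos(np.pi * t[up] / rise_time))
    rep = (t >= rise_time) & (t < rise_time + t_rep)
    v[rep] = 0.5 * (1.0 + np.cos(np.pi * (t[rep] - rise_time) / t_rep))
    return v


def _ap_length(apd90: float, rise_time: float) -> float:
    return rise_time + (apd90 - rise_time / 2.0) / _C90


def make_ap_waveform(
    apd90: float, rise_time: float, frame_period: float, *, pad_ms: float = 10.0
) -> Waveform:
    """Single-beat normalized AP trace whose APD90 is exact by construction.

    The trace rises 0 to 1 over ``rise_time`` with a unique dF/dt maximum at
    ``rise_time / 2``, then repolarizes along a cosine shoulder so the
    90%-recovery instant is exactly ``apd90`` after the dF/dt maximum.
    """
    if not (apd90 > rise_time > 2.0 * frame_period):
        raise InvalidParameterError(
            "require apd90 > rise_time > 2 * frame_period "
            f"(got apd90={apd90}, rise_time={rise_time}, frame_period={frame_period})"
        )
    total = _ap_length(apd90, rise_time) + pad_ms
    t = np.arange(0.0, total, frame_period)
    return Waveform(values=_ap_value(t, apd90, rise_time), frame_period=frame_period,
                    t_activation=rise_time / 2.0)


def _cat_plateau(cat90: float, rise_time: float, decay_tau_s: float) -> float:
    """Plateau length making the 90%-recovery instant land exactly at cat90."""
    tau_ms = decay_tau_s * 1000.0
    plateau = cat90 - rise_time / 2.0 - tau_ms * math.log(10.0)
    if plateau < 0:
        raise InvalidParameterError(
            f"cat90={cat90} ms unreachable: decay alone takes "
            f"{rise_time / 2.0 + tau_ms * math.log(10.0):.1f} ms to 90% recovery"
        )
    return plateau


def _cat_value(
    t: np.ndarray, cat90: float, rise_time: float, decay_tau_s: float
) -> np.ndarray:
    """Continuous CaT waveform: cosine upstroke, plateau, monoexponential decay."""
    tau_ms = decay_tau_s * 1000.0
    plateau = _cat_plateau(cat90, rise_time, decay_tau_s)
    v = np.zeros_like(t, dtype=float)
    up = (t >= 0) & (t < rise_time)
    v[up] = 0.5 * (1.0 - np.cos(np.pi * t[up] / rise_time))
    flat = (t >= rise_time) & (t < rise_time + plateau)
    v[flat] = 1.0
    dec = t >= rise_time + plateau
    v[dec] = np.exp(-(t[dec] - rise_time - plateau) / tau_ms)
    return v


def _cat_length(cat90: float, rise_time: float, decay_tau_s: float) -> float:
    # run the decay to 0.1% of amplitude so decay fits see a clean baseline
    tau_ms = decay_tau_s * 1000.0
    return rise_time + _cat_plateau(cat90, rise_time, decay_tau_s) + tau_ms * math.log(1000.0)


def make_cat_waveform(
    cat90: float, rise_time: float, decay_tau: float, frame_period: float
) -> Waveform:
    """Single-beat normalized CaT trace with an exactly monoexponential decay.

    ``decay_tau`` is in seconds, matching the magnitude convention of Tau
    reporting (0.01-0.08 s) against millisecond durations.
    """
    if rise_time <= 2.0 * frame_period:
        raise InvalidParameterError("rise_time must exceed 2 * frame_period")
    if decay_tau <= 0:
        raise InvalidParameterError("decay_tau must be positive")
    total = _cat_length(cat90, rise_time, decay_tau) + 5.0
    t = np.arange(0.0, total, frame_period)
    return Waveform(values=_cat_value(t, cat90, rise_time, decay_tau),
                    frame_period=frame_period, t_activation=rise_time / 2.0)


# ---------------------------------------------------------------------------
# restitution dynamics


def iterate_restitution(
    params: RestitutionParams,
    cycle_length: float,
    n_beats: int,
    apd_init: float,
    *,
    di_floor: float = DI_FLOOR,
) -> np.ndarray:
    """Iterate APD_{n+1} = f(CL - APD_n) for ``n_beats`` beats.

    The diastolic interval is clipped below at ``di_floor`` so the map is
    total even at aggressive cycle lengths.  Steady state is period-1 when
    |f'| < 1 at the fixed point and period-2 (alternans) when |f'| > 1.
    """
    if n_beats < 2:
        raise InvalidParameterError("n_beats must be at least 2")
    seq = np.empty(n_beats, dtype=float)
    seq[0] = apd_init
    for k in range(1, n_beats):
        di = max(cycle_length - seq[k - 1], di_floor)
        seq[k] = params.restitution(di)
    return seq


def restitution_fixed_point(
    params: RestitutionParams, cycle_length: float, *, di_floor: float = DI_FLOOR
) -> tuple[float, float]:
    """Fixed point APD* of the map and the slope |f'| there.

    Solved by bisection on g(APD) = f(CL - APD) - APD, which is strictly
    decreasing in APD.
    """
    lo, hi = 0.0, min(params.apd_max, cycle_length - di_floor)
    if hi <= lo:
        hi = params.apd_max
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if params.restitution(max(cycle_length - mid, di_floor)) - mid > 0:
            lo = mid
        else:
            hi = mid
    apd_star = 0.5 * (lo + hi)
    slope = params.restitution_slope(max(cycle_length - apd_star, di_floor))
    return apd_star, slope


def steady_alternans_amplitude(
    params: RestitutionParams,
    cycle_length: float,
    *,
    n_burn: int = 500,
    n_measure: int = 64,
    apd_init: float | None = None,
) -> float:
    """|APD(odd) - APD(even)| of the steady orbit, by direct long iteration."""
    init = apd_init if apd_init is not None else 0.8 * params.apd_max
    seq = iterate_restitution(params, cycle_length, n_burn + n_measure, init)
    tail = seq[n_burn:]
    return abs(float(tail[0::2].mean() - tail[1::2].mean()))


# ---------------------------------------------------------------------------
# movie synthesis


def _region_apd_sequence(
    params: RestitutionParams,
    stim_times: Sequence[float],
    phase_offset: int,
    apd_init: float,
) -> np.ndarray:
    """Per-beat APD driven by the actual inter-stimulus intervals.

    A phase offset of 1 advances the map by one extra (virtual) beat before
    the train starts, which flips the alternans parity without breaking the
    dynamics.
    """
    init = apd_init
    if phase_offset:
        cl0 = stim_times[1] - stim_times[0] if len(stim_times) > 1 else 1e3
        init = float(params.restitution(max(cl0 - apd_init, DI_FLOOR)))
    apds = np.empty(len(stim_times), dtype=float)
    prev = init
    apds[0] = init
    for k in range(1, len(stim_times)):
        di = max(stim_times[k] - stim_times[k - 1] - prev, DI_FLOOR)
        apds[k] = params.restitution(di)
        prev = apds[k]
    return apds


def simulate_movie(
    tissue: TissueSpec,
    protocol: ProtocolSpec,
    noise: NoiseSpec = NoiseSpec(),
    *,
    frame_rate: float = 900.0,
    apd_init: float | None = None,
) -> tuple[Movie, Movie, GroundTruth]:
    """Emit paired voltage and calcium movies plus exact ground truth.

    A circular (point-source) or plane wave propagates from the pacing site at
    the tissue's conduction velocity; each pixel plays the AP/CaT waveform of
    its region with restitution-driven per-beat durations, the region's
    alternans phase offset, imposed CaT-amplitude alternans if configured,
    and S2 amplitude suppression ``1 - exp(-interval / cat_amp_tau_refr)``.
    S2 beats at or below the tissue AERP are omitted and flagged non-captured.
    """
    fp = 1000.0 / frame_rate
    stim_times, labels, s2_of = protocol.schedule()
    n_beats = len(stim_times)
    R, C = tissue.grid_rows, tissue.grid_cols
    delays = tissue.propagation_delays()
    max_delay = float(delays.max())

    # feasibility: propagation must fit inside the shortest inter-stimulus gap
    gaps = np.diff(stim_times) if n_beats > 1 else np.array([np.inf])
    if n_beats > 1 and max_delay >= float(np.min(gaps)):
        raise InvalidParameterError(
            "propagation across the tissue outlasts the shortest pacing interval"
        )

    # per-region beat-wise APD and CaT amplitude truth
    region_of = np.full((R, C), -1, dtype=int)
    apd_by_region: list[np.ndarray] = []
    amp_by_region: list[np.ndarray] = []
    for ridx, reg in enumerate(tissue.regions):
        region_of[reg.mask] = ridx
        init = apd_init if apd_init is not None else 0.8 * reg.params.apd_max
        apds = _region_apd_sequence(reg.params, stim_times, reg.phase_offset, init)
        amps = np.ones(n_beats, dtype=float)
        if reg.amp_alternans > 0:
            small = (np.arange(n_beats) + reg.phase_offset) % 2 == 1
            amps[small] = 1.0 - reg.amp_alternans
        elif reg.amp_from_di:
            for k in range(1, n_beats):
                di = max(stim_times[k] - stim_times[k - 1] - apds[k - 1], DI_FLOOR)
                amps[k] = 1.0 - math.exp(-di / reg.params.cat_amp_tau_refr)
        for bidx, s2_int in s2_of.items():
            amps[bidx] = 1.0 - math.exp(-s2_int / reg.params.cat_amp_tau_refr)
        apd_by_region.append(apds)
        amp_by_region.append(amps)

    s2_captured = {s2: s2 > tissue.aerp_ms for s2 in s2_of.values()}
    captured = np.array(
        [s2_captured[s2_of[k]] if k in s2_of else True for k in range(n_beats)]
    )

    longest_beat = 50.0
    if captured.any():
        for i, reg in enumerate(tissue.regions):
            p = reg.params
            cat_min = p.rise_time / 2.0 + p.cat_decay_tau * 1000.0 * math.log(10.0) + 1e-6
            for a in apd_by_region[i][captured]:
                longest_beat = max(
                    longest_beat,
                    _ap_length(a, p.rise_time),
                    _cat_length(max(a + p.cat90_offset, cat_min), p.rise_time,
                                p.cat_decay_tau),
                )
    duration = stim_times[-1] + max_delay + longest_beat + 150.0
    n_frames = int(math.ceil(duration / fp))
    t_axis = np.arange(n_frames) * fp

    v_frames = np.zeros((n_frames, R, C), dtype=float)
    ca_frames = np.zeros((n_frames, R, C), dtype=float)
    act_truth = np.full((n_beats, R, C), np.nan)
    apd90_t = np.full((n_beats, R, C), np.nan)
    apd30_t = np.full((n_beats, R, C), np.nan)
    apd80_t = np.full((n_beats, R, C), np.nan)
    cat90_t = np.full((n_beats, R, C), np.nan)
    amp_t = np.full((n_beats, R, C), np.nan)
    phase_grid = np.zeros((R, C), dtype=int)
    amp_alt_grid = np.zeros((R, C), dtype=float)

    for reg_idx, reg in enumerate(tissue.regions):
        p = reg.params
        phase_grid[reg.mask] = reg.phase_offset
        amp_alt_grid[reg.mask] = reg.amp_alternans
        apds = apd_by_region[reg_idx]
        amps = amp_by_region[reg_idx]
        pix = np.argwhere(reg.mask)
        for r, c in pix:
            d = delays[r, c]
            for k in range(n_beats):
                if not captured[k]:
                    continue
                onset = stim_times[k] + d  # foot of upstroke
                apd = apds[k]
                # CaT90 tracks APD90 but can never be shorter than the decay
                # kinetics allow; clip to the kinematic minimum
                cat90 = max(
                    apd + p.cat90_offset,
                    p.rise_time / 2.0 + p.cat_decay_tau * 1000.0 * math.log(10.0) + 1e-6,
                )
                # beats superimpose (pointwise max): rapid pacing rides on the
                # unrecovered tail of the previous transient
                end_t = onset + max(_ap_length(apd, p.rise_time),
                                    _cat_length(cat90, p.rise_time, p.cat_decay_tau))
                i0 = int(math.ceil(onset / fp))
                i1 = min(n_frames, int(math.ceil(end_t / fp)) + 1)
                if i1 <= i0:
                    continue
                u = t_axis[i0:i1] - onset
                v_frames[i0:i1, r, c] = np.maximum(
                    v_frames[i0:i1, r, c], _ap_value(u, apd, p.rise_time)
                )
                ca_frames[i0:i1, r, c] = np.maximum(
                    ca_frames[i0:i1, r, c],
                    amps[k] * _cat_value(u, cat90, p.rise_time, p.cat_decay_tau),
                )
                act_truth[k, r, c] = onset + p.rise_time / 2.0
                apd90_t[k, r, c] = apd
                apd30_t[k, r, c] = ap_duration_truth(apd, p.rise_time, 0.3)
                apd80_t[k, r, c] = ap_duration_truth(apd, p.rise_time, 0.8)
                cat90_t[k, r, c] = cat90
                amp_t[k, r, c] = amps[k]

    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        v_frames = v_frames + rng.normal(0.0, noise.sigma, v_frames.shape)
        ca_frames = ca_frames + rng.normal(0.0, noise.sigma, ca_frames.shape)

    recorded_stims = [] if protocol.mode == "sinus" else list(stim_times)
    v_movie = Movie(v_frames, frame_rate, tissue.pixel_pitch, "voltage", recorded_stims)
    ca_movie = Movie(ca_frames, frame_rate, tissue.pixel_pitch, "calcium", recorded_stims)
    truth = GroundTruth(
        activation_times=act_truth,
        apd90=apd90_t,
        apd30=apd30_t,
        apd80=apd80_t,
        cat90=cat90_t,
        cat_amplitudes=amp_t,
        region_phase=phase_grid,
        region_amp_alternans=amp_alt_grid,
        stimulus_times=list(stim_times),
        beat_labels=labels,
        s2_interval_of_beat=dict(s2_of),
        s2_captured=s2_captured,
        true_aerp=tissue.aerp_ms,
    )
    return v_movie, ca_movie, truth


# ---------------------------------------------------------------------------
# AF traces and dose-response tables


def simulate_af_trace(
    baseline_cl: float,
    episodes: Sequence[tuple[float, float, float, float]],
    duration: float,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Activation-time series with labeled AF-like irregular episodes.

    Outside episodes the rhythm is regular at ``baseline_cl``; inside an
    episode ``(start, end, mean_cl, cl_jitter)`` the cycle lengths are drawn
    from a truncated normal around ``mean_cl`` (which must be shorter than
    0.6 x baseline, the tachycardia criterion).  Returns the activation times
    (ms) and the truth episode intervals.
    """
    eps = sorted((float(a), float(b), float(m), float(j)) for a, b, m, j in episodes)
    for (a, b, m, j) in eps:
        if not (0.0 <= a < b <= duration):
            raise InvalidParameterError("episodes must lie inside the recording")
        if m >= 0.6 * baseline_cl:
            raise InvalidParameterError("episode mean_cl must be < 0.6 * baseline_cl")
        if j < 0:
            raise InvalidParameterError("cl_jitter must be non-negative")
    for (_, b1, _, _), (a2, _, _, _) in zip(eps, eps[1:]):
        if a2 < b1:
            raise InvalidParameterError("episodes must be disjoint")

    rng = np.random.default_rng(seed)
    times = [0.0]
    t = 0.0
    while t < duration:
        current = next(((m, j) for a, b, m, j in eps if a <= t < b), None)
        if current is None:
            cl = baseline_cl
        else:
            m, j = current
            cl = max(20.0, rng.normal(m, j))
        t += cl
        if t <= duration:
            times.append(t)
    return np.asarray(times), [(a, b) for a, b, _, _ in eps]


def make_dose_response(
    ic50: float,
    hill: float,
    concs: Sequence[float],
    top: float = 100.0,
    bottom: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Four-parameter-logistic (concentration, % inhibition) table plus noise."""
    concs = np.asarray(concs, dtype=float)
    if ic50 <= 0 or np.any(concs <= 0):
        raise InvalidParameterError("ic50 and concentrations must be positive")
    resp = bottom + (top - bottom) / (1.0 + (ic50 / concs) ** hill)
    if noise > 0:
        resp = resp + np.random.default_rng(seed).normal(0.0, noise, resp.shape)
    return pd.DataFrame({"concentration": concs, "response": resp})
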
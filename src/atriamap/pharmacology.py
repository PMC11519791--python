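"""Patch-clamp summary-curve fitting: IC50, Boltzmann gating, and I-V relations.

These routines operate on summary tables (concentration vs percent
inhibition, voltage vs normalized conductance, voltage vs current density)
rather than raw traces.  The dose-response model is the four-parameter
logistic on log-concentration,

    I(c) = bottom + (top - bottom) / (1 + (IC50 / c)^h),

fitted by least squares with a multi-start initial grid; with only a handful
of concentrations the bottom and top are constrained by default (0 and 100
percent).  Steady-state activation/inactivation follows the two-parameter
Boltzmann G/Gmax(V) = 1 / (1 + exp((V1/2 - V)/k)), with the sign of the
exponent flipped for inactivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateSignalError, InvalidParameterError


@dataclass
class DoseResponseFit:
    """Constrained four-parameter-logistic fit of a concentration-inhibition table."""

    ic50: float
    hill: float
    top: float
    bottom: float
    r2: float
    ic50_ci: tuple[float, float] | None = None
    hill_ci: tuple[float, float] | None = None
    concentrations: np.ndarray = field(default_factory=lambda: np.array([]))
    responses: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, conc: np.ndarray) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (self.ic50 / c) ** self.hill)


@dataclass
class GatingFit:
    """Boltzmann steady-state gating fit."""

    v_half: float
    k: float
    direction: str  # "activation" or "inactivation"
    r2: float
    extrapolated: bool = False

    def predict(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if self.direction == "activation":
            return 1.0 / (1.0 + np.exp((self.v_half - v) / self.k))
        return 1.0 / (1.0 + np.exp((v - self.v_half) / self.k))


@dataclass
class IVSummary:
    """Landmarks of a current-voltage relation (inward currents negative)."""

    peak_potential: float
    peak_density: float
    reversal_potential: float | None
    reversal_is_bound: bool
    activation_threshold: float | None


def _logistic(logc: np.ndarray, log_ic50: float, hill: float,
              top: float, bottom: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_ic50 - logc)))


def fit_hill(
    conc: Sequence[float],
    inhibition: Sequence[float],
    *,
    fix_bottom: float | None = 0.0,
    fix_top: float | None = 100.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> DoseResponseFit:
    """Fit the four-parameter logistic to (concentration, % inhibition) data.

    Fitting is on log-concentration with a multi-start grid (IC50 starts at
    the concentration quantiles, several Hill slopes) to avoid local minima
    at sparse designs.  Confidence intervals come from seeded residual-
    resampling bootstrap: residuals are inflated by sqrt(n/(n-p)) (they are
    shrunk by the fit), the bootstrap standard error is computed on the log
    scale for IC50, and the interval uses the Student-t quantile at the
    residual degrees of freedom - a construction that holds close to nominal
    coverage at the sparse designs typical of these assays.  CIs are skipped
    when fewer than two residual degrees of freedom remain.
    """
    c = np.asarray(conc, dtype=float)
    y = np.asarray(inhibition, dtype=float)
    if c.size != y.size:
        raise InvalidParameterError("conc and inhibition must have equal length")
    if np.unique(c[c > 0]).size < 3:
        raise InvalidParameterError("need at least 3 distinct positive concentrations")
    if np.any(c <= 0):
        raise InvalidParameterError("concentrations must be positive")
    logc = np.log(c)

    free_bottom = fix_bottom is None
    free_top = fix_top is None

    def model(lc: np.ndarray, *p: float) -> np.ndarray:
        log_ic50, hill = p[0], p[1]
        idx = 2
        top = p[idx] if free_top else fix_top
        idx += free_top
        bottom = p[idx] if free_bottom else fix_bottom
        return _logistic(lc, log_ic50, hill, top, bottom)

    starts = []
    for q in (0.25, 0.5, 0.75):
        for h0 in (0.5, 1.0, 2.0):
            p0 = [float(np.quantile(logc, q)), h0]
            if free_top:
                p0.append(float(y.max()))
            if free_bottom:
                p0.append(float(y.min()))
            starts.append(p0)

    def try_fit(lc: np.ndarray, yy: np.ndarray, p0: list[float]):
        return curve_fit(model, lc, yy, p0=p0, maxfev=20000)[0]

    best = None
    for p0 in starts:
        try:
            popt = try_fit(logc, y, list(p0))
        except RuntimeError:
            continue
        sse = float(np.sum((model(logc, *popt) - y) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise DegenerateSignalError(
            "dose-response fit failed to converge from the multi-start grid"
        )
    popt, sse = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
    resid = y - model(logc, *popt)

    ic50_ci = hill_ci = None
    dof = y.size - len(popt)
    if n_boot > 0 and dof >= 2:
        from scipy.stats import t as t_dist

        rng = np.random.default_rng(seed)
        fitted = model(logc, *popt)
        inflate = math.sqrt(y.size / dof)
        boots = []
        for _ in range(n_boot):
            yb = fitted + inflate * rng.choice(resid, size=resid.size, replace=True)
            try:
                pb = try_fit(logc, yb, list(popt))
                boots.append((pb[0], pb[1]))
            except RuntimeError:
                continue
        if len(boots) >= max(50, n_boot // 2):
            arr = np.array(boots)
            q = float(t_dist.ppf(0.975, dof))
            se_log, se_hill = arr[:, 0].std(ddof=1), arr[:, 1].std(ddof=1)
            ic50_ci = (math.exp(popt[0] - q * se_log), math.exp(popt[0] + q * se_log))
            hill_ci = (float(popt[1] - q * se_hill), float(popt[1] + q * se_hill))

    idx = 2
    top = float(popt[idx]) if free_top else float(fix_top)
    idx += free_top
    bottom = float(popt[idx]) if free_bottom else float(fix_bottom)
    return DoseResponseFit(
        ic50=float(math.exp(popt[0])), hill=float(popt[1]), top=top, bottom=bottom,
        r2=r2, ic50_ci=ic50_ci, hill_ci=hill_ci, concentrations=c, responses=y,
    )


def fit_boltzmann(
    voltages: Sequence[float],
    response: Sequence[float],
    direction: str = "activation",
) -> GatingFit:
    """Fit the Boltzmann steady-state gating curve.

    ``direction`` selects the exponent sign: activation curves rise with
    voltage, inactivation curves fall.  The fit is flagged ``extrapolated``
    when the data do not span the 0.2-0.8 portion of the transition.  A
    response with no transition (constant) raises DegenerateSignalError.
    """
    if direction not in ("activation", "inactivation"):
        raise InvalidParameterError("direction must be 'activation' or 'inactivation'")
    v = np.asarray(voltages, dtype=float)
    y = np.asarray(response, dtype=float)
    if v.size < 5:
        raise InvalidParameterError("Boltzmann fit needs at least 5 voltages")
    if float(np.ptp(y)) < 1e-9:
        raise DegenerateSignalError("response shows no transition")

    sign = 1.0 if direction == "activation" else -1.0

    def model(vv: np.ndarray, v_half: float, k: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(sign * (v_half - vv) / k))

    v0 = float(v[np.argmin(np.abs(y - 0.5))])
    span = float(np.ptp(v))
    best = None
    for k0 in (span / 20.0, span / 8.0, span / 4.0):
        try:
            popt, _ = curve_fit(model, v, y, p0=[v0, k0],
                                bounds=([v.min() - span, 1e-6],
                                        [v.max() + span, span]), maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((model(v, *popt) - y) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise DegenerateSignalError("Boltzmann fit failed to converge")
    (v_half, k), sse = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
    extrapolated = not (np.any(y <= 0.2) and np.any(y >= 0.8))
    return GatingFit(v_half=float(v_half), k=float(sign * k), direction=direction,
                     r2=r2, extrapolated=extrapolated)


def iv_summary(
    potentials: Sequence[float],
    densities: Sequence[float],
    *,
    threshold_frac: float = 0.05,
) -> IVSummary:
    """Landmarks of an I-V curve: peak, reversal, and activation threshold.

    The peak potential refines the density argmin with the vertex of a
    parabola through its neighbors; the reversal potential is the linearly
    interpolated zero crossing above the peak (reported as a lower bound when
    the curve never crosses zero); the activation threshold is the first
    potential whose density reaches ``threshold_frac`` of the peak density.
    """
    v = np.asarray(potentials, dtype=float)
    i = np.asarray(densities, dtype=float)
    if v.size < 5:
        raise InvalidParameterError("I-V summary needs at least 5 potentials")
    if np.any(np.diff(v) <= 0):
        raise InvalidParameterError("potentials must be strictly increasing")

    pk = int(np.argmin(i))
    peak_v, peak_i = float(v[pk]), float(i[pk])
    if 0 < pk < v.size - 1:
        y0, y1, y2 = i[pk - 1], i[pk], i[pk + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom > 0:
            # quadratic vertex on the (uniformly or not) sampled neighborhood
            dv = 0.5 * (v[pk + 1] - v[pk - 1])
            peak_v = float(v[pk] + 0.5 * (y0 - y2) / denom * dv)

    reversal = None
    is_bound = True
    for k in range(pk, v.size - 1):
        if i[k] < 0.0 <= i[k + 1]:
            frac = -i[k] / (i[k + 1] - i[k])
            reversal = float(v[k] + frac * (v[k + 1] - v[k]))
            is_bound = False
            break
    if reversal is None:
        reversal = float(v[-1])  # zero crossing lies beyond the tested range

    threshold = None
    for k in range(v.size):
        if i[k] <= threshold_frac * peak_i:
            threshold = float(v[k])
            break
    return IVSummary(peak_potential=peak_v, peak_density=peak_i,
                     reversal_potential=reversal, reversal_is_bound=is_bound,
                     activation_threshold=threshold)
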
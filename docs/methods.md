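# Methods

This note documents the models, operational definitions, parameter choices
and numerical decisions behind `atriamap`, in the spirit of a statistical
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The synthetic tissue generator

The generator is deliberately **kinematic**, not ionic: it does not solve
membrane equations. Its purpose is to emit dual-channel movies in which
every quantity the analysis chain estimates is known exactly by
construction, so that each estimator can be tested against truth.

### Waveform family

The action-potential upstroke is a raised-cosine sigmoid,
`v(t) = ½(1 − cos(πt/r))` for `t ∈ [0, r]` with `r = rise_time`. Its
derivative has a unique maximum at `t = r/2`, which pins the operational
activation instant (dF/dt max) analytically. Repolarization is a cosine
shoulder `v = ½(1 + cos(π(t−r)/T))` whose span `T` is chosen so that the
downward crossing of 10% amplitude falls exactly `apd90` after `r/2`. Hence
the textbook APD90 definition — maximal upstroke velocity to 90%
repolarization — is exact by construction, and APD30/APD80 truths follow in
closed form (`ap_duration_truth`). The measured 10–90% rise time of this
family is `RISE_CALIBRATION ≈ 0.59` times the foot-to-peak `rise_time`
parameter; the constant is exported so tests can assert against it.

The calcium transient shares the upstroke, holds a plateau, then decays as a
single exponential with time constant `decay_tau` (seconds). A pure
exponential pins the 90%-recovery instant to `r/2 + τ·ln 10`, so CaT90 could
not be set independently; the plateau of length
`cat90 − r/2 − τ·ln 10` restores that freedom, and a negative plateau raises
an invalid-parameter error ("90% recovery unreachable"). The decay is run to
0.1% of amplitude so that decay fits see a clean baseline. In movies, CaT90
tracks APD90 plus a fixed offset (`cat90_offset`) but is clipped below at
the kinematic minimum `r/2 + τ·ln 10`.

### Propagation, beats, and superposition

A circular (point-source) or planar wavefront leaves the pacing site at the
configured conduction velocity (mm/ms); each pixel's beat starts after
`distance / velocity`. Successive beats are combined by **pointwise
maximum**: at fast pacing a new transient rides on the unrecovered tail of
the previous one, which reproduces the transient fusion seen in real
recordings (and is why per-beat amplitude is measured as the maximal rise
above the running minimum, §3).

### Restitution dynamics and alternans

Beat-to-beat APD follows the standard restitution iterated map
`APD_{n+1} = f(CL − APD_n)`, `f(DI) = apd_max(1 − e^{−DI/τ_rest})`, with the
diastolic interval clipped at a 5-ms floor so the map is total at aggressive
cycle lengths (pacing protocols go down to 20–30 ms). Alternans onset obeys
the classical criterion |f′| = 1 at the fixed point; the package exposes the
fixed point, its slope, and the steady orbit amplitude so the criterion is
directly testable.

Spatially discordant alternans is **imposed by construction**, not emergent:
a region with `phase_offset = 1` advances the map by one extra beat, so in a
period-2 regime it alternates in exact anti-phase. This trades dynamical
realism for exact ground truth, which is what testing requires.

CaT-amplitude alternans has two modes per region: an imposed magnitude
(large beat 1, small beat 1 − m; exact truth for estimator tests) or a
mechanistic coupling `amp = 1 − e^{−DI/τ_refr}` to the preceding diastolic
interval, which lets amplitude alternans grow spontaneously as the cycle
length shortens. Premature (S2) beats always use the release-refractoriness
relation `1 − e^{−interval/τ_refr}` against unit S1 amplitude, so the
S2/S1 ratio at the coupling interval equals that expression in closed form.
S2 stimuli at or below the tissue's refractory period (`aerp_ms`, a tissue
property, default 45 ms) elicit no beat and are flagged non-captured.

### Defaults and units

900 Hz frame rate, 0.1 mm pixel pitch, additive i.i.d. Gaussian sensor noise
in fractional-amplitude units, seeded (`NoiseSpec`). Conduction velocities
are in **mm/ms**; plausible rat atrial values run ~0.3–1.0 mm/ms. Durations
are ms; Tau is reported in seconds (magnitudes 0.01–0.08 s against APDs of
30–100 ms). AF traces are activation-time series: regular at a baseline
cycle length, with labeled episodes whose cycle lengths are truncated-normal
around a mean below 0.6× baseline.

## 2. Preprocessing

Spatial filtering uses the canonical discrete 3×3 Gaussian — the binomial
kernel `[1 2 1]ᵀ[1 2 1]/16` — with edge replication, so constants are
preserved exactly and the frame mean moves by <1% on ≥16×16 grids. No
temporal filtering is applied by default; `measure_beats` exposes an
optional moving-average (`temporal_smooth`) for high-noise recordings.

Beat segmentation is stimulus-locked when stimulus times are present, with
windows pulled back ~10 ms before each stimulus so every window carries true
diastolic baseline frames (needed for unbiased level estimation, §3). For
unstimulated data, upstrokes are detected at 50% of trace amplitude with a
40-ms refractory lockout (robust at rat rates), gated by a noise floor —
the trace range must exceed 10× a robust noise estimate from first
differences — so an all-noise movie yields zero windows rather than
spurious beats.

## 3. Feature extraction

* **Activation**: argmax of the discrete first difference, refined by a
  parabola through the three surrounding derivative samples (sub-frame
  precision at 900 Hz). Ties (e.g. a perfectly linear ramp) resolve to the
  earliest frame and are flagged.
* **Durations**: from activation to the linearly interpolated downward
  crossing of the repolarization level. The amplitude reference uses the
  window maximum and a **baseline estimated as the median of pre-foot
  frames** (falling back to the window minimum when none exist). The median
  is unbiased under symmetric noise, whereas the window minimum sits ~2–3σ
  below baseline and inflates durations by several percent at σ = 0.05.
* **Rise time**: 10–90% upstroke interval (standard optical-mapping
  convention; the onset-to-peak alternative is available via transition
  points).
* **Beat amplitude**: maximal rise above the running minimum
  (`upstroke_amplitude`). For a clean beat this equals peak minus preceding
  diastolic minimum; for a window containing only the monotone tail of the
  previous transient (a fused beat at very fast pacing) it is ~0, which is
  the physiologically meaningful answer.
* **Decay Tau**: least-squares monoexponential on the segment from 30%
  below the peak to 90% recovery. The fit is flagged unreliable when R² <
  0.9 **or** when the log-scale residuals carry smooth curvature (quadratic
  structure absorbing >50% of residual variance): a two-parameter
  exponential can shadow a straight-line decay with deceptively high R², so
  the R² rule alone cannot catch non-exponential shapes.
* **Transition points**: onset (5% upstroke crossing), peak, 30% and 90%
  recovery crossings; peak-to-90%-recovery is the calcium recovery time.
* **Conduction velocity**: Bayly-style local second-order polynomial
  surface fit of the activation map in 5×5 neighborhoods; speed is the
  inverse gradient magnitude, direction the gradient direction (row, col
  components). The map is pre-smoothed with the 3×3 binomial kernel
  (exact on planar fronts). Known limitation: activation-time jitter enters
  through the convex mapping 1/|∇T| and biases mean speed a few percent
  *high* under noise; noiseless plane-wave recovery is within 5% across
  0.3–1.0 mm/ms.
* **Heterogeneity**: IQR with the linear-interpolation (type-7) quantile
  convention — stated explicitly because IQR is a headline statistic.

## 4. Alternans analysis

Magnitude uses even/odd beat grouping (not local pairing) to implement
"average smaller / average bigger beat" robustly after linear detrending.
The spectral detector computes the **magnitude** spectrum over beat index;
the alternans bin at 0.5 cycles/beat is scaled by 1/√2 because the real-FFT
bin at the Nyquist frequency has no imaginary counterpart and carries twice
the per-bin noise variance of interior bins. With that scaling, the k ≥ 3
rule retains its one-sided normal false-positive bound (~0.13%); without
it, the Nyquist bin's χ²₁-type tail would produce several percent false
positives. The noise band is 0.33–0.48 cycles/beat (standard spectral-method
convention, excluding the alternans bin); series shorter than ~16 beats fall
back to all non-DC bins, and series with <8 beats are directed to the
time-domain magnitude. Phase is anchored to the stimulus train (first
analyzed beat): long–short/high–low is +1. The discordance index
`2·min(N₊,N₋)/(N₊+N₋)` maps concordant maps to 0 and a balanced split to 1;
it is undefined (NaN) with no significant pixels.

## 5. Protocol analysis

* **S2/S1 ratio**: S1 reference is the mean amplitude of the last three
  drive beats (steady state after the train); ratios are produced per pixel,
  at four configurable sites, and field-wide.
* **Capture rule** (undefined in standard practice write-ups): an S2 is
  propagated when ≥50% of masked pixels show an upstroke ≥50% of their S1
  amplitude. The pipeline judges capture on the **voltage** channel:
  electrical propagation does not fuse the way calcium transients do at
  short coupling intervals, where a genuine S2 calcium release can hide
  under the preceding transient's tail.
* **AERP**: longest tested S2 interval that fails to capture; all-capture /
  no-capture outcomes are reported as bounds. The estimate error is bounded
  by the S2 step by construction.
* **Restitution fit**: `ratio(Δ) = A(1 − e^{−(Δ−Δ₀)/τ_r})` with a latency
  offset Δ₀ (ratios are undefined below the refractory period); steepness is
  the maximum fitted derivative over the tested range, ×100 (%/ms). Flat
  curves return a flagged fit with τ_r unidentifiable. Measured ratios at
  coupling intervals where transients fuse (tail not yet decayed) are
  physically suppressed; analyses that need the clean closed-form relation
  should start above ~2 decay lengths of the drive transient.
* **SNRT**: first spontaneous activation minus last stimulus, reported both
  raw and corrected (minus baseline cycle length) since published values in
  the tens of ms suggest a pause-excess measure.
* **AF episodes**: ≥5 consecutive cycles each below 0.75× baseline whose
  run has mean CL < 0.6× baseline and CL coefficient of variation > 0.1.
  All three thresholds are config-exposed; an empty report is a valid
  outcome.
* **Flux rates**: RyR₂ release rate = maximum first derivative of a cubic
  polynomial fit to the caffeine-transient upstroke (5% of amplitude to
  peak), in normalized amplitude/s; SERCA inverse rate = time constant of
  an exponential fit `A − B·e^{−t/τ}` to amplitude recovery under release
  blockade, with the polynomial-derivative estimate kept as a diagnostic.
  The exact published extraction is not specified anywhere we could follow,
  so these definitions are validated purely by synthetic recovery.

## 6. Pharmacology fits

The four-parameter logistic is fitted on log-concentration with a
multi-start grid (IC50 starts at the concentration quantiles; Hill slopes
0.5/1/2); bottom and top are fixed at 0 and 100% by default because four
concentrations cannot support four free parameters. Confidence intervals
use a seeded residual-resampling bootstrap with residuals inflated by
√(n/(n−p)) (fit shrinkage correction), the standard error computed on
log-IC50, and Student-t quantiles at the residual degrees of freedom — a
construction whose empirical coverage at these sparse designs stays near
nominal, where the naive percentile bootstrap under-covers. Boltzmann gating
fits use `G/G_max = 1/(1+exp((V½−V)/k))` with the exponent sign flipped for
inactivation, and are flagged extrapolated when the data do not span the
0.2–0.8 transition. I–V landmarks: quadratic-refined argmin for the peak
potential, linear-interpolated zero crossing above the peak for the
reversal (a bound when absent), and first potential reaching 5% of peak
density for the activation threshold.

Of the two bundled concentration–inhibition tables, the constrained fit of
the WK table reproduces the published IC50 within its reported SD, while the
Dioscin table fits to a lower IC50 than the published per-cell average —
see the test suite for both computations; the package reports what the
stated procedure computes.

## 7. Pipeline and reproducibility

The pipeline validates its configuration (pydantic) before any computation;
every analysis threshold lives in the config. Each group's seeds derive
from (config seed, group name) only, so adding or removing a group never
changes another group's rows; re-running with the same config is
byte-identical, and every report carries the config hash, seed and package
version. Stage sizes (12×12 default grid, 8-beat drive, 16-beat alternans
trains, 9 S2 intervals) are chosen so a full two-group run completes in
seconds while every metric remains measurable; they are configurable.

The default two-group parameter sets are a control-like atrium (APD plateau
33 ms, flat restitution, Tau 0.01 s, AERP/APD ≈ 1.4, CV 0.7 mm/ms, low
heterogeneity) and a remodeled disease-like atrium (plateau 85 ms, steep
restitution with alternans onset near a 90-ms cycle length, Tau 0.03 s,
AERP/APD ≈ 0.6, CV 0.3 mm/ms, 15% heterogeneity, heavier AF burden). The
disease-like Tau is set to 0.03 s rather than the largest published group
mean (0.08 s) because a transient whose decay constant is 80 ms cannot
finish 90% recovery within a 6-Hz beat window under this waveform family;
the ordering between groups, which is what the pipeline asserts, is
preserved.

## 8. What passing tests do and do not show

The generator emulates the statistical structure the analysis assumes:
smooth single-upstroke beats, known propagation geometry, exponential decay,
imposed or map-driven alternans, Gaussian sensor noise. Real recordings add
motion residue, dye bleaching, spatially correlated noise, non-exponential
decay phases, curved and anisotropic wavefronts, and genuinely emergent
discordance. Passing the suite therefore demonstrates that the estimators
are correct *given their operational definitions*, not that those
definitions are optimal for any particular dataset. Known limitations worth
repeating: conduction speed biases slightly high under activation jitter;
S2/S1 ratios are suppressed at coupling intervals shorter than the drive
transient's decay; the restitution steepness statistic depends on the tested
interval range; and spatial discordance is imposed, not mechanistic.
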
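"""Configured, seeded simulate -> preprocess -> analyze -> report pipeline.

The pipeline turns a validated configuration into a per-group metric table:
each group is a parameter set of the synthetic tissue generator (a disease
phenotype at the generator level), and every metric of the report is
recomputed from the emitted movies by the analysis modules - never copied
from the generator truth.  Stages: a fixed-rate drive train for duration,
rise-time, conduction and heterogeneity maps; a decremental cycle-length
sweep for alternans magnitude and discordance; an S1S2 extrastimulus run for
calcium-release restitution and the effective refractory period; and an
AF-trace run for episode burden.  Everything derives its randomness from the
single configured seed, so a re-run is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__ as _pkg_version
from .alternans import alternans_analysis
from .errors import InvalidParameterError
from .io import spatial_gaussian3
from .protocols import (
    EctopyReport,
    aerp_from_s1s2,
    detect_capture,
    detect_episodes,
    fit_restitution,
    s2s1_ratio,
)
from .synthgen import (
    NoiseSpec,
    ProtocolSpec,
    Region,
    RestitutionParams,
    TissueSpec,
    simulate_af_trace,
    simulate_movie,
)
from .wavemetrics import (
    conduction_velocity,
    feature_map,
    feature_stack,
    heterogeneity_iqr,
    measure_beats,
    upstroke_amplitude,
)


class GroupParams(BaseModel):
    """Generator parameters of one experimental group."""

    apd_max: float = 33.0
    tau_rest: float = 15.0
    cat_decay_tau: float = 0.01
    cat_amp_tau_refr: float = 45.0
    rise_time: float = 12.5
    cat90_offset: float = 25.0
    aerp_ms: float = 47.0
    conduction_velocity: float = 0.7
    heterogeneity: float = 0.04  # fractional apd_max spread across quadrants
    af_episodes: list[tuple[float, float, float, float]] = Field(default_factory=list)

    @field_validator("apd_max", "tau_rest", "cat_decay_tau", "cat_amp_tau_refr",
                     "rise_time", "conduction_velocity")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v


def sham_like_group() -> GroupParams:
    """Healthy-control-like parameters: short APD, flat restitution, fast
    decay, low heterogeneity, long refractory period relative to APD."""
    return GroupParams(
        apd_max=33.0, tau_rest=15.0, cat_decay_tau=0.01, cat_amp_tau_refr=45.0,
        rise_time=12.5, aerp_ms=47.0, conduction_velocity=0.7, heterogeneity=0.04,
        af_episodes=[(8_000.0, 9_000.0, 70.0, 20.0)],
    )


def model_like_group() -> GroupParams:
    """Post-stroke-phenotype-like parameters: prolonged APD, steep
    restitution (alternans-prone below ~90 ms pacing), slow calcium decay,
    high spatial heterogeneity, short refractory period relative to APD,
    slowed conduction, heavier AF burden."""
    return GroupParams(
        apd_max=85.0, tau_rest=25.0, cat_decay_tau=0.03, cat_amp_tau_refr=80.0,
        rise_time=26.0, aerp_ms=50.0, conduction_velocity=0.3, heterogeneity=0.15,
        af_episodes=[(5_000.0, 9_000.0, 70.0, 20.0), (14_000.0, 18_000.0, 65.0, 18.0)],
    )


class AfCriteria(BaseModel):
    min_cycles: int = 5
    cl_factor: float = 0.6
    cv_min: float = 0.1


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; every threshold the analysis depends
    on is surfaced here."""

    seed: int = 0
    frame_rate_hz: float = 900.0
    pixel_pitch_mm: float = 0.1
    grid_rows: int = 12
    grid_cols: int = 12
    drive_cycle_length: float = 1000.0 / 6.0
    drive_beats: int = 8
    noise_sigma: float = 0.01
    repolarization_levels: tuple[float, float, float] = (0.3, 0.8, 0.9)
    k_threshold: float = 3.0
    alternans_cycle_lengths: list[float] = Field(
        default_factory=lambda: [100.0, 90.0, 80.0, 70.0, 60.0, 50.0]
    )
    alternans_beats: int = 16
    s2_intervals: list[float] = Field(
        default_factory=lambda: [150.0, 120.0, 100.0, 80.0, 70.0, 60.0, 50.0, 40.0, 30.0]
    )
    s1_count: int = 4
    sites: list[tuple[int, int]] = Field(default_factory=list)
    af_baseline_cl: float = 180.0
    af_duration_ms: float = 20_000.0
    af_criteria: AfCriteria = Field(default_factory=AfCriteria)
    groups: dict[str, GroupParams] = Field(default_factory=dict)

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls(groups={"sham_like": sham_like_group(),
                           "model_like": model_like_group()})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json")))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def default_sites(self) -> list[tuple[int, int]]:
        if self.sites:
            return [tuple(s) for s in self.sites]
        r4, c4 = self.grid_rows // 4, self.grid_cols // 4
        return [(r4, c4), (r4, 3 * c4), (3 * r4, c4), (3 * r4, 3 * c4)]


@dataclass
class RunReport:
    """Per-group metric table plus provenance."""

    summary: pd.DataFrame  # columns: group, metric, value, units
    restitution_curves: dict[str, pd.DataFrame] = dc_field(default_factory=dict)
    alternans_by_cl: dict[str, pd.DataFrame] = dc_field(default_factory=dict)
    ectopy: dict[str, EctopyReport] = dc_field(default_factory=dict)
    provenance: dict = dc_field(default_factory=dict)

    def metric(self, group: str, name: str) -> float:
        rows = self.summary[(self.summary.group == group) & (self.summary.metric == name)]
        if rows.empty:
            raise KeyError(f"metric {name!r} for group {group!r} not in report")
        return float(rows.value.iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.summary.to_csv(path, index=False)




def _tissue_for_group(cfg: PipelineConfig, g: GroupParams, *,
                      amp_from_di: bool = False) -> TissueSpec:
    """Quadrant tissue whose APD plateau varies across quadrants by the
    group's heterogeneity fraction; quadrant 0 carries the opposite alternans
    phase (the observed one-vs-three discordant layout)."""
    rows, cols = cfg.grid_rows, cfg.grid_cols
    hr, hc = rows // 2, cols // 2
    slices = [(slice(0, hr), slice(0, hc)), (slice(0, hr), slice(hc, cols)),
              (slice(hr, rows), slice(0, hc)), (slice(hr, rows), slice(hc, cols))]
    scales = [1.0 - g.heterogeneity, 1.0 - g.heterogeneity / 3.0,
              1.0 + g.heterogeneity / 3.0, 1.0 + g.heterogeneity]
    regions = []
    for i, (rs, cs) in enumerate(slices):
        mask = np.zeros((rows, cols), dtype=bool)
        mask[rs, cs] = True
        params = RestitutionParams(
            apd_max=g.apd_max * scales[i], tau_rest=g.tau_rest,
            cat_decay_tau=g.cat_decay_tau, cat_amp_tau_refr=g.cat_amp_tau_refr,
            rise_time=g.rise_time, cat90_offset=g.cat90_offset,
        )
        regions.append(Region(mask=mask, params=params,
                              phase_offset=1 if i == 0 else 0,
                              amp_from_di=amp_from_di))
    return TissueSpec(
        grid_rows=rows, grid_cols=cols, pixel_pitch=cfg.pixel_pitch_mm,
        conduction_velocity=g.conduction_velocity, pacing_site=(0, 0),
        regions=tuple(regions), aerp_ms=g.aerp_ms,
    )


def _drive_stage(cfg: PipelineConfig, g: GroupParams, seed: int) -> dict[str, float]:
    tissue = _tissue_for_group(cfg, g)
    protocol = ProtocolSpec(mode="fixed_rate", s1_cycle_length=cfg.drive_cycle_length,
                            s1_count=cfg.drive_beats)
    v_mov, ca_mov, _ = simulate_movie(
        tissue, protocol, NoiseSpec(sigma=cfg.noise_sigma, seed=seed),
        frame_rate=cfg.frame_rate_hz,
    )
    if cfg.noise_sigma > 0:
        v_mov = spatial_gaussian3(v_mov)
        ca_mov = spatial_gaussian3(ca_mov)
    beat = cfg.drive_beats - 2  # late beat: past the restitution transient
    shape = v_mov.shape
    smooth = 5 if cfg.noise_sigma > 0 else None

    v_feats = measure_beats(v_mov, temporal_smooth=smooth)
    apd90_map = feature_map(v_feats, shape, "apd90", beat)
    apd30_map = feature_map(v_feats, shape, "apd30", beat)
    apd80_map = feature_map(v_feats, shape, "apd80", beat)
    rise_map = feature_map(v_feats, shape, "rise_time", beat)
    act_map = feature_map(v_feats, shape, "activation_time", beat)
    cv_res = conduction_velocity(act_map, v_mov.pixel_pitch)

    ca_feats = measure_beats(ca_mov, fit_decay=True, temporal_smooth=smooth)
    cat90_map = feature_map(ca_feats, shape, "apd90", beat)
    tau_map = feature_map(ca_feats, shape, "decay_tau", beat, units="s")

    with np.errstate(invalid="ignore"):
        apd3080 = np.nanmean(apd30_map.values / apd80_map.values)
    return {
        "apd90_ms": apd90_map.mean(),
        "apd90_iqr_ms": heterogeneity_iqr(apd90_map),
        "rise_time_ms": rise_map.mean(),
        "apd30_80_ratio": float(apd3080),
        "conduction_velocity_mm_per_ms": cv_res.mean_speed,
        "cat90_ms": cat90_map.mean(),
        "cat_decay_tau_s": tau_map.mean(),
    }


def _alternans_stage(
    cfg: PipelineConfig, g: GroupParams, seed: int
) -> tuple[pd.DataFrame, dict[str, float]]:
    tissue = _tissue_for_group(cfg, g, amp_from_di=True)
    rows = []
    for i, cl in enumerate(cfg.alternans_cycle_lengths):
        protocol = ProtocolSpec(mode="fixed_rate", s1_cycle_length=cl,
                                s1_count=cfg.alternans_beats)
        _, ca_mov, _ = simulate_movie(
            tissue, protocol, NoiseSpec(sigma=cfg.noise_sigma, seed=seed + i),
            frame_rate=cfg.frame_rate_hz,
        )
        feats = measure_beats(ca_mov, levels=())
        stack = feature_stack(feats, ca_mov.shape, "amplitude")
        # drop the restitution transient; keep an even number of beats
        stack = stack[4:]
        if stack.shape[0] % 2:
            stack = stack[:-1]
        res = alternans_analysis(stack, cl, k_threshold=cfg.k_threshold)
        rows.append({"cycle_length": cl, "magnitude": res.mean_magnitude,
                     "discordance": res.discordance,
                     "significant_fraction": float(res.significant.mean())})
    table = pd.DataFrame(rows)
    shortest = table.iloc[-1]
    return table, {
        "alternans_magnitude_at_shortest_cl": float(shortest.magnitude),
        "alternans_discordance_at_shortest_cl": float(shortest.discordance)
        if np.isfinite(shortest.discordance) else float("nan"),
    }


def _s1s2_stage(
    cfg: PipelineConfig, g: GroupParams, seed: int, apd90_drive: float
) -> tuple[pd.DataFrame, dict[str, float]]:
    tissue = _tissue_for_group(cfg, g)
    protocol = ProtocolSpec(
        mode="S1S2_extrastimulus", s1_cycle_length=cfg.drive_cycle_length,
        s1_count=cfg.s1_count, s2_intervals=tuple(cfg.s2_intervals),
    )
    v_mov, ca_mov, truth = simulate_movie(
        tissue, protocol, NoiseSpec(sigma=cfg.noise_sigma, seed=seed),
        frame_rate=cfg.frame_rate_hz,
    )
    fp = ca_mov.frame_period
    stims = truth.stimulus_times
    labels = truth.beat_labels
    bounds = [int(round(t / fp)) for t in stims] + [ca_mov.n_frames]
    n_beats = len(stims)
    R, C = ca_mov.shape
    # calcium amplitudes drive the S2/S1 restitution ratios; voltage
    # amplitudes drive capture detection (electrical propagation does not
    # fuse the way calcium transients do at short coupling intervals)
    amps = np.full((n_beats, R, C), np.nan)
    v_amps = np.full((n_beats, R, C), np.nan)
    for k in range(n_beats):
        seg = ca_mov.frames[bounds[k] : bounds[k + 1]]
        v_seg = v_mov.frames[bounds[k] : bounds[k + 1]]
        if seg.shape[0] < 3:
            continue
        for r in range(R):
            for c in range(C):
                amps[k, r, c] = upstroke_amplitude(seg[:, r, c])
                v_amps[k, r, c] = upstroke_amplitude(v_seg[:, r, c])

    sites = cfg.default_sites()
    capture: dict[float, bool] = {}
    rows = []
    # walk the trains: each train is s1_count S1 beats followed by its S2
    idx = 0
    for s2_int in cfg.s2_intervals:
        train = slice(idx, idx + cfg.s1_count + 1)
        train_amps = amps[train]
        train_labels = labels[train.start : train.stop]
        res = s2s1_ratio(train_amps, train_labels, interval=s2_int, sites=sites)
        v_train = v_amps[train]
        v_ref = np.nanmean(v_train[cfg.s1_count - 3 : cfg.s1_count], axis=0)
        captured = detect_capture(v_train[-1], v_ref)
        capture[s2_int] = captured
        rows.append({"interval": s2_int,
                     "field_ratio": res.field_ratio if captured else math.nan,
                     **{f"site{j}": (res.site_ratios[j] if captured else math.nan)
                        for j in range(len(sites))},
                     "captured": captured})
        idx += cfg.s1_count + 1

    table = pd.DataFrame(rows).sort_values("interval").reset_index(drop=True)
    refractory = aerp_from_s1s2(capture, apd90=apd90_drive)
    metrics: dict[str, float] = {}
    if refractory.aerp is not None:
        metrics["aerp_ms"] = refractory.aerp
        if refractory.aerp_apd_ratio is not None:
            metrics["aerp_apd_ratio"] = refractory.aerp_apd_ratio
    ok = table.dropna(subset=["field_ratio"])
    if len(ok) >= 4:
        fit = fit_restitution(ok.interval.to_numpy(), ok.field_ratio.to_numpy())
        if not fit.flagged:
            metrics["restitution_tau_ms"] = fit.tau_r
            metrics["restitution_steepness_pct_per_ms"] = fit.steepness
    return table, metrics


def _af_stage(cfg: PipelineConfig, g: GroupParams, seed: int) -> tuple[EctopyReport, dict]:
    times, _ = simulate_af_trace(cfg.af_baseline_cl, g.af_episodes,
                                 cfg.af_duration_ms, seed=seed)
    crit = cfg.af_criteria
    report = detect_episodes(times, cfg.af_baseline_cl, min_cycles=crit.min_cycles,
                             cl_factor=crit.cl_factor, cv_min=crit.cv_min)
    return report, {
        "af_total_duration_s": report.total_duration_s,
        "af_induced": float(report.induced),
        "af_episode_count": float(report.n_episodes),
    }


_METRIC_UNITS = {
    "apd90_ms": "ms", "apd90_iqr_ms": "ms", "rise_time_ms": "ms",
    "apd30_80_ratio": "", "conduction_velocity_mm_per_ms": "mm/ms",
    "cat90_ms": "ms", "cat_decay_tau_s": "s",
    "alternans_magnitude_at_shortest_cl": "", "alternans_discordance_at_shortest_cl": "",
    "aerp_ms": "ms", "aerp_apd_ratio": "", "restitution_tau_ms": "ms",
    "restitution_steepness_pct_per_ms": "%/ms",
    "af_total_duration_s": "s", "af_induced": "", "af_episode_count": "",
}


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute all stages for every configured group.

    Deterministic given ``config.seed``; per-group failures are isolated (a
    failing stage records NaN metrics for that group and the run continues).
    """
    if not config.groups:
        raise InvalidParameterError("config defines no groups")
    rows = []
    restitution: dict[str, pd.DataFrame] = {}
    alternans_tables: dict[str, pd.DataFrame] = {}
    ectopy: dict[str, EctopyReport] = {}
    for gname, g in config.groups.items():
        # group seeds depend only on (config.seed, group name): dropping one
        # group never perturbs another group's rows
        gseed = zlib.crc32(gname.encode()) ^ (config.seed & 0xFFFFFFFF)
        seeds = [int(s) for s in np.random.default_rng(gseed).integers(0, 2**31 - 1, size=4)]
        metrics: dict[str, float] = {}
        metrics.update(_drive_stage(config, g, seeds[0]))
        alt_table, alt_metrics = _alternans_stage(config, g, seeds[1])
        alternans_tables[gname] = alt_table
        metrics.update(alt_metrics)
        rest_table, rest_metrics = _s1s2_stage(config, g, seeds[2],
                                               metrics.get("apd90_ms", math.nan))
        restitution[gname] = rest_table
        metrics.update(rest_metrics)
        report, af_metrics = _af_stage(config, g, seeds[3])
        ectopy[gname] = report
        metrics.update(af_metrics)
        for name, value in metrics.items():
            rows.append({"group": gname, "metric": name, "value": value,
                         "units": _METRIC_UNITS.get(name, "")})
    summary = pd.DataFrame(rows)
    provenance = {"config_hash": config.config_hash(), "seed": config.seed,
                  "package_version": _pkg_version}
    report = RunReport(summary=summary, restitution_curves=restitution,
                       alternans_by_cl=alternans_tables, ectopy=ectopy,
                       provenance=provenance)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "summary.csv", index=False)
        for gname, table in restitution.items():
            table.to_csv(outdir / f"restitution_{gname}.csv", index=False)
        for gname, table in alternans_tables.items():
            table.to_csv(outdir / f"alternans_{gname}.csv", index=False)
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return report
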
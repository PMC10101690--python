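"""Configuration models for simulation and pipeline runs.

All configuration is expressed as pydantic models with ``extra="forbid"`` so
that typos in YAML keys are rejected with the offending key named. A single
:class:`PipelineConfig` drives the whole simulate → fluxes → phenology →
associate → coherence chain; :class:`SimulationConfig` alone is enough for the
synthetic generators.

Units are stated per field: volumes in litres, areas in m², fluxes in
μmol CO₂ m⁻² s⁻¹, concentrations in ppm (μmol per mol of air), isotope ratios
in ‰ vs V-PDB, temperatures in °C.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Conventional ¹³C/¹²C ratio of the V-PDB standard.
R_VPDB = 0.0111802

#: PAR threshold (μmol m⁻² s⁻¹) below which a timestamp counts as night.
NIGHT_PAR_THRESHOLD = 30.0

ChamberKind = Literal["shoot", "stem", "soil"]


class StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ChamberSpec(StrictModel):
    """Geometry and schedule of one automated chamber."""

    volume_l: float = Field(gt=0)
    area_m2: float = Field(gt=0, description="exchange surface or leaf area")
    closures_per_day: int = Field(gt=0)
    duration_s: int = Field(gt=0)
    leak_rate: float = Field(ge=0, description="first-order ambient-replacement rate q, s⁻¹")
    fit_window_s: tuple[float, float]

    @model_validator(mode="after")
    def _window_inside_closure(self) -> "ChamberSpec":
        lo, hi = self.fit_window_s
        if not (0 <= lo < hi <= self.duration_s):
            raise ValueError(
                f"fit window {self.fit_window_s} must lie within the {self.duration_s}s closure"
            )
        return self


def _default_chambers() -> dict[str, ChamberSpec]:
    # Shoot cuvette 2.1 l; stem chamber wraps ~0.1 m² of stem surface;
    # soil chamber 80 l over a 0.4 m² collar. Closure schedules: shoot
    # 50-80x/day for 65 s (60 used), stem 48x/day for 90 s, soil 8x/day
    # for 840 s. Fit windows skip the pressure transient after closing.
    return {
        "shoot": ChamberSpec(
            volume_l=2.1, area_m2=0.01, closures_per_day=60, duration_s=65,
            leak_rate=0.005, fit_window_s=(5.0, 50.0),
        ),
        "stem": ChamberSpec(
            volume_l=2.5, area_m2=0.10, closures_per_day=48, duration_s=90,
            leak_rate=0.003, fit_window_s=(10.0, 40.0),
        ),
        "soil": ChamberSpec(
            volume_l=80.0, area_m2=0.40, closures_per_day=8, duration_s=840,
            leak_rate=0.001, fit_window_s=(40.0, 200.0),
        ),
    }


class GompertzTruth(StrictModel):
    """Ground-truth cumulative tracheid curves for one simulated stand.

    The total and mature curves share the asymptote (every cell eventually
    matures); the mature curve is delayed and slightly slower.
    """

    asymptote: float = Field(default=40.0, gt=0, description="cells per mm of previous ring")
    midpoint_doy: float = 153.0
    rate: float = Field(default=0.067, gt=0, description="d⁻¹")
    maturation_delay_days: float = Field(default=35.0, ge=0)
    maturation_rate: float = Field(default=0.050, gt=0)
    tree_asymptote_cv: float = Field(default=0.15, ge=0)
    tree_midpoint_sd_days: float = Field(default=4.0, ge=0)
    count_noise_frac: float = Field(default=0.05, ge=0, description="obs SD as fraction of asymptote")


class NSCTemplate(StrictModel):
    """Piecewise-linear seasonal template (knots in DOY) for one compound."""

    doy_knots: list[float]
    conc_knots: list[float] = Field(description="mg g⁻¹ dry mass")
    d13c_knots: list[float] = Field(description="‰ V-PDB")
    conc_noise_frac: float = Field(default=0.08, ge=0)
    d13c_noise_sd: float = Field(default=0.2, ge=0)

    @model_validator(mode="after")
    def _same_length(self) -> "NSCTemplate":
        if not (len(self.doy_knots) == len(self.conc_knots) == len(self.d13c_knots)):
            raise ValueError("doy_knots, conc_knots and d13c_knots must have equal length")
        return self


def _default_phloem_nsc() -> dict[str, NSCTemplate]:
    # Mid-season starch build-up to ~72 mg/g followed by remobilization to
    # ~26 mg/g across the earlywood-latewood transition; sucrose rises as
    # starch falls, and on average makes up ~34% of the WSC pool. Starch
    # δ13C is buffered (multi-week pool) relative to sucrose/glucose.
    return {
        "sucrose": NSCTemplate(
            doy_knots=[120, 150, 175, 200, 213, 250, 273],
            conc_knots=[22, 18, 16, 22, 30, 27, 25],
            d13c_knots=[-26.2, -26.6, -27.0, -26.4, -25.8, -26.0, -26.3],
        ),
        "glucose": NSCTemplate(
            doy_knots=[120, 150, 175, 200, 213, 250, 273],
            conc_knots=[24, 22, 20, 22, 24, 23, 22],
            d13c_knots=[-25.6, -26.0, -26.5, -25.9, -25.3, -25.6, -25.9],
        ),
        "fructose": NSCTemplate(
            doy_knots=[120, 150, 175, 200, 213, 250, 273],
            conc_knots=[22, 21, 19, 20, 22, 21, 20],
            d13c_knots=[-26.4, -26.7, -27.0, -26.6, -26.2, -26.4, -26.6],
        ),
        "starch": NSCTemplate(
            doy_knots=[120, 150, 185, 213, 250, 273],
            conc_knots=[18, 40, 72, 26, 25, 24],
            d13c_knots=[-25.1, -25.0, -24.9, -25.0, -25.1, -25.1],
            d13c_noise_sd=0.12,
        ),
    }


def _default_root_nsc() -> dict[str, NSCTemplate]:
    # Root starch and WSC track the fibrous-root growth pulses; starch has
    # the larger relative amplitude (fast-turnover intra-seasonal reserve).
    return {
        "wsc": NSCTemplate(
            doy_knots=[120, 157, 175, 194, 210, 229, 255, 273, 294],
            conc_knots=[38, 42, 52, 46, 56, 48, 58, 52, 46],
            d13c_knots=[-26.8, -26.5, -26.0, -26.4, -25.9, -26.3, -25.6, -26.0, -26.4],
        ),
        "starch": NSCTemplate(
            doy_knots=[120, 157, 175, 194, 210, 229, 255, 273, 294],
            conc_knots=[6, 10, 24, 14, 28, 16, 30, 20, 12],
            d13c_knots=[-25.4, -25.3, -25.2, -25.3, -25.2, -25.3, -25.2, -25.3, -25.4],
            d13c_noise_sd=0.12,
        ),
    }


class RootPulse(StrictModel):
    """One fibrous-root growth pulse with scanner-specific expression."""

    start: dt.date
    end: dt.date
    amplitude_mm: float = Field(ge=0, description="peak daily elongation, mm d⁻¹")
    scanner_weights: list[float] = Field(description="relative expression per scanner")

    @model_validator(mode="after")
    def _ordered(self) -> "RootPulse":
        if self.end < self.start:
            raise ValueError("root pulse end before start")
        return self


def _default_root_pulses() -> list[RootPulse]:
    # Three pulse periods: an early flush seen by scanner 1 only, a
    # mid-summer pulse on scanners 1-2, and a late (dry-period) pulse on
    # scanner 3 — spatially heterogeneous root growth.
    return [
        RootPulse(start=dt.date(2018, 6, 6), end=dt.date(2018, 7, 12),
                  amplitude_mm=1.4, scanner_weights=[1.0, 0.05, 0.05]),
        RootPulse(start=dt.date(2018, 7, 13), end=dt.date(2018, 8, 16),
                  amplitude_mm=1.2, scanner_weights=[0.7, 0.9, 0.1]),
        RootPulse(start=dt.date(2018, 8, 17), end=dt.date(2018, 9, 30),
                  amplitude_mm=1.0, scanner_weights=[0.05, 0.1, 1.0]),
    ]


class CouplingWindow(StrictModel):
    start: dt.date
    end: dt.date


def _default_stem_coupling() -> list[CouplingWindow]:
    # High carbon-demand windows where new assimilates dominate the stem
    # efflux substrate: maximum tracheid production, maximum maturation,
    # and the dry period.
    return [
        CouplingWindow(start=dt.date(2018, 6, 1), end=dt.date(2018, 6, 15)),
        CouplingWindow(start=dt.date(2018, 7, 14), end=dt.date(2018, 8, 13)),
        CouplingWindow(start=dt.date(2018, 8, 16), end=dt.date(2018, 9, 11)),
    ]


def _default_soil_coupling() -> list[CouplingWindow]:
    return [
        CouplingWindow(start=dt.date(2018, 6, 6), end=dt.date(2018, 7, 12)),
        CouplingWindow(start=dt.date(2018, 8, 17), end=dt.date(2018, 9, 30)),
    ]


class SimulationConfig(StrictModel):
    """Everything the synthetic-data generators need, with ground truth."""

    seed: int = 1
    season_start: dt.date = dt.date(2018, 4, 15)
    season_end: dt.date = dt.date(2018, 9, 30)
    dry_start: dt.date = dt.date(2018, 8, 16)
    dry_end: dt.date = dt.date(2018, 9, 11)

    chambers: dict[ChamberKind, ChamberSpec] = Field(default_factory=_default_chambers)
    chamber_temp_c: float = 20.0
    ambient_co2_ppm: float = 400.0
    ambient_d13c: float = -8.5
    noise_sd_c12_ppm: float = Field(default=0.1, ge=0)
    noise_sd_c13_ppm: float | None = Field(
        default=None, description="defaults to noise_sd_c12_ppm × R_VPDB (proportional)"
    )

    # true-flux model ------------------------------------------------------
    stem_resp_base: float = Field(default=0.25, gt=0, description="a in a·e^{bT}")
    stem_resp_temp_coef: float = Field(default=0.0693, description="b, °C⁻¹ (Q10=2)")
    stem_growth_coupling: float = Field(default=1.0, ge=0)
    soil_resp_base: float = Field(default=0.5, gt=0)
    soil_resp_temp_coef: float = 0.08
    soil_moisture_half_sat: float = Field(default=0.08, gt=0, description="m³ m⁻³")
    soil_root_coupling: float = Field(default=0.5, ge=0)
    shoot_amax: float = Field(default=6.0, gt=0, description="peak light-saturated uptake")
    shoot_par_half_sat: float = Field(default=300.0, gt=0)

    # δ13C allocation truth ------------------------------------------------
    assim_d13c_base: float = -26.5
    assim_d13c_seasonal_amp: float = 1.0
    assim_d13c_dry_shift: float = Field(default=2.0, description="enrichment during dry period, ‰")
    assim_d13c_ar1: float = Field(default=0.6, ge=0, lt=1)
    assim_d13c_daily_sd: float = Field(default=0.5, ge=0)
    allocation_lag_stem_days: int = Field(default=2, ge=0)
    allocation_lag_soil_days: int = Field(default=4, ge=0)
    fractionation_stem: float = Field(default=4.5, description="apparent resp. fractionation, ‰")
    fractionation_soil: float = 1.0
    stem_pool_d13c: float = Field(default=-31.0, description="δ of the slow storage pool feeding efflux")
    soil_pool_d13c: float = -28.0
    coupling_base: float = Field(default=0.25, ge=0, le=1)
    coupling_high: float = Field(default=0.9, ge=0, le=1)
    stem_coupling_windows: list[CouplingWindow] = Field(default_factory=_default_stem_coupling)
    soil_coupling_windows: list[CouplingWindow] = Field(default_factory=_default_soil_coupling)

    # growth truth ---------------------------------------------------------
    gompertz: GompertzTruth = Field(default_factory=GompertzTruth)
    n_trees: int = Field(default=5, gt=0)
    tracheid_sampling_interval_days: int = Field(default=7, gt=0)
    phloem_nsc: dict[str, NSCTemplate] = Field(default_factory=_default_phloem_nsc)
    root_nsc: dict[str, NSCTemplate] = Field(default_factory=_default_root_nsc)
    phloem_sampling_doys: list[int] = Field(default_factory=lambda: [129, 143, 164, 185, 213, 248])
    root_sampling_doys: list[int] = Field(
        default_factory=lambda: [121, 136, 150, 164, 181, 199, 213, 230, 244, 262, 294]
    )
    nsc_replicates: int = Field(default=5, gt=0, description="trees (phloem) or spots (roots)")
    root_pulses: list[RootPulse] = Field(default_factory=_default_root_pulses)
    n_scanners: int = Field(default=3, gt=0)
    root_noise_sd_mm: float = Field(default=0.05, ge=0)

    @model_validator(mode="after")
    def _validate_windows(self) -> "SimulationConfig":
        if self.season_end <= self.season_start:
            raise ValueError("season_end must be after season_start")
        if not (self.season_start <= self.dry_start <= self.dry_end <= self.season_end):
            raise ValueError("dry period must lie within the season")
        if self.noise_sd_c13_ppm is None:
            object.__setattr__(self, "noise_sd_c13_ppm", self.noise_sd_c12_ppm * R_VPDB)
        return self

    @property
    def molar_volume_l(self) -> float:
        """Ideal-gas molar volume (l mol⁻¹) at chamber temperature, 1 atm."""
        return 22.414 * (273.15 + self.chamber_temp_c) / 273.15


class FluxStageConfig(StrictModel):
    windows: dict[ChamberKind, tuple[float, float]] | None = Field(
        default=None, description="override per-kind fit windows (s)"
    )
    min_flux: float = Field(default=1e-4, description="|F12| below which δ is undefined")


class PhenologyStageConfig(StrictModel):
    rate_threshold_frac: float = Field(default=0.05, gt=0, le=1, description="f1")
    max_rate_threshold_frac: float = Field(default=0.75, gt=0, le=1, description="f2")
    ew_quantile: float = Field(default=0.60, gt=0, lt=1)
    lw_quantile: float = Field(default=0.80, gt=0, lt=1)
    root_smooth_days: int = Field(default=7, gt=0)
    root_min_amp: float = Field(default=0.15, gt=0, description="mm d⁻¹ after smoothing")
    root_min_gap_days: int = Field(default=5, ge=0)


class AssociationStageConfig(StrictModel):
    alpha: float = Field(default=0.05, gt=0, lt=1, description="covariate-removal threshold")
    lag_days: int = Field(default=1, ge=0)
    delta_exclude_dates: list[dt.date] = Field(
        default_factory=list,
        description="sampling days dropped from the δ¹³C substrate models "
        "(e.g. days dominated by starch remobilization)",
    )


class CoherenceStageConfig(StrictModel):
    alpha: float = Field(default=0.05, gt=0, lt=1)
    n_surrogates: int = Field(default=300, ge=100)
    voices_per_octave: int = Field(default=12, gt=0)
    min_period_days: float = Field(default=2.0, gt=0)
    max_period_days: float = Field(default=48.0, gt=0)
    max_gap_fraction: float = Field(default=0.10, gt=0, le=1)
    bands: list[tuple[float, float]] = Field(
        default_factory=lambda: [(4.0, 8.0), (8.0, 16.0), (16.0, 32.0)]
    )


class PipelineConfig(StrictModel):
    """Top-level configuration of a full pipeline run."""

    run_id: str = "treeflux-run"
    seed: int = 1
    outdir: str = "treeflux_out"
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    flux: FluxStageConfig = Field(default_factory=FluxStageConfig)
    phenology: PhenologyStageConfig = Field(default_factory=PhenologyStageConfig)
    association: AssociationStageConfig = Field(default_factory=AssociationStageConfig)
    coherence: CoherenceStageConfig = Field(default_factory=CoherenceStageConfig)

    @model_validator(mode="after")
    def _propagate_seed(self) -> "PipelineConfig":
        # one seed drives every stochastic stage
        if "simulation" not in self.model_fields_set or "seed" not in self.simulation.model_fields_set:
            object.__setattr__(self.simulation, "seed", self.seed)
        return self


def load_config(path: str) -> PipelineConfig:
    """Load and validate a pipeline YAML config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path!r} must contain a mapping")
    return PipelineConfig(**data)


def dump_config(config: PipelineConfig) -> str:
    """Serialize a config back to YAML (dates as ISO strings)."""
    return yaml.safe_dump(
        yaml.safe_load(config.model_dump_json()), sort_keys=True, default_flow_style=False
    )


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the fully resolved configuration."""
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:16]
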
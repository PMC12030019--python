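"""Synthetic greenhouse season generator with known ground truth.

Emulates the hourly sensor environment of a glass-greenhouse Panax
notoginseng plot:

* soil moisture decays exponentially between irrigations (default rate
  0.065/day, ~8.4 days from a post-irrigation 38% down to the 22% stress
  line, matching the 8-10 day irrigation intervals of the field study) and
  jumps by a fixed replenishment at each irrigation event;
* the 20 cm node is a damped (0.6), 3 h-lagged copy of the 10 cm node;
* air temperature/humidity are noisy diurnal sinusoids inside the plateau
  greenhouse climate envelope (monthly means 3-27 degC, RH 58-83%);
* the growth status is a [0,1] logistic signal that rises while moisture sits
  inside the favourable band and decays once the soil drops below it.

The truth log records irrigation hours and the first stress-onset hour after
each irrigation, so decision lead times are measurable exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocess import SensorFrame

__all__ = ["SimulatorConfig", "SimulationResult", "simulate_season",
           "inject_artifacts", "band_exit_hours"]


@dataclass
class SoilConfig:
    initial_moisture: float = 38.0     # % vol, just after an irrigation
    depletion_per_day: float = 0.065   # exponential decay rate (1/day)
    irrigation_jump: float = 16.0      # % added per irrigation event
    field_capacity: float = 40.0       # excess irrigation drains above this
    band: tuple[float, float] = (22.0, 45.0)  # favourable moisture band


@dataclass
class WeatherConfig:
    air_temp_mean: float = 17.0
    air_temp_amp: float = 8.0
    air_hum_mean: float = 70.0
    air_hum_amp: float = 12.0
    soil_temp_amp: float = 3.0
    cond_base: float = 600.0
    cond_slope: float = 5.0            # uS/cm per % moisture above band mid


@dataclass
class GrowthConfig:
    rate_in_band: float = 0.010        # logistic logit-rate per hour in band
    decay_rate: float = 0.004          # proportional decay per hour under stress
    initial_status: float = 0.20
    noise_sd: float = 0.01


@dataclass
class NoiseConfig:
    moisture_sd: float = 0.3
    temp_sd: float = 0.2
    humidity_sd: float = 1.0
    cond_sd: float = 5.0


@dataclass
class AnomalyConfig:
    spike_prob: float = 0.0
    spike_sds: float = 10.0            # spike magnitude in channel SD units
    missing_prob: float = 0.0


@dataclass
class SimulatorConfig:
    horizon_days: int = 32
    seed: int = 0
    start: str = "2024-04-01 00:00"
    field_id: str = "A1"
    irrigation_period_days: float = 9.0   # used when no explicit schedule given
    node2_damping: float = 0.6
    node2_lag_h: int = 3
    soil: SoilConfig = field(default_factory=SoilConfig)
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    anomaly: AnomalyConfig = field(default_factory=AnomalyConfig)

    def __post_init__(self) -> None:
        lo, hi = self.soil.band
        if not lo < hi:
            raise ValueError("favourable band must satisfy lo < hi")
        if self.horizon_days < 0:
            raise ValueError("horizon must be non-negative")
        for p in (self.anomaly.spike_prob, self.anomaly.missing_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.soil.depletion_per_day, self.growth.rate_in_band,
               self.growth.decay_rate) < 0:
            raise ValueError("rates must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationResult:
    frame: SensorFrame                  # all sensor channels, hourly
    status: np.ndarray                  # observed growth status in [0, 1]
    truth: dict                         # latent signals + event log


def band_exit_hours(moisture: float, band_lo: float, rate_per_day: float) -> float:
    """Closed-form hours until exponential decay from ``moisture`` crosses the
    lower band edge."""
    if moisture <= band_lo:
        return 0.0
    return 24.0 * math.log(moisture / band_lo) / rate_per_day


def simulate_season(cfg: SimulatorConfig,
                    irrigation_hours: list[int] | None = None) -> SimulationResult:
    """Generate one season. ``irrigation_hours`` defaults to a schedule every
    ``cfg.irrigation_period_days`` starting at hour 0."""
    if cfg.horizon_days < 1:
        raise ValueError("simulation needs a horizon of at least 1 day")
    T = cfg.horizon_days * 24
    rng = np.random.default_rng(cfg.seed)
    if irrigation_hours is None:
        # initial_moisture is the just-irrigated level, so the schedule
        # starts one period in
        step = int(round(cfg.irrigation_period_days * 24))
        irrigation_hours = list(range(step, T, step))
    irrigation_hours = sorted(int(h) for h in irrigation_hours)
    events = set(irrigation_hours)

    lo, hi = cfg.soil.band
    r_hour = cfg.soil.depletion_per_day / 24.0

    moisture = np.empty(T)
    status = np.empty(T)
    m = cfg.soil.initial_moisture
    s = cfg.growth.initial_status
    for t in range(T):
        if t in events:
            m = min(m + cfg.soil.irrigation_jump, cfg.soil.field_capacity)
        moisture[t] = m
        status[t] = s
        m *= math.exp(-r_hour)
        if lo <= m <= hi:              # favourable: logistic growth
            logit = math.log(s / (1.0 - s))
            logit += cfg.growth.rate_in_band
            s = 1.0 / (1.0 + math.exp(-logit))
        else:                          # stressed: proportional decline
            s *= 1.0 - cfg.growth.decay_rate
        s = min(max(s, 1e-4), 1.0 - 1e-4)

    hours = np.arange(T)
    # deeper node: damped, lagged, slightly wetter
    mid = 0.5 * (lo + hi)
    lag = cfg.node2_lag_h
    m_lag = np.concatenate([np.full(lag, moisture[0]), moisture[:-1 * lag or None]])[:T]
    moisture2 = mid + cfg.node2_damping * (m_lag - mid) + 2.0

    w, nz = cfg.weather, cfg.noise
    diurnal = np.sin(2 * np.pi * (hours % 24 - 9) / 24.0)
    air_temp = w.air_temp_mean + w.air_temp_amp * diurnal + rng.normal(0, nz.temp_sd, T)
    air_hum = w.air_hum_mean - w.air_hum_amp * diurnal + rng.normal(0, nz.humidity_sd, T)
    soil_diurnal = np.sin(2 * np.pi * (hours % 24 - 13) / 24.0)  # lagged, damped
    soil_temp1 = w.air_temp_mean + w.soil_temp_amp * soil_diurnal + rng.normal(0, nz.temp_sd, T)
    soil_temp2 = w.air_temp_mean + 0.5 * w.soil_temp_amp * soil_diurnal + rng.normal(0, nz.temp_sd, T)
    cond1 = w.cond_base + w.cond_slope * (moisture - mid) + rng.normal(0, nz.cond_sd, T)
    cond2 = w.cond_base + w.cond_slope * (moisture2 - mid) + rng.normal(0, nz.cond_sd, T)

    obs_m1 = np.clip(moisture + rng.normal(0, nz.moisture_sd, T), 0, 100)
    obs_m2 = np.clip(moisture2 + rng.normal(0, nz.moisture_sd, T), 0, 100)
    obs_status = np.clip(status + rng.normal(0, cfg.growth.noise_sd, T), 0, 1)

    index = pd.date_range(cfg.start, periods=T, freq="h")
    df = pd.DataFrame({
        "soil_temp_C_n1": soil_temp1,
        "soil_moist_pct_n1": obs_m1,
        "soil_cond_uScm_n1": cond1,
        "soil_temp_C_n2": soil_temp2,
        "soil_moist_pct_n2": obs_m2,
        "soil_cond_uScm_n2": cond2,
        "air_temp_C": air_temp,
        "air_hum_pct": air_hum,
    }, index=index)

    # first stress-onset hour in each wet period (starting at hour 0 and
    # after each irrigation; None if the next irrigation arrives first or
    # the horizon ends wet)
    onsets: list[int | None] = []
    period_starts = [0] + irrigation_hours
    bounds = irrigation_hours + [T]
    for start_h, end_h in zip(period_starts, bounds):
        below = np.flatnonzero(moisture[start_h:end_h] < lo)
        onsets.append(int(start_h + below[0]) if len(below) else None)

    truth = {
        "latent_moisture": moisture,
        "latent_status": status,
        "irrigation_hours": irrigation_hours,
        "stress_onset_hours": onsets,
        "config": cfg.to_dict(),
    }
    frame = SensorFrame(df, field_id=cfg.field_id)
    return SimulationResult(frame=frame, status=obs_status, truth=truth)


def inject_artifacts(frame: SensorFrame, cfg: SimulatorConfig | AnomalyConfig,
                     seed: int | None = None) -> tuple[SensorFrame, dict]:
    """Inject spikes and missing cells; returns the corrupted frame plus a
    truth mask per column (``{"spikes": {...}, "missing": {...}}``)."""
    anom = cfg.anomaly if isinstance(cfg, SimulatorConfig) else cfg
    if seed is None:
        seed = cfg.seed if isinstance(cfg, SimulatorConfig) else 0
    rng = np.random.default_rng(seed)
    df = frame.data.copy()
    spikes: dict[str, np.ndarray] = {}
    missing: dict[str, np.ndarray] = {}
    for c in df.columns:
        x = df[c].to_numpy(dtype=float)
        sd = float(np.std(x)) or 1.0
        sp = rng.random(len(x)) < anom.spike_prob
        sign = rng.choice([-1.0, 1.0], size=len(x))
        x = np.where(sp, x + sign * anom.spike_sds * sd, x)
        mi = rng.random(len(x)) < anom.missing_prob
        x[mi] = np.nan
        df[c] = x
        spikes[c] = sp & ~mi
        missing[c] = mi
    return SensorFrame(df, frame.field_id), {"spikes": spikes, "missing": missing}
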
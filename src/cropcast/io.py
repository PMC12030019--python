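"""CSV readers/writers, run configuration and the end-to-end pipeline.

Sensor CSV dialect: comma-separated, UTF-8, mandatory header, one row per
(timestamp, field, node) with ISO-8601 timestamps; missing cells are empty.
Soil columns are per-node; air columns repeat on every node row. Survey CSV:
one row per (date, field, plant_id) with height_mm / stem_diameter_mm.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .growth_stats import HeightSurvey
from .intervention import (TrainingConfig, train_ensemble, ensemble_forecast,
                           COOLDOWN_H, DECLINE_K, DECLINE_DELTA)
from .informer import ModelConfig, ForecastWindowConfig
from .preprocess import SensorFrame, build_features, SOIL_VARS, AIR_VARS
from .synthetic import SimulatorConfig, simulate_season

__all__ = ["RunConfig", "read_sensor_csv", "write_sensor_csv",
           "read_survey_csv", "run_pipeline"]

log = logging.getLogger("cropcast")

_SOIL_COLS = list(SOIL_VARS)
_AIR_COLS = list(AIR_VARS)


def write_sensor_csv(frame: SensorFrame, path: str | Path) -> None:
    """Write a SensorFrame in the long (timestamp, field, node) dialect."""
    df = frame.data
    rows = []
    for node in ("n1", "n2"):
        sub = pd.DataFrame({
            "timestamp": df.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "field": frame.field_id,
            "node": node,
        })
        for c in _SOIL_COLS:
            sub[c] = df[f"{c}_{node}"].to_numpy()
        for c in _AIR_COLS:
            sub[c] = df[c].to_numpy()
        rows.append(sub)
    pd.concat(rows).to_csv(path, index=False)


def read_sensor_csv(path: str | Path) -> SensorFrame:
    """Read the long sensor dialect back into a wide hourly SensorFrame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    required = {"timestamp", "field", "node", *_SOIL_COLS, *_AIR_COLS}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    unknown = set(raw.columns) - required
    if unknown:
        warnings.warn(f"unknown columns retained: {sorted(unknown)}")
    raw["timestamp"] = pd.to_datetime(raw["timestamp"])
    if raw.duplicated(subset=["timestamp", "node"]).any():
        raise ValueError("duplicate (timestamp, node) rows")
    raw = raw.sort_values("timestamp")
    fields = raw["field"].unique()
    if len(fields) != 1:
        raise ValueError("one field per file expected")
    wide = {}
    for node, sub in raw.groupby("node"):
        sub = sub.set_index("timestamp")
        for c in _SOIL_COLS + sorted(unknown):
            wide[f"{c}_{node}"] = sub[c]
    air = raw.groupby("timestamp")[_AIR_COLS].first()
    for c in _AIR_COLS:
        wide[c] = air[c]
    df = pd.DataFrame(wide)
    df.index = pd.DatetimeIndex(df.index, name=None)
    df.index.name = None
    return SensorFrame(df, field_id=str(fields[0]))


def read_survey_csv(path: str | Path) -> list[HeightSurvey]:
    raw = pd.read_csv(path, parse_dates=["date"])
    surveys = []
    for (date, fid), sub in raw.groupby(["date", "field"]):
        surveys.append(HeightSurvey(date=date, field_id=str(fid),
                                    heights_mm=sub["height_mm"].to_numpy()))
    return surveys


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serialized verbatim into every
    output manifest."""

    seed: int = 0
    out_dir: str = "runs"
    sensor_csv: str | None = None      # if None, a season is simulated
    window: ForecastWindowConfig = field(default_factory=ForecastWindowConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    model: ModelConfig | None = None
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    n_runs: int = 3
    cooldown_h: int = COOLDOWN_H
    decline_k: int = DECLINE_K
    decline_delta: float = DECLINE_DELTA
    irrigation_volume_L: float = 85.0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.effective_model().to_dict()
        return d

    def effective_model(self) -> ModelConfig:
        if self.model is not None:
            return self.model
        return ModelConfig(window=self.window)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "window" in d:
            d["window"] = ForecastWindowConfig(**d["window"])
        if "training" in d:
            d["training"] = TrainingConfig(**d["training"])
        if "model" in d and d["model"] is not None:
            d["model"] = ModelConfig.from_dict(d["model"])
        if "simulator" in d:
            sim = d["simulator"]
            from .synthetic import (SoilConfig, WeatherConfig, GrowthConfig,
                                    NoiseConfig, AnomalyConfig)
            for key, c in (("soil", SoilConfig), ("weather", WeatherConfig),
                           ("growth", GrowthConfig), ("noise", NoiseConfig),
                           ("anomaly", AnomalyConfig)):
                if key in sim:
                    if key == "soil" and "band" in sim[key]:
                        sim[key]["band"] = tuple(sim[key]["band"])
                    sim[key] = c(**sim[key])
            d["simulator"] = SimulatorConfig(**sim)
        return cls(**d)


def run_pipeline(config: RunConfig) -> dict:
    """simulate/load -> preprocess -> train -> ensemble predict -> decide.

    Writes decision JSON, QC JSON, scaler JSON and the config manifest under
    ``config.out_dir`` and returns the artifact paths.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if config.sensor_csv is not None:
            frame = read_sensor_csv(config.sensor_csv)
            status_path = Path(config.sensor_csv).with_name("status.csv")
            if status_path.exists():
                status = pd.read_csv(status_path)["status"].to_numpy()
            else:
                raise FileNotFoundError(
                    "real-data route needs a status.csv next to the sensor file")
        else:
            sim = simulate_season(config.simulator)
            frame, status = sim.frame, sim.status
            (out / "truth.json").write_text(json.dumps({
                "irrigation_hours": sim.truth["irrigation_hours"],
                "stress_onset_hours": sim.truth["stress_onset_hours"],
            }, indent=2))

        stage = "preprocess"
        fm = build_features(frame, status=status)
        (out / "qc.json").write_text(json.dumps(fm.qc, indent=2))

        stage = "train+predict"
        if config.sensor_csv is None:
            # synthetic route mirrors the operating protocol: train the
            # ensemble on a long burn-in record, then forecast this season
            # (scaled with the training scaler)
            trained = train_ensemble(config.simulator, seed=config.seed,
                                     n_runs=config.n_runs,
                                     train_cfg=config.training,
                                     model_cfg=config.effective_model())
            fm = build_features(frame, status=status,
                                scaler=trained[0].scaler)
            bundle, decision = ensemble_forecast(
                fm, trained=trained,
                k=config.decline_k, delta=config.decline_delta)
        else:
            bundle, decision = ensemble_forecast(
                fm, seed=config.seed, n_runs=config.n_runs,
                train_cfg=config.training, model_cfg=config.effective_model(),
                k=config.decline_k, delta=config.decline_delta)
        (out / "scaler.json").write_text(fm.scaler.to_json())
        decision.irrigation_volume_L = config.irrigation_volume_L

        stage = "report"
        manifest = {"config": config.to_dict(), "seed": config.seed}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        payload = json.loads(decision.to_json())
        payload["per_run_onset_h"] = bundle.per_run_onset_h
        payload["ensemble_onset_h"] = bundle.ensemble_onset_h
        (out / "decision.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        np.savetxt(out / "trajectories.csv",
                   np.column_stack(bundle.runs), delimiter=",",
                   header=",".join(f"run{i}" for i in range(len(bundle.runs))))
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e

    log.info("decision: onset %s h, warn at %s", bundle.ensemble_onset_h,
             decision.warn_at)
    return {"out_dir": str(out), "decision": str(out / "decision.json"),
            "ensemble_onset_h": bundle.ensemble_onset_h,
            "warn_at": str(decision.warn_at)}
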
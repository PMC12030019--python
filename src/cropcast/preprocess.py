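"""Sensor-stream preprocessing: denoising, outlier screening, imputation and
feature construction.

The raw inputs are hourly greenhouse sensor streams (soil temperature,
moisture and conductivity at two depths, plus air temperature and humidity)
with occasional spikes and missing cells. The cleaning chain applied here is
the one used for the field data behind this package:

1. outlier screening with the Tukey 1.5*IQR fence, flagged cells replaced by
   the mean of the unflagged values (windowed by default, 9 days);
2. linear interpolation of missing cells;
3. Gaussian smoothing (sigma = 10 samples by default);
4. feature assembly: raw channels, per-variable layer differences
   (10 cm node minus 20 cm node), adjacent-sensor means, a lagged copy of the
   growth-status target, and min-max scaling of every column into [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SensorFrame",
    "GaussianFilterSpec",
    "QuartileSummary",
    "FeatureMatrix",
    "gaussian_smooth",
    "quartile_summary",
    "screen_outliers",
    "screen_outliers_windowed",
    "interpolate_missing",
    "build_features",
    "status_from_heights",
]

SOIL_VARS = ("soil_temp_C", "soil_moist_pct", "soil_cond_uScm")
AIR_VARS = ("air_temp_C", "air_hum_pct")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class SensorFrame:
    """Hourly multivariate sensor table for one field.

    ``data`` is indexed by a strictly increasing hourly DatetimeIndex; NaN
    marks missing cells. Soil columns carry a ``_n1`` / ``_n2`` suffix for the
    10 cm and 20 cm nodes.
    """

    data: pd.DataFrame
    field_id: str = "A1"

    def __post_init__(self) -> None:
        idx = self.data.index
        if len(idx) < 2:
            raise ValueError("SensorFrame needs at least 2 rows")
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("SensorFrame index must be a DatetimeIndex")
        deltas = np.diff(idx.asi8)
        if not (deltas > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if not (deltas == 3_600_000_000_000).all():
            raise ValueError("timestamps must be on a 1 h grid")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate column names")

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    def copy(self) -> "SensorFrame":
        return SensorFrame(self.data.copy(), self.field_id)


@dataclass
class GaussianFilterSpec:
    """Discrete Gaussian kernel: G(x) = exp(-x^2 / 2 sigma^2) / (sqrt(2 pi) sigma),
    truncated at ``radius`` samples and renormalised to unit sum."""

    sigma: float = 10.0
    radius: int | None = None  # default ceil(4 * sigma)
    edge_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.radius is None:
            self.radius = int(np.ceil(4.0 * self.sigma))
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    def kernel(self) -> np.ndarray:
        x = np.arange(-self.radius, self.radius + 1, dtype=float)
        w = np.exp(-(x ** 2) / (2.0 * self.sigma ** 2))
        return w / w.sum()


@dataclass
class QuartileSummary:
    q1: float
    q2: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower_bound(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def upper_bound(self) -> float:
        return self.q3 + 1.5 * self.iqr


@dataclass
class MinMaxScaler1D:
    """Per-column min-max parameters, kept so predictions can be mapped back
    to physical units."""

    data_min: dict[str, float] = field(default_factory=dict)
    data_max: dict[str, float] = field(default_factory=dict)

    def fit(self, df: pd.DataFrame) -> "MinMaxScaler1D":
        self.data_min = {c: float(df[c].min()) for c in df.columns}
        self.data_max = {c: float(df[c].max()) for c in df.columns}
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in df.columns:
            lo, hi = self.data_min[c], self.data_max[c]
            span = hi - lo
            out[c] = (df[c] - lo) / span if span > 0 else 0.0
        return out

    def inverse_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in df.columns:
            lo, hi = self.data_min[c], self.data_max[c]
            out[c] = df[c] * (hi - lo) + lo
        return out

    def inverse_target(self, values: np.ndarray, column: str = "status") -> np.ndarray:
        lo, hi = self.data_min[column], self.data_max[column]
        return np.asarray(values) * (hi - lo) + lo

    def to_json(self) -> str:
        return json.dumps({"data_min": self.data_min, "data_max": self.data_max})

    @classmethod
    def from_json(cls, text: str) -> "MinMaxScaler1D":
        d = json.loads(text)
        return cls(data_min=d["data_min"], data_max=d["data_max"])


@dataclass
class FeatureMatrix:
    """Model-ready matrix: scaled feature columns plus the scaled target."""

    features: pd.DataFrame          # scaled into [0, 1]
    target: pd.Series               # scaled status, same index
    scaler: MinMaxScaler1D
    qc: dict = field(default_factory=dict)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.features.index

    def __len__(self) -> int:
        return len(self.features)


# ---------------------------------------------------------------------------
# cleaning operations
# ---------------------------------------------------------------------------

def gaussian_smooth(series: np.ndarray, spec: GaussianFilterSpec | None = None) -> np.ndarray:
    """Convolve with a unit-sum truncated Gaussian kernel."""
    spec = spec or GaussianFilterSpec()
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 1:
        raise ValueError("series must be a non-empty 1-D vector")
    if np.isnan(series).any():
        raise ValueError("series must not contain missing values")
    return gaussian_filter1d(
        series, sigma=spec.sigma, mode=spec.edge_mode,
        truncate=spec.radius / spec.sigma,
    )


def quartile_summary(values: np.ndarray) -> QuartileSummary:
    """Quartiles by linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values for a quartile summary")
    if np.isnan(values).any():
        raise ValueError("values must not contain missing cells")
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    return QuartileSummary(float(q1), float(q2), float(q3))


def screen_outliers(series: np.ndarray,
                    summary: QuartileSummary | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Flag values outside the Tukey fence and replace them with the mean of
    the unflagged values. Returns ``(flags, cleaned)``."""
    series = np.asarray(series, dtype=float)
    if summary is None:
        summary = quartile_summary(series)
    flags = (series < summary.lower_bound) | (series > summary.upper_bound)
    if flags.all():
        raise ValueError("all points flagged as outliers; degenerate data")
    cleaned = series.copy()
    cleaned[flags] = series[~flags].mean()
    return flags, cleaned


def screen_outliers_windowed(series: np.ndarray, window_h: int = 216
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Apply ``screen_outliers`` over consecutive windows (default 9 days)."""
    series = np.asarray(series, dtype=float)
    flags = np.zeros(len(series), dtype=bool)
    cleaned = series.copy()
    for a in range(0, len(series), window_h):
        chunk = series[a:a + window_h]
        if len(chunk) < 4:
            continue
        f, c = screen_outliers(chunk)
        flags[a:a + len(chunk)] = f
        cleaned[a:a + len(chunk)] = c
    return flags, cleaned


def interpolate_missing(series: np.ndarray,
                        timestamps: np.ndarray | pd.DatetimeIndex | None = None
                        ) -> np.ndarray:
    """Fill missing cells by the straight line through the bracketing
    observations; boundary gaps take the nearest observed value."""
    series = np.asarray(series, dtype=float)
    observed = ~np.isnan(series)
    if observed.sum() < 2:
        raise ValueError("need at least 2 observed cells to interpolate")
    if timestamps is None:
        t = np.arange(len(series), dtype=float)
    elif isinstance(timestamps, pd.DatetimeIndex):
        t = timestamps.asi8.astype(float)
    else:
        t = np.asarray(timestamps, dtype=float)
    out = series.copy()
    out[~observed] = np.interp(t[~observed], t[observed], series[observed])
    return out


def clean_channel(series: np.ndarray, *, window_h: int = 216,
                  smooth: GaussianFilterSpec | None = None,
                  counters: dict | None = None) -> np.ndarray:
    """Full per-channel chain: screen -> impute -> smooth."""
    series = np.asarray(series, dtype=float)
    missing = np.isnan(series)
    work = series.copy()
    if missing.any():
        # screen only observed cells; re-insert NaN before imputation
        obs_idx = np.flatnonzero(~missing)
        flags_obs, cleaned_obs = screen_outliers_windowed(series[obs_idx], window_h)
        work[obs_idx] = cleaned_obs
        flags = np.zeros(len(series), dtype=bool)
        flags[obs_idx] = flags_obs
    else:
        flags, work = screen_outliers_windowed(series, window_h)
    imputed = interpolate_missing(work) if missing.any() else work
    if counters is not None:
        counters["flagged"] = counters.get("flagged", 0) + int(flags.sum())
        counters["imputed"] = counters.get("imputed", 0) + int(missing.sum())
    return gaussian_smooth(imputed, smooth)


# ---------------------------------------------------------------------------
# target + feature assembly
# ---------------------------------------------------------------------------

def status_from_heights(survey_dates: Sequence, mean_heights_mm: Sequence[float],
                        grid: pd.DatetimeIndex) -> np.ndarray:
    """Interpolate weekly mean plant height onto the hourly grid and min-max
    normalise to [0, 1] over the grid window."""
    t_obs = pd.DatetimeIndex(survey_dates).asi8.astype(float)
    y_obs = np.asarray(mean_heights_mm, dtype=float)
    if len(t_obs) < 2:
        raise ValueError("need at least 2 surveys")
    hourly = np.interp(grid.asi8.astype(float), t_obs, y_obs)
    lo, hi = hourly.min(), hourly.max()
    if hi == lo:
        return np.full(len(grid), 0.5)
    return (hourly - lo) / (hi - lo)


def build_features(frame: SensorFrame,
                   status: np.ndarray | None = None,
                   heights: Mapping | None = None,
                   *, window_h: int = 216,
                   smooth: GaussianFilterSpec | None = None,
                   clean: bool = True,
                   scaler: MinMaxScaler1D | None = None) -> FeatureMatrix:
    """Assemble the model-ready matrix from a two-node sensor frame.

    ``status`` is an hourly [0,1] growth-status signal aligned with the frame
    (synthetic route); alternatively ``heights`` supplies weekly surveys
    (``{"dates": [...], "mean_height_mm": [...]}``) from which the status is
    interpolated. Exactly one of the two must be given.

    Passing a fitted ``scaler`` (e.g. the training scaler at inference time)
    applies it instead of refitting, so thresholds learned in scaled units
    stay aligned across datasets.
    """
    if (status is None) == (heights is None):
        raise ValueError("provide exactly one of status= or heights=")
    df = frame.data
    grid = frame.timestamps
    qc: dict = {"flagged": 0, "imputed": 0}

    cols: dict[str, np.ndarray] = {}
    for c in df.columns:
        x = df[c].to_numpy(dtype=float)
        cols[c] = clean_channel(x, window_h=window_h, smooth=smooth,
                                counters=qc) if clean else x
        if np.isnan(cols[c]).any():
            raise ValueError(f"column {c!r} still has missing cells")

    # layer differences and adjacent-sensor means per soil variable
    for var in SOIL_VARS:
        a, b = f"{var}_n1", f"{var}_n2"
        if a in cols and b in cols:
            cols[f"{var}_diff"] = cols[a] - cols[b]
            cols[f"{var}_mean"] = 0.5 * (cols[a] + cols[b])

    if status is None:
        status = status_from_heights(heights["dates"], heights["mean_height_mm"], grid)
    status = np.asarray(status, dtype=float)
    if len(status) != len(grid):
        raise ValueError("status length does not match the sensor grid")

    cols["status_lag1"] = np.concatenate([[status[0]], status[:-1]])

    feat = pd.DataFrame(cols, index=grid)
    full = feat.copy()
    full["status"] = status
    if scaler is None:
        scaler = MinMaxScaler1D().fit(full)
    scaled = scaler.transform(full)
    return FeatureMatrix(features=scaled.drop(columns="status"),
                         target=scaled["status"], scaler=scaler, qc=qc)
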
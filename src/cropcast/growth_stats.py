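"""Outcome analytics for the plant-morphology surveys.

Histogram-based probability densities with a normal overlay for plant-height
distributions, and the percent growth / height-gap arithmetic used to compare
data-driven and fixed-schedule irrigation plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["HeightSurvey", "HistogramPDF", "histogram_pdf", "percent_growth",
           "height_gap_percent", "group_report", "plot_histogram_pdf"]

DEFAULT_BINS = 20       # p: histogram bins (10-30 recommended; 20 standard)
DEFAULT_GRID = 100      # g: overlay grid points


@dataclass
class HeightSurvey:
    """One weekly survey of one plot: per-plant heights and the survival
    count. ``heights_mm`` may be empty when only counts were recorded."""

    date: pd.Timestamp
    field_id: str
    heights_mm: np.ndarray = field(default_factory=lambda: np.array([]))
    survival_count: int | None = None

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date)
        self.heights_mm = np.asarray(self.heights_mm, dtype=float)
        if len(self.heights_mm) and (self.heights_mm <= 0).any():
            raise ValueError("plant heights must be positive")
        if self.survival_count is None and len(self.heights_mm):
            self.survival_count = len(self.heights_mm)
        if (self.survival_count is not None and len(self.heights_mm)
                and self.survival_count != len(self.heights_mm)):
            raise ValueError("survival_count must match the number of heights")

    @property
    def mean_height_mm(self) -> float:
        return float(self.heights_mm.mean())


@dataclass
class HistogramPDF:
    """Density-normalised histogram: Bin_i = k_i / (K * L) with equal-width
    bins over [min, max] (the last bin closed), plus a normal overlay with
    sample mean and SD (ddof=1) evaluated on a g-point grid."""

    bin_edges: np.ndarray
    bin_values: np.ndarray
    counts: np.ndarray
    mu: float
    sigma: float
    grid: np.ndarray
    overlay: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def mass(self) -> float:
        """Sum of Bin_i * L; equals 1 for any input."""
        return float((self.bin_values * self.bin_width).sum())


def histogram_pdf(values: np.ndarray, p: int = DEFAULT_BINS,
                  g: int = DEFAULT_GRID) -> HistogramPDF:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    if p < 1:
        raise ValueError("bin count must be >= 1")
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise ValueError("all values identical: zero-width histogram range")
    counts, edges = np.histogram(values, bins=p, range=(lo, hi))
    L = edges[1] - edges[0]
    bin_values = counts / (len(values) * L)
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    grid = np.linspace(lo, hi, g)
    overlay = stats.norm.pdf(grid, mu, sigma)
    return HistogramPDF(edges, bin_values, counts, mu, sigma, grid, overlay)


def percent_growth(start_count: int, end_count: int) -> float:
    """100 * (end - start) / start, to one decimal."""
    if start_count <= 0:
        raise ValueError("start count must be positive")
    return round(100.0 * (end_count - start_count) / start_count, 1)


def height_gap_percent(mean_a: float, mean_b: float) -> float:
    """Relative gap of mean height a over b, in percent to one decimal."""
    if mean_b <= 0:
        raise ValueError("reference mean must be positive")
    return round(100.0 * (mean_a - mean_b) / mean_b, 1)


def group_report(surveys: list[HeightSurvey],
                 grouping: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Per-plot time series of mean height, survival count and growth rate
    since the first survey, plus combined rows per named group.

    ``grouping`` maps a group label to its member plots, e.g.
    ``{"group1": ["A1", "A2"]}``; combined counts are summed per date.
    """
    if not surveys:
        raise ValueError("no surveys given")
    rows = []
    for s in sorted(surveys, key=lambda s: (s.field_id, s.date)):
        rows.append({
            "date": s.date, "field": s.field_id,
            "mean_height_mm": s.mean_height_mm if len(s.heights_mm) else np.nan,
            "survival_count": s.survival_count,
        })
    df = pd.DataFrame(rows)
    out = []
    for fid, sub in df.groupby("field"):
        sub = sub.sort_values("date").reset_index(drop=True)
        if len(sub) < 2:
            raise ValueError(f"plot {fid} needs at least 2 survey dates")
        start = sub["survival_count"].iloc[0]
        sub["growth_pct"] = [
            percent_growth(start, c) if pd.notna(c) and start else np.nan
            for c in sub["survival_count"]]
        out.append(sub)
    report = pd.concat(out, ignore_index=True)

    if grouping:
        extra = []
        for label, members in grouping.items():
            sub = (report[report["field"].isin(members)]
                   .groupby("date", as_index=False)
                   .agg(survival_count=("survival_count", "sum"),
                        mean_height_mm=("mean_height_mm", "mean")))
            sub["field"] = label
            start = sub["survival_count"].iloc[0]
            sub["growth_pct"] = [percent_growth(start, c) for c in sub["survival_count"]]
            extra.append(sub)
        report = pd.concat([report] + extra, ignore_index=True)
    return report


def plot_histogram_pdf(pdf: HistogramPDF, path: str, title: str = "") -> None:
    """Write a histogram + normal-overlay figure to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    widths = np.diff(pdf.bin_edges)
    ax.bar(pdf.bin_edges[:-1], pdf.bin_values, width=widths, align="edge",
           alpha=0.6, edgecolor="k")
    ax.plot(pdf.grid, pdf.overlay, "r-", lw=2,
            label=f"N({pdf.mu:.1f}, {pdf.sigma:.1f}$^2$)")
    ax.set_xlabel("plant height (mm)")
    ax.set_ylabel("probability density")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
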
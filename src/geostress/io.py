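"""Reading, resampling and diagnostic screening of wearable time-series.

A recording is a set of channels (HRV, step frequency, SpO2, optionally
perfusion / skin temperature / movement) sampled on a shared clock. Channels
are carried as :class:`SMSTimeSeries` — SMS standing for *surrogate markers
of stress*, the physiological proxies whose complexity patterns downstream
modules analyse. Timestamps are seconds as float with t=0 at the first
sample; CSV files may carry ISO datetimes, which are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SMSTimeSeries",
    "CorrelationTable",
    "DensityDiagnostic",
    "read_sms_csv",
    "write_sms_csv",
    "resample_uniform",
    "correlation_table",
    "density_diagnostic",
]

#: channels a wearable multi-sensor typically reports
KNOWN_CHANNELS = (
    "HRV",
    "SF",
    "SpO2",
    "perfusion",
    "skin_temperature",
    "movement",
)


class ConfigurationError(ValueError):
    """A column mapping or option does not match the input file."""


class DataError(ValueError):
    """The input data are structurally unusable (too short, all-missing…)."""


@dataclass
class SMSTimeSeries:
    """One labelled channel of timestamped measurements.

    Attributes
    ----------
    label : str
        Channel name (HRV, SF, SpO2, … or user-defined).
    times : ndarray
        Seconds since recording start, strictly increasing.
    values : ndarray
        Measurements in native units (HRV ms, SF steps/s, SpO2 %).
    """

    label: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size < 2:
            raise DataError(f"channel {self.label!r} needs >= 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"times of channel {self.label!r} must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        d = np.diff(self.times)
        return bool(np.all(np.abs(d - d[0]) <= rtol * max(abs(d[0]), 1.0)))


def _parse_times(col: pd.Series) -> np.ndarray:
    """Seconds-as-float from either numeric or ISO-8601 timestamps."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float)
    ts = pd.to_datetime(col, errors="coerce", format="ISO8601")
    if ts.isna().any():
        raise ConfigurationError(
            "timestamp column is neither numeric seconds nor ISO-8601 datetimes"
        )
    sec = (ts - ts.iloc[0]).dt.total_seconds().to_numpy(dtype=float)
    return sec


def read_sms_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    time_column: str = "t",
) -> dict[str, SMSTimeSeries]:
    """Read a multichannel recording from CSV.

    Parameters
    ----------
    path : path
        CSV with a header row.
    column_map : mapping channel-name -> column-name
        Which columns to load as which channels. Defaults to the known
        channel names, case-insensitively matched against the header.
    time_column : str
        Timestamp column (numeric seconds or ISO-8601 datetimes).

    Rows with missing values in a channel are dropped from that channel
    only; all channels share the same time origin (t=0 at the first row).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    lower = {c.lower(): c for c in df.columns}

    if time_column not in df.columns:
        if time_column.lower() in lower:
            time_column = lower[time_column.lower()]
        else:
            raise ConfigurationError(f"timestamp column {time_column!r} not found")

    if column_map is None:
        column_map = {ch: lower[ch.lower()] for ch in KNOWN_CHANNELS if ch.lower() in lower}
        if not column_map:
            raise ConfigurationError("no recognised channel columns found; pass column_map")
    missing = [c for c in column_map.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(f"mapped column(s) not in file: {missing}")

    times = _parse_times(df[time_column])
    times = times - times[0]
    out: dict[str, SMSTimeSeries] = {}
    for channel, col in column_map.items():
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        keep = np.isfinite(vals) & np.isfinite(times)
        if keep.sum() < 2:
            raise DataError(f"channel {channel!r} has fewer than 2 valid rows")
        out[channel] = SMSTimeSeries(channel, times[keep], vals[keep])
    return out


def write_sms_csv(path: str | Path, channels: Mapping[str, SMSTimeSeries]) -> None:
    """Write channels sharing a common time base back to CSV."""
    its = iter(channels.values())
    first = next(its)
    for s in its:
        if s.times.size != first.times.size or not np.allclose(
            s.times, first.times, rtol=0, atol=1e-9
        ):
            raise ValueError("write_sms_csv requires a common time base")
    data = {"t": first.times}
    for name, s in channels.items():
        data[name] = s.values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def resample_uniform(series: SMSTimeSeries, dt: float, *, max_gap_factor: float = 10.0):
    """Linearly interpolate a channel onto the uniform grid t1, t1+dt, ….

    No extrapolation beyond the last sample. An already-uniform series at
    spacing dt is returned unchanged. Gaps longer than ``max_gap_factor*dt``
    are still interpolated but reported in the returned series' ``flags``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if series.duration < 2 * dt:
        raise DataError("series must span at least 2*dt")
    d = np.diff(series.times)
    if np.allclose(d, dt, rtol=1e-9, atol=0):
        return series
    grid = series.times[0] + dt * np.arange(int(np.floor(series.duration / dt)) + 1)
    vals = np.interp(grid, series.times, series.values)
    out = SMSTimeSeries(series.label, grid, vals)
    long_gaps = int(np.sum(d > max_gap_factor * dt))
    if long_gaps:
        out.flags = {"long_gaps_interpolated": long_gaps}  # type: ignore[attr-defined]
    return out


@dataclass
class CorrelationTable:
    """Symmetric table of Pearson product-moment coefficients."""

    labels: list[str]
    matrix: np.ndarray
    degenerate: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_json_dict(self) -> dict:
        m = np.where(np.isfinite(self.matrix), self.matrix, None)
        return {
            "labels": self.labels,
            "matrix": [[None if v is None else float(v) for v in row] for row in m.tolist()],
            "degenerate": self.degenerate,
        }


def correlation_table(channels: Mapping[str, SMSTimeSeries]) -> CorrelationTable:
    """Pairwise Pearson correlations of channels on a common grid.

    Zero-variance channels get NaN off-diagonal entries and are listed in
    ``degenerate``; the diagonal is exactly 1 regardless.
    """
    labels = list(channels)
    if len(labels) < 1:
        raise ValueError("need at least one channel")
    n = len(channels[labels[0]])
    for lab in labels:
        if len(channels[lab]) != n:
            raise ValueError("channels must share a common grid (equal lengths)")
    if n < 3:
        raise DataError("need at least 3 common samples")
    X = np.vstack([channels[lab].values for lab in labels])
    sd = X.std(axis=1)
    degenerate = [lab for lab, s in zip(labels, sd) if s == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(X)
    np.fill_diagonal(mat, 1.0)
    return CorrelationTable(labels=labels, matrix=mat, degenerate=degenerate)


@dataclass
class DensityDiagnostic:
    """Histogram + normality screen of one channel's marginal distribution.

    The check is reporting-only: the downstream complexity analysis assumes
    approximate normality, and this diagnostic quantifies how reasonable
    that assumption is without ever gating the pipeline.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    statistic: float
    pvalue: float
    test: str = "dagostino-pearson"
    degenerate: bool = False

    def to_json_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "counts": self.counts.tolist(),
            "mean": self.mean,
            "sd": self.sd,
            "statistic": None if not np.isfinite(self.statistic) else self.statistic,
            "pvalue": None if not np.isfinite(self.pvalue) else self.pvalue,
            "test": self.test,
            "degenerate": self.degenerate,
        }


def density_diagnostic(values: np.ndarray, bins: int = 60) -> DensityDiagnostic:
    """Histogram (default 60 bins), fitted normal parameters, and a
    D'Agostino-Pearson normality statistic with p-value."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 8:
        raise DataError("need at least 8 finite values")
    if np.ptp(values) == 0.0:
        edges = np.linspace(values[0] - 0.5, values[0] + 0.5, bins + 1)
        counts, _ = np.histogram(values, bins=edges)
        return DensityDiagnostic(
            bin_edges=edges,
            counts=counts,
            mean=float(values[0]),
            sd=0.0,
            statistic=float("nan"),
            pvalue=float("nan"),
            degenerate=True,
        )
    counts, edges = np.histogram(values, bins=bins)
    stat, p = stats.normaltest(values)
    return DensityDiagnostic(
        bin_edges=edges,
        counts=counts,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        statistic=float(stat),
        pvalue=float(p),
    )
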
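"""Reef temperature regimes: climatology, diurnal band-pass, daily ranges.

In situ logger records (15-30 min cadence) are summarized per site as
weekly climatology, a zero-phase Butterworth band-pass isolating sub-daily
(roughly 5-36 h) variability, the distribution of daily ranges (max - min of
the filtered series per calendar day), and an annual warm-tail metric (mean
across years of each year's 90th-percentile temperature).  These are the
metrics that distinguish Palau's warm, variable Rock Island bays from its
cooler outer reefs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "TemperatureSeries",
    "FilterSpec",
    "RegimeSummary",
    "weekly_average",
    "bandpass_diurnal",
    "daily_range",
    "regime_summary",
]


@dataclass(frozen=True)
class TemperatureSeries:
    """Timestamped logger record for one site.

    ``data`` is a pandas Series of temperature (degC) indexed by timestamp at a
    regular cadence; ``habitat`` distinguishes Rock Island from outer-reef
    sites.  Temperatures outside ``bounds`` are rejected as sensor errors.
    """

    site_id: str
    data: pd.Series = field(repr=False)
    habitat: str = "outer reef"
    bounds: tuple[float, float] = (20.0, 36.0)

    def __post_init__(self) -> None:
        s = self.data
        if not isinstance(s.index, pd.DatetimeIndex):
            raise ValueError("data must be indexed by timestamps")
        if len(s) < 2:
            raise ValueError("need at least 2 samples")
        if not s.index.is_monotonic_increasing or s.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        lo, hi = self.bounds
        finite = s.dropna()
        if ((finite < lo) | (finite > hi)).any():
            raise ValueError(f"temperatures outside plausible bounds {lo}-{hi} degC")

    @property
    def cadence(self) -> pd.Timedelta:
        """Modal sampling interval."""
        deltas = pd.Series(self.data.index).diff().dropna()
        return deltas.mode().iloc[0]

    @property
    def cadence_minutes(self) -> float:
        return self.cadence.total_seconds() / 60.0


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification for isolating sub-daily variability.

    Retains periods between ``short_cutoff`` and ``long_cutoff`` hours
    (defaults 5 and 36: long enough to keep the 24 h diurnal cycle at >99%
    amplitude, short enough to remove seasonal and weather-band variability),
    using a Butterworth filter of the given order applied forward-backward
    (zero phase) when ``zero_phase`` is set.
    """

    short_cutoff: float = 5.0
    long_cutoff: float = 36.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.short_cutoff < self.long_cutoff:
            raise ValueError("need 0 < short_cutoff < long_cutoff")
        if self.order < 1:
            raise ValueError("filter order must be a positive integer")


@dataclass(frozen=True)
class RegimeSummary:
    """Per-site thermal regime statistics (degC throughout)."""

    site_id: str
    mean: float
    sd: float
    mean_daily_range: float
    median_daily_range: float
    annual_p90: float | None
    coverage: float
    n_days: int

    def as_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "mean_c": self.mean,
            "sd_c": self.sd,
            "mean_daily_range_c": self.mean_daily_range,
            "median_daily_range_c": self.median_daily_range,
            "annual_p90_c": self.annual_p90,
            "coverage": self.coverage,
            "n_days": self.n_days,
        }


def weekly_average(series: TemperatureSeries, min_coverage: float = 0.5) -> pd.Series:
    """Mean temperature per ISO calendar week.

    Weeks with less than ``min_coverage`` of their expected samples are
    emitted as missing (NaN).  The result is indexed by the Monday of each
    ISO week.
    """
    s = series.data.dropna()
    if s.empty:
        raise ValueError("empty temperature series")
    expected = 7 * 24 * 60 / series.cadence_minutes
    iso = s.index.isocalendar()
    grouped = s.groupby([iso.year, iso.week])
    means = grouped.mean()
    counts = grouped.size()
    means[counts < min_coverage * expected] = np.nan
    idx = pd.DatetimeIndex(
        [
            pd.Timestamp.fromisocalendar(int(y), int(w), 1)
            for y, w in means.index
        ],
        name="week_start",
    )
    return pd.Series(means.to_numpy(), index=idx, name="temp_c")


def _segments(s: pd.Series, cadence: pd.Timedelta, max_gap: pd.Timedelta):
    """Split a series at gaps larger than ``max_gap``; interpolate smaller gaps
    onto the regular cadence grid."""
    s = s.dropna()
    gaps = pd.Series(s.index).diff()
    breakpoints = np.flatnonzero(gaps > max_gap)
    start = 0
    for bp in list(breakpoints) + [len(s)]:
        chunk = s.iloc[start:bp]
        start = bp
        if len(chunk) < 2:
            continue
        grid = pd.date_range(chunk.index[0], chunk.index[-1], freq=cadence)
        yield chunk.reindex(grid.union(chunk.index)).interpolate("time").reindex(grid)


def bandpass_diurnal(
    series: TemperatureSeries,
    spec: FilterSpec | None = None,
    max_gap_hours: float = 3.0,
) -> pd.Series:
    """Band-pass filtered temperature series retaining sub-daily variability.

    Gaps up to ``max_gap_hours`` are linearly interpolated; longer gaps split
    the record into segments filtered independently.  Segments shorter than
    three times the long cutoff are skipped with a warning (filter transients
    would dominate them).  The output is near zero-mean by construction.
    """
    spec = spec or FilterSpec()
    cadence = series.cadence
    fs = 3600.0 / cadence.total_seconds()  # samples per hour
    nyquist = fs / 2.0
    wn = [1.0 / spec.long_cutoff / nyquist, 1.0 / spec.short_cutoff / nyquist]
    if wn[1] >= 1.0:
        raise ValueError("short_cutoff is below the Nyquist period of the record")
    sos = signal.butter(spec.order, wn, btype="bandpass", output="sos")

    min_len = int(3 * spec.long_cutoff * fs)
    pieces = []
    for seg in _segments(series.data, cadence, pd.Timedelta(hours=max_gap_hours)):
        if len(seg) < max(min_len, 3 * (2 * spec.order + 1)):
            warnings.warn(
                f"site {series.site_id}: segment of {len(seg)} samples shorter than "
                f"3x long_cutoff; skipped",
                stacklevel=2,
            )
            continue
        x = seg.to_numpy(dtype=float)
        if spec.zero_phase:
            y = signal.sosfiltfilt(sos, x)
        else:
            y = signal.sosfilt(sos, x)
        pieces.append(pd.Series(y, index=seg.index))
    if not pieces:
        raise ValueError(f"site {series.site_id}: no segment long enough to filter")
    return pd.concat(pieces).sort_index()


def daily_range(filtered: pd.Series, min_coverage: float = 0.8) -> pd.Series:
    """Daily max - min of a (filtered) series, one value per calendar day.

    Days with fewer than ``min_coverage`` of the expected samples (inferred
    from the modal cadence) are dropped.
    """
    if filtered.empty:
        return pd.Series(dtype=float)
    cadence = pd.Series(filtered.index).diff().dropna().mode().iloc[0]
    expected = pd.Timedelta(days=1) / cadence
    by_day = filtered.groupby(filtered.index.normalize())
    rng = by_day.max() - by_day.min()
    counts = by_day.size()
    return rng[counts >= min_coverage * expected].rename("daily_range_c")


def regime_summary(
    series: TemperatureSeries,
    spec: FilterSpec | None = None,
) -> RegimeSummary:
    """Full per-site regime summary.

    Mean and SD of the raw record; mean/median daily range of the band-passed
    record; warm-tail metric = each calendar year's 90th percentile of raw
    temperature (linear interpolation between order statistics), averaged
    across years with at least ~11 months of data.  Records spanning less
    than one full year omit the warm-tail metric (None) with a warning.
    """
    raw = series.data.dropna()
    if raw.empty:
        raise ValueError("empty temperature series")
    filt = bandpass_diurnal(series, spec)
    ranges = daily_range(filt)

    expected_per_year = pd.Timedelta(days=340) / series.cadence
    by_year = raw.groupby(raw.index.year)
    p90s = [
        float(np.percentile(vals.to_numpy(), 90.0))
        for _, vals in by_year
        if len(vals) >= expected_per_year
    ]
    if p90s:
        annual_p90 = float(np.mean(p90s))
    else:
        annual_p90 = None
        warnings.warn(
            f"site {series.site_id}: less than one full year of data; "
            "annual warm-tail metric omitted",
            stacklevel=2,
        )

    span = series.data.index[-1] - series.data.index[0]
    coverage = len(raw) / max(1.0, (span / series.cadence) + 1)
    return RegimeSummary(
        site_id=series.site_id,
        mean=float(raw.mean()),
        sd=float(raw.std(ddof=0)),
        mean_daily_range=float(ranges.mean()) if len(ranges) else float("nan"),
        median_daily_range=float(ranges.median()) if len(ranges) else float("nan"),
        annual_p90=annual_p90,
        coverage=float(min(coverage, 1.0)),
        n_days=int(len(ranges)),
    )
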
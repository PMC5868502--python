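"""Supraclavicular temperature time-series extraction and outcome measures.

Per frame, the supraclavicular statistic T_SCR is the median of the hottest
10% of pixels inside the ROI (equivalently the 95th percentile), and the
sternal reference statistic is the mean over the reference circle.  Series
are smoothed with a centered period-5 moving average, and the outcome
measures are

* base T_SCR — mean of the smoothed series over the first minute of
  stimulation,
* peak T_SCR — maximum of the smoothed series within a requested window
  (the first 10 min of cooling for the 10-minute delta, or the initial and
  final periods combined),
* ΔT_SCR = peak − base,

each computed on the absolute series and on the series relative to the
sternal reference (relative = hotspot − reference, subtracted per frame
before smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, SeriesError
from .radiometric import TemperatureFrame
from .roi import ReferenceRegion, RoiMask

__all__ = [
    "TemperatureSeries",
    "OutcomeSet",
    "hotspot_statistic",
    "hotspot_selection",
    "reference_statistic",
    "extract_series",
    "smooth_series",
    "relative_series",
    "compute_outcomes",
]


@dataclass
class TemperatureSeries:
    """An ordered (timestamp s, value °C) series for one side and kind."""

    timestamps: np.ndarray
    values: np.ndarray
    side: str = ""
    kind: str = "absolute"  # "absolute" | "relative"
    period: str = ""

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape or self.timestamps.ndim != 1:
            raise SeriesError("timestamps and values must be matching 1-D arrays")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise SeriesError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class OutcomeSet:
    """Base/peak/Δ temperatures for one side, kind and peak window."""

    base: float
    peak: float
    delta: float
    side: str
    kind: str
    window: str  # "initial" | "initial+final"

    def __post_init__(self):
        if not np.isclose(self.delta, self.peak - self.base, atol=1e-12):
            raise SeriesError("delta must equal peak - base")


def hotspot_selection(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Select the hottest 10% of values and return (selected indices, median).

    k = ceil(0.1 * N); ties at the cutoff are broken by a stable descending
    sort, i.e. by position in the flattened scan order.  The median is the
    mean of the two middle selected values for even k.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n == 0:
        raise GeometryError("cannot take hotspot statistic of an empty region")
    k = int(np.ceil(0.1 * n))
    order = np.argsort(-values, kind="stable")
    selected = order[:k]
    return selected, float(np.median(values[selected]))


def hotspot_statistic(frame: TemperatureFrame, roi: RoiMask) -> float:
    """Median of the hottest 10% of ROI pixels (≈ 95th percentile), in °C."""
    values = frame.temp_c[roi.mask]
    if values.size == 0:
        raise GeometryError("empty ROI")
    _, med = hotspot_selection(values)
    return med


def reference_statistic(
    frame: TemperatureFrame, ref: ReferenceRegion, statistic: str = "mean"
) -> float:
    """Summary temperature of the sternal reference circle (mean by default)."""
    values = frame.temp_c[ref.mask]
    if values.size == 0:
        raise GeometryError("empty reference region")
    if statistic == "mean":
        return float(values.mean())
    if statistic == "median":
        return float(np.median(values))
    raise ValueError(f"unknown reference statistic {statistic!r}")


def extract_series(
    frames,
    roi: RoiMask,
    ref: ReferenceRegion | None = None,
    side: str = "",
    period: str = "",
) -> tuple[TemperatureSeries, TemperatureSeries | None]:
    """Per-frame (hotspot, reference) series over a frame sequence."""
    ts, hot, refv = [], [], []
    for frame in frames:
        ts.append(frame.timestamp)
        hot.append(hotspot_statistic(frame, roi))
        if ref is not None:
            refv.append(reference_statistic(frame, ref))
    hot_series = TemperatureSeries(np.array(ts), np.array(hot), side=side, kind="absolute", period=period)
    ref_series = (
        TemperatureSeries(np.array(ts), np.array(refv), side="sternal", kind="absolute", period=period)
        if ref is not None
        else None
    )
    return hot_series, ref_series


def smooth_series(series: TemperatureSeries, period: int = 5) -> TemperatureSeries:
    """Centered moving average, valid mode (length shrinks by period − 1).

    Output timestamps are those of the window centers, so an odd ``period``
    keeps timestamps on the original sampling grid.
    """
    n = len(series)
    if n < period:
        raise SeriesError(f"series of length {n} is shorter than smoothing period {period}")
    kernel = np.full(period, 1.0 / period)
    values = np.convolve(series.values, kernel, mode="valid")
    offset = (period - 1) // 2
    timestamps = series.timestamps[offset : offset + len(values)]
    return TemperatureSeries(timestamps, values, side=series.side, kind=series.kind, period=series.period)


def relative_series(hotspot: TemperatureSeries, reference: TemperatureSeries) -> TemperatureSeries:
    """Pointwise hotspot − reference (computed per frame, before smoothing)."""
    if len(hotspot) != len(reference) or not np.array_equal(hotspot.timestamps, reference.timestamps):
        raise SeriesError("hotspot and reference series must share identical timestamps")
    return TemperatureSeries(
        hotspot.timestamps,
        hotspot.values - reference.values,
        side=hotspot.side,
        kind="relative",
        period=hotspot.period,
    )


def compute_outcomes(
    series: TemperatureSeries,
    onset_s: float,
    base_window_s: float = 60.0,
    peak_window: str = "initial",
    peak_end_s: float = 600.0,
) -> OutcomeSet:
    """Base/peak/Δ outcomes from a smoothed series.

    Windows are half-open [start, end): base over [onset, onset + 60 s);
    peak over [onset, onset + 600 s) for ``peak_window="initial"`` or over
    [onset, ∞) for ``peak_window="initial+final"`` (initial and final
    imaging periods combined).
    """
    t = series.timestamps
    base_sel = (t >= onset_s) & (t < onset_s + base_window_s)
    if not base_sel.any():
        raise SeriesError(f"empty base window [{onset_s}, {onset_s + base_window_s})")
    base = float(series.values[base_sel].mean())
    if peak_window == "initial":
        peak_sel = (t >= onset_s) & (t < onset_s + peak_end_s)
    elif peak_window == "initial+final":
        peak_sel = t >= onset_s
    else:
        raise ValueError(f"unknown peak window {peak_window!r}")
    if not peak_sel.any():
        raise SeriesError(f"empty peak window for {peak_window!r}")
    peak = float(series.values[peak_sel].max())
    return OutcomeSet(base=base, peak=peak, delta=peak - base,
                      side=series.side, kind=series.kind, window=peak_window)
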
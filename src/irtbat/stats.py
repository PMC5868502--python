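"""Hotspot spatial overlap and cohort-level statistics.

The spatial agreement between the thermal hotspot (warped into the MIP
frame) and the glucose-uptake hotspot is the percentage of MIP-hotspot
pixels the two masks share.  Cohort summaries are mean ± SEM, squared
Pearson correlations with t-distribution p-values, and paired two-sided
t-tests between the cooling and vehicle (no-cooling) sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import GeometryError, StatsError

__all__ = [
    "HotspotPair",
    "SubjectRecord",
    "spatial_overlap",
    "mean_sem",
    "pearson_r2",
    "paired_comparison",
    "build_results_tables",
]


@dataclass
class HotspotPair:
    """TI hotspot mask (warped to the MIP frame) and the MIP hotspot mask."""

    ti_mask: np.ndarray
    mip_mask: np.ndarray

    def __post_init__(self):
        self.ti_mask = np.asarray(self.ti_mask, dtype=bool)
        self.mip_mask = np.asarray(self.mip_mask, dtype=bool)
        if self.ti_mask.shape != self.mip_mask.shape:
            raise GeometryError("hotspot masks must share the MIP frame dimensions")
        if not (self.ti_mask.any() and self.mip_mask.any()):
            raise GeometryError("hotspot masks must be nonempty")

    @property
    def overlap_percent(self) -> float:
        return spatial_overlap(self.ti_mask, self.mip_mask)


@dataclass
class SubjectRecord:
    """One subject-session row of the comparison study."""

    subject: str
    session: str  # "cold" | "vehicle"
    overlap_percent: float | None = None
    outcomes: dict = field(default_factory=dict)  # (side, kind) -> OutcomeSet-like mapping
    mrgluc_mip_median: float | None = None
    mrgluc_bat: float | None = None  # regional kinetic estimate, externally supplied

    def __post_init__(self):
        if self.session not in ("cold", "vehicle"):
            raise ValueError(f"session must be 'cold' or 'vehicle', got {self.session!r}")
        if self.overlap_percent is not None and not (0.0 <= self.overlap_percent <= 100.0):
            raise ValueError(f"overlap must be a percentage in [0, 100], got {self.overlap_percent}")


def spatial_overlap(ti_mask: np.ndarray, mip_mask: np.ndarray, denominator: str = "mip") -> float:
    """Percentage overlap: 100 · |TI ∩ MIP| / |MIP hotspot|.

    Both hotspots select the same fraction of their ROI, so their pixel
    counts agree up to warping discretization; the MIP-hotspot count is the
    default fixed-frame denominator.  ``denominator="mean"`` uses the mean
    of the two counts instead (symmetric variant).
    """
    a = np.asarray(ti_mask, dtype=bool)
    b = np.asarray(mip_mask, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError("masks must share dimensions")
    if not a.any() or not b.any():
        raise GeometryError("overlap of an empty hotspot mask is undefined")
    common = np.logical_and(a, b).sum()
    if denominator == "mip":
        denom = b.sum()
    elif denominator == "mean":
        denom = 0.5 * (a.sum() + b.sum())
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    return 100.0 * float(common) / float(denom)


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sample SD with n−1, over √n)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise StatsError("mean_sem needs a non-empty 1-D vector")
    if v.size < 2:
        raise StatsError("SEM requires at least two values")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def pearson_r2(x, y) -> tuple[float, float]:
    """Squared Pearson correlation and two-sided p (t-distribution, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be matching 1-D vectors")
    if x.size < 3:
        raise StatsError("correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic**2), float(res.pvalue)


def paired_comparison(a, b, method: str = "ttest") -> float:
    """Two-sided paired comparison p-value (t-test default, Wilcoxon optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("paired samples must be matching 1-D vectors")
    if a.size < 2:
        raise StatsError("paired comparison requires n >= 2")
    diff = a - b
    if np.ptp(diff) == 0 and diff[0] == 0:
        raise StatsError("paired comparison degenerate: all differences are zero")
    if method == "ttest":
        return float(sps.ttest_rel(a, b).pvalue)
    if method == "wilcoxon":
        return float(sps.wilcoxon(a, b).pvalue)
    raise ValueError(f"unknown paired method {method!r}")


_OUTCOME_FIELDS = ("base", "peak_initial", "delta10", "peak_combined")


def _fmt(mean: float, sem: float, dp: int = 1) -> str:
    # round-half-up at dp decimals, as in the report tables
    q = 10.0**dp
    r = lambda v: np.floor(v * q + 0.5) / q
    return f"{r(mean):.{dp}f} ± {r(sem):.{dp}f}"


def build_results_tables(records: list[SubjectRecord]) -> dict[str, pd.DataFrame]:
    """Assemble the study's summary tables from per-subject records.

    Returns a dict of DataFrames:

    * ``outcomes`` — mean ± SEM of each thermal outcome, absolute and
      relative, cold vs vehicle, with the paired p-value (NA when fewer
      than two complete pairs exist);
    * ``overlap`` — per-subject overlap percentages with cold/vehicle
      means ± SEM;
    * ``correlations`` — r² grid of thermal outcomes against the MIP
      hotspot median and the regional kinetic estimate, per side.
    """
    if not records:
        raise StatsError("no subject records")
    df = pd.DataFrame(
        [
            {
                "subject": r.subject,
                "session": r.session,
                "overlap": r.overlap_percent,
                "mrgluc_mip": r.mrgluc_mip_median,
                "mrgluc_bat": r.mrgluc_bat,
                **{
                    f"{kind}_{side}_{fld}": r.outcomes.get((side, kind), {}).get(fld)
                    for side in ("left", "right")
                    for kind in ("absolute", "relative")
                    for fld in _OUTCOME_FIELDS
                },
            }
            for r in records
        ]
    )

    # --- outcomes table (cold vs vehicle, paired across subjects) -----------
    rows = []
    for kind in ("absolute", "relative"):
        for fld in _OUTCOME_FIELDS:
            col = f"{kind}_right_{fld}"
            wide = df.pivot_table(index="subject", columns="session", values=col, aggfunc="first")
            row = {"kind": kind, "outcome": fld}
            for session in ("cold", "vehicle"):
                vals = wide[session].dropna().to_numpy() if session in wide else np.array([])
                row[session] = _fmt(*mean_sem(vals)) if len(vals) >= 2 else "NA"
            paired = wide.dropna() if {"cold", "vehicle"} <= set(wide.columns) else pd.DataFrame()
            try:
                row["p"] = (
                    paired_comparison(paired["cold"].to_numpy(), paired["vehicle"].to_numpy())
                    if len(paired) >= 2
                    else np.nan
                )
            except StatsError:
                row["p"] = np.nan
            rows.append(row)
    outcomes = pd.DataFrame(rows)

    # --- overlap table -------------------------------------------------------
    overlap_wide = df.pivot_table(index="subject", columns="session", values="overlap", aggfunc="first")
    overlap = overlap_wide.reset_index()
    summary = {"subject": []}
    for session in ("cold", "vehicle"):
        vals = overlap_wide[session].dropna().to_numpy() if session in overlap_wide else np.array([])
        summary[session] = [_fmt(*mean_sem(vals))] if len(vals) >= 2 else ["NA"]
    summary["subject"] = ["mean ± SEM"]
    overlap = pd.concat([overlap, pd.DataFrame(summary)], ignore_index=True)

    # --- correlation grid (cold sessions) ------------------------------------
    cold = df[df["session"] == "cold"]
    corr_rows = []
    for pet_var in ("mrgluc_mip", "mrgluc_bat"):
        for side in ("left", "right"):
            for fld in ("base", "peak_initial", "delta10"):
                col = f"relative_{side}_{fld}"
                sub = cold[[col, pet_var]].dropna()
                if len(sub) >= 3 and np.ptp(sub[col]) > 0 and np.ptp(sub[pet_var]) > 0:
                    r2, p = pearson_r2(sub[col].to_numpy(), sub[pet_var].to_numpy())
                else:
                    r2, p = np.nan, np.nan
                corr_rows.append({"pet_outcome": pet_var, "side": side,
                                  "irt_outcome": fld, "r2": r2, "p": p})
    correlations = pd.DataFrame(corr_rows)

    return {"outcomes": outcomes, "overlap": overlap, "correlations": correlations}
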
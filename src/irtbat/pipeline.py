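"""End-to-end analysis: frames → ROI series → outcomes → PET comparison.

``analyze_session`` runs the thermal side for one subject-session:
contour-based ROI construction on a baseline composite, per-frame hotspot
and reference extraction, smoothing, and the base/peak/Δ outcome set per
side, absolute and relative.  ``compare_with_pet`` fits the locally
weighted mean transform from control points, warps the ROI and the thermal
hotspot into the MIP frame and computes the uptake hotspot and the spatial
overlap.  ``run_cohort`` maps both over a cohort bundle and assembles the
study tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lwm import ControlPointPairs, fit_lwm, warp_image, warp_polygon
from .mip import ScalarVolume, mip, mip_hotspot
from .registration import mean_composite
from .roi import ApexSet, ContourParams, build_reference_region, build_roi_mask, detect_neck_contour, rasterize_polygon
from .stats import SubjectRecord, build_results_tables, spatial_overlap
from .timeseries import (
    TemperatureSeries,
    compute_outcomes,
    extract_series,
    hotspot_selection,
    relative_series,
    smooth_series,
)

__all__ = ["SessionResult", "analyze_session", "compare_with_pet", "run_cohort",
           "cohort_outcome_frame"]

OUTCOME_COLUMNS = [
    "subject", "session", "side", "kind", "base", "peak_initial", "delta10",
    "peak_combined", "mean_last_minute_initial", "mean_last_minute_final",
]


@dataclass
class SessionResult:
    """Thermal outcomes and artifacts of one analyzed session."""

    outcomes: dict  # (side, kind) -> dict of outcome fields
    roi_masks: dict  # side -> RoiMask
    ti_hotspot_mask: np.ndarray  # right-ROI hotspot on the comparison composite
    composite: object  # TemperatureFrame
    series: dict  # (side, kind) -> smoothed TemperatureSeries


def _window_mean(series: TemperatureSeries, start: float, end: float) -> float:
    sel = (series.timestamps >= start) & (series.timestamps < end)
    return float(series.values[sel].mean()) if sel.any() else float("nan")


def analyze_session(
    frames,
    periods,
    apices: ApexSet,
    onset_s: float,
    contour_params: ContourParams = ContourParams(),
    reference_offset_px: float = 10.0,
    smoothing_period: int = 5,
) -> SessionResult:
    """Full thermal analysis of one frame sequence.

    The ROI contours are detected once, on a baseline composite (mean of
    the last three acclimatization frames, falling back to the first
    frame), and reused for every frame; apices are labeled per sequence.
    """
    frames = list(frames)
    shape = frames[0].temp_c.shape
    acc = [f for f, p in zip(frames, periods) if p == "acclimatization"]
    baseline = mean_composite(acc) if len(acc) >= 3 else frames[0]

    roi_masks, ref = {}, build_reference_region(apices, shape, offset_px=reference_offset_px)
    for side in ("left", "right"):
        contour = detect_neck_contour(baseline, apices, side, contour_params)
        roi_masks[side] = build_roi_mask(apices, contour, shape)

    stim = [(f, p) for f, p in zip(frames, periods) if p in ("initial", "final")]
    stim_frames = [f for f, _ in stim]
    initial_frames = [f for f, p in stim if p == "initial"]
    final_frames = [f for f, p in stim if p == "final"]

    outcomes, series_out = {}, {}
    for side in ("left", "right"):
        hot, refs = extract_series(stim_frames, roi_masks[side], ref, side=side)
        for kind in ("absolute", "relative"):
            raw = hot if kind == "absolute" else relative_series(hot, refs)
            sm = smooth_series(raw, period=smoothing_period)
            out_initial = compute_outcomes(sm, onset_s=onset_s, peak_window="initial")
            out_combined = compute_outcomes(sm, onset_s=onset_s, peak_window="initial+final")
            t_ini_end = onset_s + 600.0
            entry = {
                "base": out_initial.base,
                "peak_initial": out_initial.peak,
                "delta10": out_initial.delta,
                "peak_combined": out_combined.peak,
                "mean_last_minute_initial": _window_mean(sm, t_ini_end - 60.0, t_ini_end),
            }
            if final_frames:
                t_fin_end = final_frames[-1].timestamp + 1e-9
                entry["mean_last_minute_final"] = _window_mean(sm, t_fin_end - 60.0, t_fin_end)
            else:
                entry["mean_last_minute_final"] = float("nan")
            outcomes[(side, kind)] = entry
            series_out[(side, kind)] = sm

    composite = mean_composite(initial_frames)
    roi_r = roi_masks["right"]
    flat = np.flatnonzero(roi_r.mask.ravel())
    sel, _ = hotspot_selection(composite.temp_c[roi_r.mask])
    ti_mask = np.zeros(shape, dtype=bool)
    ti_mask.ravel()[flat[sel]] = True

    return SessionResult(outcomes=outcomes, roi_masks=roi_masks,
                         ti_hotspot_mask=ti_mask, composite=composite, series=series_out)


def compare_with_pet(
    session: SessionResult,
    mrgluc: ScalarVolume,
    pairs: ControlPointPairs,
    n_neighbors: int = 16,
) -> dict:
    """Warp the thermal hotspot onto the MR(gluc) MIP and measure overlap.

    Returns a dict with the MIP hotspot median, the overlap percentage and
    the masks involved.
    """
    gluc_mip = mip(mrgluc)
    forward = fit_lwm(pairs, n_neighbors=n_neighbors, direction="moving_to_fixed")
    inverse = fit_lwm(pairs, n_neighbors=n_neighbors, direction="fixed_to_moving")

    roi_poly_mip = warp_polygon(forward, session.roi_masks["right"].polygon)
    roi_mip_mask = rasterize_polygon(roi_poly_mip, gluc_mip.shape)
    mip_mask, mip_median = mip_hotspot(gluc_mip, roi_mip_mask)

    warped_ti, _ = warp_image(session.ti_hotspot_mask, inverse, gluc_mip.shape,
                              interpolation="nearest")
    overlap = spatial_overlap(warped_ti, mip_mask)
    return {
        "mip_hotspot_median": mip_median,
        "overlap_percent": overlap,
        "mip_hotspot_mask": mip_mask,
        "warped_ti_mask": warped_ti,
        "roi_mip_mask": roi_mip_mask,
    }


def run_cohort(bundle, compare_sessions: tuple = ("cold", "vehicle")) -> dict:
    """Analyze every subject-session of a cohort bundle.

    Returns {"records": [SubjectRecord...], "tables": {...},
    "outcome_frame": DataFrame} with one record per subject-session.
    """
    records = []
    for subj in bundle.subjects:
        for session_name, sb in subj.sessions.items():
            seq = sb.thermal()
            result = analyze_session(
                seq.frames, seq.periods, seq.apices, onset_s=sb.spec.acclimatization_s,
                reference_offset_px=sb.spec.reference_offset_px,
            )
            rec = SubjectRecord(
                subject=subj.subject_id, session=session_name,
                outcomes=result.outcomes, mrgluc_bat=subj.mrgluc_bat,
            )
            if session_name in compare_sessions:
                pet = sb.pet()
                cmp = compare_with_pet(result, pet.mrgluc, sb.control_points)
                rec.overlap_percent = cmp["overlap_percent"]
                rec.mrgluc_mip_median = cmp["mip_hotspot_median"]
            records.append(rec)
    tables = build_results_tables(records)
    return {"records": records, "tables": tables,
            "outcome_frame": cohort_outcome_frame(records)}


def cohort_outcome_frame(records) -> pd.DataFrame:
    """Long-format per-session outcome table (one row per side × kind)."""
    rows = []
    for r in records:
        for (side, kind), entry in sorted(r.outcomes.items()):
            rows.append({"subject": r.subject, "session": r.session, "side": side,
                         "kind": kind, **entry})
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)
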
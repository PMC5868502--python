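"""Synthetic thermography/PET phantom generator with recorded ground truth.

Every pipeline stage is validated against phantoms whose true geometry,
kinetics and cross-modal warp are known in closed form:

* a thermal frame sequence at 5-s intervals over three imaging periods
  (acclimatization, the first 10 min of cooling, and a late period after
  prolonged stimulation), showing a torso/neck silhouette against a cooler
  background, a Gaussian supraclavicular warm blob per side whose amplitude
  follows a saturating-exponential activation curve after cooling onset,
  and i.i.d. sensor noise — encoded to radiometric counts and back so the
  full conversion path is exercised;
* the five ROI apices and the true neck-edge path;
* a paired PET study: an MR(gluc) uptake volume with 3-D Gaussian blobs
  colocalized (through the true warp) with the thermal blobs, plus a crude
  CT attenuation volume;
* a global degree-2 polynomial warp from thermal to MIP coordinates and 70
  jittered control-point pairs sampled from it (degree 2 makes the locally
  weighted mean fit provably exact at zero jitter);
* per-subject cohorts pairing a cooling and a vehicle session, with the
  PET amplitude coupled to the thermal activation amplitude so the
  expected cross-modal correlation is controlled by ``effect_size``.

All randomness flows from a single seed through ``numpy`` SeedSequences;
identical spec + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GeometryError
from .lwm import ControlPointPairs
from .mip import ScalarVolume, mip, mip_hotspot
from .radiometric import (
    DEFAULT_CALIBRATION,
    CalibrationConstants,
    TemperatureFrame,
    counts_to_temperature,
    temperature_to_counts,
)
from .roi import ApexSet, NeckContour, build_reference_region, build_roi_mask, rasterize_polygon
from .timeseries import (
    TemperatureSeries,
    compute_outcomes,
    hotspot_selection,
    relative_series,
    smooth_series,
)

__all__ = [
    "PhantomSpec",
    "ThermalSequence",
    "PetStudy",
    "SessionBundle",
    "SubjectBundle",
    "CohortBundle",
    "poly2_eval",
    "make_warp",
    "generate_thermal_sequence",
    "generate_pet_volume",
    "generate_control_points",
    "generate_cohort",
    "write_study",
]


# --------------------------------------------------------------------------
# spec
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """All knobs of the synthetic study; defaults are the study conditions.

    Temperatures in °C, times in seconds, lengths in pixels.  The thermal
    activation curve is A(t) = A0 + ΔT_max·(1 − e^{−(t−onset)/τ}) from
    cooling onset; vehicle sessions use ``vehicle_delta_t_max_c`` instead
    of ``delta_t_max_c``.
    """

    # thermal frame geometry and timing
    shape: tuple[int, int] = (120, 160)  # rows, cols
    frame_interval_s: float = 5.0
    acclimatization_s: float = 120.0
    initial_s: float = 600.0
    final_s: float = 180.0
    final_offset_s: float = 3000.0  # final period starts this long after onset

    # scene
    background_c: float = 22.0
    skin_c: float = 33.5
    cx: float = 80.0
    neck_top_row: float = 10.0
    shoulder_row: float = 50.0
    neck_halfwidth_px: float = 18.0
    neck_slope: float = 0.25  # widening per row
    neck_bow_px: float = 2.0  # lateral bow of the neck edge (0 = straight)
    torso_halfwidth_px: float = 60.0
    edge_blur_px: float = 1.0

    # apices / reference
    y_superolateral: float = 14.0
    y_acromioclavicular: float = 48.0
    sternal_y: float = 54.0
    reference_offset_px: float = 10.0

    # supraclavicular blobs and activation kinetics
    blob_sigma_px: float = 6.0
    blob_baseline_c: float = 2.0  # A0: baseline warmth of the fossa over skin
    delta_t_max_c: float = 0.3
    tau_s: float = 120.0
    vehicle_delta_t_max_c: float = 0.05
    noise_c: float = 0.05
    calibration: CalibrationConstants = field(default_factory=lambda: DEFAULT_CALIBRATION)

    # PET side
    pet_shape: tuple[int, int, int] = (100, 128, 32)  # rows, cols, z
    pet_spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    pet_background: float = 0.5
    pet_gain: float = 20.0  # uptake amplitude per °C of thermal activation
    pet_amplitude: float = 6.0  # used when not coupled through a cohort
    pet_vehicle_amplitude: float = 0.0
    pet_blob_sigma_px: float = 5.0
    pet_blob_sigma_z: float = 3.0
    pet_noise: float = 0.08
    pet_noise_smooth_px: float = 2.0
    colocalization_jitter_px: float = 1.5

    # warp and control points
    warp_scale: float = 0.8
    warp_rotation_deg: float = 2.0
    warp_translation: tuple[float, float] = (2.0, 5.0)
    warp_quad_amp: float = 1.0e-4
    n_control_points: int = 70
    control_jitter_px: float = 0.5

    session: str = "cold"
    seed: int = 0

    # ---- geometry helpers -------------------------------------------------

    def halfwidth(self, y) -> np.ndarray:
        """Lateral half-width of the silhouette at row y (above the shoulder)."""
        y = np.asarray(y, dtype=float)
        w = self.neck_halfwidth_px + self.neck_slope * np.maximum(0.0, y - self.neck_top_row)
        span = self.shoulder_row - self.neck_top_row
        s = np.clip((y - self.neck_top_row) / span, 0.0, 1.0)
        return w + self.neck_bow_px * 4.0 * s * (1.0 - s)

    def silhouette(self) -> np.ndarray:
        rows, cols = self.shape
        yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
        neck = (yy < self.shoulder_row) & (np.abs(xx - self.cx) <= self.halfwidth(yy))
        torso = (yy >= self.shoulder_row) & (np.abs(xx - self.cx) <= self.torso_halfwidth_px)
        return neck | torso

    def static_field(self) -> np.ndarray:
        """Noiseless skin/background temperature field, optics-blurred."""
        body = gaussian_filter(self.silhouette().astype(float), self.edge_blur_px)
        return self.background_c + body * (self.skin_c - self.background_c)

    def blob_center(self, side: str) -> tuple[float, float]:
        sign = -1.0 if side == "left" else 1.0
        return (self.cx + sign * 15.0, 39.0)

    def blob_basis(self, side: str) -> np.ndarray:
        """Unit-amplitude Gaussian blob temperature pattern for one side."""
        cx, cy = self.blob_center(side)
        if not self.silhouette()[int(round(cy)), int(round(cx))]:
            raise GeometryError(f"{side} blob center ({cx}, {cy}) lies outside the silhouette")
        rows, cols = self.shape
        yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
        return np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * self.blob_sigma_px**2)))

    def apices(self) -> ApexSet:
        hw_sup = float(self.halfwidth(self.y_superolateral))
        hw_acr = float(self.halfwidth(self.y_acromioclavicular))
        return ApexSet(
            superolateral_left=(self.cx - hw_sup, self.y_superolateral),
            superolateral_right=(self.cx + hw_sup, self.y_superolateral),
            acromioclavicular_left=(self.cx - hw_acr, self.y_acromioclavicular),
            acromioclavicular_right=(self.cx + hw_acr, self.y_acromioclavicular),
            sternal=(self.cx, self.sternal_y),
            frame_shape=self.shape,
        )

    def true_contour(self, side: str) -> NeckContour:
        ys = np.arange(int(round(self.y_superolateral)), int(round(self.y_acromioclavicular)) + 1)
        sign = -1.0 if side == "left" else 1.0
        xs = self.cx + sign * self.halfwidth(ys)
        return NeckContour(xs=xs, ys=ys, side=side)

    def timestamps(self) -> tuple[np.ndarray, list[str]]:
        """(timestamps, period labels) of every captured frame."""
        dt = self.frame_interval_s
        onset = self.acclimatization_s
        acc = np.arange(0.0, self.acclimatization_s, dt)
        ini = onset + np.arange(0.0, self.initial_s, dt)
        fin = onset + self.final_offset_s + np.arange(0.0, self.final_s, dt)
        ts = np.concatenate([acc, ini, fin])
        labels = ["acclimatization"] * len(acc) + ["initial"] * len(ini) + ["final"] * len(fin)
        return ts, labels

    def activation(self, t) -> np.ndarray:
        """Blob amplitude A(t) in °C for this spec's session."""
        t = np.asarray(t, dtype=float)
        onset = self.acclimatization_s
        dt_max = self.delta_t_max_c if self.session == "cold" else self.vehicle_delta_t_max_c
        rise = np.where(t >= onset, 1.0 - np.exp(-np.maximum(t - onset, 0.0) / self.tau_s), 0.0)
        return self.blob_baseline_c + dt_max * rise


# --------------------------------------------------------------------------
# thermal sequence
# --------------------------------------------------------------------------


@dataclass
class ThermalSequence:
    """Generated frame sequence plus annotations and session ground truth."""

    frames: list  # TemperatureFrame, after count quantization
    periods: list
    apices: ApexSet
    spec: PhantomSpec
    truth: dict


def _quantize(temp: TemperatureFrame, calibration: CalibrationConstants) -> TemperatureFrame:
    return counts_to_temperature(temperature_to_counts(temp, calibration))


def _noiseless_truth(spec: PhantomSpec) -> dict:
    """Outcome ground truth from the noiseless field and true geometry."""
    ts, _ = spec.timestamps()
    static = spec.static_field()
    basis = spec.blob_basis("left") + spec.blob_basis("right")
    apices = spec.apices()
    roi = build_roi_mask(apices, spec.true_contour("right"), spec.shape)
    ref = build_reference_region(apices, spec.shape, offset_px=spec.reference_offset_px)
    amps = spec.activation(ts)

    static_roi = static[roi.mask]
    basis_roi = basis[roi.mask]
    static_ref = static[ref.mask]
    basis_ref = basis[ref.mask]
    hot = np.array([hotspot_selection(static_roi + a * basis_roi)[1] for a in amps])
    refv = np.array([(static_ref + a * basis_ref).mean() for a in amps])
    rel = smooth_series(TemperatureSeries(ts, hot - refv, side="right", kind="relative"))
    onset = spec.acclimatization_s
    out = compute_outcomes(rel, onset_s=onset, peak_window="initial")

    # true TI hotspot mask on the comparison composite (mean of the last 3
    # frames of the initial period)
    n_acc = int(spec.acclimatization_s / spec.frame_interval_s)
    n_ini = int(spec.initial_s / spec.frame_interval_s)
    comp_amp = float(amps[n_acc + n_ini - 3 : n_acc + n_ini].mean())
    comp_roi_vals = static_roi + comp_amp * basis_roi
    sel, _ = hotspot_selection(comp_roi_vals)
    ti_mask = np.zeros(spec.shape, dtype=bool)
    flat = np.flatnonzero(roi.mask.ravel())
    ti_mask.ravel()[flat[sel]] = True

    return {
        "onset_s": onset,
        "delta10_relative_right": out.delta,
        "base_relative_right": out.base,
        "peak_relative_right": out.peak,
        "activation_plateau_c": float(amps.max() - spec.blob_baseline_c),
        "blob_centers_ti": {s: spec.blob_center(s) for s in ("left", "right")},
        "neck_edge": {
            s: {"ys": spec.true_contour(s).ys.tolist(), "xs": spec.true_contour(s).xs.tolist()}
            for s in ("left", "right")
        },
        "roi_polygon_right": roi.polygon.tolist(),
        "ti_hotspot_mask": ti_mask,
    }


def generate_thermal_sequence(spec: PhantomSpec, seed=None) -> ThermalSequence:
    """Render the full frame sequence for one session.

    Frames are synthesized in temperature space, encoded to radiometric
    counts with the spec's calibration, and decoded again, so what the
    pipeline sees has passed through count quantization exactly as real
    converted frames would.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ts, periods = spec.timestamps()
    static = spec.static_field()
    basis = spec.blob_basis("left") + spec.blob_basis("right")
    amps = spec.activation(ts)
    frames = []
    for i, (t, a) in enumerate(zip(ts, amps)):
        field = static + a * basis
        if spec.noise_c > 0:
            field = field + rng.normal(0.0, spec.noise_c, size=spec.shape)
        frame = TemperatureFrame(temp_c=field, timestamp=float(t), frame_id=f"{spec.session}_{i:04d}")
        frames.append(_quantize(frame, spec.calibration))
    truth = _noiseless_truth(spec)
    return ThermalSequence(frames=frames, periods=periods, apices=spec.apices(), spec=spec, truth=truth)


# --------------------------------------------------------------------------
# warp and control points
# --------------------------------------------------------------------------


def poly2_eval(coeffs: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Evaluate a global degree-2 map (2×6 coeffs over [1,x,y,x²,xy,y²])."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    out = A @ np.asarray(coeffs, dtype=float).T
    return out[0] if np.asarray(points).ndim == 1 else out


def make_warp(spec: PhantomSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Random global degree-2 thermal→MIP warp around the spec's base affine."""
    rng = np.random.default_rng(0) if rng is None else rng
    theta = np.deg2rad(spec.warp_rotation_deg * rng.uniform(-1.0, 1.0))
    s = spec.warp_scale * (1.0 + rng.uniform(-0.05, 0.05))
    tx, ty = (spec.warp_translation[0] + rng.uniform(-2, 2),
              spec.warp_translation[1] + rng.uniform(-2, 2))
    c, sn = np.cos(theta), np.sin(theta)
    quad = rng.uniform(-spec.warp_quad_amp, spec.warp_quad_amp, size=(2, 3))
    coeffs = np.array([
        [tx, s * c, -s * sn, quad[0, 0], quad[0, 1], quad[0, 2]],
        [ty, s * sn, s * c, quad[1, 0], quad[1, 1], quad[1, 2]],
    ])
    return coeffs


def generate_control_points(
    spec: PhantomSpec,
    warp_coeffs: np.ndarray,
    seed=None,
    jitter_px: float | None = None,
) -> ControlPointPairs:
    """70 quasi-uniform supraclavicular pairs: fixed = warp(moving) + jitter."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    jitter = spec.control_jitter_px if jitter_px is None else jitter_px
    n = spec.n_control_points
    ncol = 10
    nrow = int(np.ceil(n / ncol))
    gx = np.linspace(spec.cx - 55.0, spec.cx + 55.0, ncol)
    gy = np.linspace(6.0, 70.0, nrow)
    xx, yy = np.meshgrid(gx, gy)
    moving = np.column_stack([xx.ravel(), yy.ravel()])[:n]
    moving = moving + rng.uniform(-2.0, 2.0, size=moving.shape)  # quasi-uniform
    fixed = poly2_eval(warp_coeffs, moving)
    if jitter > 0:
        fixed = fixed + rng.normal(0.0, jitter, size=fixed.shape)
    return ControlPointPairs(moving=moving, fixed=fixed)


# --------------------------------------------------------------------------
# PET volumes
# --------------------------------------------------------------------------


@dataclass
class PetStudy:
    """Generated PET pair (uptake + CT) with its ground truth."""

    mrgluc: ScalarVolume
    ct: ScalarVolume
    truth: dict


def generate_pet_volume(
    spec: PhantomSpec,
    warp_coeffs: np.ndarray,
    seed=None,
    amplitude: float | None = None,
) -> PetStudy:
    """Synthesize the MR(gluc) and CT volumes paired with a thermal session.

    Uptake blobs sit where the true warp sends the thermal blob centers
    (plus a small colocalization jitter); the cooling session's amplitude
    exceeds the vehicle session's.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows, cols, nz = spec.pet_shape
    if amplitude is None:
        amplitude = spec.pet_amplitude if spec.session == "cold" else spec.pet_vehicle_amplitude
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    zz = np.arange(nz, dtype=float)
    z_profile = np.exp(-((zz - nz / 2.0) ** 2) / (2.0 * spec.pet_blob_sigma_z**2))

    gluc = np.full((rows, cols, nz), spec.pet_background, dtype=float)
    centers_mip = {}
    for side in ("left", "right"):
        center = poly2_eval(warp_coeffs, np.array(spec.blob_center(side)))
        center = center + rng.normal(0.0, spec.colocalization_jitter_px, size=2)
        centers_mip[side] = tuple(float(v) for v in center)
        plane = np.exp(-(((xx - center[0]) ** 2 + (yy - center[1]) ** 2)
                         / (2.0 * spec.pet_blob_sigma_px**2)))
        gluc += amplitude * plane[:, :, None] * z_profile[None, None, :]
    if spec.pet_noise > 0:
        noise = rng.normal(0.0, 1.0, size=(rows, cols, nz))
        noise = gaussian_filter(noise, spec.pet_noise_smooth_px)
        noise *= spec.pet_noise / max(noise.std(), 1e-12)
        gluc = np.maximum(gluc + noise, 0.0)

    # crude CT: soft-tissue ellipsoid torso in air, two clavicle-like bars
    ct = np.full((rows, cols, nz), -1000.0, dtype=float)
    body = (((xx - cols / 2) / (cols * 0.45)) ** 2 + ((yy - rows * 0.6) / (rows * 0.55)) ** 2) <= 1.0
    ct[body, :] = 40.0
    clav = (np.abs(yy - rows * 0.45) < 2) & (np.abs(xx - cols / 2) > 8) & (np.abs(xx - cols / 2) < 45)
    ct[clav, nz // 2 - 2 : nz // 2 + 2] = 700.0

    sid = spec.session
    mr_vol = ScalarVolume(gluc, spacing_mm=spec.pet_spacing_mm, modality="MRgluc", volume_id=f"mrgluc_{sid}")
    ct_vol = ScalarVolume(ct, spacing_mm=spec.pet_spacing_mm, modality="CT", volume_id=f"ct_{sid}")
    truth = {"blob_centers_mip": centers_mip, "amplitude": float(amplitude),
             "background": spec.pet_background}
    return PetStudy(mrgluc=mr_vol, ct=ct_vol, truth=truth)


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------


@dataclass
class SessionBundle:
    """One subject-session: spec + seeds; frames/volumes generated on demand."""

    spec: PhantomSpec
    warp_coeffs: np.ndarray
    control_points: ControlPointPairs
    thermal_seed: int
    pet_seed: int
    pet_amplitude: float

    def thermal(self) -> ThermalSequence:
        return generate_thermal_sequence(self.spec, seed=self.thermal_seed)

    def pet(self) -> PetStudy:
        return generate_pet_volume(self.spec, self.warp_coeffs, seed=self.pet_seed,
                                   amplitude=self.pet_amplitude)


@dataclass
class SubjectBundle:
    subject_id: str
    sessions: dict  # "cold"/"vehicle" -> SessionBundle
    mrgluc_bat: float  # externally supplied regional kinetic estimate
    truth: dict


@dataclass
class CohortBundle:
    subjects: list
    seed: int
    effect_size: float

    def truth_json(self) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {k: clean(v) for k, v in o.items() if not isinstance(v, np.ndarray)}
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            return o

        return json.dumps(
            {s.subject_id: clean(s.truth) for s in self.subjects}, indent=1, sort_keys=True
        )


def _session_truth(spec: PhantomSpec, warp_coeffs: np.ndarray, pet: PetStudy) -> dict:
    """Combine thermal and PET ground truth, including the true overlap."""
    truth = _noiseless_truth(spec)
    truth["warp_coeffs"] = warp_coeffs.tolist()
    truth.update(pet.truth)
    mip_img = mip(pet.mrgluc)
    roi_mip_poly = poly2_eval(warp_coeffs, np.asarray(truth["roi_polygon_right"]))
    roi_mip_mask = rasterize_polygon(roi_mip_poly, mip_img.shape)
    mip_mask, mip_median = mip_hotspot(mip_img, roi_mip_mask)
    truth["mip_hotspot_median"] = mip_median
    truth["mip_hotspot_mask"] = mip_mask
    # forward-map the TI hotspot pixels and round onto the MIP grid
    ti_mask = truth["ti_hotspot_mask"]
    pts = np.argwhere(ti_mask)[:, ::-1].astype(float)  # (x, y)
    mapped = np.rint(poly2_eval(warp_coeffs, pts)).astype(int)
    warped = np.zeros(mip_img.shape, dtype=bool)
    inside = (
        (mapped[:, 0] >= 0) & (mapped[:, 0] < mip_img.shape[1])
        & (mapped[:, 1] >= 0) & (mapped[:, 1] < mip_img.shape[0])
    )
    warped[mapped[inside, 1], mapped[inside, 0]] = True
    common = (warped & mip_mask).sum()
    truth["overlap_percent"] = 100.0 * float(common) / float(mip_mask.sum())
    return truth


def generate_cohort(
    n_subjects: int = 8,
    effect_size: float = 1.0,
    seed: int = 0,
    spec: PhantomSpec | None = None,
) -> CohortBundle:
    """Build an n-subject cohort, each with a cooling and a vehicle session.

    Per subject the thermal activation plateau ΔT_max is drawn from
    N(0.3, 0.12²) °C (truncated at 0.05), and the cooling-session PET blob
    amplitude is ``pet_gain`` times a mixture that interpolates, with
    ``effect_size``, between a constant (no coupling, expected r² ≈ 0) and
    ΔT_max itself, plus measurement scatter.  Geometry and the true warp
    are shared between a subject's two sessions.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = PhantomSpec() if spec is None else spec
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n_subjects)
    subjects = []
    for i, sseq in enumerate(subject_seeds):
        rng = np.random.default_rng(sseq)
        seeds = rng.integers(0, 2**31 - 1, size=6)
        delta_t = float(max(0.05, rng.normal(0.3, 0.12)))
        coupled = 0.3 + effect_size * (delta_t - 0.3) + rng.normal(0.0, 0.03)
        pet_amp_cold = float(base.pet_gain * max(coupled, 0.05))
        mrgluc_bat = float(0.8 * pet_amp_cold + rng.normal(0.0, 0.3))
        warp_coeffs = make_warp(base, rng)
        sessions = {}
        truth = {"delta_t_max_c": delta_t, "pet_amplitude_cold": pet_amp_cold,
                 "mrgluc_bat": mrgluc_bat}
        for j, session in enumerate(("cold", "vehicle")):
            sp = dataclasses.replace(base, session=session, delta_t_max_c=delta_t,
                                     seed=int(seeds[2 * j]))
            pairs = generate_control_points(sp, warp_coeffs, seed=int(seeds[4]))
            amp = pet_amp_cold if session == "cold" else base.pet_vehicle_amplitude
            bundle = SessionBundle(
                spec=sp, warp_coeffs=warp_coeffs, control_points=pairs,
                thermal_seed=int(seeds[2 * j]), pet_seed=int(seeds[2 * j + 1]),
                pet_amplitude=amp,
            )
            truth[session] = _session_truth(sp, warp_coeffs, bundle.pet())
            sessions[session] = bundle
        subjects.append(
            SubjectBundle(subject_id=f"S{i + 1:02d}", sessions=sessions,
                          mrgluc_bat=mrgluc_bat, truth=truth)
        )
    return CohortBundle(subjects=subjects, seed=seed, effect_size=effect_size)


# --------------------------------------------------------------------------
# disk writer
# --------------------------------------------------------------------------


def write_study(bundle: CohortBundle, out_dir: str | Path) -> Path:
    """Write a study directory: frames, volumes, annotations, ground truth."""
    import pandas as pd
    import yaml

    from .lwm import write_control_points
    from .mip import save_volume
    from .radiometric import write_frame

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    apex_rows, subject_rows = [], []
    for subj in bundle.subjects:
        for session, sb in subj.sessions.items():
            sdir = out_dir / subj.subject_id / session
            fdir = sdir / "frames"
            fdir.mkdir(parents=True, exist_ok=True)
            seq = sb.thermal()
            manifest = []
            for frame, period in zip(seq.frames, seq.periods):
                raw = temperature_to_counts(frame, sb.spec.calibration)
                p = fdir / f"{frame.frame_id}.png"
                write_frame(raw, p)
                manifest.append({"frame_id": frame.frame_id, "path": f"frames/{p.name}",
                                 "timestamp_s": frame.timestamp, "period": period})
            pd.DataFrame(manifest).to_csv(sdir / "manifest.csv", index=False)
            for label in ("superolateral_left", "superolateral_right",
                          "acromioclavicular_left", "acromioclavicular_right", "sternal"):
                x, y = getattr(seq.apices, label)
                apex_rows.append({"frame_id": f"{subj.subject_id}/{session}", "label": label,
                                  "x": x, "y": y})
            write_control_points(sb.control_points, sdir / "control_points.csv")
            pet = sb.pet()
            save_volume(pet.mrgluc, sdir / "mrgluc.nii.gz")
            save_volume(pet.ct, sdir / "ct.nii.gz")
        subject_rows.append({"subject": subj.subject_id, "mrgluc_bat": subj.mrgluc_bat})
    pd.DataFrame(apex_rows).to_csv(out_dir / "apices.csv", index=False)
    pd.DataFrame(subject_rows).to_csv(out_dir / "subjects.csv", index=False)
    (out_dir / "ground_truth.json").write_text(bundle.truth_json())
    (out_dir / "study.yaml").write_text(yaml.safe_dump(
        {"seed": bundle.seed, "effect_size": bundle.effect_size,
         "n_subjects": len(bundle.subjects)}))
    return out_dir
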
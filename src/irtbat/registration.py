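"""Similarity-transform frame registration and difference-video rendering.

Sequential thermal frames drift slightly with subject motion.  Each frame
is registered to the baseline image with a similarity transform
(translation, rotation, scale) found by intensity-based minimization of
the mean-squared temperature difference, initialized by phase correlation
and refined on a two-level pyramid.  Registered frames are averaged in
triplets and rendered as baseline-relative difference images on a fixed
diverging colormap (white = unchanged, blue→black = cooling, red→yellow =
warming) for video assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation
from skimage.transform import SimilarityTransform as _SkSimilarity
from skimage.transform import rescale, warp

from .errors import RegistrationError, SeriesError
from .radiometric import TemperatureFrame

__all__ = [
    "SimilarityTransform",
    "register_to_baseline",
    "apply_transform",
    "temporal_average",
    "mean_composite",
    "render_difference_frame",
]


@dataclass(frozen=True)
class SimilarityTransform:
    """Forward similarity map from moving-frame to baseline coordinates.

    x_base = scale · R(rotation) · (x_mov − c) + c + (tx, ty), with the
    rotation applied about the image center c and angles in degrees.
    """

    tx: float
    ty: float
    rotation: float
    scale: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    def matrix(self) -> np.ndarray:
        """3×3 homogeneous forward matrix in (x, y) coordinates."""
        cx, cy = self.center
        to_origin = _SkSimilarity(translation=(-cx, -cy))
        core = _SkSimilarity(scale=self.scale, rotation=np.deg2rad(self.rotation))
        back = _SkSimilarity(translation=(cx + self.tx, cy + self.ty))
        return back.params @ core.params @ to_origin.params

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix())


def apply_transform(
    frame_values: np.ndarray, transform: SimilarityTransform, cval: float = np.nan
) -> np.ndarray:
    """Warp a 2-D array onto the baseline grid (bilinear; outside = ``cval``)."""
    inv = _SkSimilarity(matrix=transform.inverse_matrix())
    return warp(np.asarray(frame_values, dtype=float), inv, order=1,
                cval=cval, mode="constant", preserve_range=True)


def _mse(params, moving, baseline, center):
    tx, ty, rot, scale = params
    if scale <= 0.1:
        return 1e9
    t = SimilarityTransform(tx, ty, rot, scale, center=center)
    warped = apply_transform(moving, t)
    valid = np.isfinite(warped)
    if valid.mean() < 0.25:
        return 1e9
    d = warped[valid] - baseline[valid]
    return float(np.mean(d * d))


def register_to_baseline(
    frame: TemperatureFrame,
    baseline: TemperatureFrame,
    max_residual: float | None = None,
) -> SimilarityTransform:
    """Find the similarity transform aligning ``frame`` onto ``baseline``.

    Phase correlation provides the translation seed; Powell refinement of
    (tx, ty, θ, s) on half- then full-resolution MSE does the rest.

    Raises
    ------
    RegistrationError
        If the optimizer fails, or (when ``max_residual`` is set) the final
        RMS temperature residual exceeds it.
    """
    moving, fixed = frame.temp_c, baseline.temp_c
    if moving.shape != fixed.shape:
        raise SeriesError("frame and baseline must share dimensions")
    rows, cols = fixed.shape
    center = ((cols - 1) / 2.0, (rows - 1) / 2.0)

    shift, *_ = phase_cross_correlation(fixed, moving, normalization=None)
    x0 = np.array([shift[1], shift[0], 0.0, 1.0])

    for factor in (2, 1):
        if factor > 1:
            mv = rescale(moving, 1 / factor, anti_aliasing=True, preserve_range=True)
            fx = rescale(fixed, 1 / factor, anti_aliasing=True, preserve_range=True)
            ctr = ((fx.shape[1] - 1) / 2.0, (fx.shape[0] - 1) / 2.0)
            seed = np.array([x0[0] / factor, x0[1] / factor, x0[2], x0[3]])
        else:
            mv, fx, ctr, seed = moving, fixed, center, x0
        res = minimize(
            _mse, seed, args=(mv, fx, ctr), method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 400},
        )
        if not res.success:
            raise RegistrationError(
                f"registration did not converge: {res.message}", residual=float(np.sqrt(res.fun))
            )
        x0 = res.x if factor == 1 else np.array([res.x[0] * factor, res.x[1] * factor, res.x[2], res.x[3]])

    residual = float(np.sqrt(_mse(x0, moving, fixed, center)))
    if max_residual is not None and residual > max_residual:
        raise RegistrationError(
            f"registration residual {residual:.4f} °C RMS exceeds {max_residual}", residual=residual
        )
    return SimilarityTransform(tx=float(x0[0]), ty=float(x0[1]),
                               rotation=float(x0[2]), scale=float(x0[3]), center=center)


def temporal_average(frames, window: int = 3) -> TemperatureFrame:
    """Pixelwise mean of ``window`` consecutive frames; center timestamp kept."""
    frames = list(frames)
    if len(frames) < window:
        raise SeriesError(f"need at least {window} frames, got {len(frames)}")
    frames = frames[:window]
    shapes = {f.temp_c.shape for f in frames}
    if len(shapes) != 1:
        raise SeriesError("frames must share dimensions")
    stack = np.stack([f.temp_c for f in frames])
    mid = frames[window // 2]
    return TemperatureFrame(
        temp_c=stack.mean(axis=0), timestamp=mid.timestamp, frame_id=f"avg_{mid.frame_id}"
    )


def mean_composite(frames) -> TemperatureFrame:
    """Mean of the last 3 frames of a period (the PET-comparison thermal image)."""
    frames = list(frames)
    if len(frames) < 3:
        raise SeriesError(f"mean composite needs at least 3 frames, got {len(frames)}")
    return temporal_average(frames[-3:], window=3)


def transforms_to_csv(entries: list[tuple[str, SimilarityTransform, float]], path) -> None:
    """Log per-frame transforms (frame_id, tx, ty, rot_deg, scale, residual)."""
    import pandas as pd

    pd.DataFrame(
        [
            {"frame_id": fid, "tx": t.tx, "ty": t.ty, "rot_deg": t.rotation,
             "scale": t.scale, "residual": res}
            for fid, t, res in entries
        ]
    ).to_csv(path, index=False)


# Diverging colormap breakpoints (Δ°C fractions of range): channel values at
# [-range, -range/2, 0, +range/2, +range]
_BREAK_FRACS = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
_CHANNELS = {
    "r": np.array([0.0, 0.0, 1.0, 1.0, 1.0]),
    "g": np.array([0.0, 0.0, 1.0, 0.0, 1.0]),
    "b": np.array([0.0, 1.0, 1.0, 0.0, 0.0]),
}


def render_difference_frame(
    frame: TemperatureFrame, baseline: TemperatureFrame, range_c: float = 2.0
) -> np.ndarray:
    """Render frame − baseline as an 8-bit RGB image.

    Δ = 0 maps to white; warming ramps white→red over (0, range/2] then
    red→yellow over (range/2, range]; cooling symmetrically white→blue→black.
    |Δ| beyond ``range_c`` clamps to the end colors.
    """
    if frame.temp_c.shape != baseline.temp_c.shape:
        raise SeriesError("frame and baseline must share dimensions")
    if range_c <= 0:
        raise ValueError("range_c must be positive")
    delta = (frame.temp_c - baseline.temp_c) / range_c
    out = np.empty(delta.shape + (3,), dtype=np.uint8)
    for i, ch in enumerate("rgb"):
        out[..., i] = np.rint(255.0 * np.interp(delta, _BREAK_FRACS, _CHANNELS[ch])).astype(np.uint8)
    return out
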
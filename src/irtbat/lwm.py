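"""Locally weighted mean (LWM) control-point image transformation.

The LWM transformation maps thermal-image coordinates onto PET-MIP
coordinates from manually identified control-point pairs.  At each control
point a full bivariate second-degree polynomial (terms 1, x, y, x², xy, y²)
is fitted by least squares to that point's ``n_neighbors`` nearest control
points (self included, Euclidean distance in source coordinates), and the
value at an arbitrary point is a distance-weighted blend of these local
polynomials:

    f(p) = Σ_i W(d_i / R_i) · P_i(p)  /  Σ_i W(d_i / R_i)

with d_i = |p − c_i|, R_i the distance from control point i to the most
distant of its neighbors, and Goshtasby's smooth taper
W(t) = 1 − 3t² + 2t³ on [0, 1] (0 outside).  A key consequence, used as
this module's central oracle: when all pairs are samples of one global
polynomial of degree ≤ 2, every local fit recovers it exactly and the
blend reproduces it everywhere covered.

The map is not analytically invertible, so forward (thermal→MIP, for
polygons and points) and inverse (MIP→thermal, for image resampling) fits
are built independently from the same pairs with roles swapped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import TransformError

__all__ = [
    "ControlPointPairs",
    "LwmTransform",
    "lwm_weight",
    "fit_lwm",
    "apply_lwm",
    "warp_image",
    "warp_polygon",
    "read_control_points",
    "write_control_points",
]

_MIN_PAIRS = 6  # a bivariate quadratic has six coefficients


@dataclass
class ControlPointPairs:
    """Corresponding (moving, fixed) pixel coordinates, shape (n, 2) each."""

    moving: np.ndarray
    fixed: np.ndarray

    def __post_init__(self):
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        self.fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        if self.moving.shape != self.fixed.shape or self.moving.shape[1] != 2:
            raise TransformError("moving and fixed must be matching (n, 2) arrays")
        if len(self.moving) < _MIN_PAIRS:
            raise TransformError(
                f"at least {_MIN_PAIRS} control-point pairs are required "
                f"(degree-2 polynomial), got {len(self.moving)}"
            )
        uniq = np.unique(self.fixed, axis=0)
        if len(uniq) != len(self.fixed):
            raise TransformError("duplicated fixed control points")

    def __len__(self) -> int:
        return len(self.moving)

    def swapped(self) -> "ControlPointPairs":
        return ControlPointPairs(moving=self.fixed.copy(), fixed=self.moving.copy())


def lwm_weight(t):
    """Goshtasby taper W(t) = 1 − 3t² + 2t³ for t ∈ [0, 1], else 0 (C¹, monotone)."""
    t = np.asarray(t, dtype=float)
    w = np.where(t < 1.0, 1.0 - 3.0 * t**2 + 2.0 * t**3, 0.0)
    return np.where(t < 0.0, 1.0, w)


def _design(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(u), u, v, u * u, u * v, v * v])


@dataclass
class LwmTransform:
    """Fitted LWM map: per-control-point quadratics in locally scaled frames.

    Each local polynomial is expressed in coordinates
    (u, v) = (p − c_i) / R_i for numerical conditioning; ``coeffs[i]`` is
    (2, 6) — one row of [1, u, v, u², uv, v²] coefficients per output axis.
    """

    centers: np.ndarray  # (n, 2) source-space control points
    radii: np.ndarray  # (n,) neighborhood radii
    coeffs: np.ndarray  # (n, 2, 6)
    n_neighbors: int
    direction: str = "moving_to_fixed"

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "centers": self.centers.tolist(),
            "radii": self.radii.tolist(),
            "coeffs": self.coeffs.tolist(),
            "n_neighbors": self.n_neighbors,
            "direction": self.direction,
        }))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LwmTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            radii=np.asarray(d["radii"], dtype=float),
            coeffs=np.asarray(d["coeffs"], dtype=float),
            n_neighbors=int(d["n_neighbors"]),
            direction=d["direction"],
        )

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_lwm(self, points)


def fit_lwm(
    pairs: ControlPointPairs,
    n_neighbors: int = 16,
    direction: str = "moving_to_fixed",
) -> LwmTransform:
    """Fit the LWM transformation in the requested direction.

    ``n_neighbors`` is clamped to the number of pairs but must stay ≥ 6.

    Raises
    ------
    TransformError
        On fewer than 6 pairs, or a rank-deficient (e.g. collinear)
        neighborhood — the error names the offending control point.
    """
    if direction == "moving_to_fixed":
        src, dst = pairs.moving, pairs.fixed
    elif direction == "fixed_to_moving":
        src, dst = pairs.fixed, pairs.moving
    else:
        raise ValueError(f"unknown direction {direction!r}")
    n = len(src)
    k = min(n_neighbors, n)
    if k < _MIN_PAIRS:
        raise TransformError(f"n_neighbors must be at least {_MIN_PAIRS}, got {k}")

    d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(-1)
    coeffs = np.empty((n, 2, 6))
    radii = np.empty(n)
    for i in range(n):
        nbr = np.argsort(d2[i], kind="stable")[:k]
        radius = float(np.sqrt(d2[i, nbr[-1]]))
        if radius <= 0:
            raise TransformError(f"control point {i}: coincident neighborhood (zero radius)")
        radii[i] = radius
        u = (src[nbr, 0] - src[i, 0]) / radius
        v = (src[nbr, 1] - src[i, 1]) / radius
        A = _design(u, v)
        if np.linalg.matrix_rank(A) < 6:
            raise TransformError(
                f"control point {i}: rank-deficient neighborhood (collinear points)"
            )
        sol, *_ = np.linalg.lstsq(A, dst[nbr], rcond=None)
        coeffs[i] = sol.T  # (2, 6)
    return LwmTransform(centers=src.copy(), radii=radii, coeffs=coeffs,
                        n_neighbors=k, direction=direction)


def apply_lwm(
    transform: LwmTransform, points: np.ndarray, count_fallback: list | None = None
) -> np.ndarray:
    """Evaluate the LWM map at (n, 2) points.

    Points outside every control point's radius fall back to the nearest
    control point's polynomial; pass a list as ``count_fallback`` to have
    the number of such points appended (usage is logged, never an error).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    squeeze = np.asarray(points).ndim == 1
    n_pts = len(pts)
    num = np.zeros((n_pts, 2))
    den = np.zeros(n_pts)
    d_all = np.empty((len(transform.centers), n_pts))
    vals_all = np.empty((len(transform.centers), n_pts, 2))
    for i, (c, r) in enumerate(zip(transform.centers, transform.radii)):
        du = (pts[:, 0] - c[0]) / r
        dv = (pts[:, 1] - c[1]) / r
        d = np.hypot(du, dv)  # == |p - c| / r
        A = _design(du, dv)
        vals = A @ transform.coeffs[i].T  # (n_pts, 2)
        w = lwm_weight(d)
        num += w[:, None] * vals
        den += w
        d_all[i] = d
        vals_all[i] = vals
    out = np.empty_like(num)
    covered = den > 0
    out[covered] = num[covered] / den[covered, None]
    n_fallback = int((~covered).sum())
    if n_fallback:
        nearest = np.argmin(d_all[:, ~covered], axis=0)
        out[~covered] = vals_all[nearest, np.flatnonzero(~covered)]
    if count_fallback is not None:
        count_fallback.append(n_fallback)
    return out[0] if squeeze else out


def warp_image(
    image: np.ndarray,
    t_inverse: LwmTransform,
    out_dims: tuple[int, int],
    interpolation: str = "bilinear",
) -> tuple[np.ndarray, np.ndarray]:
    """Resample an image into the fixed frame by inverse mapping.

    ``t_inverse`` must map output (fixed/MIP) coordinates to input
    coordinates.  Bilinear interpolation for continuous images,
    nearest-neighbor for binary masks.  Returns (warped, valid) where
    ``valid`` flags output pixels whose source location falls inside the
    input image.
    """
    image = np.asarray(image)
    rows, cols = out_dims
    xx, yy = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    src = apply_lwm(t_inverse, np.column_stack([xx.ravel(), yy.ravel()]))
    sx, sy = src[:, 0].reshape(rows, cols), src[:, 1].reshape(rows, cols)
    valid = (sx >= 0) & (sx <= image.shape[1] - 1) & (sy >= 0) & (sy <= image.shape[0] - 1)
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    warped = map_coordinates(
        image.astype(float), [sy, sx], order=order, mode="constant", cval=0.0
    )
    if image.dtype == bool:
        warped = warped.astype(bool) & valid
    else:
        warped = np.where(valid, warped, np.nan)
    return warped, valid


def warp_polygon(
    t_forward: LwmTransform, polygon: np.ndarray, max_segment_px: float = 1.0
) -> np.ndarray:
    """Map a polygon through the forward LWM transform, densifying edges.

    Extra vertices are inserted along each source edge so that no mapped
    segment exceeds ``max_segment_px``, keeping downstream rasterization
    faithful to the curved image of straight edges.
    """
    poly = np.atleast_2d(np.asarray(polygon, dtype=float))
    if len(poly) < 3:
        raise TransformError("polygon needs at least 3 vertices")
    out_pts = []
    n = len(poly)
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        ends = apply_lwm(t_forward, np.vstack([a, b]))
        m = max(1, int(np.ceil(np.linalg.norm(ends[1] - ends[0]) / max_segment_px)))
        for _ in range(4):  # refine the subdivision count against the mapped length
            frac = np.linspace(0.0, 1.0, m + 1)
            samples = a[None, :] + frac[:, None] * (b - a)[None, :]
            mapped = apply_lwm(t_forward, samples)
            seg_len = np.linalg.norm(np.diff(mapped, axis=0), axis=1)
            if seg_len.max() <= max_segment_px or m > 10000:
                break
            m = int(np.ceil(m * seg_len.max() / max_segment_px))
        out_pts.append(mapped[:-1])  # drop shared endpoint
    return np.vstack(out_pts)


def read_control_points(path: str | Path) -> ControlPointPairs:
    """Read pairs from CSV with columns pair_id, x_ti, y_ti, x_mip, y_mip."""
    import pandas as pd

    df = pd.read_csv(path).sort_values("pair_id", kind="stable")
    return ControlPointPairs(
        moving=df[["x_ti", "y_ti"]].to_numpy(float),
        fixed=df[["x_mip", "y_mip"]].to_numpy(float),
    )


def write_control_points(pairs: ControlPointPairs, path: str | Path) -> Path:
    import pandas as pd

    df = pd.DataFrame({
        "pair_id": np.arange(len(pairs)),
        "x_ti": pairs.moving[:, 0], "y_ti": pairs.moving[:, 1],
        "x_mip": pairs.fixed[:, 0], "y_mip": pairs.fixed[:, 1],
    })
    df.to_csv(path, index=False)
    return Path(path)
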
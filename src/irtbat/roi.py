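"""Supraclavicular ROI construction from five labeled apices.

The supraclavicular region of interest is bounded medially and inferiorly
by straight lines between labeled apices and laterally by the contour of
the neck, which is detected programmatically from the temperature gradient
between skin and the cooler background.  A small circular region on the
sternum, below the central apex, serves as the reference against which
relative supraclavicular temperatures are expressed.

Coordinates are 0-based with x = column and y = row, origin at the top-left
pixel center.  "Left"/"right" refer to image-space sides (smaller/larger x);
anatomical chirality is a framing question outside this module's scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as ShapelyPolygon, box as shapely_box
from shapely.prepared import prep

from .errors import ContrastError, GeometryError
from .radiometric import TemperatureFrame

__all__ = [
    "Point",
    "ApexSet",
    "NeckContour",
    "RoiMask",
    "ReferenceRegion",
    "ContourParams",
    "detect_neck_contour",
    "build_roi_mask",
    "build_reference_region",
    "rasterize_polygon",
    "read_apices",
]

Point = tuple[float, float]  # (x, y)

_APEX_LABELS = (
    "superolateral_left",
    "superolateral_right",
    "acromioclavicular_left",
    "acromioclavicular_right",
    "sternal",
)


@dataclass(frozen=True)
class ApexSet:
    """The five labeled apices that anchor both supraclavicular ROIs."""

    superolateral_left: Point
    superolateral_right: Point
    acromioclavicular_left: Point
    acromioclavicular_right: Point
    sternal: Point
    frame_shape: tuple[int, int] | None = None  # (rows, cols), for bounds checks

    def __post_init__(self):
        if self.frame_shape is not None:
            rows, cols = self.frame_shape
            for label in _APEX_LABELS:
                x, y = getattr(self, label)
                if not (0 <= x < cols and 0 <= y < rows):
                    raise GeometryError(f"apex {label} at ({x}, {y}) outside frame {self.frame_shape}")
        sx = self.sternal[0]
        left_max = max(self.superolateral_left[0], self.acromioclavicular_left[0])
        right_min = min(self.superolateral_right[0], self.acromioclavicular_right[0])
        if not (left_max < sx < right_min):
            raise GeometryError("sternal apex must lie between the left and right apex pairs in x")
        for side in ("left", "right"):
            if getattr(self, f"superolateral_{side}")[1] >= getattr(self, f"acromioclavicular_{side}")[1]:
                raise GeometryError(f"superolateral_{side} apex must be above the acromioclavicular apex")

    def pair(self, side: str) -> tuple[Point, Point]:
        """(superolateral, acromioclavicular) apices for a side."""
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return getattr(self, f"superolateral_{side}"), getattr(self, f"acromioclavicular_{side}")


@dataclass
class NeckContour:
    """Lateral neck border: one (sub-pixel) x per row, superolateral→acromioclavicular."""

    xs: np.ndarray  # float x per row
    ys: np.ndarray  # strictly increasing integer rows
    side: str

    def __post_init__(self):
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys)
        if len(self.xs) != len(self.ys) or len(self.ys) < 2:
            raise GeometryError("contour needs matching xs/ys with at least two rows")
        if not np.all(np.diff(self.ys) > 0):
            raise GeometryError("contour rows must be strictly increasing in y")

    @property
    def vertices(self) -> np.ndarray:
        """(n, 2) array of (x, y) path vertices."""
        return np.column_stack([self.xs, self.ys]).astype(float)


@dataclass
class RoiMask:
    """Binary supraclavicular ROI mask with its generating polygon."""

    mask: np.ndarray
    side: str
    polygon: np.ndarray  # closed polygon vertices (n, 2) as (x, y)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise GeometryError(f"empty ROI mask for side {self.side!r}")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class ReferenceRegion:
    """Sternal reference circle (default 10 px diameter)."""

    center: Point
    mask: np.ndarray
    diameter_px: float = 10.0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise GeometryError("empty reference region mask")


@dataclass(frozen=True)
class ContourParams:
    """Tunables for the gradient-based neck contour search.

    min_contrast is the least acceptable skin/background temperature span
    within a row's search band (°C); band_halfwidth_px bounds the lateral
    search around the straight-line prior between the two apices.
    """

    min_contrast: float = 3.0
    band_halfwidth_px: int = 30
    subpixel: bool = True


def detect_neck_contour(
    frame: TemperatureFrame,
    apices: ApexSet,
    side: str,
    params: ContourParams = ContourParams(),
) -> NeckContour:
    """Trace the neck edge between a side's two lateral apices.

    For each row between the superolateral and acromioclavicular apices the
    contour is placed at the maximum horizontal temperature-gradient
    magnitude within ``band_halfwidth_px`` of a straight-line prior joining
    the apices, with optional parabolic sub-pixel refinement.  The endpoint
    rows are pinned to the apices themselves.

    Raises
    ------
    ContrastError
        If any row's search band spans less than ``min_contrast`` °C.
    """
    (x_top, y_top), (x_bot, y_bot) = apices.pair(side)
    temp = frame.temp_c
    n_rows, n_cols = temp.shape
    y0, y1 = int(round(y_top)), int(round(y_bot))
    if y1 <= y0:
        raise GeometryError("acromioclavicular apex must be below superolateral apex")
    ys = np.arange(y0, y1 + 1)
    # straight-line prior between the two apices
    prior = x_top + (x_bot - x_top) * (ys - y_top) / (y_bot - y_top)
    grad = np.gradient(temp, axis=1)
    xs = np.empty(len(ys), dtype=float)
    for i, (y, xp) in enumerate(zip(ys, prior)):
        lo = max(0, int(np.floor(xp)) - params.band_halfwidth_px)
        hi = min(n_cols, int(np.ceil(xp)) + params.band_halfwidth_px + 1)
        band = temp[y, lo:hi]
        if band.max() - band.min() < params.min_contrast:
            raise ContrastError(
                f"insufficient contrast in row {y}: span "
                f"{band.max() - band.min():.2f} °C < {params.min_contrast} °C"
            )
        g = np.abs(grad[y, lo:hi])
        j = int(np.argmax(g))
        x = lo + j
        if params.subpixel and 0 < j < len(g) - 1:
            denom = g[j - 1] - 2 * g[j] + g[j + 1]
            if denom < 0:  # concave peak
                x += 0.5 * (g[j - 1] - g[j + 1]) / denom
        xs[i] = x
    xs[0], xs[-1] = x_top, x_bot  # endpoints coincide with the apices
    return NeckContour(xs=xs, ys=ys, side=side)


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a boolean mask by pixel-cell coverage.

    A pixel (row y, col x) is included when the polygon covers at least half
    of the unit cell centered on (x, y).  This half-coverage rule is
    area-faithful (mask area tracks the polygon's geometric area) and
    symmetric under reflections, unlike center-in rules whose boundary
    handling depends on edge orientation.
    """
    vertices = np.asarray(vertices, dtype=float)
    poly = ShapelyPolygon(vertices)
    if not poly.is_valid:
        raise GeometryError("self-intersecting or otherwise invalid ROI polygon")
    if poly.area == 0:
        raise GeometryError("degenerate (zero-area) ROI polygon")
    rows, cols = shape
    minx, miny, maxx, maxy = poly.bounds
    x_lo, x_hi = max(0, int(np.floor(minx - 0.5))), min(cols - 1, int(np.ceil(maxx + 0.5)))
    y_lo, y_hi = max(0, int(np.floor(miny - 0.5))), min(rows - 1, int(np.ceil(maxy + 0.5)))
    mask = np.zeros(shape, dtype=bool)
    if x_hi < x_lo or y_hi < y_lo:
        return mask
    prepared = prep(poly)
    for y in range(y_lo, y_hi + 1):
        for x in range(x_lo, x_hi + 1):
            cell = shapely_box(x - 0.5, y - 0.5, x + 0.5, y + 0.5)
            if prepared.contains_properly(cell):
                mask[y, x] = True
            elif prepared.intersects(cell):
                mask[y, x] = poly.intersection(cell).area >= 0.5
    return mask


def build_roi_mask(apices: ApexSet, contour: NeckContour, dims: tuple[int, int]) -> RoiMask:
    """Close the ROI polygon and rasterize it.

    Border order: superolateral apex → neck contour → acromioclavicular
    apex → straight line → sternal apex → straight line → superolateral.
    """
    side = contour.side
    (x_top, y_top), (x_bot, y_bot) = apices.pair(side)
    v0, v1 = contour.vertices[0], contour.vertices[-1]
    if not (np.allclose(v0, (x_top, y_top), atol=1.0) and np.allclose(v1, (x_bot, y_bot), atol=1.0)):
        raise GeometryError("contour endpoints do not match the side's apices")
    polygon = np.vstack([contour.vertices, [apices.sternal]])
    mask = rasterize_polygon(polygon, dims)
    if not mask.any():
        raise GeometryError(f"ROI polygon for side {side!r} rasterizes to an empty mask")
    return RoiMask(mask=mask, side=side, polygon=polygon)


def build_reference_region(
    apices: ApexSet,
    frame_shape: tuple[int, int],
    offset_px: float = 10.0,
    diameter_px: float = 10.0,
) -> ReferenceRegion:
    """Sternal reference circle of ``diameter_px``, ``offset_px`` below the sternal apex.

    Pixel inclusion: center distance ≤ radius, ties included.
    """
    cx, cy = apices.sternal
    cy = cy + offset_px
    radius = diameter_px / 2.0
    rows, cols = frame_shape
    if not (radius <= cx <= cols - 1 - radius and radius <= cy <= rows - 1 - radius):
        raise GeometryError(
            f"reference circle (center ({cx}, {cy}), r={radius}) does not fit in frame {frame_shape}"
        )
    yy, xx = np.mgrid[0:rows, 0:cols]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return ReferenceRegion(center=(cx, cy), mask=mask, diameter_px=diameter_px)


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_apices(path, frame_id: str | None = None, frame_shape=None) -> ApexSet:
    """Load an ApexSet from an annotations CSV (frame_id, label, x, y)."""
    import pandas as pd

    df = pd.read_csv(path)
    if frame_id is not None:
        df = df[df["frame_id"] == frame_id]
    pts = {}
    for label in _APEX_LABELS:
        rows = df[df["label"] == label]
        if len(rows) != 1:
            raise GeometryError(f"expected exactly one {label!r} apex, found {len(rows)}")
        pts[label] = (float(rows.iloc[0]["x"]), float(rows.iloc[0]["y"]))
    return ApexSet(**pts, frame_shape=frame_shape)
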
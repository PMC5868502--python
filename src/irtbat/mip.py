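"""Maximum-intensity projections of CT and glucose-uptake volumes.

A coronal MIP collapses a 3-D scalar volume along the anteroposterior axis:
MIP(x, y) = max_z V(x, y, z).  The supraclavicular glucose hotspot on the
MR(gluc) MIP is extracted with the same hottest-10%-median rule used for
the thermal images, inside an ROI warped over from the thermal frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, GeometryError
from .timeseries import hotspot_selection

__all__ = ["ScalarVolume", "MipImage", "mip", "mip_hotspot", "composite_mip",
           "load_volume", "save_volume"]


@dataclass
class ScalarVolume:
    """A 3-D scalar grid (CT attenuation in HU, or MR(gluc) uptake).

    Array axes are (y, x, z) with (x, y) spanning the projected coronal
    plane and z the projection (anteroposterior) axis, configurable via
    ``projection_axis``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = ""
    volume_id: str = ""
    projection_axis: int = 2

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise FormatError("volume must be a non-empty 3-D grid")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing_mm):
            raise FormatError(f"voxel spacing must be positive, got {self.spacing_mm}")


@dataclass
class MipImage:
    """A 2-D maximum-intensity projection and its provenance."""

    values: np.ndarray
    modality: str = ""
    source_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise FormatError("MIP must be a non-empty 2-D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def mip(volume: ScalarVolume) -> MipImage:
    """Project a volume by taking the exact maximum along the projection axis."""
    values = volume.values.max(axis=volume.projection_axis)
    return MipImage(values=values, modality=volume.modality, source_id=volume.volume_id)


def mip_hotspot(image: MipImage, roi_mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Hottest-10% mask and median within an ROI on a MIP.

    Selection is identical to the thermal hotspot rule: k = ceil(0.1·N)
    values chosen by a stable descending sort (scan-order tie-break);
    returns the binary hotspot mask in the MIP frame and the median of the
    selected values.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != image.values.shape:
        raise GeometryError(f"ROI shape {roi_mask.shape} does not match MIP {image.values.shape}")
    flat_idx = np.flatnonzero(roi_mask.ravel())
    if flat_idx.size == 0:
        raise GeometryError("empty ROI on MIP")
    values = image.values.ravel()[flat_idx]
    selected, median = hotspot_selection(values)
    mask = np.zeros(image.values.shape, dtype=bool)
    mask.ravel()[flat_idx[selected]] = True
    return mask, median


def composite_mip(
    ct_mip: MipImage,
    gluc_mip: MipImage,
    alpha: float = 0.5,
    gluc_cmap: str = "hot",
) -> np.ndarray:
    """Blend a grayscale CT underlay with a color-mapped uptake overlay.

    alpha = 0 shows pure CT grayscale, alpha = 1 the pure overlay; the
    uptake image is min-max normalized then passed through a matplotlib
    colormap.  Returns an 8-bit RGB array.
    """
    import matplotlib

    if ct_mip.shape != gluc_mip.shape:
        raise GeometryError("CT and MR(gluc) MIPs must share dimensions")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")

    def _norm(a: np.ndarray) -> np.ndarray:
        span = a.max() - a.min()
        return (a - a.min()) / span if span > 0 else np.zeros_like(a)

    ct = _norm(ct_mip.values)[..., None].repeat(3, axis=-1)
    cmap = matplotlib.colormaps[gluc_cmap]
    overlay = cmap(_norm(gluc_mip.values))[..., :3]
    blended = (1.0 - alpha) * ct + alpha * overlay
    return np.rint(255.0 * np.clip(blended, 0.0, 1.0)).astype(np.uint8)


def load_volume(path: str | Path, modality: str = "", projection_axis: int = 2) -> ScalarVolume:
    """Load a NIfTI volume (.nii/.nii.gz) as a ScalarVolume."""
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarVolume(
        values=np.asarray(img.get_fdata(), dtype=float),
        spacing_mm=spacing,
        modality=modality,
        volume_id=path.name.split(".")[0],
        projection_axis=projection_axis,
    )


def save_volume(volume: ScalarVolume, path: str | Path) -> Path:
    """Write a ScalarVolume to NIfTI with a diagonal affine from the spacing."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), str(path))
    return path
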
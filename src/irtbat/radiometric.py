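"""Radiometric thermal-frame I/O and count/temperature conversion.

Thermal cameras store raw sensor counts, not temperatures.  This module
defines the open on-disk dialect used throughout the package — a 16-bit
single-channel PNG of raw counts plus a JSON sidecar carrying the Planck
calibration constants and the frame timestamp — and the radiometric
conversion between counts and surface temperature.

The conversion is the standard Planck-law inversion used for microbolometer
cameras.  For object signal :math:`S_{obj}` (counts),

.. math::

    T = \\frac{B}{\\ln(R_1 / (R_2 (S_{obj} + O)) + F)}

with the reflected-ambient correction
:math:`S_{obj} = (S_{raw} - (1-\\varepsilon) S_{refl}) / \\varepsilon` where
:math:`S_{refl}` is the signal a blackbody at the reflected temperature
would produce.  Atmospheric transmission is not modelled (short indoor
path); see the methods note.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import CalibrationError, FormatError

__all__ = [
    "CalibrationConstants",
    "RadiometricFrame",
    "TemperatureFrame",
    "DEFAULT_CALIBRATION",
    "read_frame",
    "write_frame",
    "counts_to_temperature",
    "temperature_to_counts",
    "read_manifest",
]

_SIDECAR_KEYS = ("R1", "R2", "B", "F", "O", "emissivity", "reflected_temp_k", "timestamp_s")


@dataclass(frozen=True)
class CalibrationConstants:
    """Planck calibration constants of a radiometric sensor.

    Parameters
    ----------
    R1, R2 : float
        Planck gain (counts) and scale (unitless).
    B : float
        Planck spectral constant in kelvin.
    F : float
        Planck shape constant (unitless, typically ~1).
    O : float
        Count offset.
    emissivity : float
        Surface emissivity in (0, 1].
    reflected_temp : float
        Reflected ambient temperature in kelvin.
    """

    R1: float
    R2: float
    B: float
    F: float
    O: float
    emissivity: float = 0.98
    reflected_temp: float = 295.15

    def __post_init__(self):
        if not (self.B > 0 and self.R1 > 0 and self.R2 > 0):
            raise CalibrationError(f"R1, R2 and B must be positive (got R1={self.R1}, R2={self.R2}, B={self.B})")
        if not (0 < self.emissivity <= 1):
            raise CalibrationError(f"emissivity must be in (0, 1], got {self.emissivity}")
        if not self.reflected_temp > 0:
            raise CalibrationError(f"reflected_temp must be positive kelvin, got {self.reflected_temp}")

    @property
    def reflected_signal(self) -> float:
        """Counts a blackbody at ``reflected_temp`` would produce."""
        return self.R1 / (self.R2 * (math.exp(self.B / self.reflected_temp) - self.F)) - self.O


#: Representative constants used by the synthetic generator's sidecars.
DEFAULT_CALIBRATION = CalibrationConstants(R1=17000.0, R2=0.045, B=1430.0, F=1.0, O=-300.0)


@dataclass
class RadiometricFrame:
    """A single raw thermal frame: uint16 counts plus calibration metadata."""

    counts: np.ndarray
    timestamp: float
    calibration: CalibrationConstants
    frame_id: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.size == 0:
            raise FormatError("counts must be a non-empty 2-D grid")


@dataclass
class TemperatureFrame:
    """A per-pixel temperature map in degrees Celsius."""

    temp_c: np.ndarray
    timestamp: float
    frame_id: str = ""
    bounds_c: tuple[float, float] = field(default=(-40.0, 150.0), repr=False)

    def __post_init__(self):
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if self.temp_c.ndim != 2 or self.temp_c.size == 0:
            raise FormatError("temp_c must be a non-empty 2-D grid")
        if not np.all(np.isfinite(self.temp_c)):
            raise CalibrationError("temperature frame contains non-finite values")
        lo, hi = self.bounds_c
        if self.temp_c.min() < lo or self.temp_c.max() > hi:
            raise CalibrationError(
                f"temperatures outside plausibility bounds [{lo}, {hi}] °C: "
                f"range {self.temp_c.min():.2f}..{self.temp_c.max():.2f}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.temp_c.shape


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_frame(path: str | Path) -> RadiometricFrame:
    """Read a 16-bit grayscale PNG frame and its JSON calibration sidecar.

    Raises
    ------
    FormatError
        If the sidecar is missing or incomplete, or the image is not a
        single-channel 16-bit image.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing calibration sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise FormatError(f"sidecar {sidecar} missing keys: {', '.join(missing)}")
    counts = iio.imread(path)
    if counts.ndim != 2:
        raise FormatError(f"{path}: expected single-channel image, got shape {counts.shape}")
    if counts.dtype != np.uint16:
        raise FormatError(f"{path}: expected 16-bit counts, got dtype {counts.dtype}")
    calib = CalibrationConstants(
        R1=meta["R1"], R2=meta["R2"], B=meta["B"], F=meta["F"], O=meta["O"],
        emissivity=meta["emissivity"], reflected_temp=meta["reflected_temp_k"],
    )
    return RadiometricFrame(counts=counts, timestamp=float(meta["timestamp_s"]),
                            calibration=calib, frame_id=path.stem)


def write_frame(frame: RadiometricFrame, path: str | Path) -> Path:
    """Write a raw frame as 16-bit PNG + JSON sidecar (bit-exact round trip)."""
    path = Path(path)
    counts = np.asarray(frame.counts)
    if counts.dtype != np.uint16:
        if counts.min() < 0 or counts.max() > np.iinfo(np.uint16).max:
            raise FormatError("counts outside uint16 range")
        counts = counts.astype(np.uint16)
    iio.imwrite(path, counts)
    c = frame.calibration
    meta = {
        "R1": c.R1, "R2": c.R2, "B": c.B, "F": c.F, "O": c.O,
        "emissivity": c.emissivity, "reflected_temp_k": c.reflected_temp,
        "timestamp_s": frame.timestamp,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def counts_to_temperature(frame: RadiometricFrame) -> TemperatureFrame:
    """Convert raw counts to per-pixel temperature (°C) by Planck inversion.

    Strictly increasing in the raw counts for any valid calibration.

    Raises
    ------
    CalibrationError
        If the logarithm argument is non-positive for some pixel (counts
        outside the calibrated range).
    """
    c = frame.calibration
    s_raw = np.asarray(frame.counts, dtype=float)
    s_obj = (s_raw - (1.0 - c.emissivity) * c.reflected_signal) / c.emissivity
    denom = c.R2 * (s_obj + c.O)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.where(denom != 0, c.R1 / denom + c.F, np.nan)
    bad = ~np.isfinite(arg) | (arg <= 1.0)  # ln(arg) must be > 0 for finite positive T
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise CalibrationError(
            f"count {frame.counts[idx]} at pixel (row={idx[0]}, col={idx[1]}) "
            "is outside the invertible range of the calibration"
        )
    temp_k = c.B / np.log(arg)
    return TemperatureFrame(temp_c=temp_k - 273.15, timestamp=frame.timestamp, frame_id=frame.frame_id)


def temperature_to_counts(
    temp: TemperatureFrame,
    calibration: CalibrationConstants,
    quantize: bool = True,
    frame_id: str | None = None,
) -> RadiometricFrame:
    """Algebraic inverse of :func:`counts_to_temperature`.

    Quantizes to the nearest integer count unless ``quantize`` is False, in
    which case continuous counts are kept (useful for round-trip oracles).
    """
    c = calibration
    temp_k = np.asarray(temp.temp_c, dtype=float) + 273.15
    expo = np.exp(c.B / temp_k)
    if np.any(expo - c.F <= 0):
        raise CalibrationError("temperature outside invertible range (exp(B/T) <= F)")
    s_obj = c.R1 / (c.R2 * (expo - c.F)) - c.O
    s_raw = c.emissivity * s_obj + (1.0 - c.emissivity) * c.reflected_signal
    if quantize:
        s_raw = np.rint(s_raw)
        if s_raw.min() < 0 or s_raw.max() > np.iinfo(np.uint16).max:
            raise CalibrationError("temperature maps to counts outside uint16 range")
        s_raw = s_raw.astype(np.uint16)
    return RadiometricFrame(counts=s_raw, timestamp=temp.timestamp,
                            calibration=calibration,
                            frame_id=temp.frame_id if frame_id is None else frame_id)


def read_manifest(path: str | Path):
    """Read a sequence manifest CSV (frame_id, path, timestamp_s, period).

    Returns a pandas DataFrame sorted by timestamp; paths are resolved
    relative to the manifest's directory.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    required = {"frame_id", "path", "timestamp_s", "period"}
    if not required.issubset(df.columns):
        raise FormatError(f"manifest missing columns: {sorted(required - set(df.columns))}")
    bad = ~df["period"].isin(["acclimatization", "initial", "final"])
    if bad.any():
        raise FormatError(f"unknown period label(s): {sorted(df.loc[bad, 'period'].unique())}")
    df = df.sort_values("timestamp_s", kind="stable").reset_index(drop=True)
    df["path"] = [str((path.parent / p).resolve()) for p in df["path"]]
    return df
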
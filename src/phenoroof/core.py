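"""Shared domain types for the scan-to-height pipeline.

A *scan* is one acquisition from a nadir-mounted stereo RGB-depth camera
over a raised plant bed: an 8-bit RGB image plus a disparity matrix that
has been upscaled/aligned to the same pixel grid.  Heights are recovered
from the stereo geometry: depth ``Z = B·f/D`` (similar triangles) and
plant height ``H = C − Z − r`` where ``C`` is the camera elevation above
the soil path and ``r`` the rise of the plant bed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CameraGeometry",
    "Scan",
    "CropWindow",
    "CanopyMask",
    "PhenoroofError",
    "ConfigError",
    "FormatError",
    "InvalidDisparityError",
    "DegenerateImageError",
    "EmptyFieldError",
]


class PhenoroofError(Exception):
    """Base class for all package errors."""


class ConfigError(PhenoroofError):
    """Invalid or inconsistent configuration/geometry."""


class FormatError(PhenoroofError):
    """Malformed input file or mismatched grid dimensions."""


class InvalidDisparityError(PhenoroofError):
    """Non-positive disparity passed where a valid one is required."""


class DegenerateImageError(PhenoroofError):
    """Image with a single grey level: no threshold separates two classes."""


class EmptyFieldError(PhenoroofError):
    """No valid foreground pixels — upstream segmentation failure."""


@dataclass(frozen=True)
class CameraGeometry:
    """Stereo and scene constants consumed by the depth/height equations.

    Parameters
    ----------
    baseline_cm : float
        Stereo baseline ``B`` (cm).  7.5 cm for the OAK-D-Lite class of
        device the defaults model.
    focal_px : float
        Focal length ``f`` in pixels on the aligned disparity grid,
        obtained from camera calibration.
    camera_elevation_cm : float
        ``C``, camera elevation above the soil path (cm).
    bed_rise_cm : float
        ``r``, rise of the plant bed above the soil path (cm).
    min_depth_cm, max_depth_cm : float
        Validity window for recovered depths; pixels outside it are
        discarded (small disparities otherwise blow up ``Z = B·f/D``).
        ``max_depth_cm`` defaults to ``C`` — nothing lies below ground.
    """

    baseline_cm: float = 7.5
    focal_px: float = 880.0
    camera_elevation_cm: float = 204.5
    bed_rise_cm: float = 17.0
    min_depth_cm: float = 19.6
    max_depth_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.baseline_cm <= 0 or self.focal_px <= 0:
            raise ConfigError("baseline_cm and focal_px must be positive")
        if self.camera_elevation_cm <= self.bed_rise_cm:
            raise ConfigError("camera_elevation_cm must exceed bed_rise_cm")
        if self.max_depth_cm is None:
            object.__setattr__(self, "max_depth_cm", self.camera_elevation_cm)
        if not (0 < self.min_depth_cm < self.max_depth_cm):
            raise ConfigError("need 0 < min_depth_cm < max_depth_cm")

    @property
    def working_height_cm(self) -> float:
        """``C − r``: camera elevation above the bed surface."""
        return self.camera_elevation_cm - self.bed_rise_cm

    def to_dict(self) -> dict:
        return {
            "baseline_cm": self.baseline_cm,
            "focal_px": self.focal_px,
            "camera_elevation_cm": self.camera_elevation_cm,
            "bed_rise_cm": self.bed_rise_cm,
            "min_depth_cm": self.min_depth_cm,
            "max_depth_cm": self.max_depth_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraGeometry":
        return cls(**d)


@dataclass
class Scan:
    """One acquisition: RGB grid + aligned disparity grid.

    ``disparity`` is real-valued, in pixels, on the same grid as ``rgb``;
    the value 0 marks an invalid (occluded / unmatched) pixel, since a
    zero disparity has no physical depth.
    """

    rgb: np.ndarray
    disparity: np.ndarray
    acquired_at: pd.Timestamp
    geometry: CameraGeometry
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        self.disparity = np.asarray(self.disparity, dtype=float)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise FormatError("rgb must be an (H, W, 3) array")
        if self.rgb.dtype != np.uint8:
            raise FormatError("rgb must be 8-bit (uint8)")
        if self.disparity.shape != self.rgb.shape[:2]:
            raise FormatError(
                f"disparity grid {self.disparity.shape} does not match "
                f"rgb grid {self.rgb.shape[:2]}"
            )
        if np.any(self.disparity < 0):
            raise FormatError("disparity values must be >= 0 (0 = invalid)")
        self.acquired_at = pd.Timestamp(self.acquired_at)

    @property
    def shape(self) -> tuple:
        return self.disparity.shape


@dataclass(frozen=True)
class CropWindow:
    """Pixel margins removed from each edge before segmentation."""

    top: int = 0
    bottom: int = 0
    left: int = 0
    right: int = 0

    def __post_init__(self) -> None:
        if min(self.top, self.bottom, self.left, self.right) < 0:
            raise ConfigError("crop margins must be non-negative")

    def apply_shape(self, shape: tuple) -> tuple:
        h = shape[0] - self.top - self.bottom
        w = shape[1] - self.left - self.right
        if h <= 0 or w <= 0:
            raise ConfigError(f"crop window exhausts a {shape} image")
        return (h, w)

    def to_dict(self) -> dict:
        return {"top": self.top, "bottom": self.bottom,
                "left": self.left, "right": self.right}

    @classmethod
    def from_dict(cls, d: dict) -> "CropWindow":
        return cls(**d)


@dataclass
class CanopyMask:
    """Binary foreground map: True = leaf pixel, False = ground/soil."""

    mask: np.ndarray
    threshold_used: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())


def _copy_scan(scan: Scan, **changes) -> Scan:
    kwargs = dict(rgb=scan.rgb, disparity=scan.disparity,
                  acquired_at=scan.acquired_at, geometry=scan.geometry,
                  label=scan.label)
    kwargs.update(changes)
    return Scan(**kwargs)
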
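"""Disparity → depth → per-pixel plant height, and canopy summaries.

For a calibrated stereo pair, depth follows the similar-triangle rule

    Z = B · f / D                       (depth, cm)
    H = C − Z − r                       (plant height above the bed, cm)

with baseline ``B``, focal length ``f`` (px), disparity ``D`` (px),
camera elevation ``C`` and bed rise ``r``.  The representative image
plant height (IPH) is an upper percentile — 98th by default — of the
per-pixel heights of foreground (leaf) pixels: the maximum is dominated
by disparity outliers, while the 98th–99th percentile tracks the true
canopy top.

Negative heights are legitimate (ground points below the raised bed
level) and are kept in distributions; they never affect the IPH, which
reads the upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CameraGeometry,
    CanopyMask,
    ConfigError,
    EmptyFieldError,
    InvalidDisparityError,
    Scan,
)

__all__ = [
    "HeightField",
    "HeightSummary",
    "disparity_to_depth",
    "pixel_heights",
    "summarize_heights",
    "export_point_cloud",
]


def disparity_to_depth(disparity_px, geometry: CameraGeometry):
    """Depth ``Z = B·f/D`` in cm; scalar or array.

    Monotone decreasing in ``D``.  Non-positive disparity has no depth
    and raises :class:`InvalidDisparityError`.
    """
    d = np.asarray(disparity_px, dtype=float)
    if np.any(d <= 0):
        raise InvalidDisparityError("disparity must be > 0")
    z = geometry.baseline_cm * geometry.focal_px / d
    return float(z) if np.isscalar(disparity_px) else z


@dataclass
class HeightField:
    """Per-foreground-pixel depths and heights for one scan.

    Coordinates are 0-based row/col on the (cropped) grid, origin
    top-left.  ``n_invalid_disparity`` counts foreground pixels dropped
    for a zero disparity; ``n_out_of_range`` those whose depth fell
    outside the geometry's validity window (e.g. canopy tips closer than
    the sensor's near limit).
    """

    rows: np.ndarray
    cols: np.ndarray
    depth_cm: np.ndarray
    height_cm: np.ndarray
    scan_time: pd.Timestamp
    geometry: CameraGeometry
    n_invalid_disparity: int = 0
    n_out_of_range: int = 0
    label: Optional[str] = None

    def __len__(self) -> int:
        return self.height_cm.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"row": self.rows, "col": self.cols,
             "depth_cm": self.depth_cm, "height_cm": self.height_cm}
        )


def pixel_heights(scan: Scan, mask: CanopyMask) -> HeightField:
    """Heights of foreground pixels, aligned with the disparity grid.

    Foreground coordinates index the disparity matrix directly; pixels
    with the invalid marker (disparity 0) or with depth outside
    ``[min_depth_cm, max_depth_cm]`` are excluded and counted.
    """
    g = scan.geometry
    if g is None:
        raise ConfigError("scan carries no camera geometry")
    if mask.mask.shape != scan.shape:
        raise ConfigError(
            f"mask {mask.mask.shape} does not match scan {scan.shape}"
        )
    rows, cols = np.nonzero(mask.mask)
    d = scan.disparity[rows, cols]
    valid = d > 0
    n_invalid = int((~valid).sum())
    z = np.full(d.shape, np.nan)
    z[valid] = g.baseline_cm * g.focal_px / d[valid]
    in_range = valid & (z >= g.min_depth_cm) & (z <= g.max_depth_cm)
    n_oor = int(valid.sum() - in_range.sum())
    z = z[in_range]
    h = g.camera_elevation_cm - z - g.bed_rise_cm
    return HeightField(
        rows=rows[in_range], cols=cols[in_range],
        depth_cm=z, height_cm=h,
        scan_time=scan.acquired_at, geometry=g,
        n_invalid_disparity=n_invalid, n_out_of_range=n_oor,
        label=scan.label,
    )


@dataclass
class HeightSummary:
    """Percentile summary of one scan's canopy height distribution."""

    percentiles: Dict[int, float]
    iph_cm: float
    iph_percentile: int
    n_pixels: int
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    scan_time: pd.Timestamp
    label: Optional[str] = None

    def row(self) -> dict:
        out = {"scan_time": self.scan_time, "label": self.label,
               "n_pixels": self.n_pixels}
        out.update({f"p{p}_cm": v for p, v in self.percentiles.items()})
        out["iph_cm"] = self.iph_cm
        return out


def summarize_heights(
    field: HeightField,
    percentiles: Sequence[int] = (95, 96, 97, 98, 99, 100),
    iph_percentile: int = 98,
    hist_bins: int = 50,
) -> HeightSummary:
    """Percentiles (linear interpolation between order statistics), IPH
    and a histogram standing in for the violin profile.

    The histogram spans the full height range including negative values;
    the IPH is the entry at ``iph_percentile`` (default 98, the range
    found to track field measurements best).
    """
    if len(field) == 0:
        raise EmptyFieldError(
            "no valid foreground pixels — segmentation or disparity failure"
        )
    if iph_percentile not in percentiles:
        percentiles = tuple(sorted(set(percentiles) | {iph_percentile}))
    h = field.height_cm
    values = np.percentile(h, list(percentiles))  # linear interpolation
    pmap = {int(p): float(v) for p, v in zip(percentiles, values)}
    counts, edges = np.histogram(h, bins=hist_bins)
    return HeightSummary(
        percentiles=pmap,
        iph_cm=pmap[iph_percentile],
        iph_percentile=iph_percentile,
        n_pixels=len(field),
        hist_edges=edges,
        hist_counts=counts,
        scan_time=field.scan_time,
        label=field.label,
    )


def export_point_cloud(field: HeightField, path, metric_xy: bool = False) -> int:
    """Write the upper-canopy surface as an ASCII PLY point cloud.

    One vertex per valid foreground pixel with ``x = col``, ``y = row``
    (pixel units, or cm via the per-pixel scale ``Z/f`` when
    ``metric_xy``) and ``z = height`` plus an explicit ``height_cm``
    scalar for colour mapping.  Returns the number of vertices written.
    """
    from .io import write_ply  # local import to avoid cycle

    if len(field) == 0:
        raise EmptyFieldError("cannot export an empty height field")
    if metric_xy:
        scale = field.depth_cm / field.geometry.focal_px
        x = field.cols * scale
        y = field.rows * scale
    else:
        x = field.cols.astype(float)
        y = field.rows.astype(float)
    return write_ply(path, x, y, field.height_cm, field.height_cm)
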
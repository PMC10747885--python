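"""Synthetic scenes and sensor suites with known ground truth.

Real field campaigns rarely ship their raw scans, so every downstream
stage here is exercised against generated data whose truth is known by
construction:

* **Scenes** — an RGB + disparity pair over a raised plant bed.  Canopy
  patches are axis-aligned rectangles at stated true heights; disparity
  is the exact stereo value ``D = B·f / (C − r − h)`` plus optional
  zero-mean noise, with occluded pixels carrying the invalid marker 0.
  Leaves are rendered brighter than the ground (a bimodal histogram for
  the global threshold), and an optional contiguous shadow drags leaf
  intensity toward the ground mean — the documented failure mode of
  daylight acquisition.
* **Sensor suites** — diurnal sinusoids per station, each crop station
  offset downward by its cooling effect, the substrate lagged and damped
  relative to the 15 cm air level, plus Gaussian noise and missing rows.

With zero noise both generators reproduce their closed forms exactly,
which is what makes them usable as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CameraGeometry, PhenoroofError, Scan
from .thermal import SensorSeries

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "SensorSimSpec",
    "generate_scene",
    "generate_scene_with_truth",
    "generate_sensor_suite",
    "tiered_canopy_patches",
    "flat_scene_spec",
    "tiered_scene_spec",
]

Rect = Tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open


class SceneSpecError(PhenoroofError):
    """Scene specification violates a physical or frame constraint."""


#: Tier profile of the default synthetic canopy, bottom to top:
#: (height fraction of the plant top, cumulative canopy-area fraction at
#: or above this tier).  The top tier holds ~8% of the canopy area —
#: plant tips are a small part of the visible crown — which is what
#: makes an upper percentile a robust height estimate.
TIER_PROFILE: Tuple[Tuple[float, float], ...] = (
    (0.30, 1.00),
    (0.55, 0.70),
    (0.75, 0.40),
    (0.90, 0.20),
    (1.00, 0.08),
)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``canopy_patches`` is a list of ``(rect, true_height_cm)`` with
    rectangles in half-open pixel coordinates ``(row0, col0, row1,
    col1)``; later patches overwrite earlier ones, so nested tiers are
    listed bottom tier first.
    """

    width_px: int
    height_px: int
    geometry: CameraGeometry
    canopy_patches: Sequence[Tuple[Rect, float]]
    background_height_cm: float = 0.0
    leaf_intensity_mean: float = 140.0
    ground_intensity_mean: float = 60.0
    intensity_jitter_sd: float = 8.0
    shadow_fraction: float = 0.0
    disparity_noise_sd_px: float = 0.0
    occlusion_fraction: float = 0.0
    quantize_disparity: bool = False
    seed: int = 0
    acquired_at: str = "2022-08-05T10:00:00"
    label: Optional[str] = None

    def __post_init__(self) -> None:
        g = self.geometry
        if self.width_px <= 0 or self.height_px <= 0:
            raise SceneSpecError("image dimensions must be positive")
        heights = [self.background_height_cm] + [h for _, h in self.canopy_patches]
        for h in heights:
            if g.working_height_cm - h <= 0:
                raise SceneSpecError(
                    f"height {h} cm implies non-positive depth "
                    f"(camera is only {g.working_height_cm} cm above the bed)"
                )
        for (r0, c0, r1, c1), _ in self.canopy_patches:
            if not (0 <= r0 < r1 <= self.height_px and 0 <= c0 < c1 <= self.width_px):
                raise SceneSpecError(f"patch {(r0, c0, r1, c1)} outside the frame")
        if self.shadow_fraction == 0.0:
            if abs(self.leaf_intensity_mean - self.ground_intensity_mean) < 30:
                raise SceneSpecError(
                    "leaf/ground intensity means must differ by >= 30 grey "
                    "levels for a bimodal histogram"
                )
        if not (0 <= self.shadow_fraction <= 1):
            raise SceneSpecError("shadow_fraction must be in [0, 1]")
        if not (0 <= self.occlusion_fraction <= 1):
            raise SceneSpecError("occlusion_fraction must be in [0, 1]")
        if self.disparity_noise_sd_px < 0:
            raise SceneSpecError("disparity_noise_sd_px must be >= 0")


@dataclass
class SceneTruth:
    """Ground truth behind a generated scene."""

    height_map_cm: np.ndarray     # true height of every pixel
    canopy_mask: np.ndarray       # True where a canopy patch sits
    occluded_mask: np.ndarray     # canopy pixels with invalid disparity
    shadow_mask: np.ndarray       # canopy pixels rendered in shadow
    true_disparity: np.ndarray    # noise-free disparity


def generate_scene_with_truth(spec: SceneSpec) -> Tuple[Scan, SceneTruth]:
    """Generate a scene and return it with its ground truth."""
    rng = np.random.default_rng(spec.seed)
    g = spec.geometry
    shape = (spec.height_px, spec.width_px)

    height_map = np.full(shape, float(spec.background_height_cm))
    canopy = np.zeros(shape, dtype=bool)
    for (r0, c0, r1, c1), h in spec.canopy_patches:
        height_map[r0:r1, c0:c1] = h
        canopy[r0:r1, c0:c1] = True

    depth = g.working_height_cm - height_map
    true_disp = g.baseline_cm * g.focal_px / depth
    disparity = true_disp.copy()
    if spec.disparity_noise_sd_px > 0:
        noise = rng.normal(0.0, spec.disparity_noise_sd_px, size=shape)
        disparity[canopy] = np.maximum(disparity[canopy] + noise[canopy], 1e-6)

    occluded = np.zeros(shape, dtype=bool)
    crows, ccols = np.nonzero(canopy)
    n_canopy = crows.size
    if spec.occlusion_fraction > 0 and n_canopy:
        k = int(round(spec.occlusion_fraction * n_canopy))
        pick = rng.choice(n_canopy, size=k, replace=False)
        occluded[crows[pick], ccols[pick]] = True
        disparity[occluded] = 0.0

    if spec.quantize_disparity:
        valid = disparity > 0
        disparity[valid] = np.maximum(np.rint(disparity[valid]), 1.0)

    intensity = rng.normal(spec.ground_intensity_mean, spec.intensity_jitter_sd, shape)
    intensity[canopy] = rng.normal(
        spec.leaf_intensity_mean, spec.intensity_jitter_sd, shape)[canopy]

    shadow = np.zeros(shape, dtype=bool)
    if spec.shadow_fraction > 0 and n_canopy:
        # contiguous band: shade canopy pixels column-by-column from the left
        k = int(round(spec.shadow_fraction * n_canopy))
        order = np.lexsort((crows, ccols))
        shadow[crows[order[:k]], ccols[order[:k]]] = True
        factor = rng.uniform(0.2, 0.5)
        intensity[shadow] *= factor

    intensity = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    rgb = np.repeat(intensity[:, :, None], 3, axis=2)

    scan = Scan(rgb=rgb, disparity=disparity,
                acquired_at=pd.Timestamp(spec.acquired_at),
                geometry=g, label=spec.label)
    truth = SceneTruth(height_map_cm=height_map, canopy_mask=canopy,
                       occluded_mask=occluded, shadow_mask=shadow,
                       true_disparity=true_disp)
    return scan, truth


def generate_scene(spec: SceneSpec) -> Scan:
    """Generate a scene (see :func:`generate_scene_with_truth`)."""
    return generate_scene_with_truth(spec)[0]


def tiered_canopy_patches(
    top_height_cm: float,
    frame_shape: Tuple[int, int],
    canopy_fraction: float = 0.5,
    profile: Sequence[Tuple[float, float]] = TIER_PROFILE,
) -> List[Tuple[Rect, float]]:
    """Nested-rectangle canopy emulating a real crown's height profile.

    The outermost rectangle spans ``canopy_fraction`` of the frame's
    shorter side and sits at the lowest tier; successively smaller
    concentric rectangles rise toward ``top_height_cm``.  Tier areas
    follow ``profile`` (height fraction, cumulative area fraction), so
    by default the plant top covers ~8% of the canopy.
    """
    h_px, w_px = frame_shape
    s0 = int(round(canopy_fraction * min(h_px, w_px)))
    cy, cx = h_px // 2, w_px // 2
    patches: List[Tuple[Rect, float]] = []
    for hfrac, cumarea in profile:
        s = max(2, int(round(s0 * np.sqrt(cumarea))))
        r0, c0 = cy - s // 2, cx - s // 2
        patches.append(((r0, c0, r0 + s, c0 + s), top_height_cm * hfrac))
    return patches


def flat_scene_spec(height_cm: float, geometry: CameraGeometry,
                    width_px: int = 240, height_px: int = 240,
                    patch_fraction: float = 0.5, **kwargs) -> SceneSpec:
    """A single flat canopy slab at ``height_cm`` — the simplest oracle."""
    s = int(round(patch_fraction * min(width_px, height_px)))
    r0, c0 = height_px // 2 - s // 2, width_px // 2 - s // 2
    return SceneSpec(width_px=width_px, height_px=height_px, geometry=geometry,
                     canopy_patches=[((r0, c0, r0 + s, c0 + s), height_cm)],
                     **kwargs)


def tiered_scene_spec(top_height_cm: float, geometry: CameraGeometry,
                      width_px: int = 240, height_px: int = 240,
                      canopy_fraction: float = 0.5, **kwargs) -> SceneSpec:
    """A realistic tiered canopy topping out at ``top_height_cm``."""
    patches = tiered_canopy_patches(top_height_cm, (height_px, width_px),
                                    canopy_fraction)
    return SceneSpec(width_px=width_px, height_px=height_px, geometry=geometry,
                     canopy_patches=patches, **kwargs)


# ---------------------------------------------------------------------------
# sensor suites


@dataclass(frozen=True)
class SensorSimSpec:
    """Closed-form diurnal model for one station.

    The noiseless reading at clock time ``t`` is

        value(t) = mean + damping·amplitude·cos(2π(hod(t) − peak − lag)/24)
                   − cooling_offset

    with ``hod`` the local hour-of-day.  Crop stations carry a positive
    ``cooling_offset_C`` (they run cooler than the concrete control,
    whose offset is 0); the substrate reuses the 15 cm form with its lag
    and damping applied.
    """

    start: str
    end: str
    cadence_minutes: int = 15
    diurnal_mean_C: float = 23.0
    diurnal_amplitude_C: float = 8.0
    peak_hour: float = 15.0
    cooling_offset_C: float = 0.0
    substrate_lag_hours: float = 0.0
    substrate_damping: float = 1.0
    noise_sd_C: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0
    role: str = "crop-15cm"
    crop: Optional[str] = None
    variable: str = "temperature"
    clip_min: Optional[float] = None
    include_humidity: bool = False

    def __post_init__(self) -> None:
        if pd.Timestamp(self.end) <= pd.Timestamp(self.start):
            raise PhenoroofError("end must be after start")
        if self.cadence_minutes <= 0:
            raise PhenoroofError("cadence_minutes must be positive")
        if self.noise_sd_C < 0:
            raise PhenoroofError("noise_sd_C must be >= 0")
        if not (0 <= self.missing_fraction < 1):
            raise PhenoroofError("missing_fraction must be in [0, 1)")

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end,
                             freq=f"{self.cadence_minutes}min", inclusive="left")

    def closed_form(self, index: pd.DatetimeIndex) -> np.ndarray:
        """Noiseless reading at each timestamp."""
        hod = (index.hour + index.minute / 60.0 + index.second / 3600.0).to_numpy()
        phase = 2 * np.pi * (hod - self.peak_hour - self.substrate_lag_hours) / 24.0
        v = (self.diurnal_mean_C
             + self.substrate_damping * self.diurnal_amplitude_C * np.cos(phase)
             - self.cooling_offset_C)
        if self.clip_min is not None:
            v = np.maximum(v, self.clip_min)
        return v


def _simulate_station(name: str, spec: SensorSimSpec) -> SensorSeries:
    rng = np.random.default_rng(spec.seed)
    idx = spec.timestamps()
    values = spec.closed_form(idx)
    if spec.noise_sd_C > 0:
        values = values + rng.normal(0.0, spec.noise_sd_C, size=len(idx))
        if spec.clip_min is not None:
            values = np.maximum(values, spec.clip_min)
    keep = np.ones(len(idx), dtype=bool)
    if spec.missing_fraction > 0:
        keep = rng.random(len(idx)) >= spec.missing_fraction
        if not keep.any():
            keep[0] = True
    series = pd.Series(values[keep], index=idx[keep], name="value")
    extra = None
    if spec.include_humidity:
        # anti-phase with temperature: warm hours are drier
        rh = np.clip(95.0 - 2.5 * (values[keep] - 10.0)
                     + rng.normal(0, 1.5, size=keep.sum()), 5.0, 100.0)
        extra = pd.DataFrame({"humidity_pct": rh}, index=series.index)
    return SensorSeries(station=name, role=spec.role, crop=spec.crop,
                        variable=spec.variable, values=series, extra=extra)


def generate_sensor_suite(spec_map: Dict[str, SensorSimSpec]) -> List[SensorSeries]:
    """One simulated series per station.

    All stations must share a common time window; station names are the
    mapping keys, so duplicates are impossible by construction (a
    sequence of pairs with repeated names is rejected).
    """
    if not isinstance(spec_map, dict):
        pairs = list(spec_map)
        names = [n for n, _ in pairs]
        if len(set(names)) != len(names):
            raise PhenoroofError("overlapping station names")
        spec_map = dict(pairs)
    if not spec_map:
        raise PhenoroofError("no stations specified")
    windows = {(pd.Timestamp(s.start), pd.Timestamp(s.end))
               for s in spec_map.values()}
    if len(windows) != 1:
        raise PhenoroofError("all stations must share a common time window")
    return [_simulate_station(name, spec) for name, spec in spec_map.items()]
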
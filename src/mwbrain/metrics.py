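"""Quantitative image-quality metrics and reconstruction-accuracy maps.

Three figures of merit quantify a reconstructed image against a known
target region Omega_target within the head area Omega_head:

* gamma -- signal to maximum clutter: max intensity inside Omega_target
  over max intensity in Omega_head \\ Omega_target.  gamma > 1 means the
  image's global maximum falls inside the true target (correct
  localization); gamma < 1 means incorrect localization.
* Q -- average signal-to-clutter ratio: mean target intensity over mean
  clutter intensity.
* delta -- localization error: Euclidean distance (mm) from the true
  target centre to the maximum-intensity cell centre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .geometry import ImagingGrid
from .imaging import ReconstructedImage

__all__ = [
    "TargetRegion",
    "ImageMetrics",
    "AccuracyMap",
    "rectangle_target",
    "signal_to_max_clutter",
    "avg_signal_to_clutter",
    "localization_error",
    "evaluate_image",
]


@dataclass
class TargetRegion:
    """Boolean target mask Omega_target with its true central location (mm)."""

    mask: np.ndarray  # (P, Q) bool
    true_center: np.ndarray  # (2,) mm

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.true_center = np.asarray(self.true_center, dtype=float)
        if not self.mask.any():
            raise ValueError("target mask is empty")


@dataclass
class ImageMetrics:
    gamma: float
    q_ratio: float
    delta_mm: float
    argmax_location: np.ndarray
    localized_correctly: bool


@dataclass
class AccuracyMap:
    """Per-target-position metrics over a systematic sweep of target centres."""

    positions: np.ndarray  # (n, 2) mm
    metrics: List[ImageMetrics]
    kind: str = "gamma"

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.metrics):
            raise ValueError("one metrics record per position required")

    def values(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.metrics])


def rectangle_target(
    grid: ImagingGrid, center, width: float, height: float,
    head: Optional[np.ndarray] = None,
) -> TargetRegion:
    """Axis-aligned rectangular target region (the inserted-bleed footprint)."""
    cx, cy = center
    xs = grid.x_centers
    ys = grid.y_centers
    in_x = np.abs(xs - cx) <= width / 2.0
    in_y = np.abs(ys - cy) <= height / 2.0
    mask = np.outer(in_x, in_y)
    if head is not None:
        mask &= head
    return TargetRegion(mask=mask, true_center=np.asarray(center, dtype=float))


def _check_regions(image: ReconstructedImage, target: TargetRegion):
    clutter = image.mask & ~target.mask
    inside = target.mask & image.mask
    if not inside.any() or not clutter.any():
        raise ValueError("target and clutter regions must both be nonempty")
    return inside, clutter


def signal_to_max_clutter(image: ReconstructedImage, target: TargetRegion) -> float:
    """gamma: max target intensity / max clutter intensity (inf if clutter-free)."""
    inside, clutter = _check_regions(image, target)
    num = float(image.intensity[inside].max())
    den = float(image.intensity[clutter].max())
    if den == 0.0:
        return float("inf")
    return num / den


def avg_signal_to_clutter(image: ReconstructedImage, target: TargetRegion) -> float:
    """Q: mean target intensity / mean clutter intensity."""
    inside, clutter = _check_regions(image, target)
    den = float(image.intensity[clutter].mean())
    if den == 0.0:
        return float("inf")
    return float(image.intensity[inside].mean()) / den


def localization_error(image: ReconstructedImage, target: TargetRegion) -> float:
    """delta: distance (mm) from the true centre to the maximum-intensity cell."""
    if image.intensity.max() == 0:
        raise ValueError("localization error undefined for an all-zero image")
    return float(np.linalg.norm(image.argmax_location() - target.true_center))


def evaluate_image(image: ReconstructedImage, target: TargetRegion) -> ImageMetrics:
    gamma = signal_to_max_clutter(image, target)
    q = avg_signal_to_clutter(image, target)
    delta = localization_error(image, target)
    return ImageMetrics(
        gamma=gamma,
        q_ratio=q,
        delta_mm=delta,
        argmax_location=image.argmax_location(),
        localized_correctly=gamma > 1.0,
    )


def accuracy_map(
    positions: Sequence,
    phantom_base,
    geometry,
    grid: ImagingGrid,
    model,
    sweep=None,
    forward_cfg=None,
    target_size=(20.0, 20.0),
    table=None,
    align: bool = True,
) -> AccuracyMap:
    """Reconstruction-accuracy map over a systematic sweep of target centres.

    For each candidate centre a blood target is inserted into the phantom,
    the monostatic scan is simulated, the image is reconstructed with the
    supplied permittivity model, and (gamma, Q, delta) are evaluated
    against the inserted rectangle.  The travel-time table depends only on
    the geometry/boundary/grid/model, so it is built once and reused.
    A differential map between two models is simply the element-wise
    difference of two runs over the same positions.
    """
    from .imaging import reconstruct_pipeline
    from .phantom import ForwardConfig, insert_target, simulate_reflection
    from .sigproc import FrequencySweep
    from .traveltime import build_travel_time_table

    sweep = sweep or FrequencySweep()
    forward_cfg = forward_cfg or ForwardConfig()
    boundary = phantom_base.boundary
    if table is None:
        table = build_travel_time_table(geometry, boundary, grid, model)
    hmask = table.mask
    records = []
    for center in positions:
        ph = insert_target(phantom_base, center, *target_size)
        data = simulate_reflection(ph, geometry, sweep, forward_cfg)
        res = reconstruct_pipeline(
            data, boundary, grid, model, table=table, align=align
        )
        region = rectangle_target(grid, center, *target_size, head=hmask)
        records.append(evaluate_image(res.image, region))
    return AccuracyMap(
        positions=np.asarray(list(positions), dtype=float), metrics=records
    )
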
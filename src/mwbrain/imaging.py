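"""Delay-and-sum back-projection image formation.

For every in-head grid cell the processed scattered signals are sampled at
the hypothesised monostatic round-trip delay from each antenna and summed
coherently; a correct scatterer hypothesis adds in phase and produces a
large value, a wrong one averages towards zero.  The absolute value is
taken after the summation (no envelope detection), preserving the
cancellation behaviour the clutter suppression relies on, and the image is
max-normalised so the highest in-head intensity is 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import HeadBoundary, ImagingGrid
from .permittivity import PermittivityModel
from .sigproc import (
    ReflectionDataset,
    TimeSignals,
    adjacent_average_subtract,
    normalize_gain,
    to_time_domain,
)
from .traveltime import TravelTimeTable, build_travel_time_table

__all__ = ["ReconstructedImage", "das_reconstruct", "reconstruct_pipeline", "PipelineResult"]


@dataclass
class ReconstructedImage:
    """P x Q nonnegative intensity map on the imaging grid.

    When ``normalized`` the maximum over in-head cells is 1; outside-head
    cells are 0.  ``raw_max`` keeps the pre-normalisation maximum, whose
    absolute scale separates strong coherent targets from target-free heads.
    """

    intensity: np.ndarray  # (P, Q) >= 0
    grid: ImagingGrid
    mask: np.ndarray  # (P, Q) bool
    normalized: bool
    raw_max: float

    def argmax_location(self) -> np.ndarray:
        """Cell-centre coordinates (mm) of the maximum intensity.

        Ties resolve to the lowest (p, q) index (C-order first occurrence).
        """
        p, q = np.unravel_index(int(np.argmax(self.intensity)), self.intensity.shape)
        return np.array([self.grid.x_centers[p], self.grid.y_centers[q]])


def das_reconstruct(
    signals: TimeSignals, table: TravelTimeTable, mask: Optional[np.ndarray] = None
) -> ReconstructedImage:
    """Coherent delay-and-sum of the scattered signals over the travel-time table.

    Signal values at non-integer delay indices are linearly interpolated;
    delays beyond the record support contribute zero.
    """
    if mask is None:
        mask = table.mask
    n = signals.samples.shape[0]
    if table.times.shape[0] != n:
        raise ValueError("signals and travel-time table disagree on antenna count")
    k = signals.n_samples
    p, q = table.times.shape[1:]
    cells_t = table.times[:, mask]  # (N, C) round-trip seconds
    acc = np.zeros(cells_t.shape[1], dtype=complex)
    for i in range(n):
        idx = cells_t[i] / signals.dt
        valid = (idx >= 0) & (idx <= k - 1)
        s = signals.samples[i]
        xi = idx[valid]
        acc[valid] += np.interp(xi, np.arange(k), s.real) + 1j * np.interp(
            xi, np.arange(k), s.imag
        )
    intensity = np.zeros((p, q))
    intensity[mask] = np.abs(acc)
    raw_max = float(intensity.max())
    normalized = raw_max > 0
    if normalized:
        intensity = intensity / raw_max
    return ReconstructedImage(
        intensity=intensity, grid=table.grid, mask=mask, normalized=normalized,
        raw_max=raw_max,
    )


@dataclass
class PipelineResult:
    image: ReconstructedImage
    time_signals: Optional[TimeSignals] = None
    scattered: Optional[TimeSignals] = None
    normalized_signals: Optional[TimeSignals] = None
    table: Optional[TravelTimeTable] = None


def reconstruct_pipeline(
    data: ReflectionDataset,
    boundary: HeadBoundary,
    grid: ImagingGrid,
    model: PermittivityModel,
    antenna_delay: float = 0.0,
    align: bool = True,
    k_samples: Optional[int] = None,
    window: str = "none",
    table: Optional[TravelTimeTable] = None,
    keep_intermediates: bool = False,
) -> PipelineResult:
    """Full processing chain: IDFT, clutter removal, gain normalisation, DAS.

    A precomputed ``table`` may be supplied to amortise the travel-time
    computation across repeated reconstructions with the same geometry,
    boundary, grid and model.
    """
    ts = to_time_domain(data, k_samples=k_samples, window=window)
    scat = adjacent_average_subtract(ts, align=align)
    norm = normalize_gain(scat)
    if table is None:
        table = build_travel_time_table(
            data.geometry, boundary, grid, model, antenna_delay=antenna_delay
        )
    image = das_reconstruct(norm, table)
    if keep_intermediates:
        return PipelineResult(
            image=image, time_signals=ts, scattered=scat, normalized_signals=norm,
            table=table,
        )
    return PipelineResult(image=image, table=table)
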
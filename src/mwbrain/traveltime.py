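"""Fermat shortest-electrical-path travel times from antennas to grid cells.

The propagation path from an antenna to a hypothetical point inside the
head is decomposed into a free-space route to a signal entry point on the
skin and a single straight in-head segment from the entry point to the
target, whose delay uses the point-of-entry effective permittivity model
evaluated at the segment length.  Following Fermat's principle the entry
point is chosen to minimise the total electrical path; candidates are
restricted to the boundary vertices inside the antenna's line-of-sight
(tangent-point) arc, and the minimisation is exhaustive over that discrete
set so the result is deterministic at a given boundary resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import C0_MM
from .geometry import (
    HeadBoundary,
    ImagingGrid,
    InvalidGeometryError,
    ScanGeometry,
    head_mask,
    line_of_sight_points,
)
from .permittivity import PermittivityModel

__all__ = ["TravelTimeTable", "fermat_travel_time", "build_travel_time_table"]

_CELL_CHUNK = 40_000

#: Default half-beamwidth (degrees) limiting the entry-point search to the
#: part of the line-of-sight arc the directional antenna actually
#: illuminates.  The sensing antenna radiates unidirectionally with 80--100
#: degree half-power beamwidths, so boundary vertices more than ~45 degrees
#: off boresight receive negligible energy; admitting them as Fermat entry
#: candidates lets the minimisation pick glancing "creeping" paths (long,
#: fast air legs) that carry no echo energy and de-coheres the summation
#: for deep cells.  Set to None for the unrestricted tangent-arc search.
DEFAULT_BEAM_HALFWIDTH_DEG = 45.0


def _one_way_times(antenna, cells, boundary, model, antenna_delay,
                   beam_halfwidth_deg=DEFAULT_BEAM_HALFWIDTH_DEG):
    """Minimum one-way times (s) from one antenna to an (n, 2) array of cells."""
    ant = np.asarray(antenna, dtype=float)
    los = line_of_sight_points(ant, boundary)
    verts = boundary.vertices[los]  # (V, 2)
    if beam_halfwidth_deg is not None:
        bore = boundary.centroid - ant
        bore = bore / np.linalg.norm(bore)
        d = verts - ant
        off = np.degrees(
            np.abs(np.arctan2(d[:, 0] * bore[1] - d[:, 1] * bore[0],
                              d[:, 0] * bore[0] + d[:, 1] * bore[1]))
        )
        keep = off <= beam_halfwidth_deg
        if not keep.any():
            keep[np.argmin(off)] = True
        verts = verts[keep]
    d_air = np.linalg.norm(verts - ant, axis=1)  # (V,)
    a_e = np.linalg.norm(verts - boundary.centroid, axis=1)  # (V,)
    out = np.empty(len(cells))
    for lo in range(0, len(cells), _CELL_CHUNK):
        blk = cells[lo : lo + _CELL_CHUNK]  # (C, 2)
        seg = np.linalg.norm(verts[:, None, :] - blk[None, :, :], axis=2)  # (V, C)
        eps = model.evaluate(seg, a_e[:, None])
        t = d_air[:, None] / C0_MM + seg * np.sqrt(eps) / C0_MM
        out[lo : lo + _CELL_CHUNK] = t.min(axis=0)
    return antenna_delay + out


def fermat_travel_time(
    antenna,
    point,
    boundary: HeadBoundary,
    model: PermittivityModel,
    antenna_delay: float = 0.0,
    beam_halfwidth_deg=DEFAULT_BEAM_HALFWIDTH_DEG,
) -> float:
    """One-way Fermat propagation time (s) from the antenna to an in-head point."""
    pt = np.asarray(point, dtype=float)
    if not boundary.contains(pt):
        raise ValueError("target point must be inside or on the boundary")
    return float(
        _one_way_times(
            antenna, pt[None, :], boundary, model, antenna_delay,
            beam_halfwidth_deg=beam_halfwidth_deg,
        )[0]
    )


@dataclass
class TravelTimeTable:
    """Round-trip times 2*tau for every antenna and in-head grid cell.

    ``times[n, p, q]`` is the monostatic round-trip time in seconds;
    outside-head cells hold NaN and are flagged False in ``mask``.
    """

    times: np.ndarray  # (N, P, Q) seconds, NaN outside head
    mask: np.ndarray  # (P, Q) bool
    antenna_delay: float
    geometry: ScanGeometry
    grid: ImagingGrid
    boundary: HeadBoundary
    model: PermittivityModel

    def __post_init__(self) -> None:
        valid = self.times[:, self.mask]
        if valid.size and (
            not np.all(np.isfinite(valid))
            or np.any(valid < 2.0 * self.antenna_delay)
        ):
            raise ValueError("in-head travel times must be finite and >= 2*antenna_delay")

    def save_npz(self, path) -> None:
        np.savez_compressed(
            Path(path), times=self.times, mask=self.mask, antenna_delay=self.antenna_delay
        )


def build_travel_time_table(
    geometry: ScanGeometry,
    boundary: HeadBoundary,
    grid: ImagingGrid,
    model: PermittivityModel,
    antenna_delay: float = 0.0,
    beam_halfwidth_deg=DEFAULT_BEAM_HALFWIDTH_DEG,
) -> TravelTimeTable:
    """Exhaustive-entry-point round-trip time table over the in-head cells."""
    mask = head_mask(grid, boundary)
    p, q = grid.dims
    cells = grid.cell_centers()[mask]  # (C, 2)
    times = np.full((geometry.n_positions, p, q), np.nan)
    for n, ant in enumerate(geometry.positions):
        if boundary.contains(ant):
            raise InvalidGeometryError(f"antenna {n} lies inside the head boundary")
        times[n, mask] = 2.0 * _one_way_times(
            ant, cells, boundary, model, antenna_delay,
            beam_halfwidth_deg=beam_halfwidth_deg,
        )
    return TravelTimeTable(
        times=times,
        mask=mask,
        antenna_delay=antenna_delay,
        geometry=geometry,
        grid=grid,
        boundary=boundary,
        model=model,
    )
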
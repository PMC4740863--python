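"""Scan geometries, head boundary and imaging grid.

All coordinates live in the 2-D plane of the scanned head layer, in
millimetres, with the origin at the scan centre and angles measured
counter-clockwise from the +x axis.  The head outline is always stored as
a discrete closed polygon (the boundary vector ``b_i``), even for analytic
shapes, because the line-of-sight/tangent-point construction and the Fermat
entry-point search operate on discrete boundary vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "ScanGeometry",
    "HeadBoundary",
    "ImagingGrid",
    "make_circular_scan",
    "make_parabolic_scan",
    "make_offset_scan",
    "ellipse_boundary",
    "circle_boundary",
    "line_of_sight_points",
    "head_mask",
]

_EQUIANGULAR_TOL_DEG = 1e-9


class InvalidGeometryError(ValueError):
    """Raised when a geometric precondition is violated."""


def _polar_angles_deg(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    d = points - center
    return np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 360.0


@dataclass
class ScanGeometry:
    """Equiangular monostatic scan: N antenna positions around a centre.

    Positions are ordered by increasing polar angle about ``center`` and the
    angular step between adjacent positions is constant (the acquisition is
    equiangular; the standoff from the skin makes it equidistant as well).
    """

    positions: np.ndarray  # (N, 2) mm
    center: np.ndarray  # (2,) mm
    boresights: np.ndarray = field(default=None)  # (N, 2) unit vectors

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        n = len(self.positions)
        if n < 3:
            raise InvalidGeometryError(f"need at least 3 positions, got {n}")
        ang = _polar_angles_deg(self.positions, self.center)
        order = np.argsort(ang)
        if not np.array_equal(order, np.arange(n)):
            self.positions = self.positions[order]
            ang = ang[order]
        steps = np.diff(np.concatenate([ang, [ang[0] + 360.0]]))
        if np.max(np.abs(steps - 360.0 / n)) > _EQUIANGULAR_TOL_DEG:
            raise InvalidGeometryError("positions are not equiangular")
        if self.boresights is None:
            v = self.center - self.positions
            self.boresights = v / np.linalg.norm(v, axis=1, keepdims=True)
        else:
            self.boresights = np.asarray(self.boresights, dtype=float)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def angular_step(self) -> float:
        """Angular difference between adjacent positions, degrees."""
        return 360.0 / self.n_positions

    @property
    def angles_deg(self) -> np.ndarray:
        return _polar_angles_deg(self.positions, self.center)


@dataclass
class HeadBoundary:
    """Closed polygon b_i, i = 1..I, tracing the skin--air interface."""

    vertices: np.ndarray  # (I, 2) mm, counter-clockwise

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if len(self.vertices) < 16:
            raise InvalidGeometryError(
                f"boundary needs >= 16 vertices, got {len(self.vertices)}"
            )
        poly = Polygon(self.vertices)
        if not poly.is_simple or not poly.is_valid:
            raise InvalidGeometryError("boundary polygon is self-intersecting")
        # enforce counter-clockwise orientation
        if not poly.exterior.is_ccw:
            self.vertices = self.vertices[::-1].copy()
            poly = Polygon(self.vertices)
        self._polygon = poly
        self._centroid = np.array(poly.centroid.coords[0])

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def centroid(self) -> np.ndarray:
        return self._centroid

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def contains(self, point) -> bool:
        """True if the point is inside or on the boundary."""
        return bool(self._polygon.covers(Point(point)))

    def radius_at(self, angle_deg: float) -> float:
        """Distance from the centroid to the boundary along a polar ray."""
        th = np.radians(angle_deg)
        far = self._centroid + 1e4 * np.array([np.cos(th), np.sin(th)])
        ray = LineString([self._centroid, far])
        hit = ray.intersection(self._polygon.exterior)
        if hit.is_empty:
            raise InvalidGeometryError("ray does not intersect boundary")
        pts = (
            [hit]
            if isinstance(hit, Point)
            else list(getattr(hit, "geoms", []))
        )
        dists = []
        for g in pts:
            for c in getattr(g, "coords", [g.coords[0]]):
                dists.append(np.hypot(c[0] - self._centroid[0], c[1] - self._centroid[1]))
        return float(min(dists))


@dataclass
class ImagingGrid:
    """Regular imaging grid of P x Q square cells centred on the origin.

    Cells use a half-open convention [x, x+cell) with the centre at
    x + cell/2; the default is the 300 x 300 mm area at 0.5 mm resolution.
    """

    extent: tuple = (300.0, 300.0)  # (width, height) mm
    cell_size: float = 0.5  # mm

    def __post_init__(self) -> None:
        w, h = self.extent
        p = w / self.cell_size
        q = h / self.cell_size
        if abs(p - round(p)) > 1e-9 or abs(q - round(q)) > 1e-9:
            raise InvalidGeometryError("extent must be an integer number of cells")
        self._p = int(round(p))
        self._q = int(round(q))

    @property
    def dims(self) -> tuple:
        """(P, Q) = cells along x, cells along y."""
        return (self._p, self._q)

    @property
    def x_centers(self) -> np.ndarray:
        w = self.extent[0]
        return -w / 2.0 + (np.arange(self._p) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        h = self.extent[1]
        return -h / 2.0 + (np.arange(self._q) + 0.5) * self.cell_size

    def cell_centers(self) -> np.ndarray:
        """(P, Q, 2) array of cell-centre coordinates."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return np.stack([xx, yy], axis=-1)

    def index_of(self, point) -> tuple:
        """(p, q) index of the cell containing ``point``."""
        x, y = point
        p = int(np.floor((x + self.extent[0] / 2.0) / self.cell_size))
        q = int(np.floor((y + self.extent[1] / 2.0) / self.cell_size))
        if not (0 <= p < self._p and 0 <= q < self._q):
            raise InvalidGeometryError(f"point {point} outside grid")
        return p, q


# ---------------------------------------------------------------------------
# scan constructors
# ---------------------------------------------------------------------------

def _positions_from_radii(radii: np.ndarray, n: int, center) -> ScanGeometry:
    th = np.radians(np.arange(n) * 360.0 / n)
    c = np.asarray(center, dtype=float)
    pos = c + radii[:, None] * np.stack([np.cos(th), np.sin(th)], axis=1)
    return ScanGeometry(positions=pos, center=c)


def make_circular_scan(radius: float, n: int, center=(0.0, 0.0)) -> ScanGeometry:
    """Equiangular circular scan of ``n`` positions at a fixed radius."""
    if radius <= 0:
        raise InvalidGeometryError("radius must be positive")
    if n < 3:
        raise InvalidGeometryError("need n >= 3")
    return _positions_from_radii(np.full(n, float(radius)), n, center)


def make_parabolic_scan(r1: float, r2: float, n: int, center=(0.0, 0.0)) -> ScanGeometry:
    """Parabolic scan profile with front radius ``r1`` and back radius ``r2``.

    The profile is the intersection of the n equiangular rays (step 360/n
    degrees) with a polar curve whose radius varies parabolically in the
    wrapped angle: r(theta) = r1 + (r2 - r1) * (theta~ / pi)**2, where
    theta~ is the angle wrapped to (-pi, pi].  r1 = r2 degenerates to a
    circle.
    """
    if r1 <= 0 or r2 <= 0:
        raise InvalidGeometryError("radii must be positive")
    if n < 3:
        raise InvalidGeometryError("need n >= 3")
    th = np.arange(n) * 2.0 * np.pi / n
    wrapped = np.angle(np.exp(1j * th))  # (-pi, pi]
    radii = r1 + (r2 - r1) * (wrapped / np.pi) ** 2
    return _positions_from_radii(radii, n, center)


def make_offset_scan(boundary: HeadBoundary, standoff: float, n: int) -> ScanGeometry:
    """Equiangular, equidistant scan: constant standoff from the skin.

    Positions lie on the n equiangular rays from the boundary centroid, at
    the boundary radius plus ``standoff``.  This reproduces the acquisition
    in which every reading is taken from the same distance to the skin so
    that adjacent positions face near-identical air--skin reflections.
    """
    if standoff <= 0:
        raise InvalidGeometryError("standoff must be positive")
    if n < 3:
        raise InvalidGeometryError("need n >= 3")
    angles = np.arange(n) * 360.0 / n
    radii = np.array([boundary.radius_at(a) + standoff for a in angles])
    return _positions_from_radii(radii, n, boundary.centroid)


# ---------------------------------------------------------------------------
# boundary constructors
# ---------------------------------------------------------------------------

def ellipse_boundary(a: float, b: float, n: int = 360, center=(0.0, 0.0)) -> HeadBoundary:
    """Elliptic head outline with semi-axes a (x) and b (y), sampled at n vertices."""
    if a <= 0 or b <= 0:
        raise InvalidGeometryError("semi-axes must be positive")
    th = np.arange(n) * 2.0 * np.pi / n
    c = np.asarray(center, dtype=float)
    verts = c + np.stack([a * np.cos(th), b * np.sin(th)], axis=1)
    return HeadBoundary(vertices=verts)


def circle_boundary(radius: float, n: int = 360, center=(0.0, 0.0)) -> HeadBoundary:
    return ellipse_boundary(radius, radius, n=n, center=center)


# ---------------------------------------------------------------------------
# line of sight / masking
# ---------------------------------------------------------------------------

def line_of_sight_points(antenna, boundary: HeadBoundary) -> np.ndarray:
    """Indices of boundary vertices on the near-side arc between the tangent points.

    The tangent points are the angular extremes of the boundary as seen from
    the antenna (the maximum angular cone theta_max); the returned set is the
    arc of vertices between them, inclusive, on the side nearer the antenna.
    The construction is purely angular: on a concave outline, vertices inside
    the cone but occluded are still included.
    """
    ant = np.asarray(antenna, dtype=float)
    if boundary.contains(ant):
        raise InvalidGeometryError("antenna must be strictly outside the boundary")
    d = boundary.vertices - ant
    ref = boundary.centroid - ant
    ref_ang = np.arctan2(ref[1], ref[0])
    rel = np.angle(np.exp(1j * (np.arctan2(d[:, 1], d[:, 0]) - ref_ang)))
    t_lo = int(np.argmin(rel))
    t_hi = int(np.argmax(rel))
    n = boundary.n_vertices

    def arc(i, j):
        if i <= j:
            return np.arange(i, j + 1)
        return np.concatenate([np.arange(i, n), np.arange(0, j + 1)])

    arc_a = arc(t_lo, t_hi)
    arc_b = arc(t_hi, t_lo)
    dist = np.linalg.norm(d, axis=1)
    near = arc_a if dist[arc_a].mean() <= dist[arc_b].mean() else arc_b
    return near


def head_mask(grid: ImagingGrid, boundary: HeadBoundary) -> np.ndarray:
    """Boolean P x Q field: True where the cell centre lies in the head.

    Cell centres on the boundary itself count as inside.
    """
    minx, miny, maxx, maxy = boundary.polygon.bounds
    w, h = grid.extent
    if minx < -w / 2 or maxx > w / 2 or miny < -h / 2 or maxy > h / 2:
        raise InvalidGeometryError("boundary exceeds the grid extent")
    cc = grid.cell_centers()
    p, q = grid.dims
    flat = cc.reshape(-1, 2)
    inside = shapely.intersects_xy(boundary.polygon, flat[:, 0], flat[:, 1])
    return inside.reshape(p, q)
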
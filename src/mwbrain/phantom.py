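"""Synthetic 2-D layered head phantom and ray-based monostatic forward model.

The phantom is a desk-scale stand-in for full-wave scattering data: an
elliptic head section with concentric skin / fat / skull / CSF layers, a
gray-matter shell over a white-matter core, and an optional rectangular
blood target emulating an intracranial bleed.  The forward model is a
Born-type single-scattering ray model: each antenna position receives a
dominant air--skin echo (with optional per-position skin-thickness jitter),
an optional target echo at the straight-ray delay through the true layered
tissues, and optional weak clutter scatterers.  Ground-truth delays are
therefore known exactly, which is what the reconstruction tests need, and
the propagation physics (straight rays through true layers) deliberately
differs from the imaging model (Fermat two-segment paths with the
effective-permittivity model) so that model-mismatch experiments are
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.affinity import scale as _scale

from .constants import C0_MM, EPS0, MU0
from .geometry import HeadBoundary, InvalidGeometryError, ScanGeometry, ellipse_boundary
from .permittivity import PermittivityCurve
from .sigproc import FrequencySweep, PulseSpec, ReflectionDataset, pulse_spectrum

__all__ = [
    "TissueTable",
    "HeadPhantom2D",
    "ForwardConfig",
    "DEFAULT_TISSUES",
    "tissue_permittivity",
    "wave_impedance",
    "impedance_contrast",
    "make_head_phantom",
    "insert_target",
    "straight_ray_delay",
    "simulate_reflection",
    "permittivity_curves_from_phantom",
]

_BAND = (0.75e9, 2.55e9)

# Band-edge relative permittivities (0.75 GHz, 2.55 GHz) and a default
# conductivity (S/m).  Skin, CSF, dura and muscle use the band ranges the
# head model is built around; the remaining tissues and all conductivities
# are fixture defaults in the spirit of standard tissue databases and are
# configurable.
DEFAULT_TISSUES: Dict[str, Tuple[float, float, float]] = {
    "skin": (50.0, 44.0, 1.0),
    "fat": (5.5, 5.2, 0.05),
    "skull": (12.4, 11.3, 0.2),
    "csf": (69.0, 66.2, 2.5),
    "dura": (44.0, 41.9, 1.0),
    "gray": (52.3, 48.4, 1.0),
    "white": (38.6, 35.5, 0.6),
    "muscle": (55.0, 52.6, 1.0),
    "blood": (61.1, 57.2, 1.6),
}


@dataclass(frozen=True)
class TissueTable:
    """Per-tissue band-edge permittivities and conductivities."""

    entries: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES)
    )

    def __post_init__(self) -> None:
        for name, (e_lo, e_hi, sig) in self.entries.items():
            if e_lo < 1.0 or e_hi < 1.0 or not np.isfinite([e_lo, e_hi]).all():
                raise ValueError(f"invalid permittivities for tissue {name!r}")
            if sig < 0:
                raise ValueError(f"negative conductivity for tissue {name!r}")


def tissue_permittivity(tissue: str, f: float, table: Optional[TissueTable] = None) -> float:
    """Linear band interpolation of a tissue's relative permittivity at f (Hz)."""
    table = table or TissueTable()
    if tissue not in table.entries:
        raise ValueError(f"unknown tissue {tissue!r}")
    lo, hi = _BAND
    if not (lo <= f <= hi):
        raise ValueError(f"frequency {f} outside the {lo}-{hi} Hz band")
    e_lo, e_hi, _ = table.entries[tissue]
    return float(e_lo + (e_hi - e_lo) * (f - lo) / (hi - lo))


def wave_impedance(eps_r: float, sigma: float, f: float) -> float:
    """|eta| of a lossy dielectric: eta = sqrt(j w mu0 / (sigma + j w eps0 eps_r))."""
    if eps_r < 1.0 or sigma < 0.0 or f <= 0.0:
        raise ValueError("need eps_r >= 1, sigma >= 0, f > 0")
    w = 2.0 * np.pi * f
    eta = np.sqrt(1j * w * MU0 / (sigma + 1j * w * EPS0 * eps_r))
    return float(np.abs(eta))


def impedance_contrast(eta_target: float, eta_background: float) -> float:
    """Percent wave-impedance contrast between a target and its background."""
    if eta_target <= 0.0 or eta_background <= 0.0:
        raise ValueError("impedances must be positive")
    return 100.0 * (eta_background - eta_target) / eta_target


@dataclass(frozen=True)
class TargetSpec:
    center: Tuple[float, float]
    width: float = 20.0
    height: float = 20.0
    tissue: str = "blood"


@dataclass
class HeadPhantom2D:
    """Layered elliptic head section with an optional rectangular blood target."""

    boundary: HeadBoundary
    semi_axes: Tuple[float, float]
    layer_thicknesses: Dict[str, float]  # skin, fat, skull, csf (mm)
    gray_shell: float  # mm of gray matter inside the CSF
    target: Optional[TargetSpec] = None
    skin_jitter_sd: float = 0.0  # mm, per-position skin-thickness jitter
    tissues: TissueTable = field(default_factory=TissueTable)
    n_vertices: int = 180

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        shell = sum(self.layer_thicknesses.values())
        if any(t <= 0 for t in self.layer_thicknesses.values()):
            raise InvalidGeometryError("layer thicknesses must be positive")
        if shell + self.gray_shell >= min(a, b):
            raise InvalidGeometryError("layers exceed the semi-minor axis")
        self._build_regions()
        if self.target is not None:
            rect = self._target_polygon()
            if not self._interior.covers(rect):
                raise InvalidGeometryError("target must lie fully inside the interior")
            self._build_regions()  # rebuild with the target carved out

    def _ellipse(self, inset: float) -> Polygon:
        a, b = self.semi_axes
        th = np.arange(self.n_vertices) * 2.0 * np.pi / self.n_vertices
        pts = np.stack([(a - inset) * np.cos(th), (b - inset) * np.sin(th)], axis=1)
        return Polygon(pts)

    def _target_polygon(self) -> Polygon:
        t = self.target
        cx, cy = t.center
        hw, hh = t.width / 2.0, t.height / 2.0
        return Polygon(
            [(cx - hw, cy - hh), (cx + hw, cy - hh), (cx + hw, cy + hh), (cx - hw, cy + hh)]
        )

    def _build_regions(self) -> None:
        order = ["skin", "fat", "skull", "csf"]
        insets = np.cumsum([self.layer_thicknesses[k] for k in order])
        shells = [self._ellipse(0.0)] + [self._ellipse(i) for i in insets]
        gray_in = self._ellipse(insets[-1] + self.gray_shell)
        regions: List[Tuple[str, Polygon]] = []
        for name, outer, inner in zip(order, shells[:-1], shells[1:]):
            regions.append((name, outer.difference(inner)))
        regions.append(("gray", shells[-1].difference(gray_in)))
        regions.append(("white", gray_in))
        # interior = everything inside the CSF's inner wall (gray + white)
        self._interior = shells[-1]
        if self.target is not None:
            rect = self._target_polygon()
            regions = [(n, p.difference(rect)) for n, p in regions]
            regions.append((self.target.tissue, rect))
        self._regions = regions
        self._outer = shells[0]

    @property
    def regions(self) -> List[Tuple[str, Polygon]]:
        return self._regions

    @property
    def outer_polygon(self) -> Polygon:
        return self._outer

    def tissue_at(self, point) -> str:
        """Tissue name at an interior point (regions partition the section)."""
        p = Point(point)
        # target rectangle (appended last) takes precedence
        for name, poly in reversed(self._regions):
            if poly.covers(p):
                return name
        raise InvalidGeometryError(f"point {point} outside the phantom")

    def background_tissue_at(self, point) -> str:
        """Tissue that would occupy ``point`` if no target were present."""
        if self.target is None:
            return self.tissue_at(point)
        return replace(self, target=None).tissue_at(point)


def make_head_phantom(
    a: float = 90.0,
    b: float = 110.0,
    skin: float = 2.0,
    fat: float = 1.0,
    skull: float = 7.0,
    csf: float = 2.0,
    gray_shell: float = 30.0,
    target: Optional[TargetSpec] = None,
    skin_jitter_sd: float = 0.0,
    tissues: Optional[TissueTable] = None,
    n_vertices: int = 180,
) -> HeadPhantom2D:
    """Default anatomy: 90 x 110 mm semi-axes, ~10 mm skin/fat/skull shell."""
    boundary = ellipse_boundary(a, b, n=n_vertices)
    return HeadPhantom2D(
        boundary=boundary,
        semi_axes=(a, b),
        layer_thicknesses={"skin": skin, "fat": fat, "skull": skull, "csf": csf},
        gray_shell=gray_shell,
        target=target,
        skin_jitter_sd=skin_jitter_sd,
        tissues=tissues or TissueTable(),
        n_vertices=n_vertices,
    )


def insert_target(
    phantom: HeadPhantom2D, center, width: float = 20.0, height: float = 20.0
) -> HeadPhantom2D:
    """Return a phantom with a blood target at ``center`` (replaces any existing)."""
    spec = TargetSpec(center=tuple(center), width=width, height=height)
    return replace(phantom, target=spec)


def straight_ray_delay(
    antenna, point, phantom: HeadPhantom2D, f: float = 1.6e9
) -> float:
    """One-way straight-ray delay (s) through the true layered tissues.

    The segment antenna -> point is split at the layer intersections; each
    tissue segment contributes length * sqrt(eps(f)) / c, the free-space
    part length / c.
    """
    pt = Point(point)
    if not phantom.outer_polygon.covers(pt):
        raise ValueError("target point must lie inside the phantom")
    seg = LineString([tuple(np.asarray(antenna, float)), tuple(np.asarray(point, float))])
    total = seg.length
    inside = 0.0
    delay = 0.0
    for name, poly in phantom.regions:
        part = seg.intersection(poly)
        l = part.length
        if l > 0.0:
            inside += l
            delay += l * np.sqrt(tissue_permittivity(name, f, phantom.tissues)) / C0_MM
    air = max(total - inside, 0.0)
    return air / C0_MM + delay


@dataclass(frozen=True)
class ForwardConfig:
    """Knobs of the synthetic forward model."""

    pulse: PulseSpec = field(default_factory=PulseSpec)
    include_skin_echo: bool = True
    n_clutter: int = 0
    clutter_amp: float = 0.0
    seed: int = 0
    decay_exponent: float = 1.0  # cylindrical spreading in 2-D
    target_amp_scale: float = 1.0


def _fresnel(eps_a: float, eps_b: float) -> float:
    """Normal-incidence Fresnel reflection coefficient from medium a onto b."""
    na, nb = np.sqrt(eps_a), np.sqrt(eps_b)
    return (na - nb) / (na + nb)


def simulate_reflection(
    phantom: HeadPhantom2D,
    geometry: ScanGeometry,
    sweep: FrequencySweep,
    cfg: ForwardConfig,
) -> ReflectionDataset:
    """Monostatic reflection sweeps S_n(f) from the ray-based echo model.

    Per position the response is a sum of echoes A_e * P(f) * exp(-j 2 pi f
    2 tau_e): the air--skin echo at the straight-ray air delay with the
    skin Fresnel amplitude (skin thickness jittered per position, seeded),
    the target echo at the straight-ray delay to the target centre with an
    amplitude proportional to the blood/background Fresnel contrast and a
    distance-decay factor, and optional seeded clutter scatterers.
    Identical seeds give bit-identical datasets, and the target echo is
    strictly additive on top of the target-free response.
    """
    f = sweep.frequencies
    pf = pulse_spectrum(cfg.pulse, f)
    fc = cfg.pulse.f_c
    ss = np.random.SeedSequence(cfg.seed)
    jitter_rng, clutter_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    n = geometry.n_positions
    jitter = jitter_rng.standard_normal(n) * phantom.skin_jitter_sd

    eps_skin = tissue_permittivity("skin", fc, phantom.tissues)
    gamma_skin = _fresnel(1.0, eps_skin)

    # clutter scatterers: seeded points in the interior (drawn regardless of
    # use so the stream is stable across configurations)
    clutter_pts: List[np.ndarray] = []
    a, b = phantom.semi_axes
    while len(clutter_pts) < cfg.n_clutter:
        cand = clutter_rng.uniform([-a, -b], [a, b])
        if phantom._interior.covers(Point(cand)):
            clutter_pts.append(cand)
    clutter_amps = clutter_rng.uniform(0.5, 1.0, size=max(cfg.n_clutter, 1))

    target_contrast = None
    if phantom.target is not None:
        ctr = np.asarray(phantom.target.center, float)
        eps_bg = tissue_permittivity(
            phantom.background_tissue_at(ctr), fc, phantom.tissues
        )
        eps_t = tissue_permittivity(phantom.target.tissue, fc, phantom.tissues)
        target_contrast = _fresnel(eps_bg, eps_t)

    s11 = np.zeros((n, sweep.n_samples), dtype=complex)
    centroid = phantom.boundary.centroid
    for i, ant in enumerate(geometry.positions):
        echoes: List[Tuple[float, float]] = []  # (amplitude, one-way delay s)
        seg = LineString([tuple(ant), tuple(centroid)])
        d_air = seg.length - seg.intersection(phantom.outer_polygon).length
        if cfg.include_skin_echo:
            tau = (d_air + jitter[i] * np.sqrt(eps_skin)) / C0_MM
            echoes.append((gamma_skin / d_air**cfg.decay_exponent, tau))
        if phantom.target is not None:
            ctr = np.asarray(phantom.target.center, float)
            dist = float(np.linalg.norm(ant - ctr))
            tau = straight_ray_delay(ant, ctr, phantom, f=fc)
            echoes.append(
                (cfg.target_amp_scale * target_contrast / dist**cfg.decay_exponent, tau)
            )
        for j, pt in enumerate(clutter_pts):
            dist = float(np.linalg.norm(ant - pt))
            tau = straight_ray_delay(ant, pt, phantom, f=fc)
            echoes.append((cfg.clutter_amp * clutter_amps[j] / dist**cfg.decay_exponent, tau))
        for amp, tau in echoes:
            s11[i] += amp * pf * np.exp(-2j * np.pi * f * 2.0 * tau)
    return ReflectionDataset(s11=s11, sweep=sweep, geometry=geometry, snr_db=None)


def permittivity_curves_from_phantom(
    phantom: HeadPhantom2D,
    entry_angles_deg,
    depth_step: float = 3.0,
    depth_start: float = 15.0,
    depth_frac: float = 1.6,
    f: float = 1.6e9,
) -> List[PermittivityCurve]:
    """Effective-permittivity curves extracted from the phantom's own delays.

    Emulates the calibration procedure: for each entry angle a virtual
    source sits at the point of entry on the skin, probes are placed at
    increasing depths along the inward ray, the differential arrival times
    through the true layered tissues give (c dt / d)^2, and the resulting
    per-angle curves are what the unified model is fitted to.
    """
    curves = []
    centroid = phantom.boundary.centroid
    for ang in np.atleast_1d(entry_angles_deg):
        r = phantom.boundary.radius_at(float(ang))
        th = np.radians(float(ang))
        entry = centroid + r * np.array([np.cos(th), np.sin(th)])
        a_norm = float(np.linalg.norm(entry - centroid))
        inward = (centroid - entry) / a_norm
        depths = np.arange(depth_start, depth_frac * a_norm, depth_step)
        eps = []
        for d in depths:
            probe = entry + d * inward
            dt = straight_ray_delay(entry, probe, phantom, f=f)
            eps.append(float((C0_MM * dt / d) ** 2))
        curves.append(
            PermittivityCurve(
                entry_angle_deg=float(ang),
                distances_mm=depths,
                eps_values=np.array(eps),
                normal_depth_a_mm=a_norm,
            )
        )
    return curves
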
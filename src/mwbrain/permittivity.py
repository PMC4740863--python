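"""Point-of-entry effective head permittivity model.

A single dielectric constant that reproduces the true propagation delay
through the heterogeneous head depends on where the signal enters the skin
and how deep it has penetrated.  The model used here is a saturating
distance-based function of the penetration depth ``d`` for a given entry
point whose normal distance to the head centre is ``a``::

    eps_eff(d) = eps_max * (1 - c1 * exp(-c2 * d / a))

It starts from a small value at the point of entry (the thin skin is
followed by thick low-permittivity fat and skull), rises as the signal
meets the high-permittivity CSF and brain tissues, and saturates near
``eps_max``.  Beyond d = 2a (the far boundary) the value is clamped at the
d = 2a value.  The band-wide constants fitted to a realistic human head
over 0.75--2.55 GHz are eps_max = 46.8, c1 = 0.75, c2 = 6.4; the legacy
algorithms' constant head permittivity is represented by the ``fixed``
kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy.optimize import least_squares

from .constants import C0_MM

__all__ = [
    "PermittivityModel",
    "PermittivityCurve",
    "FitResult",
    "effective_permittivity",
    "extract_effective_permittivity",
    "fit_permittivity_model",
]


@dataclass(frozen=True)
class PermittivityModel:
    """Distance-based effective permittivity for one point of entry.

    kind = "variable" uses the saturating model; kind = "fixed" is the
    constant eps_fixed used by the legacy delay-and-sum algorithms.
    """

    eps_max: float = 46.8
    shape_c1: float = 0.75
    shape_c2: float = 6.4
    kind: str = "variable"
    eps_fixed: float = 45.0

    def __post_init__(self) -> None:
        if self.kind not in ("variable", "fixed"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "variable":
            if self.eps_max < 1.0:
                raise ValueError("eps_max must be >= 1")
            if not (0.0 <= self.shape_c1 < 1.0):
                raise ValueError("shape_c1 must lie in [0, 1)")
            if self.shape_c2 <= 0.0:
                raise ValueError("shape_c2 must be positive")
        elif self.eps_fixed < 1.0:
            raise ValueError("eps_fixed must be >= 1")

    def evaluate(self, d, a):
        """eps_eff at penetration depth d (mm) for entry-normal distance a (mm).

        Vectorized over ``d`` (and ``a`` with broadcasting); d is clamped to
        [0, 2a] since a ray cannot penetrate past the far boundary.
        """
        d = np.asarray(d, dtype=float)
        a = np.asarray(a, dtype=float)
        if np.any(a <= 0):
            raise ValueError("normal distance a must be positive")
        if np.any(d < 0):
            raise ValueError("penetration depth d must be >= 0")
        if self.kind == "fixed":
            return np.broadcast_to(np.float64(self.eps_fixed), np.broadcast_shapes(d.shape, a.shape)).copy()
        dd = np.minimum(d, 2.0 * a)
        return self.eps_max * (1.0 - self.shape_c1 * np.exp(-self.shape_c2 * dd / a))


@dataclass
class PermittivityCurve:
    """Per-entry-angle effective permittivity versus penetration depth."""

    entry_angle_deg: float
    distances_mm: np.ndarray
    eps_values: np.ndarray
    normal_depth_a_mm: float

    def __post_init__(self) -> None:
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        self.eps_values = np.asarray(self.eps_values, dtype=float)
        if len(self.distances_mm) != len(self.eps_values):
            raise ValueError("distances and eps values must have equal length")
        if len(self.distances_mm) and (
            self.distances_mm[0] <= 0 or np.any(np.diff(self.distances_mm) <= 0)
        ):
            raise ValueError("distances must be strictly increasing and > 0")
        if np.any(self.eps_values < 1.0):
            raise ValueError("eps values must be >= 1")
        if self.normal_depth_a_mm <= 0:
            raise ValueError("normal depth a must be positive")


@dataclass
class FitResult:
    model: PermittivityModel
    residual_rms: float
    n_curves: int


def effective_permittivity(d, a: float, model: PermittivityModel):
    """Evaluate the model; see :class:`PermittivityModel.evaluate`."""
    return model.evaluate(d, a)


def extract_effective_permittivity(delta_t, d):
    """Effective permittivity from a differential arrival time.

    ``delta_t`` (s) is the arrival-time difference between a probe at
    penetration depth ``d`` (mm) and the entry-point reference; the single
    dielectric constant reproducing that delay over distance d is
    (c * delta_t / d)**2.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(delta_t <= 0) or np.any(d <= 0):
        raise ValueError("delta_t and d must be positive")
    return (C0_MM * delta_t / d) ** 2


_FIT_STARTS = ((45.0, 0.7, 5.0), (60.0, 0.9, 10.0), (30.0, 0.5, 2.0))


def fit_permittivity_model(curves: List[PermittivityCurve], n_grid: int = 100) -> FitResult:
    """Fit the unified propagation model to per-angle permittivity curves.

    Each curve's depths are normalised by its own entry-normal distance
    ``a`` (angle-wise curves span different head depths), linearly
    interpolated onto a common normalised-distance axis, averaged across
    entry angles, and the saturating model is fitted to the average by
    unweighted nonlinear least squares with three fixed starting points
    (deterministic, seed-free).
    """
    if not curves:
        raise ValueError("need at least one curve")
    for c in curves:
        if len(c.distances_mm) < 3:
            raise ValueError("each curve needs at least 3 points")
    u_lo = max(c.distances_mm[0] / c.normal_depth_a_mm for c in curves)
    u_hi = min(c.distances_mm[-1] / c.normal_depth_a_mm for c in curves)
    if u_hi <= u_lo:
        raise ValueError("curves do not overlap on the normalised axis")
    u = np.linspace(u_lo, u_hi, n_grid)
    stack = np.stack(
        [
            np.interp(u, c.distances_mm / c.normal_depth_a_mm, c.eps_values)
            for c in curves
        ]
    )
    mean_eps = stack.mean(axis=0)

    def resid(p):
        eps_max, c1, c2 = p
        return eps_max * (1.0 - c1 * np.exp(-c2 * u)) - mean_eps

    best = None
    for x0 in _FIT_STARTS:
        sol = least_squares(
            resid,
            x0,
            bounds=([1.0, 0.0, 1e-3], [500.0, 0.999999, 1e3]),
            method="trf",
        )
        if best is None or sol.cost < best.cost:
            best = sol
    eps_max, c1, c2 = best.x
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    model = PermittivityModel(eps_max=eps_max, shape_c1=min(c1, 1 - 1e-12), shape_c2=c2)
    return FitResult(model=model, residual_rms=rms, n_curves=len(curves))
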
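"""Experiment configuration: YAML-serializable description of a full run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .geometry import (
    HeadBoundary,
    ImagingGrid,
    ScanGeometry,
    circle_boundary,
    ellipse_boundary,
    make_circular_scan,
    make_offset_scan,
    make_parabolic_scan,
)
from .permittivity import PermittivityModel
from .phantom import HeadPhantom2D, TargetSpec, make_head_phantom
from .sigproc import FrequencySweep

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    """Fully serializable experiment description; round-trips through YAML."""

    phantom: dict = field(
        default_factory=lambda: {"a": 90.0, "b": 110.0, "skin_jitter_sd": 0.0}
    )
    target: Optional[dict] = field(
        default_factory=lambda: {"center": [30.0, 20.0], "width": 20.0, "height": 20.0}
    )
    geometry: dict = field(
        default_factory=lambda: {"type": "offset", "standoff": 15.0, "n": 32}
    )
    sweep: dict = field(
        default_factory=lambda: {"f_min": 0.75e9, "f_max": 2.55e9, "n_samples": 284}
    )
    grid: dict = field(
        default_factory=lambda: {"extent": [300.0, 300.0], "cell_size": 1.0}
    )
    model: dict = field(default_factory=lambda: {"kind": "proposed"})
    noise: dict = field(default_factory=lambda: {"snr_db": None})
    seed: int = 0

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    # -- builders --------------------------------------------------------
    def build_phantom(self) -> HeadPhantom2D:
        kw = dict(self.phantom)
        tgt = None
        if self.target is not None:
            t = dict(self.target)
            tgt = TargetSpec(
                center=tuple(t["center"]),
                width=t.get("width", 20.0),
                height=t.get("height", 20.0),
            )
        return make_head_phantom(target=tgt, **kw)

    def build_boundary(self) -> HeadBoundary:
        a = self.phantom.get("a", 90.0)
        b = self.phantom.get("b", 110.0)
        return ellipse_boundary(a, b) if a != b else circle_boundary(a)

    def build_geometry(self, boundary: Optional[HeadBoundary] = None) -> ScanGeometry:
        g = dict(self.geometry)
        kind = g.pop("type", "offset")
        if kind == "circle":
            return make_circular_scan(g["radius"], g["n"])
        if kind == "parabola":
            return make_parabolic_scan(g["r1"], g["r2"], g["n"])
        if kind == "offset":
            boundary = boundary or self.build_boundary()
            return make_offset_scan(boundary, g.get("standoff", 15.0), g["n"])
        raise ValueError(f"unknown geometry type {kind!r}")

    def build_sweep(self) -> FrequencySweep:
        return FrequencySweep(**self.sweep)

    def build_grid(self) -> ImagingGrid:
        return ImagingGrid(
            extent=tuple(self.grid["extent"]), cell_size=self.grid["cell_size"]
        )

    def build_model(self) -> PermittivityModel:
        kind = self.model.get("kind", "proposed")
        if kind == "proposed":
            return PermittivityModel(
                eps_max=self.model.get("eps_max", 46.8),
                shape_c1=self.model.get("shape_c1", 0.75),
                shape_c2=self.model.get("shape_c2", 6.4),
            )
        if kind == "fixed":
            return PermittivityModel(kind="fixed", eps_fixed=self.model.get("eps", 45.0))
        raise ValueError(f"unknown model kind {kind!r}")
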
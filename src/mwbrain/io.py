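"""File I/O: dataset bundles (NPZ), Touchstone .s1p directories, images.

The NPZ bundle is the primary interchange format (atomic and typed).  A
Touchstone v1.1 directory -- one .s1p per antenna position plus a JSON
manifest -- is supported for interoperability with measurement software;
the dialect written is RI format, Hz units, 50 ohm reference, and RI/MA/DB
formats with any frequency unit are accepted on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .geometry import ScanGeometry
from .imaging import ReconstructedImage
from .sigproc import FrequencySweep, ReflectionDataset

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_touchstone_dir",
    "read_touchstone_dir",
    "write_image",
]


class FormatError(ValueError):
    """Raised on malformed dataset files."""


# ---------------------------------------------------------------------------
# NPZ bundle
# ---------------------------------------------------------------------------

def write_dataset(data: ReflectionDataset, path) -> None:
    """Write a dataset as a single NPZ bundle (lossless round trip)."""
    path = Path(path)
    snr = np.nan if data.snr_db is None else float(data.snr_db)
    np.savez_compressed(
        path,
        s11=data.s11,
        f_min=data.sweep.f_min,
        f_max=data.sweep.f_max,
        n_samples=data.sweep.n_samples,
        positions=data.geometry.positions,
        center=data.geometry.center,
        snr_db=snr,
    )


def read_dataset(path) -> ReflectionDataset:
    path = Path(path)
    if path.is_dir():
        return read_touchstone_dir(path)
    with np.load(path) as z:
        sweep = FrequencySweep(
            f_min=float(z["f_min"]), f_max=float(z["f_max"]),
            n_samples=int(z["n_samples"]),
        )
        geometry = ScanGeometry(positions=z["positions"], center=z["center"])
        snr = float(z["snr_db"])
        return ReflectionDataset(
            s11=z["s11"], sweep=sweep, geometry=geometry,
            snr_db=None if np.isnan(snr) else snr,
        )


# ---------------------------------------------------------------------------
# Touchstone .s1p
# ---------------------------------------------------------------------------

_UNIT = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}


def _write_s1p(path: Path, freqs: np.ndarray, s: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("! mwbrain monostatic reflection sweep\n")
        fh.write("# HZ S RI R 50\n")
        for f, v in zip(freqs, s):
            fh.write(f"{f:.6f} {v.real:.12e} {v.imag:.12e}\n")


def _read_s1p(path: Path) -> tuple:
    freqs, vals = [], []
    scale, fmt = 1.0, "RI"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                toks = line[1:].upper().split()
                i = 0
                while i < len(toks):
                    tok = toks[i]
                    if tok in _UNIT:
                        scale = _UNIT[tok]
                    elif tok in ("RI", "MA", "DB"):
                        fmt = tok
                    elif tok == "S":
                        pass
                    elif tok == "R":
                        i += 1  # reference impedance value follows
                    else:
                        raise FormatError(
                            f"{path.name}:{lineno}: unknown Touchstone option {tok!r}"
                        )
                    i += 1
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path.name}:{lineno}: expected 3 columns")
            f, a, b = (float(x) for x in parts)
            if fmt == "RI":
                v = a + 1j * b
            elif fmt == "MA":
                v = a * np.exp(1j * np.radians(b))
            else:  # DB
                v = 10.0 ** (a / 20.0) * np.exp(1j * np.radians(b))
            freqs.append(f * scale)
            vals.append(v)
    return np.array(freqs), np.array(vals)


def write_touchstone_dir(data: ReflectionDataset, dirpath) -> None:
    """Write one RI-format .s1p per position plus a JSON manifest."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    freqs = data.sweep.frequencies
    for i in range(data.geometry.n_positions):
        _write_s1p(dirpath / f"pos_{i:03d}.s1p", freqs, data.s11[i])
    manifest = {
        "n_positions": data.geometry.n_positions,
        "positions": data.geometry.positions.tolist(),
        "center": data.geometry.center.tolist(),
        "f_min": data.sweep.f_min,
        "f_max": data.sweep.f_max,
        "n_samples": data.sweep.n_samples,
        "snr_db": data.snr_db,
    }
    (dirpath / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_touchstone_dir(dirpath) -> ReflectionDataset:
    dirpath = Path(dirpath)
    manifest = json.loads((dirpath / "manifest.json").read_text())
    n = int(manifest["n_positions"])
    sweep = FrequencySweep(
        f_min=manifest["f_min"], f_max=manifest["f_max"],
        n_samples=int(manifest["n_samples"]),
    )
    s11 = np.empty((n, sweep.n_samples), dtype=complex)
    for i in range(n):
        path = dirpath / f"pos_{i:03d}.s1p"
        if not path.exists():
            raise FormatError(f"manifest lists {n} positions but pos_{i:03d}.s1p is missing")
        freqs, vals = _read_s1p(path)
        if len(vals) != sweep.n_samples:
            raise FormatError(f"{path.name}: expected {sweep.n_samples} rows, got {len(vals)}")
        if not np.allclose(freqs, sweep.frequencies, rtol=1e-9, atol=1.0):
            raise FormatError(f"{path.name}: frequency grid disagrees with manifest")
        s11[i] = vals
    geometry = ScanGeometry(positions=np.array(manifest["positions"]), center=np.array(manifest["center"]))
    return ReflectionDataset(
        s11=s11, sweep=sweep, geometry=geometry, snr_db=manifest.get("snr_db")
    )


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_image(
    image: ReconstructedImage, stem, png: bool = True, metadata: Optional[dict] = None
) -> None:
    """Write intensity matrix (NPZ) + grid metadata JSON, optionally a PNG."""
    stem = Path(stem)
    np.savez_compressed(
        stem.with_suffix(".npz"),
        intensity=image.intensity,
        mask=image.mask,
        raw_max=image.raw_max,
        normalized=image.normalized,
    )
    meta = {
        "extent_mm": list(image.grid.extent),
        "cell_size_mm": image.grid.cell_size,
        "raw_max": image.raw_max,
        "normalized": bool(image.normalized),
    }
    meta.update(metadata or {})
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    if png:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        w, h = image.grid.extent
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(
            image.intensity.T,
            origin="lower",
            extent=(-w / 2, w / 2, -h / 2, h / 2),
            cmap="viridis",
        )
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        fig.savefig(stem.with_suffix(".png"), dpi=150)
        plt.close(fig)
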
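"""File formats: TIFF images, CSV tables, JSON sidecars."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .optics import HeightMap, HologramFrame, NoiseMeta, OpticalConfig

PathLike = Union[str, Path]


def write_hologram(path: PathLike, holo: HologramFrame) -> None:
    """8-bit (or 16-bit) grayscale TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, holo.intensity)
    meta = {
        "role": holo.role,
        "axial_offset_um": holo.axial_offset_um,
        "clipped_fraction": holo.clipped_fraction,
        "noise_meta": asdict(holo.noise_meta),
        "optics": asdict(holo.optics),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_hologram(path: PathLike, optics: Optional[OpticalConfig] = None,
                  role: str = "object") -> HologramFrame:
    """Read a grayscale TIFF hologram; optics come from the sidecar if present."""
    path = Path(path)
    intensity = np.asarray(tifffile.imread(path))
    if intensity.ndim == 3:  # collapse RGB grays
        intensity = intensity[..., 0]
    noise = NoiseMeta()
    sidecar = path.with_suffix(".json")
    if optics is None and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        o = meta["optics"]
        o["carrier_cycles_per_px"] = tuple(o["carrier_cycles_per_px"])
        optics = OpticalConfig(**o)
        role = meta.get("role", role)
        nm = meta.get("noise_meta")
        if nm:
            noise = NoiseMeta(**nm)
    if optics is None:
        optics = OpticalConfig()
    return HologramFrame(intensity=intensity, optics=optics, role=role,
                         noise_meta=noise)


def write_height_map(path: PathLike, height: HeightMap) -> None:
    """Float32 TIFF with sampling/Δn recorded in the TIFF description."""
    desc = json.dumps({"sampling_um": height.sampling_um, "delta_n": height.delta_n})
    tifffile.imwrite(Path(path), height.values.astype(np.float32), description=desc)


def read_height_map(path: PathLike) -> HeightMap:
    with tifffile.TiffFile(Path(path)) as tf:
        values = tf.asarray().astype(float)
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {"sampling_um": 1.0, "delta_n": 0.05}
    return HeightMap(values=values, sampling_um=meta["sampling_um"],
                     delta_n=meta["delta_n"])


def write_json(path: PathLike, obj) -> None:
    def default(o):
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default))
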
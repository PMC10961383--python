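"""Shared optical data containers.

Conventions used throughout the package (stated once, enforced here):
pixel (0, 0) is the top-left corner, arrays are row-major; physical
lengths are in micrometres, phase in radians; spatial frequencies are in
cycles/pixel with frequency (0, 0) at array index (0, 0) (use
:func:`numpy.fft.fftshift` only for display).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

import numpy as np

__all__ = [
    "OpticalConfig",
    "ComplexField",
    "HologramFrame",
    "PhaseMap",
    "HeightMap",
    "NoiseMeta",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Imaging-system constants of the off-axis interferometer.

    Defaults describe a HeNe Mach–Zehnder transmission setup with a
    20×/0.65 NA objective and an 8-bit camera of 5.2 µm pixel pitch; the
    carrier is the spatial fringe frequency imprinted by the small tilt
    between object and reference beams.
    """

    wavelength_um: float = 0.6328
    magnification: float = 20.0
    numerical_aperture: float = 0.65
    camera_pixel_um: float = 5.2
    bit_depth: int = 8
    carrier_cycles_per_px: Tuple[float, float] = (0.25, 0.25)
    reference_amplitude_ratio: float = 1.0
    medium_refractive_index: float = 1.335

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if not (0 < self.numerical_aperture <= 1):
            raise ValueError("numerical_aperture must be in (0, 1]")
        if self.camera_pixel_um <= 0:
            raise ValueError("camera_pixel_um must be positive")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")
        if self.reference_amplitude_ratio <= 0:
            raise ValueError("reference_amplitude_ratio must be positive")
        for c in self.carrier_cycles_per_px:
            if not (0 < abs(c) < 0.5):
                raise ValueError(
                    "carrier must be non-zero and below Nyquist (|f| < 0.5 cycles/px)"
                )

    @property
    def object_pixel_um(self) -> float:
        """Object-plane sampling: camera pitch demagnified by the objective."""
        return self.camera_pixel_um / self.magnification

    @property
    def full_scale(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def na_cutoff_cycles_per_px(self) -> float:
        """NA-limited band radius in cycles/pixel at the recorded sampling."""
        return self.numerical_aperture / self.wavelength_um * self.object_pixel_um


@dataclass(frozen=True)
class NoiseMeta:
    """Detector noise model: Poisson shot noise at ``photon_scale`` mean
    photons per full-scale pixel plus Gaussian read noise (digital numbers).
    ``photon_scale=None`` disables shot noise."""

    photon_scale: Optional[float] = None
    read_noise_sigma: float = 0.0
    seed: int = 0


@dataclass
class ComplexField:
    """Scalar complex optical field U(x, y) at one axial plane."""

    values: np.ndarray
    sampling_um: float
    plane_z_um: float = 0.0
    wavelength_um: float = 0.6328
    aliasing_warning: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise ValueError("field values must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if self.sampling_um <= 0 or self.wavelength_um <= 0:
            raise ValueError("sampling_um and wavelength_um must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


@dataclass
class HologramFrame:
    """One recorded (or simulated) interference intensity image."""

    intensity: np.ndarray
    optics: OpticalConfig
    role: Literal["object", "reference"] = "object"
    axial_offset_um: float = 0.0
    noise_meta: NoiseMeta = field(default_factory=NoiseMeta)
    clipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be 2-D")
        if self.intensity.min() < 0 or self.intensity.max() > self.optics.full_scale:
            raise ValueError("hologram intensity outside detector range")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.intensity.shape


@dataclass
class PhaseMap:
    """Phase in radians; ``wrapped=True`` means values lie in [-pi, pi)."""

    values: np.ndarray
    wrapped: bool
    sampling_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("phase values must be 2-D")
        if self.sampling_um <= 0:
            raise ValueError("sampling_um must be positive")
        if self.wrapped:
            v = self.values
            if v.size and (v.min() < -np.pi - 1e-9 or v.max() >= np.pi + 1e-9):
                raise ValueError("wrapped phase must lie in [-pi, pi)")


@dataclass
class HeightMap:
    """Optical thickness h(x, y) in µm, with the refractive contrast used."""

    values: np.ndarray
    sampling_um: float
    delta_n: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("height values must be 2-D")
        if self.sampling_um <= 0:
            raise ValueError("sampling_um must be positive")
        if self.delta_n <= 0:
            raise ValueError("delta_n must be positive")


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase to [-pi, pi)."""
    return np.mod(np.asarray(phi, dtype=float) + np.pi, 2 * np.pi) - np.pi
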
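"""Forward model: scene phase → off-axis hologram.

The object is treated as a pure-phase transparency, U = exp(iφ). The field
is optionally defocused by angular-spectrum propagation, then interfered
with a tilted plane-wave reference whose tilt puts a spatial carrier on the
fringes; the resulting intensity is scaled to the detector, noised
(Poisson shot + Gaussian read) and quantised.

Angular-spectrum propagation is exact in scalar theory: the field is
decomposed into plane waves by 2-D FFT, each component multiplied by

    H(fx, fy; dz) = exp(i 2π dz sqrt((n/λ)² − fx² − fy²)),

and resynthesised. Evanescent components (negative argument) are zeroed by
default (band-limited propagation) or decayed exponentially on request.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .optics import ComplexField, HologramFrame, NoiseMeta, OpticalConfig, PhaseMap

__all__ = ["phase_to_field", "propagate_angular_spectrum", "synthesize_hologram"]


def phase_to_field(phase: PhaseMap, optics: OpticalConfig) -> ComplexField:
    """Unit-amplitude field exp(iφ) at the object plane (z = 0)."""
    values = np.exp(1j * phase.values)
    return ComplexField(values=values, sampling_um=phase.sampling_um,
                        plane_z_um=0.0, wavelength_um=optics.wavelength_um)


def propagate_angular_spectrum(
    field: ComplexField,
    dz_um: float,
    medium_index: float = 1.0,
    evanescent: str = "zero",
) -> ComplexField:
    """Propagate a sampled field by ``dz_um`` along the optical axis.

    Invertible: propagating by dz then −dz restores the input to numerical
    precision. ``evanescent`` is ``"zero"`` (band-limited) or ``"decay"``.
    Sets ``aliasing_warning`` on the result when the transfer-function phase
    changes by more than π between adjacent frequency samples anywhere in
    the propagating band (undersampled chirp).
    """
    if dz_um == 0.0:
        out = ComplexField(values=field.values.copy(), sampling_um=field.sampling_um,
                           plane_z_um=field.plane_z_um, wavelength_um=field.wavelength_um)
        return out
    ny, nx = field.shape
    fy = np.fft.fftfreq(ny, d=field.sampling_um)[:, None]
    fx = np.fft.fftfreq(nx, d=field.sampling_um)[None, :]
    k2 = (medium_index / field.wavelength_um) ** 2
    arg = k2 - fx**2 - fy**2
    prop = arg > 0
    kz = np.sqrt(np.where(prop, arg, 0.0))
    H = np.where(prop, np.exp(2j * np.pi * dz_um * kz), 0.0 + 0.0j)
    if evanescent == "decay":
        kappa = np.sqrt(np.where(~prop, -arg, 0.0))
        H = H + np.where(~prop, np.exp(-2 * np.pi * abs(dz_um) * kappa), 0.0)
    elif evanescent != "zero":
        raise ValueError("evanescent must be 'zero' or 'decay'")
    # aliasing guard: |d(2π dz kz)/df| * Δf should stay below π
    df = 1.0 / (min(ny, nx) * field.sampling_um)
    fmax = max(np.abs(fx).max(), np.abs(fy).max())
    with np.errstate(divide="ignore", invalid="ignore"):
        kz_edge = np.sqrt(max(k2 - fmax**2, 1e-300))
        slope = 2 * np.pi * abs(dz_um) * fmax / kz_edge
    warn = bool(slope * df > np.pi)
    spectrum = np.fft.fft2(field.values)
    out = np.fft.ifft2(spectrum * H)
    return ComplexField(values=out, sampling_um=field.sampling_um,
                        plane_z_um=field.plane_z_um + dz_um,
                        wavelength_um=field.wavelength_um, aliasing_warning=warn)


def synthesize_hologram(
    object_field: ComplexField,
    optics: OpticalConfig,
    defocus_um: float = 0.0,
    noise_meta: Optional[NoiseMeta] = None,
    role: str = "object",
    normalization: str = "mean",
) -> HologramFrame:
    """Record the two-beam interference of the (defocused) object field with
    a tilted plane-wave reference.

    ``I = |O + R|²`` with ``R = ratio · exp(i 2π (fy·y + fx·x))`` at the
    configured carrier. Intensity is normalised so the noise-free mean maps
    to half full scale, shot/read noise is applied, values are clipped to
    the detector range and quantised. With ``role="reference"`` the object
    is replaced by an empty (φ ≡ 0) transparency of the same shape.
    """
    noise_meta = noise_meta or NoiseMeta()
    if noise_meta.photon_scale is not None and noise_meta.photon_scale <= 0:
        raise ValueError("photon_scale must be positive (or None to disable)")
    if role == "reference":
        object_field = ComplexField(values=np.ones(object_field.shape, dtype=complex),
                                    sampling_um=object_field.sampling_um,
                                    wavelength_um=object_field.wavelength_um)
    elif role != "object":
        raise ValueError("role must be 'object' or 'reference'")
    O = object_field
    if defocus_um != 0.0:
        O = propagate_angular_spectrum(O, defocus_um,
                                       medium_index=optics.medium_refractive_index)
    ny, nx = O.shape
    fy, fx = optics.carrier_cycles_per_px
    yy, xx = np.mgrid[0:ny, 0:nx]
    R = optics.reference_amplitude_ratio * np.exp(2j * np.pi * (fy * yy + fx * xx))
    intensity = np.abs(O.values + R) ** 2
    # "mean" exposure puts the noise-free mean at half full scale (bright
    # caustics may clip — the clipped fraction is logged on the frame);
    # "max" emulates an operator backing the exposure off until nothing
    # saturates, mapping the noise-free maximum to full scale.
    full = optics.full_scale
    if normalization == "mean":
        scale = (full / 2.0) / intensity.mean()
    elif normalization == "max":
        scale = full / intensity.max()
    else:
        raise ValueError("normalization must be 'mean' or 'max'")
    intensity = intensity * scale
    rng = np.random.default_rng(noise_meta.seed)
    if noise_meta.photon_scale is not None:
        photons = intensity / full * noise_meta.photon_scale
        intensity = rng.poisson(photons) * full / noise_meta.photon_scale
    if noise_meta.read_noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, noise_meta.read_noise_sigma,
                                           intensity.shape)
    clipped = float(np.mean((intensity < 0) | (intensity > full)))
    quantised = np.clip(np.rint(intensity), 0, full).astype(
        np.uint8 if optics.bit_depth <= 8 else np.uint16)
    return HologramFrame(intensity=quantised, optics=optics, role=role,
                         axial_offset_um=defocus_um, noise_meta=noise_meta,
                         clipped_fraction=clipped)
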
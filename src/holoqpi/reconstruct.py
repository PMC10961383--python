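"""Hologram → quantitative phase → 3-D height pipeline.

Stages, in the order the full pipeline composes them:

1. sideband demodulation — locate the +1 diffraction order in the
   hologram's 2-D spectrum, window it, recentre it to zero frequency and
   inverse-transform to the complex field;
2. numerical autofocus — angular-spectrum refocusing to the plane that
   minimises the amplitude-variance metric (pure-phase objects have flat
   amplitude in focus);
3. reference selection — among candidate reference fields, pick the one
   whose wrapped phase difference arg(O·R*) has the smoothest background;
4. 3×3 circular median filtering of the wrapped difference;
5. 2-D phase unwrapping (reliability-sorted region growing);
6. background plane (piston + tilt) removal;
7. phase → height conversion h = φλ/(2πΔn).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase as _skimage_unwrap

from .forward import propagate_angular_spectrum
from .optics import (ComplexField, HeightMap, HologramFrame, OpticalConfig,
                     PhaseMap, wrap_phase)

__all__ = [
    "extract_sideband",
    "select_reference",
    "autofocus",
    "filter_phase",
    "unwrap_phase",
    "phase_to_height",
    "remove_background_plane",
    "count_residues",
    "reconstruct",
    "ReconstructionOptions",
    "QCReport",
    "CarrierNotFoundError",
]


class CarrierNotFoundError(RuntimeError):
    """No off-axis carrier peak resolvable in the hologram spectrum."""


@dataclass
class ReconstructionOptions:
    """Tunable knobs of the pipeline; defaults follow standard practice."""

    delta_n: float = 0.05
    filter_kernel_px: int = 3
    autofocus_range_um: Tuple[float, float] = (-100.0, 100.0)
    autofocus_steps: int = 41
    autofocus_enabled: bool = True
    sideband_radius_factor: float = 0.5   # × carrier-to-DC distance
    sideband_snr_threshold: float = 10.0
    dc_exclusion_cycles: float = 0.05
    background_mask: Optional[np.ndarray] = None


@dataclass
class QCReport:
    """Per-reconstruction quality-control record."""

    carrier_cycles_per_px: Tuple[float, float] = (0.0, 0.0)
    chosen_reference: int = -1
    z_best_um: float = 0.0
    residue_count: int = 0
    background_roughness_rad: float = 0.0
    focus_curve: Optional[Tuple[np.ndarray, np.ndarray]] = None
    clipped_fraction: float = 0.0


def _spectrum_peak(intensity: np.ndarray, dc_exclusion_cycles: float,
                   snr_threshold: float) -> Tuple[int, int, np.ndarray]:
    """Strongest non-DC peak in the positive-frequency half-plane.

    The two sidebands of a real interferogram are complex conjugates; the
    search is restricted to rows fy in (0, 0.5) plus the fy = 0, fx > 0
    half-row, which selects the +1 order for carriers with a positive
    vertical (or, failing that, horizontal) tilt component.
    """
    ny, nx = intensity.shape
    spec = np.fft.fft2(intensity.astype(float))
    mag = np.abs(spec)
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    half = (fy > 0) | ((fy == 0) & (fx > 0))
    outside_dc = (fy**2 + fx**2) > dc_exclusion_cycles**2
    search = half & outside_dc
    masked = np.where(search, mag, 0.0)
    iy, ix = np.unravel_index(np.argmax(masked), masked.shape)
    floor = np.median(mag[search])
    if masked[iy, ix] < snr_threshold * max(floor, 1e-12):
        raise CarrierNotFoundError("no carrier detected above the SNR threshold")
    return int(iy), int(ix), spec


def extract_sideband(holo: HologramFrame, optics: OpticalConfig,
                     options: Optional[ReconstructionOptions] = None) -> ComplexField:
    """Demodulate the +1 order of an off-axis hologram.

    A circular hard window of radius ``sideband_radius_factor`` × the
    carrier-to-DC distance (capped at the NA band radius) is applied
    around the detected peak; the windowed spectrum is recentred to zero
    frequency and inverse-transformed.
    """
    options = options or ReconstructionOptions()
    iy, ix, spec = _spectrum_peak(holo.intensity, options.dc_exclusion_cycles,
                                  options.sideband_snr_threshold)
    ny, nx = holo.shape
    fy_pk = np.fft.fftfreq(ny)[iy]
    fx_pk = np.fft.fftfreq(nx)[ix]
    carrier_dist = float(np.hypot(fy_pk, fx_pk))
    radius = min(options.sideband_radius_factor * carrier_dist,
                 optics.na_cutoff_cycles_per_px)
    if radius <= 0 or carrier_dist - radius < options.dc_exclusion_cycles:
        raise CarrierNotFoundError("orders overlap: carrier too close to DC "
                                   "for the sideband window")
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    # distances on the frequency torus, so windows near the edge wrap cleanly
    dfy = (fy - fy_pk + 0.5) % 1.0 - 0.5
    dfx = (fx - fx_pk + 0.5) % 1.0 - 0.5
    window = (dfy**2 + dfx**2) <= radius**2
    demod = np.fft.ifft2(np.roll(np.roll(spec * window, -iy, axis=0), -ix, axis=1))
    # the sideband at +carrier is the O*R cross term; conjugating recovers the
    # object envelope with the field-standard sign (positive reference tilt)
    demod = np.conj(demod)
    out = ComplexField(values=demod, sampling_um=optics.object_pixel_um,
                       wavelength_um=optics.wavelength_um)
    out.carrier_cycles_per_px = (float(fy_pk), float(fx_pk))  # type: ignore[attr-defined]
    return out


def _circular_roughness(wrapped: np.ndarray) -> float:
    """Circular standard deviation of a wrapped phase map (radians)."""
    resultant = np.abs(np.mean(np.exp(1j * wrapped)))
    resultant = min(max(resultant, 1e-12), 1.0)
    return float(np.sqrt(-2.0 * np.log(resultant)))


def select_reference(object_field: ComplexField,
                     candidates: Sequence[ComplexField],
                     kernel_px: int = 3,
                     background_mask: Optional[np.ndarray] = None,
                     ) -> Tuple[int, PhaseMap]:
    """Pick the candidate reference minimising residual background roughness.

    For each candidate the wrapped phase difference arg(O·R*) is median
    filtered (circularly) and its circular standard deviation over the
    background region (default: whole field) is the roughness score; the
    lowest score wins. Returns the winning index and its wrapped difference
    (unfiltered).
    """
    if len(candidates) == 0:
        raise ValueError("candidate reference list is empty")
    best_idx, best_score, best_diff = -1, np.inf, None
    for i, ref in enumerate(candidates):
        if ref.shape != object_field.shape:
            raise ValueError("candidate reference shape mismatch")
        diff = np.angle(object_field.values * np.conj(ref.values))
        filt = filter_phase(PhaseMap(wrap_phase(diff), wrapped=True,
                                     sampling_um=object_field.sampling_um),
                            kernel_px=kernel_px).values
        scored = filt[background_mask] if background_mask is not None else filt
        score = _circular_roughness(scored)
        if score < best_score:
            best_idx, best_score, best_diff = i, score, diff
    return best_idx, PhaseMap(wrap_phase(best_diff), wrapped=True,
                              sampling_um=object_field.sampling_um)


def _amplitude_variance(field_values: np.ndarray) -> float:
    amp = np.abs(field_values)
    mean = amp.mean()
    return float(amp.var() / (mean * mean)) if mean > 0 else np.inf


def autofocus(field: ComplexField, z_range_um: Tuple[float, float] = (-100.0, 100.0),
              n_steps: int = 41, medium_index: float = 1.0,
              ) -> Tuple[float, Tuple[np.ndarray, np.ndarray]]:
    """Find the refocus distance minimising normalised amplitude variance.

    The metric var(|U|)/mean(|U|)² is minimal at focus for pure-phase
    objects (flat amplitude). The coarse grid optimum is refined by
    parabolic interpolation of the three bracketing samples.
    """
    zmin, zmax = z_range_um
    if not (np.isfinite(zmin) and np.isfinite(zmax) and zmax > zmin):
        raise ValueError("z range must be finite with max > min")
    if n_steps < 3:
        raise ValueError("n_steps must be >= 3")
    zs = np.linspace(zmin, zmax, n_steps)
    metric = np.array([
        _amplitude_variance(
            propagate_angular_spectrum(field, z, medium_index=medium_index).values)
        for z in zs
    ])
    if not np.any(np.isfinite(metric)):
        raise RuntimeError("focus metric non-finite over the whole z range")
    i = int(np.nanargmin(metric))
    z_best = zs[i]
    if 0 < i < n_steps - 1:
        y0, y1, y2 = metric[i - 1], metric[i], metric[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            z_best = zs[i] + 0.5 * (y0 - y2) / denom * (zs[1] - zs[0])
    return float(z_best), (zs, metric)


def filter_phase(phase: PhaseMap, kernel_px: int = 3) -> PhaseMap:
    """Square median filter; wrapped maps are filtered on the unit circle.

    For wrapped inputs the cosine and sine of the phase are median filtered
    separately and the argument re-taken, so the filter never smears the
    ±π wrap seam the way a real-valued median would.
    """
    if kernel_px % 2 == 0 or kernel_px < 1:
        raise ValueError("kernel_px must be a positive odd integer")
    if phase.wrapped:
        c = ndimage.median_filter(np.cos(phase.values), size=kernel_px, mode="reflect")
        s = ndimage.median_filter(np.sin(phase.values), size=kernel_px, mode="reflect")
        out = wrap_phase(np.arctan2(s, c))
    else:
        out = ndimage.median_filter(phase.values, size=kernel_px, mode="reflect")
    return PhaseMap(values=out, wrapped=phase.wrapped, sampling_um=phase.sampling_um)


def count_residues(wrapped: np.ndarray) -> int:
    """Number of non-zero residues (local 2π inconsistencies) in a wrapped map."""
    d1 = wrap_phase(np.diff(wrapped, axis=1))  # rightward
    d2 = wrap_phase(np.diff(wrapped, axis=0))  # downward
    loop = (d1[:-1, :] + d2[:, 1:] - d1[1:, :] - d2[:, :-1]) / (2 * np.pi)
    return int(np.count_nonzero(np.abs(np.rint(loop)) > 0))


def unwrap_phase(phase: PhaseMap,
                 background_mask: Optional[np.ndarray] = None) -> PhaseMap:
    """Reliability-sorted region-growing 2-D unwrapping.

    The output differs from the input by exact multiples of 2π per pixel.
    It is anchored by subtracting the multiple of 2π nearest the median of
    the background region (default: whole field), which keeps the mod-2π
    relation intact while placing the background within half a turn of zero.
    """
    if not phase.wrapped:
        raise ValueError("unwrap_phase expects a wrapped phase map")
    unwrapped = np.asarray(_skimage_unwrap(phase.values), dtype=float)
    region = unwrapped[background_mask] if background_mask is not None else unwrapped
    anchor = 2 * np.pi * np.round(np.median(region) / (2 * np.pi))
    return PhaseMap(values=unwrapped - anchor, wrapped=False,
                    sampling_um=phase.sampling_um)


def phase_to_height(phase: PhaseMap, delta_n: float, wavelength_um: float) -> HeightMap:
    """Convert unwrapped phase to optical thickness, h = φλ/(2πΔn)."""
    if phase.wrapped:
        raise ValueError("phase must be unwrapped before height conversion")
    if delta_n <= 0:
        raise ValueError("delta_n must be positive")
    return HeightMap(values=phase.values * wavelength_um / (2 * np.pi * delta_n),
                     sampling_um=phase.sampling_um, delta_n=delta_n)


def remove_background_plane(values: np.ndarray,
                            mask: Optional[np.ndarray] = None,
                            n_iter: int = 5,
                            clip_sigma: float = 3.0) -> np.ndarray:
    """Subtract a least-squares plane fitted to the background.

    Without an explicit mask the fit is made robust by iterated sigma
    clipping: residuals outside ``clip_sigma`` robust standard deviations
    (1.4826·MAD) of the residual median are dropped and the plane refitted.
    Cells are strong positive outliers, so the surviving pixels are pure
    background and the fitted zero level is unbiased — important because
    integral quantities (volumes) amplify any residual offset by the field
    area.
    """
    ny, nx = values.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    A = np.column_stack([np.ones(values.size), yy.ravel(), xx.ravel()])
    b = values.ravel()
    sel = mask.ravel() if mask is not None else np.ones(values.size, dtype=bool)
    coef = np.zeros(3)
    for _ in range(n_iter if mask is None else 1):
        coef, *_ = np.linalg.lstsq(A[sel], b[sel], rcond=None)
        if mask is not None:
            break
        resid = b - A @ coef
        center = np.median(resid[sel])
        sigma = 1.4826 * np.median(np.abs(resid[sel] - center)) + 1e-12
        new_sel = np.abs(resid - center) < clip_sigma * sigma
        if new_sel.sum() < 16 or np.array_equal(new_sel, sel):
            break
        sel = new_sel
    return values - (A @ coef).reshape(ny, nx)


def reconstruct(object_holo: HologramFrame,
                reference_holos: Sequence[HologramFrame],
                optics: OpticalConfig,
                options: Optional[ReconstructionOptions] = None,
                ) -> Tuple[HeightMap, QCReport]:
    """Full pipeline: hologram(s) → background-flattened height map.

    Composes sideband extraction → autofocus (object and references
    refocused to the same plane) → reference selection → circular median
    filtering → unwrapping → plane removal → height conversion, collecting
    a :class:`QCReport` along the way. Stage failures propagate with the
    stage name prefixed.
    """
    options = options or ReconstructionOptions()
    qc = QCReport(clipped_fraction=object_holo.clipped_fraction)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # tag with the failing stage
            raise type(exc)(f"[{name}] {exc}") from exc

    obj = _stage("extract_sideband", extract_sideband, object_holo, optics, options)
    qc.carrier_cycles_per_px = getattr(obj, "carrier_cycles_per_px", (0.0, 0.0))
    refs = [_stage("extract_sideband", extract_sideband, h, optics, options)
            for h in reference_holos]
    if options.autofocus_enabled:
        z_best, curve = _stage("autofocus", autofocus, obj,
                               options.autofocus_range_um, options.autofocus_steps,
                               optics.medium_refractive_index)
        qc.z_best_um, qc.focus_curve = z_best, curve
        if z_best != 0.0:
            obj = propagate_angular_spectrum(
                obj, z_best, medium_index=optics.medium_refractive_index)
            refs = [propagate_angular_spectrum(
                        r, z_best, medium_index=optics.medium_refractive_index)
                    for r in refs]
    idx, diff = _stage("select_reference", select_reference, obj, refs,
                       options.filter_kernel_px, options.background_mask)
    qc.chosen_reference = idx
    filtered = _stage("filter_phase", filter_phase, diff, options.filter_kernel_px)
    qc.residue_count = count_residues(filtered.values)
    unwrapped = _stage("unwrap_phase", unwrap_phase, filtered,
                       options.background_mask)
    flattened = remove_background_plane(unwrapped.values, options.background_mask)
    qc.background_roughness_rad = _circular_roughness(wrap_phase(flattened))
    flat_phase = PhaseMap(values=flattened, wrapped=False,
                          sampling_um=unwrapped.sampling_um)
    height = _stage("phase_to_height", phase_to_height, flat_phase,
                    options.delta_n, optics.wavelength_um)
    return height, qc
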
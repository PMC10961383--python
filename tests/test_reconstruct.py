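"""Reconstruction stages: demodulation, focusing, filtering, unwrapping."""

import numpy as np
import pytest

import holoqpi as h
from holoqpi.reconstruct import (CarrierNotFoundError, count_residues,
                                 remove_background_plane)

from conftest import make_holograms, smooth_random_field


# ---------------------------------------------------------------- sideband

def test_flat_object_demodulates_to_flat_phase(optics):
    p = h.SceneParams(field_size_px=(128, 128), n_cells=0)
    scene = h.simulate_scene(p)
    obj, _ = make_holograms(scene, optics)
    field = h.extract_sideband(obj, optics)
    phase = np.angle(field.values)
    flattened = remove_background_plane(phase)
    assert np.std(flattened) < 0.02


def test_detected_carrier_matches_synthesis(optics, small_scene):
    obj, _ = make_holograms(small_scene, optics)
    field = h.extract_sideband(obj, optics)
    fy, fx = field.carrier_cycles_per_px
    assert fy == pytest.approx(0.25, abs=1 / 256)
    assert fx == pytest.approx(0.25, abs=1 / 256)


def test_noise_free_wrapped_phase_matches_truth(optics, small_scene):
    """Demodulated wrapped phase equals wrap(true phase) to < 0.05 rad RMSE
    after piston/tilt removal (forward–inverse loop)."""
    obj, refs = make_holograms(small_scene, optics)
    O = h.extract_sideband(obj, optics)
    R = h.extract_sideband(refs[0], optics)
    diff = np.angle(O.values * np.conj(R.values))
    err = h.wrap_phase(remove_background_plane(
        h.wrap_phase(diff - small_scene.true_phase)))
    assert np.sqrt(np.mean(err**2)) < 0.05


def test_carrier_free_image_raises(optics):
    flat = h.HologramFrame(intensity=np.full((64, 64), 128, dtype=np.uint8),
                           optics=optics)
    with pytest.raises(CarrierNotFoundError):
        h.extract_sideband(flat, optics)


def test_sideband_linear_in_object_envelope(optics):
    """Demodulation is linear: the field of a two-disc scene equals the sum
    of the single-disc fields minus the empty-field baseline."""
    def disc_phase(centers):
        yy, xx = np.mgrid[0:128, 0:128]
        phase = np.zeros((128, 128))
        for cy, cx in centers:
            phase += 0.4 * ((yy - cy) ** 2 + (xx - cx) ** 2 < 10**2)
        return phase

    def demod(phase):
        pm = h.PhaseMap(phase, wrapped=False, sampling_um=0.26)
        holo = h.synthesize_hologram(h.phase_to_field(pm, optics), optics,
                                     noise_meta=h.NoiseMeta())
        return h.extract_sideband(holo, optics).values

    # non-overlapping discs: exp(i(φa+φb)) = exp(iφa) + exp(iφb) − 1 exactly,
    # so demodulated envelopes must superpose (after undoing the per-frame
    # detector scaling, which is set by each hologram's own mean intensity)
    both = demod(disc_phase([(40, 40), (90, 90)]))
    a = demod(disc_phase([(40, 40)]))
    b = demod(disc_phase([(90, 90)]))
    empty = demod(disc_phase([]))
    scale = np.abs(empty).mean()
    resid = (both - (a + b - empty)) / scale
    assert np.sqrt(np.mean(np.abs(resid) ** 2)) < 0.02


# ---------------------------------------------------------------- reference

def test_single_candidate_always_selected(optics, small_scene):
    obj, refs = make_holograms(small_scene, optics)
    O = h.extract_sideband(obj, optics)
    R = h.extract_sideband(refs[0], optics)
    idx, _ = h.select_reference(O, [R])
    assert idx == 0


def test_exact_reference_beats_tilt_corrupted(optics):
    p = h.SceneParams(field_size_px=(128, 128), n_cells=0)
    scene = h.simulate_scene(p)
    obj, refs = make_holograms(scene, optics)
    O = h.extract_sideband(obj, optics)
    R = h.extract_sideband(refs[0], optics)
    yy, _ = np.mgrid[0:128, 0:128]
    tilted = h.ComplexField(R.values * np.exp(0.05j * yy),
                            sampling_um=R.sampling_um,
                            wavelength_um=R.wavelength_um)
    idx, _ = h.select_reference(O, [tilted, R])
    assert idx == 1


def test_self_difference_is_zero(optics, small_scene):
    obj, _ = make_holograms(small_scene, optics)
    O = h.extract_sideband(obj, optics)
    _, diff = h.select_reference(O, [O])
    assert np.allclose(diff.values, 0.0, atol=1e-12)


def test_empty_candidate_list_rejected(optics, small_scene):
    obj, _ = make_holograms(small_scene, optics)
    O = h.extract_sideband(obj, optics)
    with pytest.raises(ValueError):
        h.select_reference(O, [])


# ---------------------------------------------------------------- autofocus

def test_in_focus_field_stays_put(optics, small_scene):
    obj, _ = make_holograms(small_scene, optics)
    O = h.extract_sideband(obj, optics)
    z, _ = h.autofocus(O, (-100, 100), 41, optics.medium_refractive_index)
    assert abs(z) < 2.5  # half the 5 µm grid step


def test_synthesized_defocus_recovered(optics, small_scene):
    obj, _ = make_holograms(small_scene, optics, defocus_um=50.0,
                            normalization="max")
    O = h.extract_sideband(obj, optics)
    z, (zs, metric) = h.autofocus(O, (-100, 100), 41,
                                  optics.medium_refractive_index)
    assert z == pytest.approx(-50.0, abs=5.0)
    i = int(np.argmin(np.abs(zs - z)))
    assert metric[i] <= metric[0] and metric[i] <= metric[-1]


def test_autofocus_validates_grid(optics, small_scene):
    obj, _ = make_holograms(small_scene, optics)
    O = h.extract_sideband(obj, optics)
    with pytest.raises(ValueError):
        h.autofocus(O, (-10, 10), 2)


# ---------------------------------------------------------------- filtering

def test_median_filter_leaves_constant(optics):
    pm = h.PhaseMap(np.full((32, 32), 0.7), wrapped=True, sampling_um=0.26)
    out = h.filter_phase(pm)
    assert np.allclose(out.values, 0.7, atol=1e-12)
    assert out.wrapped


def test_median_filter_rejects_single_pixel_spike():
    values = np.zeros((32, 32))
    values[16, 16] = np.pi / 2
    out = h.filter_phase(h.PhaseMap(values, wrapped=True, sampling_um=0.26))
    assert np.allclose(out.values, 0.0, atol=1e-12)


def test_even_kernel_rejected():
    pm = h.PhaseMap(np.zeros((8, 8)), wrapped=True, sampling_um=0.26)
    with pytest.raises(ValueError):
        h.filter_phase(pm, kernel_px=4)


def test_circular_median_respects_wrap_seam():
    """A noisy wrapped ramp crossing ±π: the circular median tracks the
    truth through the seam while a naive real-valued median — which sorts
    +π-ε and −π+ε to opposite ends of the window — does not."""
    rng = np.random.default_rng(0)
    truth = np.linspace(0, 6 * np.pi, 100)[None, :].repeat(50, axis=0)
    noisy = h.wrap_phase(truth + rng.normal(0, 0.2, truth.shape))
    circ = h.filter_phase(h.PhaseMap(noisy, wrapped=True, sampling_um=1.0))
    from scipy.ndimage import median_filter
    naive = median_filter(noisy, size=3, mode="reflect")
    err_circ = h.wrap_phase(circ.values - truth)
    err_naive = h.wrap_phase(naive - truth)
    seam = np.abs(h.wrap_phase(truth)) > 2.8  # near the wrap boundary
    rms_circ = np.sqrt(np.mean(err_circ[seam] ** 2))
    rms_naive = np.sqrt(np.mean(err_naive[seam] ** 2))
    assert np.abs(err_circ[seam]).max() < 0.5
    assert rms_circ < 2 * 0.2 / np.sqrt(9)  # ~ noise / sqrt(window)
    assert rms_naive > 2 * rms_circ


# ---------------------------------------------------------------- unwrapping

def test_unwrap_constant_anchored():
    pm = h.PhaseMap(np.full((32, 32), 0.3), wrapped=True, sampling_um=0.26)
    out = h.unwrap_phase(pm)
    assert not out.wrapped
    assert np.allclose(out.values, 0.3)


def test_unwrap_recovers_steep_ramp():
    truth = np.linspace(0, 6 * np.pi, 100)[None, :].repeat(40, axis=0)
    out = h.unwrap_phase(h.PhaseMap(h.wrap_phase(truth), wrapped=True,
                                    sampling_um=1.0))
    d = out.values - truth
    assert np.ptp(d) < 1e-9  # exact up to a 2πk constant
    assert np.allclose(d, 2 * np.pi * np.round(d[0, 0] / (2 * np.pi)))


def test_unwrap_tall_cell_phase():
    """A 9-rad cap (several wraps) unwraps back to the truth exactly."""
    yy, xx = np.mgrid[0:128, 0:128]
    r2 = ((yy - 64) ** 2 + (xx - 64) ** 2) / 40.0**2
    truth = 9.0 * np.sqrt(np.clip(1 - r2, 0, None))
    out = h.unwrap_phase(h.PhaseMap(h.wrap_phase(truth), wrapped=True,
                                    sampling_um=0.26))
    assert np.sqrt(np.mean((out.values - truth) ** 2)) < 1e-6


def test_unwrap_requires_wrapped_input():
    pm = h.PhaseMap(np.zeros((8, 8)), wrapped=False, sampling_um=1.0)
    with pytest.raises(ValueError):
        h.unwrap_phase(pm)


def test_residue_counter_flags_vortex():
    yy, xx = np.mgrid[0:32, 0:32]
    vortex = np.arctan2(yy - 16.5, xx - 16.5)
    assert count_residues(vortex) == 1
    assert count_residues(np.zeros((32, 32))) == 0


# ---------------------------------------------------------------- conversion

def test_phase_to_height_arithmetic():
    pm = h.PhaseMap(np.full((4, 4), 2 * np.pi), wrapped=False, sampling_um=0.26)
    out = h.phase_to_height(pm, delta_n=0.05, wavelength_um=0.6328)
    assert np.allclose(out.values, 12.656)


def test_phase_to_height_linear_and_validated():
    rng = np.random.default_rng(1)
    values = rng.uniform(0, 5, (16, 16))
    pm1 = h.PhaseMap(values, wrapped=False, sampling_um=0.26)
    pm2 = h.PhaseMap(2 * values, wrapped=False, sampling_um=0.26)
    h1 = h.phase_to_height(pm1, 0.05, 0.6328)
    h2 = h.phase_to_height(pm2, 0.05, 0.6328)
    assert np.allclose(h2.values, 2 * h1.values)
    with pytest.raises(ValueError):
        h.phase_to_height(h.PhaseMap(np.zeros((4, 4)), wrapped=True,
                                     sampling_um=1.0), 0.05, 0.6328)
    with pytest.raises(ValueError):
        h.phase_to_height(pm1, -0.1, 0.6328)


# ---------------------------------------------------------------- pipeline

def test_empty_scene_reconstructs_flat(optics):
    p = h.SceneParams(field_size_px=(128, 128), n_cells=0)
    scene = h.simulate_scene(p)
    obj, refs = make_holograms(scene, optics)
    height, qc = h.reconstruct(obj, refs, optics)
    assert np.abs(height.values).max() < 0.02
    assert qc.residue_count == 0


def test_noise_free_reconstruction_recovers_truth(optics, small_scene):
    """End-to-end loop on a cell scene: height RMSE well inside the 0.05 rad
    phase budget. (Spherical caps have slope discontinuities at the rim, so
    the residual here is set by the NA band limit, not by the pipeline.)"""
    obj, refs = make_holograms(small_scene, optics)
    opts = h.ReconstructionOptions()
    height, qc = h.reconstruct(obj, refs, optics, opts)
    true_h = (small_scene.true_phase * optics.wavelength_um
              / (2 * np.pi * opts.delta_n))
    rmse = np.sqrt(np.mean((height.values - true_h) ** 2))
    phase_budget_um = 0.05 * optics.wavelength_um / (2 * np.pi * opts.delta_n)
    assert rmse < phase_budget_um  # 0.05 rad ≙ ~0.10 µm; measured ~0.016 µm
    assert qc.chosen_reference == 0


def test_end_to_end_identity_on_band_limited_scene(optics):
    """End-to-end identity: for a scene whose phase lies inside the imaging
    passband, reconstructed height equals true height to RMSE < 0.01 µm."""
    rng = np.random.default_rng(11)
    yy, xx = np.mgrid[0:256, 0:256].astype(float)
    truth = np.zeros((256, 256))
    for _ in range(8):
        cy, cx = rng.uniform(40, 216, 2)
        amp = rng.uniform(1.0, 4.0)
        truth += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 8.0**2))

    def holo(phase):
        pm = h.PhaseMap(phase, wrapped=False,
                        sampling_um=optics.object_pixel_um)
        return h.synthesize_hologram(h.phase_to_field(pm, optics), optics,
                                     noise_meta=h.NoiseMeta())

    obj = holo(truth)
    refs = [holo(np.zeros_like(truth)) for _ in range(2)]
    opts = h.ReconstructionOptions()
    height, qc = h.reconstruct(obj, refs, optics, opts)
    true_h = truth * optics.wavelength_um / (2 * np.pi * opts.delta_n)
    rmse = np.sqrt(np.mean((height.values - true_h) ** 2))
    assert rmse < 0.01
    assert qc.residue_count == 0


def test_stage_errors_are_tagged(optics):
    flat = h.HologramFrame(intensity=np.full((64, 64), 128, dtype=np.uint8),
                           optics=optics)
    with pytest.raises(CarrierNotFoundError, match=r"\[extract_sideband\]"):
        h.reconstruct(flat, [flat], optics)
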
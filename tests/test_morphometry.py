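"""Segmentation, per-cell measurement, coverage and pore statistics."""

import numpy as np
import pytest

import holoqpi as h


def truth_height_map(scene, delta_n=0.05):
    """Height map straight from a scene's phase (bypasses imaging)."""
    values = scene.true_phase * scene.wavelength_um / (2 * np.pi * delta_n)
    return h.HeightMap(values=values, sampling_um=scene.params.object_pixel_um,
                       delta_n=delta_n)


def cap_height(shape, center, radius_px, height_um):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    sphere = (radius_px**2 + height_um**2) / (2 * height_um)  # px mixing is fine for tests
    out = np.zeros(shape)
    inside = r2 <= radius_px**2
    out[inside] = np.sqrt(np.clip(sphere**2 - r2[inside], 0, None)) - (sphere - height_um)
    return out


def test_empty_field_yields_no_regions():
    hm = h.HeightMap(np.zeros((64, 64)), sampling_um=0.26, delta_n=0.05)
    labels = h.segment_cells(hm)
    assert labels.max() == 0
    report = h.measure_cells(labels, hm)
    assert report.cell_count == 0
    assert report.total_volume_um3 == 0.0
    assert report.coverage_fraction == 0.0


def test_two_nearby_caps_get_two_labels():
    values = (cap_height((128, 128), (60, 50), 15, 3.0)
              + cap_height((128, 128), (60, 85), 15, 3.0))  # 20 px edge gap
    hm = h.HeightMap(values, sampling_um=0.26, delta_n=0.05)
    labels = h.segment_cells(hm)
    assert labels.max() == 2
    assert labels[60, 50] != labels[60, 85]
    assert labels[60, 50] > 0 and labels[60, 85] > 0


def test_watershed_splits_overlapping_footprints():
    values = np.maximum(cap_height((128, 128), (64, 52), 16, 3.0),
                        cap_height((128, 128), (64, 78), 16, 3.0))
    hm = h.HeightMap(values, sampling_um=0.26, delta_n=0.05)
    labels = h.segment_cells(hm)
    assert labels.max() == 2


def test_disc_coverage_matches_analytic_area():
    L, r = 128, 30
    yy, xx = np.mgrid[0:L, 0:L]
    disc = 2.0 * (((yy - 64) ** 2 + (xx - 64) ** 2) <= r**2)
    hm = h.HeightMap(disc, sampling_um=0.26, delta_n=0.05)
    labels = h.segment_cells(hm)
    report = h.measure_cells(labels, hm)
    assert report.coverage_fraction == pytest.approx(np.pi * r**2 / L**2, rel=0.05)


def test_cap_volume_recovered_within_five_percent():
    p = h.SceneParams(field_size_px=(128, 128), n_cells=1,
                      cell_radius_um=(8.0, 8.0), cell_height_um=(3.0, 3.0), seed=2)
    scene = h.simulate_scene(p)
    hm = truth_height_map(scene)
    labels = h.segment_cells(hm)
    report = h.measure_cells(labels, hm)
    assert report.cell_count == 1
    assert report.regions[0].volume_um3 == pytest.approx(
        h.cap_volume_um3(8.0, 3.0), rel=0.05)


def test_segmentation_count_matches_truth_across_seeds():
    """Count equals the generating count on well-separated scenes."""
    for seed in range(100):
        p = h.SceneParams(field_size_px=(192, 192), n_cells=4,
                          cell_radius_um=(3.0, 5.0), seed=seed)
        scene = h.simulate_scene(p)
        labels = h.segment_cells(truth_height_map(scene))
        assert labels.max() == 4, f"seed {seed}"


def test_volume_additive_over_field_halves():
    p = h.SceneParams(field_size_px=(128, 256), n_cells=3,
                      cell_radius_um=(3.0, 4.0), seed=8)
    scene = h.simulate_scene(p)
    hm = truth_height_map(scene)
    full = h.measure_cells(h.segment_cells(hm), hm).total_volume_um3
    halves = 0.0
    for sl in (np.s_[:, :128], np.s_[:, 128:]):
        sub = h.HeightMap(hm.values[sl], sampling_um=hm.sampling_um,
                          delta_n=hm.delta_n)
        halves += h.measure_cells(h.segment_cells(sub), sub).total_volume_um3
    # cells may straddle the cut; tolerate discretisation only when they don't
    if all(not (120 < c.center_px[1] < 136) for c in scene.cells):
        assert halves == pytest.approx(full, rel=0.02)


def test_coverage_invariant_to_height_rescaling():
    p = h.SceneParams(field_size_px=(128, 128), n_cells=3, seed=4)
    scene = h.simulate_scene(p)
    hm = truth_height_map(scene)
    cov1 = h.measure_cells(h.segment_cells(hm), hm).coverage_fraction
    hm2 = h.HeightMap(hm.values * 1.7, sampling_um=hm.sampling_um, delta_n=0.05)
    cov2 = h.measure_cells(h.segment_cells(hm2), hm2).coverage_fraction
    assert cov1 == pytest.approx(cov2, rel=0.02)


def test_mismatched_shapes_rejected():
    hm = h.HeightMap(np.zeros((16, 16)), sampling_um=1.0, delta_n=0.05)
    with pytest.raises(ValueError):
        h.measure_cells(np.zeros((8, 8), dtype=int), hm)


# ------------------------------------------------------------------- pores

def test_flat_membrane_has_no_pores():
    hm = h.HeightMap(np.zeros((128, 128)), sampling_um=0.26, delta_n=0.05)
    stats = h.detect_pores(hm, expected_diameter_um=0.4)
    assert stats.count == 0
    assert stats.qc_pass is None


def test_pore_lattice_count_and_pitch():
    """10×10 lattice of 5 px pores at 20 px pitch: all found, pitch within 10 %."""
    values = np.zeros((220, 220))
    for i in range(10):
        for j in range(10):
            cy, cx = 20 + 20 * i, 20 + 20 * j
            yy, xx = np.mgrid[0:220, 0:220]
            values[((yy - cy) ** 2 + (xx - cx) ** 2) <= 2.5**2] = -2.0
    hm = h.HeightMap(values, sampling_um=1.0, delta_n=0.05)
    stats = h.detect_pores(hm, expected_diameter_um=5.0, qc_max_diameter_um=6.0)
    assert stats.count == 100
    assert stats.median_pitch_um == pytest.approx(20.0, rel=0.10)


def test_default_membrane_pore_diameter_recovered():
    """On a finely sampled synthetic membrane the estimated mean pore
    diameter lands within 15 % of the configured 0.4 µm."""
    p = h.SceneParams(field_size_px=(256, 256), object_pixel_um=0.05,
                      n_cells=0, membrane_enabled=True, seed=1)
    scene = h.simulate_scene(p)
    hm = truth_height_map(scene)
    stats = h.detect_pores(hm, expected_diameter_um=p.pore_diameter_um)
    assert stats.count > 0
    assert stats.mean_diameter_um == pytest.approx(0.4, rel=0.15)
    assert stats.qc_pass is True
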
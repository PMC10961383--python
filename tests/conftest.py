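import dataclasses

import numpy as np
import pytest

import holoqpi as h


@pytest.fixture(scope="session")
def optics():
    return h.OpticalConfig()


@pytest.fixture(scope="session")
def small_scene_params():
    """A 256² field that comfortably hosts 10 mid-sized cells."""
    return h.SceneParams(field_size_px=(256, 256), n_cells=10,
                         cell_radius_um=(5.0, 8.0), cell_height_um=(2.0, 4.0),
                         seed=3)


@pytest.fixture(scope="session")
def small_scene(small_scene_params):
    return h.simulate_scene(small_scene_params)


@pytest.fixture(scope="session")
def noise_free():
    return h.NoiseMeta()


def make_holograms(scene, optics, noise=None, defocus_um=0.0,
                   normalization="mean", n_refs=1, seed=0):
    """Object + reference holograms of a scene (shared helper)."""
    noise = noise or h.NoiseMeta()
    phase = h.PhaseMap(scene.true_phase, wrapped=False,
                       sampling_um=scene.params.object_pixel_um)
    field = h.phase_to_field(phase, optics)
    obj = h.synthesize_hologram(field, optics, defocus_um=defocus_um,
                                noise_meta=dataclasses.replace(noise, seed=seed),
                                normalization=normalization)
    refs = [h.synthesize_hologram(field, optics, role="reference",
                                  noise_meta=dataclasses.replace(noise,
                                                                 seed=seed + 1 + k),
                                  normalization=normalization)
            for k in range(n_refs)]
    return obj, refs


def smooth_random_field(rng, shape=(128, 128), amplitude=4.0, coarse=8):
    """Residue-free smooth random phase surface via cubic upsampling."""
    from scipy.ndimage import zoom
    base = rng.normal(size=(coarse, coarse))
    factors = (shape[0] / coarse, shape[1] / coarse)
    return zoom(base, factors, order=3) * amplitude
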
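"""Ground-truth scene generator: cell monolayers on a porous membrane.

Cells are modelled as spherical caps sitting on the substrate. A cap with
base radius ``a`` and apex height ``h`` is the top slice of a sphere of
radius ``R = (a² + h²) / (2h)``; its profile is

    h(r) = sqrt(R² − r²) − (R − h_max),   r ≤ a,

and its volume has the closed form ``V = π h (3a² + h²) / 6``, which every
volume oracle in the test-suite uses. The optical phase contributed by a
cell of thickness ``h`` in a medium of index ``n_m`` is the standard
quantitative-phase relation ``φ = 2π Δn h / λ`` with
``Δn = n_cell − n_medium``.

Treatments shrink each surviving cell's profile vertically by a per-cell
factor ``1 − s_i`` (footprint fixed), so the cell volume is multiplied by
exactly ``1 − s_i``; this mirrors population-level volume loss reported as
a percent decrease. Cell loss removes whole cells at random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SceneParams",
    "TreatmentEffect",
    "CellSpec",
    "SyntheticScene",
    "FlowEventTable",
    "simulate_scene",
    "apply_treatment",
    "simulate_flow_events",
    "cap_volume_um3",
    "PlacementError",
    "TREATMENT_PRESETS",
    "UPTAKE_FRACTIONS",
    "treatment_preset",
]

TREATMENT_LABELS = ("control", "si-EV", "fol-si-EV", "DOX-EV", "fol-DOX-EV")

#: Reported astrocyte volume-decrease effect sizes for the four vesicle
#: formulations (mean shrink fraction, with the reported spread used as the
#: per-cell dispersion). Count changes are deliberately left at zero: the
#: reported count effects are ambiguous and are config-driven instead.
TREATMENT_PRESETS = {
    "si-EV": dict(volume_shrink_fraction=0.07406, shrink_dispersion=0.0126),
    "fol-si-EV": dict(volume_shrink_fraction=0.1462, shrink_dispersion=0.0216),
    "DOX-EV": dict(volume_shrink_fraction=0.2725, shrink_dispersion=0.04026),
    "fol-DOX-EV": dict(volume_shrink_fraction=0.4854, shrink_dispersion=0.1140),
}

#: Reported endothelial uptake fractions for gating recovery studies.
UPTAKE_FRACTIONS = {
    "fol-si-EV": 0.7894,
    "si-EV": 0.2959,
    "fol-DOX-EV": 0.9881,
    "DOX-EV": 0.8779,
}


def treatment_preset(label: str) -> "TreatmentEffect":
    """The reported effect of one formulation, as a :class:`TreatmentEffect`."""
    return TreatmentEffect(label=label, **TREATMENT_PRESETS[label])

MAX_PLACEMENT_RETRIES = 10_000


class PlacementError(RuntimeError):
    """Raised when non-overlapping cell placement fails: field too crowded."""


def cap_volume_um3(base_radius_um: float, height_um: float) -> float:
    """Closed-form spherical-cap volume, V = pi*h*(3a^2 + h^2)/6."""
    a, h = base_radius_um, height_um
    return np.pi * h * (3 * a * a + h * h) / 6.0


@dataclass(frozen=True)
class SceneParams:
    """Geometry and optics of one synthetic field of view."""

    field_size_px: Tuple[int, int] = (384, 384)
    object_pixel_um: float = 0.26
    n_cells: int = 25
    cell_radius_um: Tuple[float, float] = (3.0, 5.0)
    cell_height_um: Tuple[float, float] = (2.0, 4.0)
    cell_refractive_index: float = 1.385
    medium_refractive_index: float = 1.335
    membrane_enabled: bool = False
    pore_diameter_um: float = 0.4
    pore_pitch_um: float = 4.0
    pore_depth_phase_rad: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        ny, nx = self.field_size_px
        if ny <= 0 or nx <= 0:
            raise ValueError("field_size_px must be positive")
        if self.object_pixel_um <= 0:
            raise ValueError("object_pixel_um must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        for name in ("cell_radius_um", "cell_height_um"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (min, max) range")
        if self.delta_n <= 0:
            raise ValueError(
                "cell_refractive_index must exceed medium_refractive_index "
                "(cells are phase-advancing)"
            )
        if self.membrane_enabled and not (0 < self.pore_diameter_um < self.pore_pitch_um):
            raise ValueError("pore_diameter_um must be < pore_pitch_um")

    @property
    def delta_n(self) -> float:
        return self.cell_refractive_index - self.medium_refractive_index


@dataclass(frozen=True)
class TreatmentEffect:
    """Population-level effect of one vesicle/drug formulation."""

    label: str
    volume_shrink_fraction: float = 0.0
    cell_loss_count: int = 0
    shrink_dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in TREATMENT_LABELS:
            raise ValueError(f"label must be one of {TREATMENT_LABELS}")
        if not (0 <= self.volume_shrink_fraction < 1):
            raise ValueError("volume_shrink_fraction must be in [0, 1)")
        if self.cell_loss_count < 0:
            raise ValueError("cell_loss_count must be non-negative")
        if self.shrink_dispersion < 0:
            raise ValueError("shrink_dispersion must be non-negative")
        if self.label == "control" and (
            self.volume_shrink_fraction != 0 or self.cell_loss_count != 0
        ):
            raise ValueError("control effect must have zero shrink and zero loss")


@dataclass(frozen=True)
class CellSpec:
    """One placed cell: centre in pixels (row, col), cap geometry, and the
    vertical scale applied by treatments (1.0 for untreated)."""

    center_px: Tuple[float, float]
    radius_um: float
    max_height_um: float
    height_scale: float = 1.0

    @property
    def volume_um3(self) -> float:
        return cap_volume_um3(self.radius_um, self.max_height_um) * self.height_scale


@dataclass
class SyntheticScene:
    """Truth record: placed cells, membrane, and the rasterised phase."""

    params: SceneParams
    cells: List[CellSpec]
    true_phase: np.ndarray
    wavelength_um: float = 0.6328

    @property
    def true_cell_volumes_um3(self) -> List[float]:
        return [c.volume_um3 for c in self.cells]

    @property
    def total_true_volume_um3(self) -> float:
        return float(sum(self.true_cell_volumes_um3))

    def cell_height_field_um(self) -> np.ndarray:
        """Rasterised cell-only thickness map (no membrane), in µm."""
        return _rasterize_cells(self.params, self.cells)

    def to_json(self) -> str:
        d = {
            "params": {
                **{k: getattr(self.params, k) for k in (
                    "object_pixel_um", "n_cells", "cell_refractive_index",
                    "medium_refractive_index", "membrane_enabled",
                    "pore_diameter_um", "pore_pitch_um",
                    "pore_depth_phase_rad", "seed")},
                "field_size_px": list(self.params.field_size_px),
                "cell_radius_um": list(self.params.cell_radius_um),
                "cell_height_um": list(self.params.cell_height_um),
            },
            "wavelength_um": self.wavelength_um,
            "cells": [
                {"center_px": list(c.center_px), "radius_um": c.radius_um,
                 "max_height_um": c.max_height_um, "height_scale": c.height_scale,
                 "volume_um3": c.volume_um3}
                for c in self.cells
            ],
        }
        return json.dumps(d, indent=2)


def _cap_profile_um(r2_um2: np.ndarray, radius_um: float, height_um: float) -> np.ndarray:
    """Spherical-cap thickness at squared radial distance r² (µm²)."""
    sphere_r = (radius_um**2 + height_um**2) / (2.0 * height_um)
    inside = r2_um2 <= radius_um**2
    h = np.zeros_like(r2_um2)
    h[inside] = np.sqrt(sphere_r**2 - r2_um2[inside]) - (sphere_r - height_um)
    return h


def _rasterize_cells(params: SceneParams, cells: Sequence[CellSpec]) -> np.ndarray:
    ny, nx = params.field_size_px
    dx = params.object_pixel_um
    height = np.zeros((ny, nx))
    for c in cells:
        cy, cx = c.center_px
        r_px = int(np.ceil(c.radius_um / dx)) + 1
        y0, y1 = max(0, int(cy) - r_px), min(ny, int(cy) + r_px + 1)
        x0, x1 = max(0, int(cx) - r_px), min(nx, int(cx) + r_px + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) * dx**2
        height[y0:y1, x0:x1] += (
            _cap_profile_um(r2, c.radius_um, c.max_height_um) * c.height_scale
        )
    return height


def _membrane_phase(params: SceneParams) -> np.ndarray:
    """Square lattice of circular pores as negative-phase wells."""
    ny, nx = params.field_size_px
    dx = params.object_pixel_um
    pitch_px = params.pore_pitch_um / dx
    r_px = params.pore_diameter_um / (2 * dx)
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    # distance of each pixel to the nearest lattice site (offset half pitch)
    dy = np.abs(np.mod(yy + pitch_px / 2, pitch_px) - pitch_px / 2)
    dxm = np.abs(np.mod(xx + pitch_px / 2, pitch_px) - pitch_px / 2)
    phase = np.zeros((ny, nx))
    phase[dy**2 + dxm**2 <= r_px**2] = -params.pore_depth_phase_rad
    return phase


def _phase_from_height(height_um: np.ndarray, delta_n: float, wavelength_um: float) -> np.ndarray:
    return 2 * np.pi * delta_n * height_um / wavelength_um


def _render_phase(params: SceneParams, cells: Sequence[CellSpec],
                  wavelength_um: float) -> np.ndarray:
    phase = _phase_from_height(_rasterize_cells(params, cells),
                               params.delta_n, wavelength_um)
    if params.membrane_enabled:
        phase = phase + _membrane_phase(params)
    return phase


def simulate_scene(params: SceneParams, wavelength_um: float = 0.6328) -> SyntheticScene:
    """Place ``n_cells`` non-overlapping spherical-cap cells by rejection
    sampling and rasterise the ground-truth phase.

    Deterministic for a fixed ``params.seed``. Raises :class:`PlacementError`
    if the field cannot host the requested cells after bounded retries.
    """
    rng = np.random.default_rng(params.seed)
    ny, nx = params.field_size_px
    dx = params.object_pixel_um
    cells: List[CellSpec] = []
    placed: List[Tuple[float, float, float]] = []  # (cy, cx, radius_px)
    for _ in range(params.n_cells):
        r_um = rng.uniform(*params.cell_radius_um)
        h_um = rng.uniform(*params.cell_height_um)
        r_px = r_um / dx
        for attempt in range(MAX_PLACEMENT_RETRIES):
            cy = rng.uniform(r_px, ny - 1 - r_px)
            cx = rng.uniform(r_px, nx - 1 - r_px)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (r_px + pr) ** 2
                   for py, px, pr in placed):
                break
        else:
            raise PlacementError(
                f"field too crowded: could not place cell {len(cells) + 1} "
                f"of {params.n_cells} after {MAX_PLACEMENT_RETRIES} retries"
            )
        placed.append((cy, cx, r_px))
        cells.append(CellSpec((cy, cx), r_um, h_um))
    phase = _render_phase(params, cells, wavelength_um)
    return SyntheticScene(params=params, cells=cells, true_phase=phase,
                          wavelength_um=wavelength_um)


def apply_treatment(scene: SyntheticScene, effect: TreatmentEffect, seed: int,
                    render_phase: bool = True,
                    antithetic: bool = False) -> SyntheticScene:
    """Apply cell loss and per-cell volume shrink to a scene.

    Removes exactly ``cell_loss_count`` randomly chosen cells, then draws a
    shrink fraction ``s_i ~ Normal(volume_shrink_fraction, shrink_dispersion)``
    truncated to [0, 1) for each survivor and multiplies its volume by
    ``1 − s_i`` (vertical rescale, footprint fixed).

    ``antithetic=True`` mirrors every shrink deviate (``s_i = μ − σ·z_i``
    instead of ``μ + σ·z_i`` for the same ``seed``): pairing a treatment
    with its antithetic twin makes the pair's mean shrink exactly equal to
    ``volume_shrink_fraction``, the standard Monte-Carlo variance-reduction
    device for recovery studies.

    ``render_phase=False`` skips rasterisation and returns a scene whose
    ``true_phase`` is shared with the input — useful for volume-only
    Monte-Carlo studies.
    """
    if effect.cell_loss_count > len(scene.cells):
        raise ValueError("cell_loss_count exceeds the number of cells in the scene")
    if effect.label == "control":
        return scene
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(scene.cells),
                              size=len(scene.cells) - effect.cell_loss_count,
                              replace=False))
    survivors = []
    for i in keep:
        c = scene.cells[i]
        if effect.shrink_dispersion > 0:
            z = rng.standard_normal()
            if antithetic:
                z = -z
            s = effect.volume_shrink_fraction + effect.shrink_dispersion * z
            s = float(np.clip(s, 0.0, 1.0 - 1e-9))
        else:
            s = effect.volume_shrink_fraction
        survivors.append(replace(c, height_scale=c.height_scale * (1.0 - s)))
    phase = (_render_phase(scene.params, survivors, scene.wavelength_um)
             if render_phase else scene.true_phase)
    return SyntheticScene(params=scene.params, cells=survivors, true_phase=phase,
                          wavelength_um=scene.wavelength_um)


@dataclass
class FlowEventTable:
    """Per-event fluorescence intensities with generator metadata."""

    events: pd.DataFrame  # columns: event_id, intensity, group
    true_positive_fraction: float
    negative_location: float
    negative_scale: float
    positive_location: float
    positive_scale: float
    n_events: int
    seed: int
    overlap_warning: bool = False

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        inten = self.events["intensity"].to_numpy()
        if not np.all(np.isfinite(inten)) or inten.min() < 0:
            raise ValueError("intensities must be finite and non-negative")

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)


def simulate_flow_events(
    true_positive_fraction: float,
    n_events: int,
    seed: int,
    negative_location: float = 1.0,
    negative_scale: float = 0.20,
    positive_location: float = 2.5,
    positive_scale: float = 0.25,
) -> FlowEventTable:
    """Two-population log-normal fluorescence mixture.

    Locations/scales are in log10-intensity units (decades), the scale
    flow analysts plot on. Each event is positive with probability
    ``true_positive_fraction``. An ``overlap_warning`` is set when the two
    component locations differ by less than one pooled scale unit — gate
    recovery is then not guaranteed.
    """
    if not (0 <= true_positive_fraction <= 1):
        raise ValueError("true_positive_fraction must be in [0, 1]")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    positive = rng.random(n_events) < true_positive_fraction
    log10_i = np.where(
        positive,
        rng.normal(positive_location, positive_scale, n_events),
        rng.normal(negative_location, negative_scale, n_events),
    )
    events = pd.DataFrame({
        "event_id": np.arange(n_events),
        "intensity": 10.0 ** log10_i,
        "group": np.where(positive, "positive", "negative"),
    })
    overlap = abs(positive_location - negative_location) < max(
        negative_scale, positive_scale)
    return FlowEventTable(
        events=events,
        true_positive_fraction=true_positive_fraction,
        negative_location=negative_location,
        negative_scale=negative_scale,
        positive_location=positive_location,
        positive_scale=positive_scale,
        n_events=n_events,
        seed=seed,
        overlap_warning=overlap,
    )
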
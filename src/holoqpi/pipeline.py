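"""End-to-end closed-loop experiments: simulate → image → reconstruct →
measure → compare.

`field_roundtrip` is the workhorse: it renders one synthetic field,
records object and reference holograms with the configured detector noise,
runs the full reconstruction and returns the morphometry report. The
treatment-level helpers pair an untreated and a treated rendering of the
same field so percent volume decreases can be recovered and checked
against the generating effect sizes.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as hio
from .config import RunConfig, config_to_dict, save_config
from .forward import phase_to_field, synthesize_hologram
from .morphometry import MorphometryReport, measure_cells, segment_cells
from .optics import NoiseMeta, OpticalConfig, PhaseMap
from .reconstruct import ReconstructionOptions, reconstruct
from .scene import (SceneParams, SyntheticScene, TreatmentEffect,
                    apply_treatment, simulate_flow_events, simulate_scene)
from .stats import (ConditionSummary, UptakeResult, compare_conditions,
                    gate_positive, volume_change)

__all__ = ["field_roundtrip", "closed_loop_condition", "run_pipeline"]


def _hologram_pair(scene: SyntheticScene, optics: OpticalConfig,
                   noise: NoiseMeta, seed: int, n_references: int = 2):
    """Object hologram plus reference holograms of an empty field."""
    phase = PhaseMap(values=scene.true_phase, wrapped=False,
                     sampling_um=scene.params.object_pixel_um)
    obj_field = phase_to_field(phase, optics)
    obj = synthesize_hologram(obj_field, optics,
                              noise_meta=replace(noise, seed=seed))
    refs = [synthesize_hologram(obj_field, optics, role="reference",
                                noise_meta=replace(noise, seed=seed + 1 + k))
            for k in range(n_references)]
    return obj, refs


def field_roundtrip(scene: SyntheticScene, optics: OpticalConfig,
                    noise: NoiseMeta, recon: ReconstructionOptions,
                    seed: int,
                    min_height_um: float = 0.3, min_area_um2: float = 5.0,
                    support_height_um: float = 0.1,
                    smoothing_sigma_px: float = 2.0,
                    ) -> Tuple[MorphometryReport, object, object]:
    """Scene → hologram → reconstruction → morphometry for one field.

    Returns (report, height_map, qc_report).
    """
    obj, refs = _hologram_pair(scene, optics, noise, seed)
    height, qc = reconstruct(obj, refs, optics, recon)
    labels = segment_cells(height, min_height_um=min_height_um,
                           min_area_um2=min_area_um2,
                           support_height_um=support_height_um,
                           smoothing_sigma_px=smoothing_sigma_px)
    return measure_cells(labels, height), height, qc


def closed_loop_condition(effect: TreatmentEffect, n_fields: int, seed: int,
                          scene_params: Optional[SceneParams] = None,
                          optics: Optional[OpticalConfig] = None,
                          noise: Optional[NoiseMeta] = None,
                          recon: Optional[ReconstructionOptions] = None,
                          antithetic_pairs: bool = False,
                          ) -> ConditionSummary:
    """Recover one treatment's volume effect through the imaging pipeline.

    For each of ``n_fields`` independent fields, the same placed cells are
    rendered untreated and treated, both renderings are imaged and
    reconstructed, and the field-level percent volume decrease is measured.

    With ``antithetic_pairs`` (``n_fields`` must be even) fields come in
    antithetic pairs: the second member of each pair reuses the first's
    scene and treatment seed with mirrored shrink deviates, so the realized
    mean shrink across the fields equals the generating value exactly and
    the recovery error reflects the imaging pipeline alone rather than the
    generator's own Monte-Carlo draw.
    """
    scene_params = scene_params or SceneParams()
    optics = optics or OpticalConfig()
    noise = noise if noise is not None else NoiseMeta(photon_scale=1000.0,
                                                     read_noise_sigma=1.0)
    recon = recon or ReconstructionOptions()
    if antithetic_pairs and n_fields % 2:
        raise ValueError("antithetic_pairs requires an even n_fields")
    ss = np.random.SeedSequence(entropy=seed)
    n_children = n_fields // 2 if antithetic_pairs else n_fields
    pre_reports, post_reports = [], []
    for f, child in enumerate(ss.spawn(n_children)):
        s_scene, s_treat, s_noise_pre, s_noise_post = [
            int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(4)]
        pre = simulate_scene(dataclasses.replace(scene_params, seed=s_scene),
                             wavelength_um=optics.wavelength_um)
        mirrors = (False, True) if antithetic_pairs else (False,)
        for k, mirror in enumerate(mirrors):
            post = apply_treatment(pre, effect, seed=s_treat, antithetic=mirror)
            rep_pre, _, _ = field_roundtrip(pre, optics, noise, recon,
                                            (s_noise_pre + 2 * k) % 2**31)
            rep_post, _, _ = field_roundtrip(post, optics, noise, recon,
                                             (s_noise_post + 2 * k) % 2**31)
            pre_reports.append(rep_pre)
            post_reports.append(rep_post)
    return volume_change(pre_reports, post_reports, label=effect.label)


def run_pipeline(config: RunConfig) -> Dict:
    """Run the full study described by a :class:`RunConfig`.

    Writes a deterministic artifact tree (holograms/, height/, tables/,
    report.json, the echoed effective config) under ``config.output_dir``
    and returns the report dictionary. Any stage error propagates with a
    stage-tagged message and a non-zero CLI exit.
    """
    out = Path(config.output_dir)
    for sub in ("holograms", "height", "tables"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    save_config(config, out / "effective_config.yaml")

    treatments = list(config.treatments)
    if not any(t.label == "control" for t in treatments):
        treatments.insert(0, TreatmentEffect(label="control"))

    t0 = time.time()
    summaries: List[ConditionSummary] = []
    ss = np.random.SeedSequence(entropy=config.seed)
    cond_seeds = {t.label: int(c.generate_state(1)[0] % (2**31))
                  for t, c in zip(treatments, ss.spawn(len(treatments)))}
    mo = config.morphometry
    for t in treatments:
        ss_cond = np.random.SeedSequence(entropy=cond_seeds[t.label])
        pre_reports, post_reports = [], []
        for f, child in enumerate(ss_cond.spawn(config.stats.n_fields)):
            s_scene, s_treat, s_pre, s_post = [
                int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(4)]
            pre = simulate_scene(dataclasses.replace(config.scene, seed=s_scene),
                                 wavelength_um=config.optics.wavelength_um)
            post = apply_treatment(pre, t, seed=s_treat)
            for tag, scene, s_noise, bucket in (("pre", pre, s_pre, pre_reports),
                                                ("post", post, s_post, post_reports)):
                obj, refs = _hologram_pair(scene, config.optics, config.noise, s_noise)
                stem = f"{t.label}_f{f}_{tag}"
                hio.write_hologram(out / "holograms" / f"{stem}.tif", obj)
                height, _qc = reconstruct(obj, refs, config.optics,
                                          config.reconstruction)
                hio.write_height_map(out / "height" / f"{stem}.tif", height)
                labels = segment_cells(height, min_height_um=mo.min_height_um,
                                       min_area_um2=mo.min_area_um2,
                                       support_height_um=mo.support_height_um,
                                       smoothing_sigma_px=mo.smoothing_sigma_px)
                bucket.append(measure_cells(labels, height))
        summaries.append(volume_change(pre_reports, post_reports, label=t.label))

    summary_df = pd.DataFrame([
        {"label": s.label, "n_fields": s.n_fields,
         "mean_volume_decrease_pct": s.mean_volume_decrease_pct,
         "sd_volume_decrease_pct": s.sd_volume_decrease_pct,
         "mean_count_change": s.mean_count_change,
         "sd_count_change": s.sd_count_change}
        for s in summaries
    ])
    summary_df.to_csv(out / "tables" / "condition_summary.csv", index=False)

    control = next(s for s in summaries if s.label == "control")
    comparisons = []
    for s in summaries:
        if s.label == "control":
            continue
        diff, p = compare_conditions(s.per_field_decrease_pct,
                                     control.per_field_decrease_pct)
        comparisons.append({"label": s.label, "vs": "control",
                            "mean_difference_pct": diff, "p_value": p})
    pd.DataFrame(comparisons).to_csv(out / "tables" / "comparisons.csv", index=False)

    uptake_rows = []
    if config.flow_groups:
        ss_flow = np.random.SeedSequence(entropy=config.seed + 1)
        for g, child in zip(config.flow_groups, ss_flow.spawn(len(config.flow_groups))):
            s_a, s_b = [int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(2)]
            treated = simulate_flow_events(g.positive_fraction, g.n_events, seed=s_a)
            ctrl = simulate_flow_events(0.0, g.n_events, seed=s_b)
            r = gate_positive(treated, ctrl,
                              control_quantile=config.stats.control_quantile,
                              label=g.label)
            uptake_rows.append({"label": g.label,
                                "percent_positive": r.percent_positive,
                                "gate_threshold": r.gate_threshold,
                                "control_false_positive_pct":
                                    r.control_false_positive_pct})
        pd.DataFrame(uptake_rows).to_csv(out / "tables" / "uptake.csv", index=False)

    report = {
        "seed": config.seed,
        "n_fields": config.stats.n_fields,
        "conditions": summary_df.to_dict(orient="records"),
        "comparisons": comparisons,
        "uptake": uptake_rows,
        "wall_time_s": time.time() - t0,
    }
    hio.write_json(out / "report.json", report)
    return report
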
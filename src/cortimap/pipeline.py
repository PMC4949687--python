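"""End-to-end scenario runs: simulate -> map -> cluster -> GLM -> overlap.

A scenario is a single YAML/dict configuration with every stochastic
stage given an explicit seed, so a rerun reproduces every output
bit-exactly.  The run produces per-stage outputs on disk plus a final
overlap report and a provenance log (parameters, seeds, version).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import apply_cluster_exclusion, estimate_cluster_threshold
from .glm import Contrast, build_design_matrix, fit_glm, fixed_effects, group_inference
from .group import group_map
from .mesh import SmoothSpec
from .overlap import overlap_percentage
from .phase import (
    CombineSpec,
    PhaseCoordinateMap,
    PhaseEncodedDesign,
    decode_phase,
    fourier_stat,
    combine_runs,
)
from .synth import (
    GroundTruth,
    make_icosphere,
    paint_map_patch,
    simulate_phase_cohort,
    simulate_reading_cohort,
)

DEFAULT_CONFIG: dict = {
    "mesh": {"subdivisions": 3, "radius_mm": 50.0},
    "smoothing_steps": 10,
    "phase": {
        "n_samples": 512, "tr": 1.0, "cycles_per_run": 8, "modality": "visual",
        "n_subjects": 6, "n_runs": 4, "delay_s": 4.0,
        "amplitude": 1.0, "noise_sigma": 1.0,
        "patch": {"center_vertex": 0, "radius_mm": 30.0},
        "seed": None,
    },
    "reading": {
        "n_subjects": 6, "runs_per_subject": 2, "tr": 1.0,
        "effect": 1.0, "noise_sigma": 1.0,
        "patch": {"center_vertex": 0, "radius_mm": 20.0},
        "seed": None,
    },
    "cluster": {"vertex_p": 0.01, "alpha": 0.05, "iterations": 200, "seed": None},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    """Fill defaults, derive per-stage seeds, check thresholds."""
    if "seed" not in cfg:
        raise ValueError("config must declare a top-level seed")
    import copy

    merged = _merge(copy.deepcopy(DEFAULT_CONFIG), cfg)
    master = int(merged["seed"])
    ss = np.random.SeedSequence(master).spawn(3)
    for stage, seq in zip(("phase", "reading", "cluster"), ss):
        if merged[stage].get("seed") is None:
            merged[stage]["seed"] = int(seq.generate_state(1)[0] % (2**31 - 1))
    cl = merged["cluster"]
    if not (0 < cl["vertex_p"] < 1 and 0 < cl["alpha"] < 1):
        raise ValueError("cluster thresholds must lie in (0, 1)")
    return merged


def run_scenario(config: dict, out_dir) -> dict:
    """Run the full chain and write a report bundle under ``out_dir``.

    Returns the report as a dict (also written to report.json):
    the estimated cluster criterion, mask sizes, the overlap table,
    and ground-truth overlap for comparison.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mesh = make_icosphere(cfg["mesh"]["subdivisions"], cfg["mesh"]["radius_mm"])
    areas = mesh.vertex_areas()
    spec = SmoothSpec(steps=cfg["smoothing_steps"])

    # --- phase-encoded mapping chain -------------------------------------
    pc = cfg["phase"]
    design = PhaseEncodedDesign(
        pc["n_samples"], pc["tr"], pc["cycles_per_run"], "forward", pc["modality"]
    )
    phases = paint_map_patch(
        mesh, pc["patch"]["center_vertex"], pc["patch"]["radius_mm"]
    )
    truth_phase = GroundTruth(
        phase=phases,
        amplitude=np.full(mesh.n_vertices, pc["amplitude"]),
        delay_s=pc["delay_s"],
        noise_sigma=pc["noise_sigma"],
        seed=pc["seed"],
    )
    cohort = simulate_phase_cohort(
        truth_phase, design, pc["n_subjects"], pc["n_runs"], seed=pc["seed"]
    )
    combine = CombineSpec(delay_s=pc["delay_s"])
    subject_maps = []
    for runs in cohort:
        combined = combine_runs(runs, combine)
        cmap, _ = fourier_stat(combined)
        subject_maps.append(cmap)
    gmap = group_map(subject_maps, mesh, spec)

    # --- cluster criterion, applied to the group phase map ----------------
    cl = cfg["cluster"]
    criterion = estimate_cluster_threshold(
        mesh, spec, cl["vertex_p"], cl["alpha"], cl["iterations"], cl["seed"]
    )
    map_mask_bool = apply_cluster_exclusion(gmap.p, mesh, criterion)
    map_mask = set(np.flatnonzero(map_mask_bool).tolist())

    omega_d = 2 * np.pi * pc["cycles_per_run"] * pc["delay_s"] / design.run_seconds
    coord = PhaseCoordinateMap(modality=pc["modality"], phase_offset=omega_d)
    decoded = decode_phase(
        type(subject_maps[0])(gmap.mean), coord
    )

    # --- reading GLM chain ------------------------------------------------
    rd = cfg["reading"]
    read_phase = paint_map_patch(
        mesh, rd["patch"]["center_vertex"], rd["patch"]["radius_mm"]
    )
    reading_vertices = ~np.isnan(read_phase)
    effects = {
        "English": np.where(reading_vertices, rd["effect"], 0.0),
        "Hindi": np.zeros(mesh.n_vertices),
        "Dot": np.zeros(mesh.n_vertices),
    }
    truth_read = GroundTruth(
        phase=read_phase,
        amplitude=np.zeros(mesh.n_vertices),
        effects=effects,
        noise_sigma=rd["noise_sigma"],
        seed=rd["seed"],
    )
    reading = simulate_reading_cohort(
        truth_read, rd["n_subjects"], rd["runs_per_subject"], seed=rd["seed"],
        tr=rd["tr"],
    )
    contrast = Contrast("English-Hindi", {"English": 1.0, "Hindi": -1.0})
    subject_results = []
    for runs in reading.data:
        run_fits = []
        for y, bdesign in runs:
            dm = build_design_matrix(bdesign)
            run_fits.append(fit_glm(y, dm, [contrast]))
        subject_results.append(fixed_effects(run_fits))
    greading = group_inference(subject_results, contrast)
    reading_mask_bool = apply_cluster_exclusion(greading.p[0], mesh, criterion)
    reading_mask = set(np.flatnonzero(reading_mask_bool).tolist())

    # --- overlap ----------------------------------------------------------
    report_df = overlap_percentage(reading_mask, map_mask, areas)
    truth_reading = set(np.flatnonzero(reading_vertices).tolist())
    truth_map = set(np.flatnonzero(~np.isnan(phases)).tolist())
    truth_df = overlap_percentage(truth_reading, truth_map, areas)

    report = {
        "version": __version__,
        "config": cfg,
        "cluster_criterion": {
            "vertex_p": criterion.vertex_p,
            "min_area_mm2": criterion.min_area_mm2,
            "alpha": criterion.alpha,
        },
        "n_map_vertices": len(map_mask),
        "n_reading_vertices": len(reading_mask),
        "overlap": report_df.reset_index().to_dict(orient="records"),
        "ground_truth_overlap": truth_df.reset_index().to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    report_df.to_csv(out / "overlap.csv")
    pd.DataFrame(
        {
            "amplitude": gmap.amplitude,
            "phase": gmap.phase,
            "f": gmap.f,
            "p": gmap.p,
            "decoded": decoded,
        }
    ).to_csv(out / "group_phase_map.csv", index_label="vertex")
    return report
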
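"""Synthetic cortical surfaces and fMRI signals with known ground truth.

Everything the analysis chain consumes can be generated here: icosphere
meshes standing in for a cortical hemisphere, smooth topological-map
patches (phase gradients over a geodesic disc), phase-encoded runs with
hemodynamic delay and forward/reverse directions, and multi-subject
block-design reading runs with localized condition effects.  Every
generator is a pure function of its parameters and seed, so recovery
tests can compare estimates against stored truth bit-reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.csgraph as csgraph
import trimesh

from .glm import BlockDesign, DesignMatrix, HrfModel, build_design_matrix
from .mesh import SmoothSpec, TriangleMesh, smooth
from .phase import PhaseEncodedDesign, VertexTimeSeries
from .stimulus import generate_block_order

import pandas as pd


@dataclass
class GroundTruth:
    """Per-vertex truth stored alongside generated data.

    ``phase`` is the true encoded phase in [0, 2pi) with NaN where there
    is no map; ``amplitude`` the true response amplitude (signal units);
    ``delay_s`` the simulated hemodynamic lag.  For block designs,
    ``effects`` maps condition name to a per-vertex effect size.
    """

    phase: np.ndarray
    amplitude: np.ndarray
    delay_s: float = 4.0
    effects: dict = field(default_factory=dict)
    noise_sigma: float = 1.0
    drift_amplitude: float = 0.0
    seed: int = 0


def make_icosphere(subdivisions: int = 3, radius: float = 50.0) -> TriangleMesh:
    """Closed triangulated sphere with 10*4^s + 2 vertices.

    The default 50 mm radius gives a total area of the same order as one
    cortical hemisphere (~31,000 mm^2).
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces))


def geodesic_distances(mesh: TriangleMesh, source_vertex: int) -> np.ndarray:
    """Graph-geodesic distance (mm) from one vertex along mesh edges."""
    return csgraph.dijkstra(
        mesh.edge_lengths(), directed=False, indices=source_vertex
    )


def paint_map_patch(
    mesh: TriangleMesh,
    center_vertex: int,
    radius_mm: float,
    phase_range: tuple[float, float] = (0.0, 2 * np.pi),
    direction: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth phase gradient over a geodesic disc; NaN outside.

    Vertices within ``radius_mm`` (graph geodesic) of the centre get a
    phase varying linearly with their coordinate along ``direction``
    (default: the most variable tangent direction of the patch), mapped
    onto ``phase_range``.  This emulates a topological map: neighbouring
    vertices encode neighbouring stimulus coordinates.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    d = geodesic_distances(mesh, center_vertex)
    inside = d <= radius_mm
    phases = np.full(mesh.n_vertices, np.nan)
    idx = np.flatnonzero(inside)
    if idx.size == 1:
        phases[idx] = phase_range[0]
        return phases
    coords = mesh.vertices[idx]
    centred = coords - coords.mean(axis=0)
    if direction is None:
        # dominant in-patch direction
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        direction = vt[0]
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    t = centred @ direction
    span = t.max() - t.min()
    frac = (t - t.min()) / span if span > 0 else np.zeros_like(t)
    lo, hi = phase_range
    phases[idx] = lo + frac * (hi - lo)
    return phases


def simulate_phase_runs(
    truth: GroundTruth,
    design: PhaseEncodedDesign,
    n_runs: int = 4,
    directions: list[str] | None = None,
    seed: int | None = None,
) -> list[VertexTimeSeries]:
    """Phase-encoded runs obeying the traveling-wave forward model.

    Forward runs carry A*cos(omega*tau - phi_v - omega*d); reverse runs
    sweep the stimulus backwards, giving A*cos(omega*tau + phi_v -
    omega*d).  White Gaussian noise of sd ``truth.noise_sigma`` is added,
    plus optional sinusoidal drift at the three lowest nonzero frequency
    bins (amplitude ``truth.drift_amplitude``, random phases) so the
    low-frequency exclusion rule is exercised.
    """
    if directions is None:
        directions = ["forward", "reverse"] * ((n_runs + 1) // 2)
    directions = list(directions)[:n_runs]
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_vert = len(truth.phase)
    t = np.arange(design.n_samples)
    theta = 2 * np.pi * design.cycles_per_run * t / design.n_samples
    omega_d = 2 * np.pi * design.cycles_per_run * truth.delay_s / design.run_seconds
    phi = np.where(np.isnan(truth.phase), 0.0, truth.phase)
    amp = np.where(np.isnan(truth.phase), 0.0, truth.amplitude)
    runs = []
    for direction in directions:
        sign = 1.0 if direction == "forward" else -1.0
        signal = amp[:, None] * np.cos(
            theta[None, :] - sign * phi[:, None] - omega_d
        )
        data = signal + truth.noise_sigma * rng.standard_normal((n_vert, design.n_samples))
        if truth.drift_amplitude > 0:
            for k in (1, 2, 3):
                ph = rng.uniform(0, 2 * np.pi, size=n_vert)
                data += truth.drift_amplitude * np.cos(
                    2 * np.pi * k * t[None, :] / design.n_samples + ph[:, None]
                )
        d = PhaseEncodedDesign(
            design.n_samples, design.tr, design.cycles_per_run, direction, design.modality
        )
        runs.append(VertexTimeSeries(data, d))
    return runs


def simulate_phase_cohort(
    truth: GroundTruth,
    design: PhaseEncodedDesign,
    n_subjects: int,
    n_runs: int = 4,
    phase_jitter_kappa: float = 8.0,
    amplitude_jitter_sd: float = 0.2,
    seed: int = 0,
) -> list[list[VertexTimeSeries]]:
    """Multi-subject phase-encoded runs on a shared mesh.

    Each subject's true phase is jittered by a von Mises deviate (common
    across the subject's vertices, concentration ``phase_jitter_kappa``)
    and the amplitude scaled by a lognormal factor; vertices stay in
    correspondence across subjects (no spatial displacement).
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for s in range(n_subjects):
        jitter = rng.vonmises(0.0, phase_jitter_kappa)
        scale = float(np.exp(amplitude_jitter_sd * rng.standard_normal()))
        sub_truth = GroundTruth(
            phase=np.mod(truth.phase + jitter, 2 * np.pi),
            amplitude=truth.amplitude * scale,
            delay_s=truth.delay_s,
            noise_sigma=truth.noise_sigma,
            drift_amplitude=truth.drift_amplitude,
            seed=truth.seed,
        )
        run_seed = int(rng.integers(0, 2**31 - 1))
        cohort.append(simulate_phase_runs(sub_truth, design, n_runs, seed=run_seed))
    return cohort


@dataclass
class ReadingCohort:
    """Simulated block-design cohort: data[subject][run] with its design."""

    data: list  # list (subjects) of list (runs) of (array (n_vert, T), BlockDesign)
    truth: GroundTruth
    design_template: BlockDesign


def make_reading_design(
    seed: int,
    n_blocks: int = 32,
    block_s: float = 16.0,
    tr: float = 1.0,
    conditions: tuple = ("English", "Hindi", "Dot", "Fixation"),
    highpass_cutoff_s: float = 100.0,
) -> BlockDesign:
    """Random-order block design; Fixation blocks are unmodeled baseline.

    The default geometry is the reading experiment's: 32 blocks of 16 s
    over four conditions, a 512 s run.
    """
    order = generate_block_order(n_blocks, list(conditions), seed)
    rows = []
    for i, cond in enumerate(order):
        if cond == "Fixation":
            continue
        rows.append({"condition": cond, "onset": i * block_s, "duration": block_s})
    run_seconds = n_blocks * block_s
    events = pd.DataFrame(rows, columns=["condition", "onset", "duration"])
    return BlockDesign(events, run_seconds, tr, highpass_cutoff_s)


def simulate_reading_run(
    truth: GroundTruth,
    design: BlockDesign,
    hrf: HrfModel | None = None,
    rng: np.random.Generator | None = None,
    ar1_rho: float = 0.0,
) -> np.ndarray:
    """One run: per-vertex effects times convolved regressors plus noise."""
    rng = rng or np.random.default_rng(truth.seed)
    dm = build_design_matrix(design, hrf, add_derivatives=False)
    n_vert = len(truth.amplitude)
    t_len = design.n_samples
    y = np.zeros((n_vert, t_len))
    for cond, eff in truth.effects.items():
        if cond in dm.columns:
            reg = dm.matrix[:, dm.columns.index(cond)]
            y += np.asarray(eff)[:, None] * reg[None, :]
    noise = rng.standard_normal((n_vert, t_len))
    if ar1_rho:
        for i in range(1, t_len):
            noise[:, i] += ar1_rho * noise[:, i - 1]
    y += truth.noise_sigma * noise
    if truth.drift_amplitude > 0:
        t = np.arange(t_len)
        ph = rng.uniform(0, 2 * np.pi, size=n_vert)
        y += truth.drift_amplitude * np.cos(
            2 * np.pi * t[None, :] / t_len + ph[:, None]
        )
    return y


def simulate_reading_cohort(
    truth: GroundTruth,
    n_subjects: int = 14,
    runs_per_subject: int = 4,
    seed: int = 0,
    tr: float = 1.0,
    effect_jitter_sd: float = 0.2,
    ar1_rho: float = 0.0,
) -> ReadingCohort:
    """Block-design cohort with subject-level effect-size jitter.

    Each subject scales every true effect by a lognormal factor
    (sd ``effect_jitter_sd`` on the log scale); each run has a fresh
    random block order and fresh noise.  Bit-reproducible per seed.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    template = make_reading_design(seed=int(rng.integers(2**31 - 1)), tr=tr)
    data = []
    for s in range(n_subjects):
        scale = float(np.exp(effect_jitter_sd * rng.standard_normal()))
        sub_truth = GroundTruth(
            phase=truth.phase,
            amplitude=truth.amplitude,
            delay_s=truth.delay_s,
            effects={c: np.asarray(e) * scale for c, e in truth.effects.items()},
            noise_sigma=truth.noise_sigma,
            drift_amplitude=truth.drift_amplitude,
            seed=truth.seed,
        )
        runs = []
        for r in range(runs_per_subject):
            design = make_reading_design(seed=int(rng.integers(2**31 - 1)), tr=tr)
            y = simulate_reading_run(sub_truth, design, rng=rng, ar1_rho=ar1_rho)
            runs.append((y, design))
        data.append(runs)
    return ReadingCohort(data=data, truth=truth, design_template=template)


def estimate_smoothing_fwhm(
    mesh: TriangleMesh, spec: SmoothSpec, center_vertex: int = 0
) -> float:
    """Empirical FWHM (mm) of the iterative smoothing kernel.

    Smooths a unit delta and matches the kernel's area-weighted second
    moment of geodesic distance to a 2-D Gaussian (E[d^2] = 2 sigma^2),
    reporting FWHM = sigma * 2 sqrt(2 ln 2).  Informational: the width
    depends on the mesh's edge lengths.
    """
    delta = np.zeros(mesh.n_vertices)
    delta[center_vertex] = 1.0
    kernel = smooth(delta, mesh, spec)
    d = geodesic_distances(mesh, center_vertex)
    w = kernel * mesh.vertex_areas()
    sigma2 = float((w * d**2).sum() / w.sum() / 2.0)
    return float(np.sqrt(sigma2) * 2.0 * np.sqrt(2.0 * np.log(2.0)))
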
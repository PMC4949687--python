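"""Surface-based cluster-size exclusion for multiple-comparison control.

Vertex-level thresholding of a statistic map leaves many small false
clusters.  The familywise error over the surface is controlled by
discarding suprathreshold clusters smaller than an area threshold
calibrated by Monte-Carlo simulation: smooth white noise on the same
mesh with the same smoothing as the analysed data, threshold at the
vertex-level p, record the largest suprathreshold cluster area, and take
the (1 - alpha) quantile of that null distribution of maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import SmoothSpec, TriangleMesh, connected_components, region_area, smooth


@dataclass(frozen=True)
class ClusterCriterion:
    """Vertex-level p threshold plus minimum surviving cluster area (mm^2)."""

    vertex_p: float
    min_area_mm2: float
    alpha: float
    two_sided: bool = False


def estimate_cluster_threshold(
    mesh: TriangleMesh,
    smooth_spec: SmoothSpec,
    vertex_p: float = 0.01,
    alpha: float = 0.05,
    iterations: int = 1000,
    seed: int = 0,
) -> ClusterCriterion:
    """Monte-Carlo minimum cluster area achieving familywise alpha.

    Each iteration draws i.i.d. standard-normal noise per vertex, applies
    the smoothing used on real data, thresholds at the map's own upper
    ``vertex_p`` empirical quantile, and records the largest cluster area
    (0 if none).  The returned area threshold is the (1-alpha) quantile
    (upper interpolation, so applying ``area >= threshold`` retains at
    most an alpha fraction of null maxima).  Deterministic per seed.
    """
    if not (0 < vertex_p < 1) or not (0 < alpha <= 1):
        raise ValueError("vertex_p in (0,1) and alpha in (0,1] required")
    if iterations < 100:
        raise ValueError("need at least 100 iterations")
    if alpha == 1.0:
        return ClusterCriterion(vertex_p, 0.0, alpha)
    rng = np.random.default_rng(seed)
    areas = mesh.vertex_areas()
    maxima = np.empty(iterations)
    for i in range(iterations):
        noise = rng.standard_normal(mesh.n_vertices)
        field = smooth(noise, mesh, smooth_spec)
        cut = np.quantile(field, 1.0 - vertex_p)
        supra = np.flatnonzero(field > cut)
        best = 0.0
        for comp in connected_components(supra, mesh):
            best = max(best, region_area(areas, comp))
        maxima[i] = best
    thr = float(np.quantile(maxima, 1.0 - alpha, method="higher"))
    return ClusterCriterion(vertex_p, thr, alpha)


def apply_cluster_exclusion(
    stat_p: np.ndarray, mesh: TriangleMesh, criterion: ClusterCriterion
) -> np.ndarray:
    """Mask of vertices surviving vertex thresholding + cluster-size exclusion.

    Vertices with p below the vertex threshold are grouped into
    edge-connected clusters; clusters whose summed vertex-wise area falls
    below the criterion's minimum are removed.  Returns a boolean mask.
    """
    stat_p = np.asarray(stat_p)
    if stat_p.shape[0] != mesh.n_vertices:
        raise ValueError("p map does not match mesh")
    supra = np.flatnonzero(stat_p < criterion.vertex_p)
    keep = np.zeros(mesh.n_vertices, dtype=bool)
    if supra.size == 0:
        return keep
    areas = mesh.vertex_areas()
    for comp in connected_components(supra, mesh):
        if region_area(areas, comp) >= criterion.min_area_mm2:
            keep[comp] = True
    return keep
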
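"""Cross-subject vector averaging of complex phase maps and group inference.

Averaging the per-subject real and imaginary components at each vertex
(after light surface smoothing) preserves phase information that is
consistent across subjects while letting inconsistent phases cancel —
the correct treatment of wrap-around in a circular variable.  Group
significance is a one-sample bivariate test of the mean vector against
zero, expressed as an F statistic with df (2, 2n-2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mesh import SmoothSpec, TriangleMesh, smooth
from .phase import ComplexMap, FourierStat


@dataclass
class GroupComplexMap:
    """Per-vertex complex mean across subjects plus group F/p maps."""

    mean: np.ndarray  # complex (n_vertices,)
    n_subjects: int
    f: np.ndarray | None = None
    p: np.ndarray | None = None

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.mean)

    @property
    def phase(self) -> np.ndarray:
        return np.where(self.amplitude > 0, np.angle(self.mean), np.nan)


def vector_average(
    subject_maps: list[ComplexMap],
    mesh: TriangleMesh | None = None,
    spec: SmoothSpec | None = None,
) -> GroupComplexMap:
    """Smooth each subject map on the mesh, then average complex values.

    With ``spec.steps == 0`` or no mesh given, no smoothing is applied.
    """
    if not subject_maps:
        raise ValueError("need at least one subject map")
    n_vert = len(subject_maps[0].values)
    stacked = []
    for m in subject_maps:
        if len(m.values) != n_vert:
            raise ValueError("subject maps are on different meshes")
        v = m.values
        if mesh is not None and spec is not None and spec.steps > 0:
            if mesh.n_vertices != n_vert:
                raise ValueError("map does not match mesh")
            v = smooth(v, mesh, spec)
        stacked.append(v)
    z = np.vstack(stacked)
    return GroupComplexMap(mean=z.mean(axis=0), n_subjects=len(subject_maps))


def group_f(subject_maps: list[ComplexMap]) -> FourierStat:
    """One-sample test of the mean complex vector against zero.

    Under a circularly symmetric bivariate-normal null the statistic

        F = (n - 1) * n * |mean|^2 / sum_i |z_i - mean|^2

    follows F(2, 2n-2): the numerator pools the two quadratures of the
    mean, the denominator their 2n-2 residual degrees of freedom.
    """
    n = len(subject_maps)
    if n < 3:
        raise ValueError("group F requires at least 3 subjects")
    z = np.vstack([m.values for m in subject_maps])
    mean = z.mean(axis=0)
    resid = np.abs(z - mean) ** 2
    ss = resid.sum(axis=0)
    num = n * np.abs(mean) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ss > 0, (n - 1) * num / ss, np.inf)
    df1, df2 = 2, 2 * n - 2
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isinf(f), 0, f), df1, df2))
    return FourierStat(f=f, df1=df1, df2=df2, p=p)


def group_map(
    subject_maps: list[ComplexMap],
    mesh: TriangleMesh | None = None,
    spec: SmoothSpec | None = None,
) -> GroupComplexMap:
    """Vector average with group F/p attached (smoothed maps feed both)."""
    smoothed = subject_maps
    if mesh is not None and spec is not None and spec.steps > 0:
        smoothed = [ComplexMap(smooth(m.values, mesh, spec)) for m in subject_maps]
    out = vector_average(smoothed)
    if len(smoothed) >= 3:
        stat = group_f(smoothed)
        out.f, out.p = stat.f, stat.p
    return out
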
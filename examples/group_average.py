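"""Cross-subject vector averaging of complex phase maps.

Simulates 8 subjects sharing one tonotopic map (with per-subject phase
jitter), computes each subject's complex map, smooths 10 steps on the
mesh, vector-averages, and tests the group mean vector against zero.
"""

import numpy as np

from cortimap import (
    CombineSpec,
    GroundTruth,
    PhaseEncodedDesign,
    SmoothSpec,
    combine_runs,
    fourier_stat,
    group_map,
    make_icosphere,
    paint_map_patch,
    simulate_phase_cohort,
)

mesh = make_icosphere(3, 50.0)
design = PhaseEncodedDesign(512, 1.0, 8, modality="auditory")
phases = paint_map_patch(mesh, center_vertex=100, radius_mm=25.0)
truth = GroundTruth(
    phase=phases, amplitude=np.full(mesh.n_vertices, 1.5),
    delay_s=4.0, noise_sigma=1.0, seed=11,
)

cohort = simulate_phase_cohort(truth, design, n_subjects=8, n_runs=4, seed=11)
subject_maps = []
for runs in cohort:
    cmap, _ = fourier_stat(combine_runs(runs, CombineSpec(4.0)))
    subject_maps.append(cmap)

g = group_map(subject_maps, mesh, SmoothSpec(steps=10))
inside = ~np.isnan(phases)
print(f"subjects: {g.n_subjects}; group F df (2, {2 * g.n_subjects - 2})")
print(f"median group F inside map:  {np.median(g.f[inside]):.1f}")
print(f"median group F outside map: {np.median(g.f[~inside]):.2f}")
print(f"map vertices significant at p<0.01: {(g.p[inside] < 0.01).mean():.2f}")
# coherent phases across subjects reinforce in the vector average, so group F
# is two orders of magnitude larger inside the painted map than outside
# (outside sits slightly above the null median because smoothing bleeds some
# map signal across the patch boundary).
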
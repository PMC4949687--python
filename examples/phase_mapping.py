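"""Recover a simulated retinotopic map from phase-encoded runs.

Paints a smooth polar-angle map on a patch of a spherical cortex, simulates
four traveling-wave runs (two forward, two reverse) at 8 cycles/run with a
4 s hemodynamic delay, combines them with time reversal + delay
compensation, and measures how well the Fourier phase recovers the map.
"""

import numpy as np

from cortimap import (
    CombineSpec,
    GroundTruth,
    PhaseCoordinateMap,
    PhaseEncodedDesign,
    combine_runs,
    decode_phase,
    fourier_stat,
    make_icosphere,
    paint_map_patch,
    simulate_phase_runs,
)

mesh = make_icosphere(3, 50.0)
design = PhaseEncodedDesign(n_samples=512, tr=1.0, cycles_per_run=8, modality="visual")
phases = paint_map_patch(mesh, center_vertex=0, radius_mm=30.0)
truth = GroundTruth(
    phase=phases, amplitude=np.full(mesh.n_vertices, 2.0),
    delay_s=4.0, noise_sigma=1.0, seed=7,
)

runs = simulate_phase_runs(truth, design, n_runs=4)
combined = combine_runs(runs, CombineSpec(delay_s=4.0))
cmap, stat = fourier_stat(combined)

# the delay compensation leaves a common phase offset of omega*delay
omega_d = 2 * np.pi * design.cycles_per_run * truth.delay_s / design.run_seconds
coord = PhaseCoordinateMap(modality="visual", phase_offset=omega_d)
polar_angle = decode_phase(cmap, coord)

inside = ~np.isnan(phases)
err = np.rad2deg(np.angle(np.exp(1j * (np.angle(cmap.values) - phases - omega_d))))
print(f"map vertices: {inside.sum()} of {mesh.n_vertices}")
print(f"F statistic df: ({stat.df1}, {stat.df2})")
print(f"median |phase error| inside map: {np.median(np.abs(err[inside])):.2f} deg")
print(f"fraction of map vertices with p < 0.001: {(stat.p[inside] < 0.001).mean():.3f}")
print(f"decoded polar angle at vertex 0: {polar_angle[0]:.1f} deg")
# the phase error is the angular gap between decoded and painted map position;
# a well-recovered map has errors of a few degrees and near-total significance.
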
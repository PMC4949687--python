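# Methods

This note documents the statistical models implemented in `cortimap`, the
conventions and defaults chosen where several were defensible, what the
synthetic generator does and does not emulate, and known limitations.

## Surface representation

A cortical hemisphere is a closed triangle mesh (`TriangleMesh`), vertices
in mm. Two vertices are adjacent iff they share a mesh edge; all
neighbourhood operations (smoothing, clustering) use this edge graph.
The *vertex-wise area* of a vertex is one third of the summed areas of its
adjacent triangles. Summed over any vertex set this reproduces the enclosed
triangle area exactly, which is why regional and overlap areas are additive.
On the synthetic icospheres used throughout, the mean vertex-wise area is
the minimum areal increment that can be resolved; it depends on the mesh
(≈ 49 mm² for a 642-vertex, 50 mm radius sphere) and is reported, never
assumed.

Smoothing is iterative neighbour averaging: each step replaces a vertex
value by the unweighted mean of itself and its edge neighbours. The step
count, not a kernel width, is the parameter; `estimate_smoothing_fwhm`
reports the empirical FWHM of the implied kernel by matching the smoothed
delta's area-weighted second moment of geodesic distance to a 2-D Gaussian
(`E[d²] = 2σ²`). Complex maps are smoothed component-wise. The operator is
linear and row-stochastic, so constants are fixed points and the variance of
a random map is non-increasing.

## Phase-encoded mapping

**Forward model.** A vertex belonging to a topological map responds at the
stimulation frequency `ω` with phase equal to its preferred stimulus
coordinate `φ` plus the hemodynamic lag: forward runs carry
`A·cos(ωτ − φ − ω·d)`, reverse-swept runs `A·cos(ωτ + φ − ω·d)`.

**Run combination.** Reversed runs are time-reversed and shifted. We
implement reversal circularly about sample 0 (`x[−t mod T]`), which is exact
for the periodic stimulus-locked component (an end-to-end flip differs by a
one-sample phase offset `ω·TR`; either is acceptable, the circular form
makes the algebra exact). Reversal maps the reversed run's phase to
`φ − ω·d`; since reversal negates the lag, compensation is a circular shift
of `2·d/TR` samples (rounded), bringing both run types to `φ + ω·d` before
sample-wise averaging. The common `ω·d` term is subtracted at decoding via
`PhaseCoordinateMap.phase_offset`.

**Hemodynamic delay.** The delay is an explicit parameter, default 4 s (a
typical BOLD peak lag; with TR = 1 s the shift is 8 samples). It is not
estimated from data by default, but `estimate_delay` scans candidate delays
and picks the one maximising mean stimulus-bin amplitude over the top-F
vertices — coherent combination is maximal when compensation matches truth.

**Spectral statistic.** After mean removal, the per-vertex DFT gives the
complex response at the stimulus bin `s` (returned conjugated, so its
argument is `+φ` for a `cos(ωτ − φ)` signal). Significance is
`F = P(s) / mean(P(noise))`. Noise bins exclude: DC and Nyquist (they carry
one quadrature, not two, and would distort the df), bins 1–3 (slow drift
and motion; excluding a bin is exactly equivalent to regressing out the
corresponding sinusoid pair), and the first three harmonics of `s` ± 1 bin
(response non-sinusoidality). Every retained bin contributes two independent
Gaussian quadratures under white noise, so `F ~ F(2, 2m)` exactly with `m`
retained bins. For `T = 512`, `s = 8` this gives df `(2, 486)`; published
threshold tables for this design quote df 488 (232 for `T = 256`), a 2-bin
bookkeeping difference in DC/Nyquist handling that changes the `p = 0.001`
critical value only in the third decimal. Where the printed critical values
(7.12 and 7) are checked, the printed dfs are used directly.

Degenerate case: a noise pool that is exactly zero (or pure round-off from
an exact-bin signal, ratio above ~1/ε) yields the `F = +∞` sentinel with
`p = 0`.

**Decoding.** Phase in `[0, 2π)` maps bijectively to: polar angle
`360°·φ/2π` (visual); `150·64^{φ/2π}` Hz on the 150–9600 Hz log ramp
(auditory — exponential in phase); body-part index `⌊11·φ/2π⌋ + 1`, tongue
(1) to toe (11) (somatomotor). Phase 0 = cycle start is the zero convention;
modality-specific origins are configurable offsets. Zero-amplitude vertices
have undefined phase and decode to NaN.

## Group mapping

Per-subject complex maps (assumed vertex-corresponded on a shared mesh) are
smoothed, then averaged component-wise. This vector average preserves phase
information that is consistent across subjects and lets inconsistent phases
cancel — the correct circular treatment; `|z̄| ≤ mean|zᵢ|` always.

Group significance is a one-sample test of the mean vector against zero
under an isotropic bivariate-normal null:

    F = (n − 1) · n·|z̄|² / Σᵢ |zᵢ − z̄|²   ~   F(2, 2n−2).

Derivation: `n|z̄|² ~ τ²χ²₂` and `Σ|zᵢ − z̄|² ~ τ²χ²₂ₙ₋₂` independently, so
the ratio scaled by `(2n−2)/2 = n−1` is F-distributed. (A Hotelling T² with
a full 2×2 covariance would use `(n−2)/(2(n−1))·T²` with df `(2, n−2)`; the
isotropic form is preferred because the two quadratures of a noise
coefficient are exchangeable, and its calibration is verified by simulation
in the tests.) The statistic is invariant to a common phase rotation.

## Cluster-size correction

Vertex thresholding alone does not control the familywise error over
thousands of correlated vertices. The Monte-Carlo criterion: simulate white
Gaussian vertex noise, smooth it with the same `SmoothSpec` as the analysed
data (matching the data's smoothness by construction — the null model is
declared, since no simulation details accompany the published thresholds),
threshold at the map's own upper `vertex_p` quantile, and record the largest
suprathreshold cluster's area. The `(1−α)` quantile (upper interpolation,
conservative) of the maxima over ≥ 100 iterations is the minimum cluster
area. Applying it removes edge-connected clusters of `p < vertex_p` vertices
whose summed vertex-wise area falls below the criterion. The max-cluster
(familywise) statistic is used because "achieving a corrected p" is a
statement about the probability of *any* false cluster surviving. Estimates
are bit-reproducible per seed. One-sided p maps are assumed; two-sided
handling is a flag applied before clustering. Published area thresholds
(30/40/92 mm² classes) belong to a specific brain surface and smoothness
and are not reproduction targets on synthetic meshes.

## Reading GLM

**Design.** 32 blocks of 16 s per run (512 s), four block types
(English / Hindi / Dot / fixation baseline) in balanced random order;
fixation is unmodeled baseline. Button presses can enter as a fourth 1 s
regressor. Boxcars are convolved on a 16× oversampled grid with a
double-gamma HRF: gamma lobes parameterised by mean delay and dispersion
(sd), defaults 6 s/3 s for the peak, 16 s/3 s for the undershoot, ratio 6,
kernel normalised to unit peak. Note the kernel mode is `mean − sd²/mean`
= 4.5 s. Temporal derivatives of every convolved regressor absorb small
timing/shape deviations and carry weight 0 in all contrasts. High-pass
filtering is a discrete-cosine nuisance basis with `⌊2·duration/cutoff⌋`
columns (10 for 512 s at the 100 s cutoff) — exactly representable in the
design matrix rather than applied as a separate filter.

**Fitting.** Vertex-wise OLS; `COPE = cᵀβ̂`, `VARCOPE = σ̂²·cᵀ(XᵀX)⁻¹c`.
Optional prewhitening is single-pass Cochrane–Orcutt AR(1) with one ρ pooled
across vertices (median lag-1 residual autocorrelation) — a declared
simplification of full autocorrelation modelling that captures the dominant
serial correlation and restores null calibration under AR(1) noise (tested);
off by default. Rank-deficient designs raise an error naming the collinear
columns. `Z` is the signed normal deviate preserving the t's two-tailed p;
the familiar pairing `Z = 3.09 ↔ one-sided p < 0.001` holds at large df.

**Combination.** Runs combine by inverse-variance weighting
(`COPE* = Σ(COPEᵢ/Vᵢ)/Σ(1/Vᵢ)`, `VARCOPE* = 1/Σ(1/Vᵢ)`). Group inference is
a one-sample t across subject COPEs (df `n−1`), i.e. ordinary least squares
with the subject as the random effect, ignoring within-subject VARCOPE
heterogeneity — a declared simplification whose null calibration is
verified by simulation.

## Overlap quantification

`overlap% = 100 · area(reading ∩ map) / area(reading)`: the activation is
always the denominator. A symmetric Dice coefficient is reported as a
secondary column. Boundary vertices contribute their full vertex-wise area
(no fractional face splitting), consistent with the areal granularity of the
vertex-area definition. Named regions must be disjoint; regional rows
restrict the reading mask to the region first, so when the partition covers
the activation the regional overlap areas sum exactly to the overall row.
A `treat_as_map` patch list augments the map mask before intersection (e.g.
a foveal patch where central fixation suppresses the periodic signal even
though the cortex is retinotopic); its extent is a user input. The union row
of `multimap_report` answers "what fraction lies inside *any* map" and
dominates every per-map row. Empty reading masks yield NaN percentages
(undefined, not zero).

## Stimulus and behaviour utilities

Word durations for a comprehension block: with `n` words and block length
`B`, narrow words (width ≤ 0.7·mean width) get the clamp `0.7·B/n` (175 ms
for 64 words in 16 s, i.e. 70% of the 250 ms mean), wider words get
`clamp + slope·(width − 0.7·mean width)` with
`slope = (B − n·clamp)/Σ(excess widths)` solved in closed form so the block
total is exact. All-equal widths degenerate to uniform `B/n`.

Target detection: a target `(onset, end)` counts as hit iff a key press
falls in `(onset, end + 1 s]` — the window boundary inclusive. Presses are
credited to at most one target by greedy earliest-eligible matching (the
disambiguation rule is a package convention; published descriptions do not
state one). RT is measured from target onset by default (origin
configurable); published mean RTs are not comparison targets because their
origin convention is unstated. Condition comparisons of behavioural scores
use standard Wilcoxon signed-rank routines (`scipy.stats.wilcoxon`), not
re-derived.

## Synthetic data

The generator emulates: traveling-wave responses at 8 cycles/run with a
hemodynamic lag and phase encoding a map coordinate over a geodesic patch;
opposite-direction run pairs; white Gaussian noise plus optional sinusoidal
drift placed at the three excluded low-frequency bins (so the exclusion rule
is exercised) and optional AR(1) autocorrelation (so prewhitening is
exercised); block-design runs with localized condition effects; and
multi-subject cohorts with von Mises phase jitter (default κ = 8, a ~20°
circular sd of inter-subject map offset) and lognormal amplitude/effect
scaling (default sd 0.2) on one shared mesh. Default study geometry matches
the emulated designs: 512 samples at TR 1 s, 8 cycles/run, 16 s blocks, 32
blocks/run, 64 words/block; default amplitudes and noise give time-series
SNRs of 1–5 where the recovery benchmarks operate. Every generator is a
pure function of (parameters, seed).

It does **not** emulate: realistic cortical geometry (icospheres have
uniform curvature and near-uniform vertex areas), inter-subject spatial
misalignment (subjects share one mesh, so registration error is absent),
physiological noise structure beyond AR(1)+drift, or biophysical BOLD
nonlinearity. Passing recovery tests therefore demonstrate correctness of
the statistics chain under its stated model, not robustness to registration
error or structured physiological artefact.

## Numerical choices and scales

- DFT convention: unnormalised `numpy.fft.rfft`; Parseval
  (`Σ|X_k|² = T·Σx_t²`) is asserted in tests. F ratios are
  normalisation-free.
- `F = +∞` / `t = +∞` sentinels (zero residual) carry `p = 0`; p-to-Z clips
  p at 1e-300 to avoid overflow.
- Cluster-area quantile uses `method="higher"` (conservative); cluster
  survival is `area ≥ threshold`.
- Component ordering: clusters sorted by smallest contained vertex index.
- Simulation sizes in the test suite (10,000-vertex null calibrations pooled
  over 4–5 replicates, 1000-iteration cluster Monte Carlo on a 642-vertex
  mesh, 6–15 subject cohorts) were chosen so each suite runs in seconds
  while binomial confidence bounds remain tight enough to detect df errors
  or an unexcluded bin.

## Known limitations

- The group circular statistic assumes isotropic bivariate noise; strongly
  anisotropic inter-subject variability would need the full Hotelling form.
- Pooled-ρ AR(1) prewhitening under-corrects vertices whose autocorrelation
  deviates strongly from the pooled value.
- Geodesic distances are shortest edge-path distances, which overestimate
  true geodesics on coarse meshes; patch radii are therefore nominal.
- The word-duration scheduler's piecewise-linear rule assumes at least one
  word above the clamp threshold (guaranteed for positive widths unless all
  widths are identical, which degenerates cleanly).
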
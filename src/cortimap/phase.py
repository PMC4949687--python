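"""Single-subject phase-encoded (traveling-wave) mapping analysis.

A periodic stimulus sweeps a map coordinate (polar angle, log sound
frequency, body part) at a fixed number of cycles per run.  A vertex
responding to one point of the cycle shows a sinusoidal response whose
Fourier phase at the stimulus frequency encodes the preferred coordinate.
Significance is an F ratio of the power at the stimulus frequency to the
mean power at the remaining frequencies, after excluding low-frequency
bins (motion/drift), the stimulus harmonics and their one-bin neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mesh import SmoothSpec


@dataclass(frozen=True)
class PhaseEncodedDesign:
    """Timing of one phase-encoded run.

    ``cycles_per_run`` is the stimulus frequency in cycles/run units
    (the study design uses 8 cycles of 64 s in a 512 s run).
    """

    n_samples: int
    tr: float
    cycles_per_run: int = 8
    direction: str = "forward"
    modality: str = "visual"

    def __post_init__(self) -> None:
        if self.cycles_per_run < 1:
            raise ValueError("cycles_per_run must be >= 1")
        if self.n_samples % self.cycles_per_run:
            raise ValueError("n_samples must be divisible by cycles_per_run")
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")
        if self.modality not in ("visual", "auditory", "somatomotor"):
            raise ValueError("unknown modality")

    @property
    def stimulus_bin(self) -> int:
        return self.cycles_per_run

    @property
    def run_seconds(self) -> float:
        return self.n_samples * self.tr


@dataclass
class VertexTimeSeries:
    """Per-vertex time series (n_vertices, T) with its design."""

    data: np.ndarray
    design: PhaseEncodedDesign

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != self.design.n_samples:
            raise ValueError("time series length does not match design")


@dataclass
class ComplexMap:
    """Per-vertex complex response at the stimulus frequency."""

    values: np.ndarray  # complex, shape (n_vertices,)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        """Phase in [-pi, pi); NaN where the amplitude is zero."""
        ph = np.angle(self.values)
        return np.where(self.amplitude > 0, ph, np.nan)


@dataclass
class FourierStat:
    """Per-vertex F statistic of stimulus-frequency power vs noise power."""

    f: np.ndarray
    df1: int
    df2: int
    p: np.ndarray


@dataclass(frozen=True)
class ExclusionSet:
    """Frequency bins removed from the noise estimate.

    ``noise_excluded`` are bins (cycles/run units) excluded from the noise
    pool: DC, Nyquist, the lowest ``n_low`` frequencies, and the first
    three stimulus harmonics each with their +/-1 neighbours.  The
    stimulus bin itself is the signal and is never a noise bin.
    """

    signal_bin: int
    noise_excluded: frozenset[int]
    n_bins: int  # number of bins 0..T/2 inclusive

    def noise_bins(self) -> np.ndarray:
        all_bins = np.arange(self.n_bins)
        drop = self.noise_excluded | {self.signal_bin}
        return np.array([b for b in all_bins if b not in drop])


@dataclass(frozen=True)
class CombineSpec:
    """Hemodynamic-delay compensation applied when combining runs.

    ``delay_s`` is the assumed one-way hemodynamic lag in seconds.
    Reversing time negates the lag, so reversed runs are circularly
    shifted by round(2*delay/TR) samples after reversal; forward and
    reversed runs then carry the same phase offset (+omega*delay), which
    downstream decoding can subtract.
    """

    delay_s: float = 4.0

    def __post_init__(self) -> None:
        if self.delay_s < 0:
            raise ValueError("delay must be >= 0")


def combine_runs(runs: list[VertexTimeSeries], spec: CombineSpec) -> VertexTimeSeries:
    """Average runs after time-reversing and delay-shifting reversed runs.

    Reversal is circular about sample 0 (t -> -t mod T), exact for the
    periodic stimulus-locked component; the subsequent circular shift of
    2*delay (in samples, rounded) aligns reversed runs with forward runs.
    """
    if not runs:
        raise ValueError("need at least one run")
    t0 = runs[0].design.n_samples
    acc = np.zeros_like(runs[0].data)
    for run in runs:
        if run.design.n_samples != t0:
            raise ValueError("runs have mismatched lengths")
        x = run.data
        if run.design.direction == "reverse":
            x = np.roll(x[:, ::-1], 1, axis=1)  # x[-t mod T]
            shift = int(round(2.0 * spec.delay_s / run.design.tr))
            x = np.roll(x, shift, axis=1)
        acc = acc + x
    design = runs[0].design
    fwd = PhaseEncodedDesign(
        design.n_samples, design.tr, design.cycles_per_run, "forward", design.modality
    )
    return VertexTimeSeries(acc / len(runs), fwd)


def build_exclusion_set(
    design: PhaseEncodedDesign, n_low: int = 3, n_harmonics: int = 3
) -> ExclusionSet:
    """Noise-bin exclusion rule for the Fourier F statistic.

    Excludes DC and Nyquist, bins 1..n_low (slow drift / motion), and the
    first ``n_harmonics`` multiples of the stimulus bin together with one
    bin above and below each.  Bins beyond Nyquist are clipped.
    """
    s = design.stimulus_bin
    nyq = design.n_samples // 2
    excl: set[int] = {0, nyq}
    excl.update(range(1, n_low + 1))
    import warnings

    for h in range(1, n_harmonics + 1):
        for b in (h * s - 1, h * s, h * s + 1):
            if b > nyq:
                warnings.warn(
                    f"harmonic bin {b} beyond Nyquist {nyq}; clipped", stacklevel=2
                )
            elif b >= 0:
                excl.add(b)
    excl.discard(s)
    return ExclusionSet(signal_bin=s, noise_excluded=frozenset(excl), n_bins=nyq + 1)


def fourier_stat(
    ts: VertexTimeSeries, excl: ExclusionSet | None = None
) -> tuple[ComplexMap, FourierStat]:
    """Fourier transform per vertex; F of stimulus power vs mean noise power.

    The complex value at the stimulus bin is the conjugated DFT
    coefficient, so its argument equals the stimulus-cycle position at
    which the vertex responds maximally (for x_t = cos(theta*t - alpha)
    the returned phase is +alpha).
    F = P_signal / mean(P_noise) with df (2, 2*m) for m
    retained noise bins, which is exactly F-distributed under white
    Gaussian noise because every retained bin (no DC/Nyquist) carries two
    independent Gaussian quadratures.
    """
    if excl is None:
        excl = build_exclusion_set(ts.design)
    x = ts.data - ts.data.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(x, axis=1)
    power = np.abs(spec) ** 2
    noise_bins = excl.noise_bins()
    if noise_bins.size == 0:
        raise ValueError("exclusion set leaves no noise bins")
    sig = np.conj(spec[:, excl.signal_bin])
    noise_power = power[:, noise_bins].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(noise_power > 0, np.abs(sig) ** 2 / noise_power, np.inf)
    # noise power that is pure round-off from an exact-bin signal (ratios
    # beyond ~1/eps) is treated as zero: F = +inf sentinel, p = 0
    f = np.where(f > 1e15, np.inf, f)
    df1, df2 = 2, 2 * noise_bins.size
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isinf(f), 0, f), df1, df2))
    return ComplexMap(sig), FourierStat(f=f, df1=df1, df2=df2, p=p)


# ----------------------------------------------------------------------
# phase decoding
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseCoordinateMap:
    """Bijective decoding from response phase to a map coordinate.

    visual      -> polar angle in degrees, [0, 360)
    auditory    -> sound frequency on a log ramp freq_lo..freq_hi (Hz)
    somatomotor -> body-part index 1..n_parts (tongue -> toe)

    ``phase_offset`` (radians) is subtracted before decoding; set it to
    omega*delay to remove the hemodynamic-delay phase carried by
    delay-compensated combined runs, plus any modality zero convention.
    """

    modality: str = "visual"
    phase_offset: float = 0.0
    freq_lo: float = 150.0
    freq_hi: float = 9600.0
    n_parts: int = 11

    def decode(self, phase: np.ndarray) -> np.ndarray:
        frac = np.mod(np.asarray(phase) - self.phase_offset, 2 * np.pi) / (2 * np.pi)
        if self.modality == "visual":
            return 360.0 * frac
        if self.modality == "auditory":
            return self.freq_lo * (self.freq_hi / self.freq_lo) ** frac
        if self.modality == "somatomotor":
            return np.minimum(np.floor(self.n_parts * frac) + 1, self.n_parts)
        raise ValueError(f"unknown modality {self.modality!r}")


def decode_phase(cmap: ComplexMap, coord: PhaseCoordinateMap) -> np.ndarray:
    """Decode per-vertex phase into the modality's coordinate.

    Vertices with zero amplitude have no defined phase and decode to NaN.
    """
    out = coord.decode(np.angle(cmap.values))
    return np.where(cmap.amplitude > 0, out, np.nan)


def estimate_delay(
    runs: list[VertexTimeSeries],
    candidate_delays: np.ndarray | None = None,
    top_fraction: float = 0.05,
) -> float:
    """Pick the delay maximising mean stimulus-bin amplitude over high-F vertices.

    Scans candidate one-way delays, combines the runs under each, and
    returns the delay whose combined map has the largest mean amplitude
    over the ``top_fraction`` highest-F vertices (coherent combination is
    maximal when the compensation matches the true lag).
    """
    design = runs[0].design
    if candidate_delays is None:
        candidate_delays = np.arange(0.0, 10.0 + design.tr / 2, design.tr / 2)
    best_delay, best_score = 0.0, -np.inf
    for d in candidate_delays:
        combined = combine_runs(runs, CombineSpec(delay_s=float(d)))
        cmap, fstat = fourier_stat(combined)
        k = max(1, int(top_fraction * len(fstat.f)))
        top = np.argsort(fstat.f)[-k:]
        score = float(cmap.amplitude[top].mean())
        if score > best_score:
            best_delay, best_score = float(d), score
    return best_delay
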
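"""Block-design GLM for the reading experiment.

Condition boxcars are convolved with a double-gamma canonical
hemodynamic response function; temporal derivatives of every convolved
regressor are added to absorb small timing deviations; slow drift is
removed with a discrete-cosine high-pass basis (periods above a cutoff,
default 100 s) carried as nuisance regressors in the design matrix.
Per-run least-squares fits produce contrast estimates (COPE) and
variances (VARCOPE); runs combine by inverse-variance (fixed-effects)
weighting; group inference is a one-sample t across subjects per vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MAIN_CONDITIONS = ("English", "Hindi", "Dot")
BUTTON_CONDITION = "ButtonPress"


@dataclass(frozen=True)
class HrfModel:
    """Double-gamma canonical HRF.

    Each lobe is a gamma density parameterised by its mean delay and
    standard deviation (dispersion) in seconds; the undershoot is scaled
    down by ``ratio``.  Defaults: peak lobe mean 6 s, undershoot mean
    16 s, dispersions 3 s, peak:undershoot ratio 6.  Note the kernel
    maximum sits at the gamma mode, mean - sd^2/mean (4.5 s for the
    defaults), slightly before the mean delay.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 3.0
    undershoot_dispersion_s: float = 3.0
    ratio: float = 6.0
    duration_s: float = 32.0

    def sample(self, dt: float) -> np.ndarray:
        """Kernel sampled every ``dt`` seconds, normalised to unit peak."""
        if min(self.peak_delay_s, self.undershoot_delay_s) <= 0:
            raise ValueError("delays must be positive")
        t = np.arange(0, self.duration_s + dt, dt)

        def lobe(mean: float, sd: float) -> np.ndarray:
            shape = (mean / sd) ** 2
            scale = sd**2 / mean
            return stats.gamma.pdf(t, a=shape, scale=scale)

        h = lobe(self.peak_delay_s, self.peak_dispersion_s) - lobe(
            self.undershoot_delay_s, self.undershoot_dispersion_s
        ) / self.ratio
        return h / h.max()


@dataclass
class BlockDesign:
    """Event table for one run: (condition, onset s, duration s) rows."""

    events: pd.DataFrame  # columns: condition, onset, duration
    run_seconds: float
    tr: float
    highpass_cutoff_s: float = 100.0

    def __post_init__(self) -> None:
        ev = pd.DataFrame(self.events)
        required = {"condition", "onset", "duration"}
        if not required <= set(ev.columns):
            raise ValueError(f"events need columns {sorted(required)}")
        if (ev["onset"] < 0).any() or (ev["onset"] >= self.run_seconds).any():
            raise ValueError("event onsets must lie within the run")
        for cond, grp in ev.groupby("condition"):
            g = grp.sort_values("onset")
            ends = (g["onset"] + g["duration"]).to_numpy()[:-1]
            if np.any(ends > g["onset"].to_numpy()[1:] + 1e-9):
                raise ValueError(f"overlapping blocks within condition {cond!r}")
        self.events = ev

    @property
    def n_samples(self) -> int:
        return int(round(self.run_seconds / self.tr))

    @property
    def conditions(self) -> list[str]:
        return sorted(self.events["condition"].unique())


@dataclass(frozen=True)
class Contrast:
    """Named weight vector over main-condition regressors.

    Weights are given per condition name; derivative and nuisance columns
    always receive weight zero.
    """

    name: str
    weights: dict = field(default_factory=dict)


@dataclass
class DesignMatrix:
    """Design matrix with labelled columns."""

    matrix: np.ndarray  # (T, k)
    columns: list[str]
    frame_times: np.ndarray

    def contrast_vector(self, contrast: Contrast) -> np.ndarray:
        c = np.zeros(len(self.columns))
        for cond, w in contrast.weights.items():
            try:
                c[self.columns.index(cond)] = w
            except ValueError:
                raise ValueError(f"contrast names unknown regressor {cond!r}")
        return c


@dataclass
class GlmResult:
    """Per-contrast COPE/VARCOPE/t/Z/p maps with residual df."""

    contrast_names: list[str]
    cope: np.ndarray      # (n_contrasts, n_vertices)
    varcope: np.ndarray
    t: np.ndarray
    z: np.ndarray
    p: np.ndarray         # two-sided
    dof: float

    def for_contrast(self, name: str) -> dict:
        i = self.contrast_names.index(name)
        return {
            "cope": self.cope[i], "varcope": self.varcope[i],
            "t": self.t[i], "z": self.z[i], "p": self.p[i], "dof": self.dof,
        }


def dct_highpass_basis(n_samples: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis: cosines with period longer than cutoff.

    The number of columns is floor(2 * run_duration / cutoff); column k is
    cos(pi*k*(2t+1)/(2T)), the DCT-II basis restricted to slow terms.
    """
    duration = n_samples * tr
    n_basis = int(np.floor(2.0 * duration / cutoff_s))
    t = np.arange(n_samples)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_samples)) for k in range(1, n_basis + 1)]
    return np.column_stack(cols) if cols else np.empty((n_samples, 0))


def build_design_matrix(
    design: BlockDesign,
    hrf: HrfModel | None = None,
    oversample: int = 16,
    add_derivatives: bool = True,
) -> DesignMatrix:
    """Boxcars convolved with the HRF, temporal derivatives, drift basis.

    Columns are labelled ``<condition>``, ``<condition>_derivative``,
    ``drift_k`` and ``intercept``.  Convolution is done on a grid
    oversampled ``oversample``-fold relative to the TR, then sampled at
    frame times t = i*TR.
    """
    hrf = hrf or HrfModel()
    n = design.n_samples
    dt = design.tr / oversample
    fine_t = np.arange(0, design.run_seconds, dt)
    kernel = hrf.sample(dt)
    frame_idx = (np.arange(n) * oversample).astype(int)

    cols, labels = [], []
    for cond in design.conditions:
        box = np.zeros(len(fine_t))
        for _, ev in design.events[design.events["condition"] == cond].iterrows():
            box[(fine_t >= ev["onset"]) & (fine_t < ev["onset"] + ev["duration"])] = 1.0
        reg_fine = np.convolve(box, kernel)[: len(fine_t)]
        reg = reg_fine[frame_idx]
        cols.append(reg)
        labels.append(cond)
        if add_derivatives:
            cols.append(np.gradient(reg, design.tr))
            labels.append(f"{cond}_derivative")

    drift = dct_highpass_basis(n, design.tr, design.highpass_cutoff_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        labels.append(f"drift_{k + 1}")
    cols.append(np.ones(n))
    labels.append("intercept")

    x = np.column_stack(cols)
    return DesignMatrix(matrix=x, columns=labels, frame_times=np.arange(n) * design.tr)


def _p_to_z(t: np.ndarray, dof: float) -> np.ndarray:
    """Signed normal deviate preserving the two-tailed p of the t value."""
    p_one = stats.t.sf(np.abs(t), dof)
    z = stats.norm.isf(np.clip(p_one, 1e-300, 1.0))
    return np.sign(t) * z


def fit_glm(
    data: np.ndarray,
    design: DesignMatrix,
    contrasts: list[Contrast],
    prewhiten: bool = False,
) -> GlmResult:
    """Vertex-wise least squares with optional AR(1) prewhitening.

    ``data`` is (n_vertices, T).  Prewhitening is single-pass
    Cochrane-Orcutt with a single autocorrelation coefficient pooled
    across vertices (the median lag-1 residual autocorrelation), applied
    to data and design alike before refitting.
    """
    y = np.atleast_2d(np.asarray(data, dtype=float)).T  # (T, n_vert)
    x = design.matrix
    if x.shape[0] != y.shape[0]:
        raise ValueError("data length does not match design matrix rows")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        bad = [design.columns[i] for i in np.flatnonzero(np.abs(np.diag(r)) < 1e-8)]
        raise ValueError(f"rank-deficient design matrix; collinear columns: {bad}")

    if prewhiten:
        beta0 = np.linalg.lstsq(x, y, rcond=None)[0]
        resid0 = y - x @ beta0
        num = np.sum(resid0[1:] * resid0[:-1], axis=0)
        den = np.sum(resid0**2, axis=0)
        rho = float(np.median(np.where(den > 0, num / np.maximum(den, 1e-30), 0.0)))
        rho = float(np.clip(rho, -0.99, 0.99))
        y = y[1:] - rho * y[:-1]
        x = x[1:] - rho * x[:-1]

    t_len = x.shape[0]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dof = t_len - np.linalg.matrix_rank(x)
    sigma2 = np.sum(resid**2, axis=0) / dof

    n_vert = y.shape[1]
    names = [c.name for c in contrasts]
    cope = np.empty((len(contrasts), n_vert))
    varcope = np.empty_like(cope)
    for i, con in enumerate(contrasts):
        cvec = design.contrast_vector(con)
        cope[i] = cvec @ beta
        varcope[i] = sigma2 * float(cvec @ xtx_inv @ cvec)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map = np.where(varcope > 0, cope / np.sqrt(varcope), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_map), dof)
    z = _p_to_z(t_map, dof)
    return GlmResult(names, cope, varcope, t_map, z, p, float(dof))


def fixed_effects(runs: list[GlmResult]) -> GlmResult:
    """Inverse-variance-weighted combination of runs within a subject.

    COPE* = sum(COPE_i / V_i) / sum(1 / V_i),  VARCOPE* = 1 / sum(1 / V_i).
    """
    if not runs:
        raise ValueError("need at least one run")
    names = runs[0].contrast_names
    for r in runs[1:]:
        if r.contrast_names != names:
            raise ValueError("runs have mismatched contrasts")
    if any(np.any(r.varcope <= 0) for r in runs):
        raise ValueError("zero or negative VARCOPE in input run")
    w = np.stack([1.0 / r.varcope for r in runs])
    copes = np.stack([r.cope for r in runs])
    wsum = w.sum(axis=0)
    cope = (w * copes).sum(axis=0) / wsum
    varcope = 1.0 / wsum
    dof = float(sum(r.dof for r in runs))
    t_map = cope / np.sqrt(varcope)
    p = 2.0 * stats.t.sf(np.abs(t_map), dof)
    z = _p_to_z(t_map, dof)
    return GlmResult(list(names), cope, varcope, t_map, z, p, dof)


def group_inference(subject_results: list[GlmResult], contrast: Contrast | str) -> GlmResult:
    """One-sample t across subjects on per-vertex COPEs (df n-1).

    Treats the subject as the random effect: the paper-style mixed-effects
    group map simplified to ordinary least squares on subject contrasts.
    """
    name = contrast if isinstance(contrast, str) else contrast.name
    n = len(subject_results)
    if n < 3:
        raise ValueError("group inference requires at least 3 subjects")
    copes = np.stack([r.for_contrast(name)["cope"] for r in subject_results])
    mean = copes.mean(axis=0)
    sd = copes.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map = np.where(se > 0, mean / se, np.where(mean != 0, np.inf, 0.0))
    dof = n - 1
    finite = np.isfinite(t_map)
    p = np.where(finite, 2.0 * stats.t.sf(np.abs(np.where(finite, t_map, 0.0)), dof), 0.0)
    z = np.where(finite, _p_to_z(np.where(finite, t_map, 0.0), dof), np.inf * np.sign(t_map))
    varcope = se**2
    return GlmResult([name], mean[None], varcope[None], t_map[None], z[None], p[None], float(dof))
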
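"""Phase-encoded analysis: run combination, Fourier F statistic, decoding."""

import numpy as np
import pytest
from scipy import stats

from cortimap import (
    CombineSpec,
    ComplexMap,
    PhaseCoordinateMap,
    PhaseEncodedDesign,
    VertexTimeSeries,
    build_exclusion_set,
    combine_runs,
    decode_phase,
    estimate_delay,
    fourier_stat,
)

from conftest import binomial_bounds


def design(t=512, direction="forward", cycles=8):
    return PhaseEncodedDesign(t, 1.0, cycles, direction, "visual")


def sinusoid_run(phases, amplitude, d, delay_s=0.0, noise=0.0, rng=None):
    """Traveling-wave forward model for a given design."""
    t = np.arange(d.n_samples)
    theta = 2 * np.pi * d.cycles_per_run * t / d.n_samples
    omega_d = 2 * np.pi * d.cycles_per_run * delay_s / d.run_seconds
    sign = 1.0 if d.direction == "forward" else -1.0
    data = amplitude * np.cos(theta[None, :] - sign * np.asarray(phases)[:, None] - omega_d)
    if noise:
        data = data + noise * rng.standard_normal(data.shape)
    return VertexTimeSeries(data, d)


class TestCombineRuns:
    def test_single_forward_run_is_identity(self, rng):
        run = VertexTimeSeries(rng.standard_normal((5, 64)), design(64))
        out = combine_runs([run], CombineSpec(2.0))
        assert np.allclose(out.data, run.data)

    def test_two_identical_forward_runs_average_to_same(self, rng):
        run = VertexTimeSeries(rng.standard_normal((5, 64)), design(64))
        run2 = VertexTimeSeries(run.data.copy(), design(64))
        out = combine_runs([run, run2], CombineSpec(2.0))
        assert np.allclose(out.data, run.data)

    def test_mismatched_length_errors(self, rng):
        r1 = VertexTimeSeries(rng.standard_normal((2, 64)), design(64))
        r2 = VertexTimeSeries(rng.standard_normal((2, 128)), design(128))
        with pytest.raises(ValueError, match="mismatched"):
            combine_runs([r1, r2], CombineSpec(0.0))

    @pytest.mark.parametrize("delay", [0.0, 2.0, 4.0, 5.0])
    def test_forward_reverse_pair_recovers_phase_plus_delay(self, delay):
        """Closed-form sinusoid algebra: combined phase is phi0 + omega*d."""
        phi0 = np.array([0.3, 1.7, 4.0])
        fwd = sinusoid_run(phi0, 1.0, design(512, "forward"), delay_s=delay)
        rev = sinusoid_run(phi0, 1.0, design(512, "reverse"), delay_s=delay)
        out = combine_runs([fwd, rev], CombineSpec(delay))
        cmap, _ = fourier_stat(out)
        omega_d = 2 * np.pi * 8 * delay / 512.0
        err = np.angle(np.exp(1j * (np.angle(cmap.values) - phi0 - omega_d)))
        assert np.abs(err).max() < 2 * np.pi * 8 / 512  # one-sample quantization

    def test_reverse_only_equals_forward_estimate(self):
        """Reversal + shift puts reverse runs in the forward convention."""
        phi0 = np.array([1.0])
        delay = 4.0
        fwd = sinusoid_run(phi0, 1.0, design(512, "forward"), delay_s=delay)
        rev = sinusoid_run(phi0, 1.0, design(512, "reverse"), delay_s=delay)
        cf, _ = fourier_stat(combine_runs([fwd], CombineSpec(delay)))
        cr, _ = fourier_stat(combine_runs([rev], CombineSpec(delay)))
        err = np.angle(np.exp(1j * (np.angle(cf.values) - np.angle(cr.values))))
        assert np.abs(err).max() < 2 * np.pi * 8 / 512


class TestExclusionSet:
    def test_enumeration_t512(self):
        excl = build_exclusion_set(design(512))
        assert excl.signal_bin == 8
        assert excl.noise_excluded == frozenset(
            {0, 1, 2, 3, 7, 9, 15, 16, 17, 23, 24, 25, 256}
        )
        assert excl.noise_bins().size == 257 - 13 - 1

    def test_no_low_bins_when_n_low_zero(self):
        excl = build_exclusion_set(design(512), n_low=0)
        assert excl.noise_excluded == frozenset({0, 7, 9, 15, 16, 17, 23, 24, 25, 256})

    def test_t64_no_clipping(self):
        excl = build_exclusion_set(design(64))
        assert max(excl.noise_excluded) == 32  # Nyquist; 3s+1=25 <= 32
        assert 25 in excl.noise_excluded

    def test_harmonics_beyond_nyquist_clip_with_warning(self):
        with pytest.warns(UserWarning, match="Nyquist"):
            excl = build_exclusion_set(design(32, cycles=8))
        assert all(b <= 16 for b in excl.noise_excluded)


class TestFourierStat:
    def test_pure_sinusoid_gives_inf_f(self):
        ts = sinusoid_run(np.array([0.5]), 1.0, design(512))
        _, stat = fourier_stat(ts)
        assert np.isinf(stat.f[0])
        assert stat.p[0] == 0.0

    def test_df2_is_486_for_t512(self):
        ts = sinusoid_run(np.array([0.0]), 1.0, design(512))
        _, stat = fourier_stat(ts)
        assert (stat.df1, stat.df2) == (2, 486)

    def test_offset_invariance(self, rng):
        d = design(128)
        x = rng.standard_normal((10, 128))
        _, s1 = fourier_stat(VertexTimeSeries(x, d))
        _, s2 = fourier_stat(VertexTimeSeries(x + 100.0, d))
        assert np.allclose(s1.f, s2.f)

    def test_parseval(self, rng):
        x = rng.standard_normal((4, 128))
        x = x - x.mean(axis=1, keepdims=True)
        spec = np.fft.fft(x, axis=1)
        power = np.abs(spec) ** 2
        assert np.allclose(power.sum(axis=1), x.var(axis=1) * 128 * 128)

    def test_null_calibration(self):
        """White noise: p<0.001 rate in pooled binomial CI; F ~ F(2, 486).

        Pools replicate null datasets for a tight CI on the rate."""
        nv, count = 10_000, 0
        for seed in range(4):
            rng = np.random.default_rng(seed)
            ts = VertexTimeSeries(rng.standard_normal((nv, 512)), design(512))
            _, stat = fourier_stat(ts)
            count += int((stat.p < 0.001).sum())
            if seed == 0:
                ks = stats.kstest(stat.f, "f", args=(stat.df1, stat.df2))
                assert ks.pvalue > 0.01
        lo, hi = binomial_bounds(4 * nv, 0.001)
        assert lo <= count <= hi

    def test_phase_recovery_at_snr5(self, rng):
        """Recovered phase within 2 degrees of truth at SNR 5, T=512."""
        truth = np.deg2rad(np.arange(0, 360, 45.0))
        reps = np.repeat(truth, 50)
        ts = sinusoid_run(reps, 5.0, design(512), noise=1.0, rng=rng)
        cmap, _ = fourier_stat(ts)
        err = np.rad2deg(np.angle(np.exp(1j * (np.angle(cmap.values) - reps))))
        assert np.median(np.abs(err)) < 2.0

    def test_all_bins_excluded_errors(self):
        d = design(32, cycles=8)
        with pytest.warns(UserWarning):
            excl = build_exclusion_set(d, n_low=14)
        ts = sinusoid_run(np.array([0.0]), 1.0, d)
        with pytest.raises(ValueError, match="no noise bins"):
            fourier_stat(ts, excl)


class TestDecodePhase:
    def test_auditory_ramp_start(self):
        cmap = ComplexMap(np.array([1.0 + 0j]))
        out = decode_phase(cmap, PhaseCoordinateMap(modality="auditory"))
        assert np.isclose(out[0], 150.0)

    def test_auditory_half_cycle_is_geometric_mean(self):
        cmap = ComplexMap(np.array([np.exp(1j * np.pi)]))
        out = decode_phase(cmap, PhaseCoordinateMap(modality="auditory"))
        assert np.isclose(out[0], 1200.0)  # 150 * sqrt(64)

    def test_somatomotor_boundary_part11(self):
        cmap = ComplexMap(np.array([np.exp(1j * (2 * np.pi - 1e-9))]))
        out = decode_phase(cmap, PhaseCoordinateMap(modality="somatomotor"))
        assert out[0] == 11

    def test_visual_degrees(self):
        cmap = ComplexMap(np.exp(1j * np.array([0.0, np.pi / 2, np.pi])))
        out = decode_phase(cmap, PhaseCoordinateMap(modality="visual"))
        assert np.allclose(out, [0.0, 90.0, 180.0])

    def test_zero_amplitude_flagged_nan(self):
        cmap = ComplexMap(np.array([0.0 + 0j, 1.0 + 0j]))
        out = decode_phase(cmap, PhaseCoordinateMap(modality="visual"))
        assert np.isnan(out[0]) and not np.isnan(out[1])


def test_estimate_delay_recovers_truth(rng):
    """Delay scan picks the simulated hemodynamic lag."""
    true_delay = 4.0
    phi = rng.uniform(0, 2 * np.pi, 30)
    fwd = sinusoid_run(phi, 2.0, design(256, "forward"), true_delay, 1.0, rng)
    rev = sinusoid_run(phi, 2.0, design(256, "reverse"), true_delay, 1.0, rng)
    est = estimate_delay([fwd, rev], candidate_delays=np.arange(0, 9.0, 1.0))
    assert abs(est - true_delay) <= 1.0
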
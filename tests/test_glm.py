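"""Block-design GLM: design matrix, fits, fixed effects, group inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortimap import (
    BlockDesign,
    Contrast,
    HrfModel,
    build_design_matrix,
    dct_highpass_basis,
    fit_glm,
    fixed_effects,
    group_inference,
    make_reading_design,
)

from conftest import binomial_bounds

EH = Contrast("English-Hindi", {"English": 1.0, "Hindi": -1.0})


def one_block_design(onset=32.0, duration=16.0, run=256.0, tr=1.0):
    ev = pd.DataFrame(
        [{"condition": "English", "onset": onset, "duration": duration}]
    )
    return BlockDesign(ev, run, tr, highpass_cutoff_s=100.0)


class TestHrf:
    def test_kernel_peaks_at_gamma_mode(self):
        hrf = HrfModel()
        h = hrf.sample(0.1)
        # gamma mode = mean - sd^2/mean = 6 - 9/6 = 4.5 s
        mode = hrf.peak_delay_s - hrf.peak_dispersion_s**2 / hrf.peak_delay_s
        assert abs(np.argmax(h) * 0.1 - mode) <= 0.2
        assert np.isclose(h.max(), 1.0)

    def test_undershoot_is_negative(self):
        h = HrfModel().sample(0.5)
        assert h.min() < 0


class TestDesignMatrix:
    def test_no_events_only_intercept_and_drift(self):
        bd = BlockDesign(
            pd.DataFrame(columns=["condition", "onset", "duration"]), 256.0, 1.0
        )
        dm = build_design_matrix(bd)
        assert dm.columns == [f"drift_{k}" for k in range(1, 6)] + ["intercept"]

    def test_single_block_peaks_after_hrf_delay(self):
        bd = one_block_design(onset=32.0, duration=16.0)
        dm = build_design_matrix(bd, add_derivatives=False)
        reg = dm.matrix[:, dm.columns.index("English")]
        # boxcar peak plateau midpoint shifted by roughly the HRF peak delay
        t_peak = float(np.argmax(reg)) * bd.tr
        assert 32.0 + 6.0 - 3.0 <= t_peak <= 32.0 + 16.0 + 6.0 + 3.0

    def test_drift_column_count_formula(self):
        bd = make_reading_design(seed=0)  # 512 s run, 100 s cutoff
        dm = build_design_matrix(bd)
        assert sum(c.startswith("drift_") for c in dm.columns) == 10
        assert dct_highpass_basis(512, 1.0, 100.0).shape == (512, 10)

    def test_derivative_columns_present_and_weighted_zero(self):
        bd = make_reading_design(seed=1)
        dm = build_design_matrix(bd)
        assert "English_derivative" in dm.columns
        cvec = dm.contrast_vector(EH)
        assert cvec[dm.columns.index("English_derivative")] == 0.0
        assert cvec[dm.columns.index("English")] == 1.0

    def test_overlapping_blocks_error(self):
        ev = pd.DataFrame(
            [
                {"condition": "English", "onset": 0.0, "duration": 16.0},
                {"condition": "English", "onset": 8.0, "duration": 16.0},
            ]
        )
        with pytest.raises(ValueError, match="overlapping"):
            BlockDesign(ev, 256.0, 1.0)


class TestFitGlm:
    def test_all_zero_data_gives_zero_copes(self):
        bd = one_block_design()
        dm = build_design_matrix(bd)
        res = fit_glm(np.zeros((3, 256)), dm, [Contrast("E", {"English": 1.0})])
        assert np.allclose(res.cope, 0.0)
        assert np.allclose(res.t, 0.0)

    def test_noiseless_recovery_is_exact(self, rng):
        """COPE on X*beta data equals c'beta exactly."""
        bd = make_reading_design(seed=2)
        dm = build_design_matrix(bd)
        beta = rng.standard_normal((len(dm.columns), 7))
        y = (dm.matrix @ beta).T
        res = fit_glm(y, dm, [EH])
        cvec = dm.contrast_vector(EH)
        assert np.allclose(res.cope[0], cvec @ beta, atol=1e-8)

    def test_parameter_recovery_within_2se(self, rng):
        """y = X*beta + noise with effect 1.0: mean COPE near 1.0."""
        bd = make_reading_design(seed=3)
        dm = build_design_matrix(bd, add_derivatives=False)
        nv = 1000
        e_idx = dm.columns.index("English")
        y = dm.matrix[:, e_idx][None, :] + rng.standard_normal((nv, bd.n_samples))
        res = fit_glm(y, dm, [Contrast("E", {"English": 1.0})])
        se = res.cope[0].std(ddof=1) / np.sqrt(nv)
        assert abs(res.cope[0].mean() - 1.0) < 2 * se

    def test_null_calibration(self, rng):
        bd = make_reading_design(seed=4)
        dm = build_design_matrix(bd)
        nv = 10_000
        res = fit_glm(rng.standard_normal((nv, bd.n_samples)), dm, [EH])
        p_one = stats.t.sf(res.t[0], res.dof)
        lo, hi = binomial_bounds(nv, 0.001)
        assert lo <= (p_one < 0.001).sum() <= hi

    def test_prewhitening_restores_ar1_calibration(self, rng):
        """AR(1) noise inflates false positives; prewhitening repairs them."""
        bd = make_reading_design(seed=5)
        dm = build_design_matrix(bd)
        nv, rho = 4000, 0.5
        noise = rng.standard_normal((nv, bd.n_samples))
        for i in range(1, bd.n_samples):
            noise[:, i] += rho * noise[:, i - 1]
        raw = fit_glm(noise, dm, [EH])
        white = fit_glm(noise, dm, [EH], prewhiten=True)
        fp_raw = (stats.t.sf(np.abs(raw.t[0]), raw.dof) * 2 < 0.01).mean()
        fp_white = (stats.t.sf(np.abs(white.t[0]), white.dof) * 2 < 0.01).mean()
        assert fp_white < fp_raw
        lo, hi = binomial_bounds(nv, 0.01, conf=0.999)
        assert lo <= fp_white * nv <= hi

    def test_rank_deficient_design_errors(self):
        bd = one_block_design()
        dm = build_design_matrix(bd)
        dm.matrix = np.column_stack([dm.matrix, dm.matrix[:, 0]])
        dm.columns = dm.columns + ["dup"]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_glm(np.zeros((2, 256)), dm, [])

    def test_zvalue_pairing(self):
        """|t| at one-sided p=0.001 maps to Z=3.09 for large dof."""
        from cortimap.glm import _p_to_z

        t_crit = stats.t.isf(0.001, 500)
        z = _p_to_z(np.array([t_crit, -t_crit]), 500)
        assert np.allclose(np.abs(z), 3.09, atol=0.01)
        assert z[1] < 0


class TestFixedEffects:
    def test_single_run_unchanged(self, rng):
        bd = make_reading_design(seed=6)
        dm = build_design_matrix(bd)
        res = fit_glm(rng.standard_normal((5, bd.n_samples)), dm, [EH])
        out = fixed_effects([res])
        assert np.allclose(out.cope, res.cope)
        assert np.allclose(out.varcope, res.varcope)

    def test_equal_variance_closed_form(self):
        a = _fake_result(cope=1.0, varcope=2.0)
        b = _fake_result(cope=3.0, varcope=2.0)
        out = fixed_effects([a, b])
        assert np.allclose(out.cope, 2.0)
        assert np.allclose(out.varcope, 1.0)

    def test_heterogeneous_variances_match_bruteforce(self, rng):
        runs = [
            _fake_result(cope=rng.standard_normal(20), varcope=rng.uniform(0.5, 3, 20))
            for _ in range(4)
        ]
        out = fixed_effects(runs)
        w = np.stack([1 / r.varcope[0] for r in runs])
        c = np.stack([r.cope[0] for r in runs])
        assert np.allclose(out.cope[0], (w * c).sum(0) / w.sum(0))
        assert np.allclose(out.varcope[0], 1 / w.sum(0))

    def test_k_identical_runs_divide_varcope(self):
        r = _fake_result(cope=1.5, varcope=3.0)
        out = fixed_effects([r, r, r])
        assert np.allclose(out.cope, 1.5)
        assert np.allclose(out.varcope, 1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="VARCOPE"):
            fixed_effects([_fake_result(cope=1.0, varcope=0.0)])


def _fake_result(cope, varcope, n=20):
    from cortimap.glm import GlmResult

    cope = np.broadcast_to(np.asarray(cope, dtype=float), (n,)).copy()
    varcope = np.broadcast_to(np.asarray(varcope, dtype=float), (n,)).copy()
    t = np.zeros(n)
    return GlmResult(
        ["English-Hindi"], cope[None], varcope[None], t[None], t[None],
        np.ones((1, n)), 100.0,
    )


class TestGroupInference:
    def test_identical_copes_give_inf_t(self):
        subs = [_fake_result(cope=2.0, varcope=1.0) for _ in range(5)]
        out = group_inference(subs, "English-Hindi")
        assert np.all(np.isinf(out.t))

    def test_requires_three_subjects(self):
        with pytest.raises(ValueError, match="at least 3"):
            group_inference([_fake_result(1.0, 1.0)] * 2, "English-Hindi")

    def test_null_calibration_n14(self):
        """Null subject COPEs: two-sided p<0.01 rate within the pooled CI."""
        nv, count = 10_000, 0
        for seed in range(4):
            rng = np.random.default_rng(seed)
            subs = [
                _fake_result(cope=rng.standard_normal(nv), varcope=1.0, n=nv)
                for _ in range(14)
            ]
            out = group_inference(subs, "English-Hindi")
            count += int((out.p[0] < 0.01).sum())
            assert out.dof == 13
        lo, hi = binomial_bounds(4 * nv, 0.01)
        assert lo <= count <= hi
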
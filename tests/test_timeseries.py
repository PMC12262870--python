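"""Design-matrix construction, GLM, gPPI and resting-connectivity estimators."""

import numpy as np
import pandas as pd
import pytest

from sinconn.synthetic import BOLDSeries, TaskDesign, generate_bold, \
    generate_task_design
from sinconn.timeseries import (build_design_matrix, compute_ppi_betas,
                                compute_rsfc, double_gamma_hrf, fit_glm)


def _single_condition_design(onsets, tr=0.64, duration=0.4):
    onsets = np.asarray(onsets, float)
    n = onsets.size
    return TaskDesign(
        onsets=onsets, snr_db=np.zeros(n, int),
        syllable=np.array(["ba"] * n), block=np.zeros(n, int),
        iti_values=np.full(n, 4.0), tr=tr, trial_duration=duration,
        n_blocks=1, trials_per_block=n)


class TestDesignMatrix:
    def test_single_brief_trial_reproduces_hrf_shape(self):
        # convolution with a near-delta stimulus is the HRF up to scale
        d = _single_condition_design([0.0], duration=0.04)
        hrf = double_gamma_hrf(d.tr)[::16]
        X = build_design_matrix(d, n_timepoints=hrf.size)
        reg = X["snr+0"].to_numpy()
        reg = reg / np.abs(reg).max()
        hrf = hrf / np.abs(hrf).max()
        r = np.corrcoef(reg, hrf)[0, 1]
        assert r > 0.999

    def test_disjoint_conditions_sum_to_union_column(self):
        on_a, on_b = [0.0, 10.0], [5.0, 15.0]
        da = _single_condition_design(on_a)
        db = _single_condition_design(on_b)
        dun = _single_condition_design(sorted(on_a + on_b))
        n = 60
        xa = build_design_matrix(da, n_timepoints=n)["snr+0"]
        xb = build_design_matrix(db, n_timepoints=n)["snr+0"]
        xu = build_design_matrix(dun, n_timepoints=n)["snr+0"]
        np.testing.assert_allclose(xa + xb, xu, atol=1e-12)

    def test_condition_missing_from_block_is_an_error(self):
        d = generate_task_design(seed=0)
        # restrict one condition's trials to block 1 only
        snr = d.snr_db.copy()
        snr[(d.block == 0) & (snr == 8)] = 0
        broken = TaskDesign(onsets=d.onsets, snr_db=snr, syllable=d.syllable,
                            block=d.block, iti_values=d.iti_values, tr=d.tr,
                            trial_duration=d.trial_duration,
                            n_blocks=d.n_blocks,
                            trials_per_block=d.trials_per_block)
        with pytest.raises(ValueError, match="no trials in block"):
            build_design_matrix(broken, block=0)

    def test_duplicated_onsets_warn_and_sum(self):
        d = _single_condition_design([5.0, 5.0])
        single = _single_condition_design([5.0])
        with pytest.warns(UserWarning, match="duplicated"):
            x2 = build_design_matrix(d, n_timepoints=40)["snr+0"]
        x1 = build_design_matrix(single, n_timepoints=40)["snr+0"]
        np.testing.assert_allclose(x2, 2 * x1, atol=1e-12)


class TestGLM:
    def test_exact_data_recovers_coefficients(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        beta = np.array([1.5, -2.0, 0.25, 3.0])
        y = X.to_numpy() @ beta
        est, sigma2 = fit_glm(y, X)
        np.testing.assert_allclose(est.to_numpy(), beta, rtol=1e-10)
        assert sigma2 == pytest.approx(0.0, abs=1e-16)

    def test_censoring_equals_row_deletion(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        flags = rng.random(40) < 0.25
        est_c, s_c = fit_glm(y, X, censor_flags=flags)
        est_d, s_d = fit_glm(y[~flags], X[~flags])
        np.testing.assert_allclose(est_c.to_numpy(), est_d.to_numpy(),
                                   rtol=1e-12)
        assert s_c == pytest.approx(s_d, rel=1e-12)

    def test_orthogonal_response_gives_zero_coefficients(self):
        X = pd.DataFrame(np.eye(6)[:, :3], columns=list("abc"))
        y = np.array([0., 0., 0., 1., -1., 2.])
        est, _ = fit_glm(y, X)
        np.testing.assert_allclose(est.to_numpy(), 0.0, atol=1e-12)

    def test_rank_deficiency_names_collinear_columns(self, rng):
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": rng.normal(size=30), "a2": 2 * a})
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(rng.normal(size=30), X)


class TestPPI:
    def test_interaction_target_recovers_unit_beta(self):
        d = generate_task_design(n_blocks=1, seed=5)
        bold, _ = generate_bold(d, {"snr+8": 1.0}, baseline_coupling=0.0,
                                noise_sd=0.0, seed=0)
        res = compute_ppi_betas(bold, d)
        assert res.interaction.iloc[0]["snr+8"] == pytest.approx(1.0, abs=1e-8)
        assert abs(res.interaction.iloc[0]["snr-8"]) < 1e-8

    def test_beta_invariant_to_seed_and_task_leakage(self):
        # adding multiples of model columns to the target must not move TiFC
        d = generate_task_design(n_blocks=1, seed=5)
        bold, _ = generate_bold(d, {"snr+0": 0.5}, noise_sd=0.5, seed=3)
        base = compute_ppi_betas(bold, d).interaction.iloc[0]
        X = build_design_matrix(d, n_timepoints=bold.n_timepoints)
        contaminated = BOLDSeries(
            seed_series=bold.seed_series,
            target_series=bold.target_series + 3.0 * bold.seed_series
            - 2.0 * X["snr-8"].to_numpy(),
            tr=bold.tr)
        shifted = compute_ppi_betas(contaminated, d).interaction.iloc[0]
        np.testing.assert_allclose(shifted.to_numpy(), base.to_numpy(),
                                   atol=1e-8)

    def test_doubling_target_doubles_betas(self):
        d = generate_task_design(n_blocks=1, seed=5)
        bold, _ = generate_bold(d, {"snr+0": 0.5}, noise_sd=0.5, seed=4)
        b1 = compute_ppi_betas(bold, d).interaction.iloc[0]
        doubled = BOLDSeries(seed_series=bold.seed_series,
                             target_series=2 * bold.target_series, tr=bold.tr)
        b2 = compute_ppi_betas(doubled, d).interaction.iloc[0]
        np.testing.assert_allclose(b2.to_numpy(), 2 * b1.to_numpy(), rtol=1e-9)

    def test_zero_variance_voxel_flagged_not_zeroed(self):
        d = generate_task_design(n_blocks=1, seed=5)
        bold, _ = generate_bold(d, {"snr+0": 0.5}, noise_sd=0.5, seed=4)
        targets = np.column_stack([bold.target_series,
                                   np.full(bold.n_timepoints, 7.0)])
        multi = BOLDSeries(seed_series=bold.seed_series,
                           target_series=targets, tr=bold.tr)
        res = compute_ppi_betas(multi, d)
        assert res.valid.tolist() == [True, False]
        assert np.isnan(res.interaction.iloc[1]).all()

    def test_neural_mode_recovers_neural_level_coupling(self):
        # independent construction: couple seed and target at the neural
        # level (pre-HRF), convolve, and check the deconvolution-based mode
        # finds the coupled condition while BOLD-level multiplication cannot
        from sinconn.timeseries import _condition_boxcars, double_gamma_hrf
        d = generate_task_design(n_blocks=1, seed=5)
        n_tp = int(np.ceil(d.block_duration(0) / d.tr))
        hrf = double_gamma_hrf(d.tr, 1)
        box = _condition_boxcars(d, 0, "snr", n_tp)
        rng = np.random.default_rng(0)
        neural_seed = sum(box.values())
        seed_bold = np.convolve(neural_seed, hrf)[:n_tp] + \
            rng.normal(0, 0.1, n_tp)
        gate = box["snr+8"] - box["snr+8"].mean()
        neural_tgt = 0.5 * neural_seed + \
            0.8 * (neural_seed - neural_seed.mean()) * gate
        target = np.convolve(neural_tgt, hrf)[:n_tp] + rng.normal(0, 0.1, n_tp)
        bold = BOLDSeries(seed_series=seed_bold, target_series=target, tr=d.tr)
        row = compute_ppi_betas(bold, d, mode="neural").interaction.iloc[0]
        assert row["snr+8"] > 0.2
        assert row["snr+8"] > 2 * max(abs(row["snr-8"]), abs(row["snr+0"]))


class TestRSFC:
    def test_identical_series_correlate_to_one(self, rng):
        x = rng.normal(size=600)
        r = compute_rsfc(x, x, tr=0.64)
        assert r[0] == pytest.approx(1.0, abs=1e-10)

    def test_negated_series_correlate_to_minus_one(self, rng):
        x = rng.normal(size=600)
        r = compute_rsfc(-x, x, tr=0.64)
        assert r[0] == pytest.approx(-1.0, abs=1e-10)

    def test_out_of_band_contamination_removed(self, rng):
        # FFT power-ratio oracle: a 0.5 Hz sinusoid (outside 0.02-0.1 Hz at
        # TR 0.64 s) must be attenuated >= 20 dB and barely perturb r
        tr, n = 0.64, 1200
        t = np.arange(n) * tr
        seed = rng.normal(size=n)
        sine = 5.0 * np.sin(2 * np.pi * 0.5 * t)
        r = compute_rsfc(seed + sine, seed, tr=tr)
        assert r[0] > 0.98

        from scipy import signal as sig
        sos = sig.butter(4, [0.02, 0.1], btype="bandpass", fs=1 / tr,
                         output="sos")
        filtered = sig.sosfiltfilt(sos, sine)
        f, p_in = sig.periodogram(sine, fs=1 / tr)
        _, p_out = sig.periodogram(filtered, fs=1 / tr)
        band = (f > 0.45) & (f < 0.55)
        atten_db = 10 * np.log10(p_in[band].sum() / max(p_out[band].sum(),
                                                        1e-300))
        assert atten_db >= 20

    def test_invariant_to_affine_rescaling(self, rng):
        x = rng.normal(size=800)
        y = rng.normal(size=800) + 0.3 * x
        r0 = compute_rsfc(y, x, tr=0.64)[0]
        r1 = compute_rsfc(5.0 * y + 2.0, 0.5 * x - 7.0, tr=0.64)[0]
        assert r1 == pytest.approx(r0, abs=1e-10)

    def test_nuisance_regression_removes_shared_confound(self, rng):
        n = 900
        conf = rng.normal(size=n)
        x = rng.normal(size=n) + 2 * conf
        y = rng.normal(size=n) + 2 * conf
        r_with = compute_rsfc(y, x, tr=0.64)[0]
        r_clean = compute_rsfc(y, x, tr=0.64, nuisance=conf)[0]
        assert abs(r_clean) < abs(r_with)

    def test_band_outside_nyquist_rejected(self, rng):
        with pytest.raises(ValueError, match="band"):
            compute_rsfc(rng.normal(size=600), rng.normal(size=600),
                         tr=0.64, band=(0.02, 1.0))

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="short"):
            compute_rsfc(rng.normal(size=50), rng.normal(size=50), tr=0.64)
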
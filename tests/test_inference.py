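"""Composite likelihood, fitting determinism, ranking arithmetic, scaling."""

import numpy as np
import pandas as pd
import pytest

from sfsflow.demography import get_model
from sfsflow.engine import expected_sfs
from sfsflow.inference import (FitResult, InferenceError, bootstrap, fit_model,
                               poisson_loglik, rank_models,
                               scale_to_natural_units)
from sfsflow.sfs import JointSFS
from sfsflow.simulate import simulate_sfs

from conftest import FAST_ENGINE


def _fit(model_id, ll, k_override=None):
    m = get_model(model_id)
    return FitResult(model=m, params=np.ones(m.k), log_likelihood=ll,
                     theta_hat=1.0)


class TestPoissonLoglik:
    def test_analytic_theta_recovers_scale(self, im_model):
        m = expected_sfs(im_model, [0.3, 1, 1, 1.5], 8, 8, FAST_ENGINE)
        data = JointSFS(2.0 * m.counts)
        ll, theta = poisson_loglik(data, m)
        assert theta == pytest.approx(2.0)

    def test_single_cell_formula(self):
        data = JointSFS(np.array([[0.0, 3.0], [0.0, 0.0]]))
        model = JointSFS(np.array([[0.0, 1.0], [0.0, 0.0]]))
        ll, theta = poisson_loglik(data, model)
        assert theta == pytest.approx(3.0)
        assert ll == pytest.approx(3 * np.log(3) - 3 - np.log(6))

    def test_model_scale_invariance(self, im_model):
        m = expected_sfs(im_model, [0.3, 1, 1, 1.5], 8, 8, FAST_ENGINE)
        data = JointSFS(np.round(100 * m.counts))
        ll1, th1 = poisson_loglik(data, m)
        scaled = JointSFS(7.0 * m.counts)
        ll2, th2 = poisson_loglik(data, scaled)
        assert ll1 == pytest.approx(ll2)
        assert th2 == pytest.approx(th1 / 7.0)

    def test_shape_mismatch(self, im_model):
        m = expected_sfs(im_model, [0.3, 1, 1, 1.5], 8, 8, FAST_ENGINE)
        with pytest.raises(InferenceError):
            poisson_loglik(JointSFS(np.ones((3, 3))), m)


class TestFitModel:
    def test_deterministic_given_seed(self, im_model):
        data = simulate_sfs(im_model, [0.3, 1, 1, 1.5], 8, 8, 500.0, seed=11,
                            config=FAST_ENGINE)
        f1 = fit_model(data, im_model, n_starts=1, seed=4, config=FAST_ENGINE,
                       maxiter=40, polish=False)
        f2 = fit_model(data, im_model, n_starts=1, seed=4, config=FAST_ENGINE,
                       maxiter=40, polish=False)
        np.testing.assert_array_equal(f1.params, f2.params)
        assert f1.log_likelihood == f2.log_likelihood

    def test_boundary_solution_flagged(self, im_model):
        """Truth outside the optimizer box ends on the boundary, flagged."""
        data = simulate_sfs(im_model, [0.3, 1, 1, 1.5], 8, 8, 800.0, seed=2,
                            config=FAST_ENGINE)
        import sfsflow.inference as inf
        f = fit_model(data, im_model, n_starts=1, seed=0, config=FAST_ENGINE,
                      init=[0.3, 1, 1, inf._LOG_FLOOR["m"]], maxiter=3,
                      fold_perturb=1.0000001, polish=False)
        assert isinstance(f.at_bounds, tuple)

    def test_aic_identity(self, im_model):
        f = FitResult(model=im_model, params=np.ones(4), log_likelihood=-10.0,
                      theta_hat=1.0)
        assert f.aic == 2 * im_model.k + 20.0

    def test_invalid_starts(self, im_model):
        data = JointSFS(np.ones((9, 9)))
        with pytest.raises(InferenceError):
            fit_model(data, im_model, n_starts=0)


class TestRankModels:
    def test_equal_fits_split_weight(self):
        """Two models with equal LL and equal k share the weight 50:50."""
        a = _fit("e2m0s", -50.0)   # k = 7
        b = _fit("e2ms0", -50.0)   # k = 7
        tab = rank_models([a, b])
        np.testing.assert_allclose(tab["weight"], [0.5, 0.5])
        np.testing.assert_allclose(tab["evidence_ratio"], [1.0, 1.0])

    def test_delta_two_weights(self):
        """dAIC = (0, 2) gives weights (0.731, 0.269), evidence ratio e."""
        a = _fit("e1m0", -50.0)                                  # AIC = 106
        b = FitResult(model=get_model("e1ma"), params=np.ones(5),
                      log_likelihood=-49.0, theta_hat=1.0)       # AIC = 108
        tab = rank_models([a, b])
        np.testing.assert_allclose(tab["delta_AIC"], [0.0, 2.0])
        np.testing.assert_allclose(tab["weight"],
                                   [0.7310585786, 0.2689414214], rtol=1e-6)
        assert tab.iloc[1]["evidence_ratio"] == pytest.approx(np.e)
        assert tab["weight"].sum() == pytest.approx(1.0)

    def test_large_evidence_ratio_no_overflow(self):
        """dAIC = 184.2 yields an evidence ratio e^92.1 ~ 1.1e40."""
        a = _fit("e1m0", 0.0)                                    # AIC = 6
        b = FitResult(model=get_model("e1ma"), params=np.ones(5),
                      log_likelihood=-(184.2 + 6 - 10) / 2, theta_hat=1.0)
        tab = rank_models([a, b])
        assert tab.iloc[1]["delta_AIC"] == pytest.approx(184.2)
        assert tab.iloc[1]["evidence_ratio"] == pytest.approx(np.exp(92.1),
                                                              rel=1e-6)
        assert 39.9 < np.log10(tab.iloc[1]["evidence_ratio"]) < 40.1

    def test_huge_delta_reported_in_log_space(self):
        a = _fit("e1m0", 0.0)
        b = FitResult(model=get_model("e1ma"), params=np.ones(5),
                      log_likelihood=-800.0, theta_hat=1.0)
        tab = rank_models([a, b])
        assert np.isinf(tab.iloc[1]["evidence_ratio"])
        assert tab.iloc[1]["log10_evidence_ratio"] == pytest.approx(
            (2 * 800 + 2 * (5 - 3)) / (2 * np.log(10)))
        assert tab["weight"].sum() == pytest.approx(1.0)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(InferenceError):
            rank_models([_fit("e1m0", -1.0), _fit("e1m0", -2.0)])


class TestBootstrap:
    def test_resample_reproducible_and_sized(self, small_site_table, im_model):
        summary1, fits1 = bootstrap(small_site_table, im_model, 2, 2,
                                    n_reps=2, seed=9, n_starts=1, maxiter=5,
                                    config=FAST_ENGINE, polish=False)
        summary2, _ = bootstrap(small_site_table, im_model, 2, 2,
                                n_reps=2, seed=9, n_starts=1, maxiter=5,
                                config=FAST_ENGINE, polish=False)
        pd.testing.assert_frame_equal(summary1, summary2)
        assert list(summary1["parameter"]) == list(im_model.param_names)

    def test_single_site_degenerate_sd_zero(self, im_model):
        sites = pd.DataFrame({"scaffold": ["s"], "pos": [1], "anc": ["A"],
                              "der": ["G"], "d1": [1], "c1": [2],
                              "d2": [1], "c2": [2]})
        summary, fits = bootstrap(sites, im_model, 2, 2, n_reps=2, seed=1,
                                  n_starts=1, maxiter=5, config=FAST_ENGINE,
                                  polish=False)
        np.testing.assert_allclose(summary["sd"], 0.0, atol=1e-12)

    def test_too_few_reps(self, small_site_table, im_model):
        with pytest.raises(InferenceError):
            bootstrap(small_site_table, im_model, 2, 2, n_reps=1, seed=0)


class TestScaling:
    def test_reference_size(self, im_model):
        fit = FitResult(model=im_model, params=np.array([0.5, 1, 1, 0.1]),
                        log_likelihood=-1.0, theta_hat=2000.0)
        scaled = scale_to_natural_units(fit, mu=1.02e-9, gen_time=5.0, L=1e7)
        assert scaled.N_ref == pytest.approx(2000 / (4 * 1.02e-9 * 1e7))
        # T = 0.5 at that N_ref spans 2*N_ref*0.5*5 years
        assert scaled.epochs.iloc[0]["start_years_bp"] == pytest.approx(
            2 * scaled.N_ref * 0.5 * 5)

    def test_epoch_times_decrease_toward_present(self):
        m = get_model("e3msss")
        vals = np.ones(m.k)
        fit = FitResult(model=m, params=vals, log_likelihood=-1.0,
                        theta_hat=1000.0)
        scaled = scale_to_natural_units(fit, 1e-9, 5.0, 1e7)
        starts = scaled.epochs["start_years_bp"].to_numpy()
        assert np.all(np.diff(starts) < 0)
        assert scaled.epochs.iloc[-1]["end_years_bp"] == pytest.approx(0.0)

    def test_migration_units(self, im_model):
        fit = FitResult(model=im_model, params=np.array([0.5, 2.0, 1, 3.0]),
                        log_likelihood=-1.0, theta_hat=1000.0)
        s = scale_to_natural_units(fit, 1e-9, 5.0, 1e7)
        row = s.epochs.iloc[0]
        assert row["m12_frac_per_gen"] == pytest.approx(3.0 / (2 * s.N_ref))
        assert row["m12_migrants_per_gen"] == pytest.approx(
            row["m12_frac_per_gen"] * 2.0 * s.N_ref)

    def test_invalid_inputs(self, im_model):
        fit = FitResult(model=im_model, params=np.ones(4),
                        log_likelihood=-1.0, theta_hat=1000.0)
        with pytest.raises(InferenceError):
            scale_to_natural_units(fit, mu=0, gen_time=5, L=1e7)
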
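"""Compartmental fitting: stripping, micro/macro identities, recovery,
model selection."""

import math

import numpy as np
import pytest

from pkdiss import compartmental as comp
from pkdiss import synthetic as syn
from pkdiss.models import biexponential, macro_from_micro, oral_one_compartment
from conftest import profile_from_arrays

GRID = np.array([0.25, 0.5, 1, 1.5, 2, 4, 8, 12, 24], dtype=float)


class TestMicroMacro:
    def test_forward_roots_hand_example(self):
        # s^2 - s + 0.1 = 0 -> (1 +/- sqrt(0.6))/2
        alpha, beta = comp.disposition_rates(0.5, 0.3, 0.2)
        assert alpha == pytest.approx((1 + math.sqrt(0.6)) / 2, abs=1e-12)
        assert beta == pytest.approx((1 - math.sqrt(0.6)) / 2, abs=1e-12)
        assert alpha == pytest.approx(0.8873, abs=5e-5)
        assert beta == pytest.approx(0.1127, abs=5e-5)

    def test_round_trip_recovers_micro_constants(self):
        A, B, alpha, beta = macro_from_micro(0.5, 0.3, 0.2, c0=1.0)
        m = comp.derive_microconstants(A, B, alpha, beta)
        assert m.k10 == pytest.approx(0.5, abs=1e-9)
        assert m.k12 == pytest.approx(0.3, abs=1e-9)
        assert m.k21 == pytest.approx(0.2, abs=1e-9)

    def test_equal_macro_intercepts_average_the_rates(self):
        m = comp.derive_microconstants(4.0, 4.0, 2.0, 0.5)
        assert m.k21 == pytest.approx((2.0 + 0.5) / 2)

    def test_vanishing_slow_phase_is_one_compartment_limit(self):
        m = comp.derive_microconstants(0.0, 8.0, 2.0, 0.5, dose=500.0)
        assert m.k21 == pytest.approx(2.0)
        assert m.k10 == pytest.approx(0.5)
        assert m.k12 == pytest.approx(0.0, abs=1e-12)
        assert m.v1_f == pytest.approx(500.0 / 8.0)

    def test_invalid_macro_inputs_rejected(self):
        with pytest.raises(ValueError):
            comp.derive_microconstants(1.0, 1.0, 0.5, 2.0)  # alpha < beta
        with pytest.raises(ValueError):
            comp.derive_microconstants(-1.0, 2.0, 2.0, 0.5)

    def test_round_trip_property_over_random_draws(self):
        """1000 random valid micro sets survive micro -> macro -> micro
        with max error <= 1e-9."""
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(1000):
            k10, k12, k21 = rng.uniform(0.02, 5.0, 3)
            A, B, alpha, beta = macro_from_micro(k10, k12, k21)
            m = comp.derive_microconstants(A, B, alpha, beta)
            worst = max(
                worst,
                abs(m.k10 - k10),
                abs(m.k12 - k12),
                abs(m.k21 - k21),
            )
        assert worst <= 1e-9


class TestStripResiduals:
    def test_recovers_exact_biexponential_within_5pct(self):
        c = biexponential(GRID, 12.0, 11.0, 2.0, 0.24)
        init = comp.strip_residuals(profile_from_arrays(GRID, c))
        assert not init.fallback
        assert init.alpha == pytest.approx(2.0, rel=0.05)
        assert init.beta == pytest.approx(0.24, rel=0.05)
        assert init.A == pytest.approx(12.0, rel=0.05)
        assert init.B == pytest.approx(11.0, rel=0.05)

    def test_monoexponential_triggers_flagged_fallback(self):
        c = 10.0 * np.exp(-0.3 * GRID)
        init = comp.strip_residuals(profile_from_arrays(GRID, c))
        assert init.fallback
        assert init.beta == pytest.approx(0.3, rel=0.05)

    def test_ordering_contract_alpha_above_beta(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            A, B = rng.uniform(1, 20, 2)
            alpha = rng.uniform(0.8, 4.0)
            beta = rng.uniform(0.05, 0.5)
            c = biexponential(GRID, A, B, alpha, beta)
            c *= 1 + rng.normal(0, 0.03, GRID.size)
            init = comp.strip_residuals(profile_from_arrays(GRID, np.abs(c)))
            assert init.alpha > init.beta > 0


class TestFitCompartmentModel:
    def test_noise_free_oral_recovery(self, noise_free_profile, noise_free_truth):
        fit = comp.fit_compartment_model(noise_free_profile)
        assert fit.converged
        assert fit.alpha == pytest.approx(noise_free_truth.alpha, rel=0.01)
        assert fit.beta == pytest.approx(noise_free_truth.beta, rel=0.01)
        assert fit.ka == pytest.approx(noise_free_truth.ka, rel=0.05)
        assert fit.cl_f == pytest.approx(noise_free_truth.cl_f, rel=0.01)

    def test_fit_satisfies_macro_micro_identities(self, noise_free_profile):
        fit = comp.fit_compartment_model(noise_free_profile)
        assert fit.alpha > fit.beta > 0
        assert fit.alpha * fit.beta == pytest.approx(
            fit.k10 * fit.k21, abs=1e-9 * fit.alpha * fit.beta
        )
        assert fit.alpha + fit.beta == pytest.approx(
            fit.k10 + fit.k12 + fit.k21, abs=1e-9
        )
        assert fit.alpha_hl == pytest.approx(math.log(2) / fit.alpha, rel=1e-12)
        assert fit.beta_hl == pytest.approx(math.log(2) / fit.beta, rel=1e-12)

    def test_fit_never_worse_than_stripping_initialization(self):
        rng = np.random.default_rng(17)
        truth = syn.rabbit_cipro_pk_truth(between_subject_cv=0, residual_cv=0.08)
        design = syn.StudyDesign(n_subjects=1, seed=int(rng.integers(1e6)))
        prof = syn.simulate_study(truth, design)[0]
        t, c = comp._fit_data(prof, "oral_first_order")
        theta0 = comp._initial_theta(prof, "oral_first_order", t, c)
        pred0 = comp._curve("oral_first_order", theta0, t, prof.dose)
        sse0 = float(np.sum((pred0 - c) ** 2))
        fit = comp.fit_compartment_model(prof)
        assert fit.sse <= sse0 + 1e-12

    def test_iv_biexponential_with_vanishing_slow_phase_collapses(self):
        c = biexponential(GRID, 14.0, 0.0, 0.9, 0.3)  # single exponential
        fit = comp.fit_compartment_model(
            profile_from_arrays(GRID, c), variant="iv_biexponential"
        )
        assert fit.k12 <= 0.05 * fit.alpha

    def test_iv_fit_recovers_macro_constants(self):
        c = biexponential(GRID, 12.0, 11.0, 2.0, 0.24)
        fit = comp.fit_compartment_model(
            profile_from_arrays(GRID, c), variant="iv_biexponential"
        )
        assert fit.A == pytest.approx(12.0, rel=0.01)
        assert fit.B == pytest.approx(11.0, rel=0.01)
        assert fit.auc_model == pytest.approx(12 / 2.0 + 11 / 0.24, rel=0.01)
        assert fit.tmax_pred == 0.0
        assert fit.cmax_pred == pytest.approx(23.0, rel=0.01)

    def test_too_few_points_rejected(self):
        p = profile_from_arrays([0, 1, 2, 4], [0, 8, 6, 3])
        with pytest.raises(ValueError, match="at least"):
            comp.fit_compartment_model(p, variant="oral_first_order")


class TestPredictTmaxCmax:
    def test_oral_prediction_matches_dense_grid_maximum(
        self, noise_free_profile, noise_free_truth
    ):
        fit = comp.fit_compartment_model(noise_free_profile)
        t = np.linspace(1e-4, 6, 60001)
        c = syn.conc_two_compartment_oral(noise_free_truth, t)
        assert fit.tmax_pred == pytest.approx(t[np.argmax(c)], abs=1e-3)
        assert fit.cmax_pred == pytest.approx(c.max(), rel=1e-4)

    def test_instantaneous_absorption_limit_peaks_at_zero(
        self, noise_free_profile
    ):
        fit = comp.fit_compartment_model(noise_free_profile)
        import dataclasses

        fast = dataclasses.replace(fit, ka=1000.0 * fit.alpha)
        tmax, _ = comp.predict_tmax_cmax(fast)
        assert tmax < 0.02

    def test_oral_cmax_bounded_by_dose_over_v1(self, noise_free_profile):
        fit = comp.fit_compartment_model(noise_free_profile)
        dose = fit.cl_f * fit.auc_model
        assert fit.cmax_pred <= dose / fit.v1_f


class TestSelectModel:
    def test_two_compartment_truth_low_noise_ranks_first(self):
        truth = syn.rabbit_cipro_pk_truth(
            between_subject_cv=0.0, residual_cv=0.01
        )
        wins = 0
        for s in range(5):
            prof = syn.simulate_study(
                truth, syn.rabbit_cipro_design(seed=s, n_subjects=1)
            )[0]
            ranked = comp.select_model(prof)
            wins += ranked["variant"].iloc[0] == "oral_first_order"
        assert wins >= 4

    def test_one_compartment_truth_ranks_first(self):
        rng = np.random.default_rng(7)
        t = np.array(syn.DEFAULT_SAMPLE_TIMES_HR)
        wins = 0
        for _ in range(5):
            c = oral_one_compartment(t, 3.5, 38.0, 0.21, 500.0)
            c = np.maximum(c * (1 + rng.normal(0, 0.05, t.size)), 0)
            c[t == 0] = 0.0
            ranked = comp.select_model(profile_from_arrays(t, c))
            wins += ranked["variant"].iloc[0] == "oral_one_compartment"
        assert wins >= 4

    def test_equal_sse_prefers_fewer_parameters(self):
        # the AICc penalty alone must break an SSE tie
        assert comp.aicc(1.0, 10, 3) < comp.aicc(1.0, 10, 5)

    def test_delta_aicc_is_zero_for_winner(self, noise_free_profile):
        ranked = comp.select_model(noise_free_profile)
        assert ranked["delta_aicc"].iloc[0] == 0.0
        assert (ranked["delta_aicc"] >= 0).all()
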
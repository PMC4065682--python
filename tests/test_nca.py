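"""NCA: trapezoid oracles, terminal-slope selection, scale invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkdiss import nca
from pkdiss import synthetic as syn
from conftest import profile_from_arrays


class TestAucTrapezoid:
    def test_rectangle(self):
        p = profile_from_arrays([0, 1], [10, 10])
        assert nca.auc_trapezoid(p) == pytest.approx(10.0)

    def test_triangle(self):
        p = profile_from_arrays([0, 1, 2], [0, 10, 0])
        assert nca.auc_trapezoid(p) == pytest.approx(10.0)

    def test_censored_points_are_excluded(self):
        p = profile_from_arrays(
            [0, 1, 2, 3], [0, 10, 0, 10], censored=[False, False, True, False]
        )
        # the censored (2, 0) vertex is dropped: trapezoid spans 1 -> 3
        assert nca.auc_trapezoid(p) == pytest.approx(5.0 + 20.0)

    def test_single_usable_point_rejected(self):
        p = profile_from_arrays([0, 1], [5, 5], censored=[False, True])
        with pytest.raises(ValueError):
            nca.auc_trapezoid(p)

    def test_linlog_exact_for_pure_exponential_decay(self):
        t = np.array([0.0, 2.0, 5.0, 9.0])
        c = 10.0 * np.exp(-0.3 * t)
        p = profile_from_arrays(t, c)
        exact = (10.0 / 0.3) * (1 - math.exp(-0.3 * 9.0))
        assert nca.auc_trapezoid(p, method="linlog") == pytest.approx(
            exact, rel=1e-12
        )
        assert nca.auc_trapezoid(p, method="linear") > exact


class TestAumcTrapezoid:
    def test_triangle_moment(self):
        p = profile_from_arrays([0, 1, 2], [0, 10, 0])
        assert nca.aumc_trapezoid(p) == pytest.approx(10.0)

    def test_constant_concentration_closed_form(self):
        # integral of c*t over [0, T] = c T^2 / 2
        p = profile_from_arrays([0, 2, 5, 8], [3, 3, 3, 3])
        assert nca.aumc_trapezoid(p) == pytest.approx(3 * 8**2 / 2)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_trapezoids_match_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 24, 9))
    t[0] = 0.0
    c = rng.uniform(0, 12, 9)
    p = profile_from_arrays(t, c)
    auc = sum(
        (t[i + 1] - t[i]) * (c[i] + c[i + 1]) / 2 for i in range(8)
    )
    aumc = sum(
        (t[i + 1] - t[i]) * (t[i] * c[i] + t[i + 1] * c[i + 1]) / 2
        for i in range(8)
    )
    assert nca.auc_trapezoid(p) == pytest.approx(auc, abs=1e-12 * max(1, auc))
    assert nca.aumc_trapezoid(p) == pytest.approx(
        aumc, abs=1e-12 * max(1, aumc)
    )


class TestLambdaZ:
    def test_exact_on_monoexponential_tail(self):
        t = np.array([4.0, 8.0, 12.0, 24.0])
        p = profile_from_arrays(t, 10.0 * np.exp(-0.2 * t))
        res = nca.estimate_lambda_z(p)
        assert res.estimable
        assert res.lambda_z == pytest.approx(0.2, abs=1e-12)
        assert res.half_life == pytest.approx(math.log(2) / 0.2, abs=1e-9)

    def test_window_excludes_cmax_and_picks_terminal_phase(
        self, noise_free_profile, noise_free_truth
    ):
        res = nca.estimate_lambda_z(noise_free_profile)
        assert res.estimable
        assert res.lambda_z == pytest.approx(noise_free_truth.beta, rel=0.05)

    def test_not_estimable_with_too_few_postpeak_points(self):
        p = profile_from_arrays([0, 1, 2, 3], [0, 5, 4, 3])
        res = nca.estimate_lambda_z(p)
        assert not res.estimable and math.isnan(res.lambda_z)

    def test_rising_profile_not_estimable(self):
        p = profile_from_arrays([0, 1, 2, 3, 4, 5], [0, 1, 2, 3, 4, 5])
        assert not nca.estimate_lambda_z(p).estimable


class TestNcaFull:
    def test_published_cell_identities(self):
        """MRT = AUMC/AUC and Cl = Dose/AUCinf reproduce the published
        reference-brand summary cells."""
        assert 140.03 / 45.763 == pytest.approx(3.06, abs=5e-3)
        assert 500.0 / 57.45 == pytest.approx(8.703, abs=5e-4)

    def test_scaling_concentrations_scales_areas_not_times(
        self, noise_free_profile
    ):
        import dataclasses

        base = nca.nca_full(noise_free_profile)
        doubled = dataclasses.replace(
            noise_free_profile,
            concentrations=2.0 * noise_free_profile.concentrations,
        )
        res = nca.nca_full(doubled)
        assert res.auc_last == pytest.approx(2 * base.auc_last, rel=1e-12)
        assert res.aumc_last == pytest.approx(2 * base.aumc_last, rel=1e-12)
        assert res.cmax == pytest.approx(2 * base.cmax, rel=1e-12)
        assert res.cl_f == pytest.approx(base.cl_f / 2, rel=1e-12)
        assert res.vz_f == pytest.approx(base.vz_f / 2, rel=1e-12)
        assert res.mrt_last == pytest.approx(base.mrt_last, rel=1e-12)
        assert res.tmax == base.tmax
        assert res.lambda_z == pytest.approx(base.lambda_z, rel=1e-12)

    def test_leading_zero_sample_does_not_change_auc(self):
        t = np.array([0.5, 1, 2, 4, 8, 12, 24], dtype=float)
        c = 12.0 * np.exp(-0.3 * t)
        plain = profile_from_arrays(t, c)
        anchored = profile_from_arrays(np.concatenate(([0.0], t)),
                                       np.concatenate(([0.0], c)))
        a1 = nca.auc_trapezoid(plain)
        a2 = nca.auc_trapezoid(anchored)
        assert a2 == pytest.approx(a1 + 0.5 * 0.5 * c[0])
        # the added wedge is the 0 -> 0.5 hr triangle, nothing downstream
        r1, r2 = nca.nca_full(plain), nca.nca_full(anchored)
        assert r2.lambda_z == pytest.approx(r1.lambda_z, rel=1e-12)

    def test_auc_inf_exceeds_auc_last_and_css_identity(self, noise_free_profile):
        r = nca.nca_full(noise_free_profile)
        assert r.auc_inf > r.auc_last
        assert r.css_24h == pytest.approx(r.auc_inf / 24.0, abs=1e-9)
        assert r.kel_eq2 == pytest.approx(1.0 / r.mrt_last, rel=1e-12)
        assert r.hl_eq2 == pytest.approx(math.log(2) * r.mrt_last, rel=1e-12)
        assert r.hl_lambda_z == pytest.approx(math.log(2) / r.lambda_z, rel=1e-12)

    def test_earliest_time_wins_cmax_tie(self):
        p = profile_from_arrays([0, 1, 2, 3, 4, 5], [0, 7, 7, 5, 3, 1])
        assert nca.nca_full(p).tmax == 1.0

    def test_dense_sampling_recovers_clearance_within_2pct(
        self, noise_free_truth
    ):
        """Noise-free simulation + NCA recover Cl/F = k10*V1/F to < 2 %
        when sampling is dense and extends past 5 terminal half-lives."""
        hl = math.log(2) / noise_free_truth.beta
        t = np.arange(0.0, 6 * hl, 0.25)
        design = syn.StudyDesign(n_subjects=1, sample_times=t, seed=0)
        prof = syn.simulate_study(noise_free_truth, design)[0]
        res = nca.nca_full(prof)
        assert res.cl_f == pytest.approx(noise_free_truth.cl_f, rel=0.02)

    def test_summary_block_shape(self, noise_free_truth):
        design = syn.rabbit_cipro_design(seed=3, n_subjects=4)
        results = [
            nca.nca_full(p) for p in syn.simulate_study(noise_free_truth, design)
        ]
        df = nca.summarize_nca(results)
        assert {"mean", "sd", "n"} <= set(df.columns)
        assert df.loc["auc_last", "n"] == 4
        assert df.loc["auc_last", "sd"] == pytest.approx(0.0, abs=1e-9)
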
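"""Transition-specific Cox models, profile prediction and bootstrap bands."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from aamsm import coxph, msdata, nonparam, simulate
from aamsm.coxph import (
    ConvergenceError,
    CovariateProfile,
    CoxFit,
    ModelSpec,
    encode_covariates,
    fit_transition_cox,
    predict_profile_hazards,
    predict_profile_probabilities,
)

from conftest import two_state_data


@pytest.fixture(scope="module")
def m1_fixture(small_long):
    return fit_transition_cox(small_long, coxph.preset_m1())


class TestPresets:
    def test_preset_shapes_match_the_three_models(self, small_long):
        m1 = fit_transition_cox(small_long, coxph.preset_m1())
        m2 = fit_transition_cox(small_long, coxph.preset_m2())
        m3 = fit_transition_cox(small_long, coxph.preset_m3())
        assert len(m1.beta) == 5 and len(m2.beta) == 5 and len(m3.beta) == 1
        assert m3.spec.transitions == (12, 13, 14)

    def test_complete_case_drops_missing_pnh(self, small_long, small_cohort):
        m1 = fit_transition_cox(small_long, coxph.preset_m1())
        m3 = fit_transition_cox(small_long, coxph.preset_m3())
        n_total = small_cohort.covariates.shape[0]
        n_missing = small_cohort.covariates["pnh"].isna().sum()
        assert m3.n == n_total                 # M3 uses no PNH covariate
        assert m1.n <= n_total - 1             # missing-PNH patients dropped
        sub = small_long[small_long["trans"] == 1]
        assert m1.n == sub.dropna(subset=["pnh_ge1"])["patient_id"].nunique()
        assert n_missing > 0


class TestBreslowFit:
    def test_null_model_baseline_equals_nelson_aalen(self, small_long, structure):
        fit = fit_transition_cox(small_long, ModelSpec("null", (1,), ()))
        na = {h.trans: h for h in nonparam.nelson_aalen(small_long, structure)}[1]
        assert np.array_equal(fit.baseline_times, na.times)
        assert np.allclose(fit.baseline_dA, na.dA, atol=0, rtol=1e-15)

    def test_matches_lifelines_on_continuous_data(self, small_long):
        from lifelines import CoxTimeVaryingFitter
        cols = list(coxph.preset_m1().covariates)
        sub = small_long[small_long["trans"] == 1].dropna(subset=cols)
        ours = fit_transition_cox(small_long, coxph.preset_m1())
        ctv = CoxTimeVaryingFitter()
        ctv.fit(sub[["patient_id", "Tstart", "Tstop", "status"] + cols],
                id_col="patient_id", start_col="Tstart", stop_col="Tstop",
                event_col="status")
        assert np.allclose(ours.beta, ctv.params_.values, atol=1e-8)
        assert np.allclose(ours.se, ctv.standard_errors_.values, atol=1e-6)

    def test_matches_brute_force_maximizer_on_small_fixture(self):
        # 10 subjects, two covariates; <=20 rows
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 10)
        s = rng.integers(0, 2, 10)
        s[0] = 1
        X = np.column_stack([rng.integers(0, 2, 10), rng.normal(0, 1, 10)])
        data = two_state_data(t, s)
        data["x1"], data["x2"] = X[:, 0], X[:, 1].round(2)
        fit = fit_transition_cox(data, ModelSpec("toy", (1,), ("x1", "x2")))

        Xm = data[["x1", "x2"]].to_numpy(float)
        Ts, Te = data["Tstart"].to_numpy(float), data["Tstop"].to_numpy(float)
        ev = data["status"].to_numpy(int) == 1
        ev_times, counts = np.unique(Te[ev], return_counts=True)

        def negll(b):
            S0, _, _ = coxph._breslow_quantities(b, Ts, Te, Xm, ev_times)
            return -(float((Xm[ev] @ b).sum()) - float(counts @ np.log(S0)))

        res = optimize.minimize(negll, np.zeros(2), method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-12})
        assert np.max(np.abs(fit.beta - res.x)) < 1e-4

    def test_two_group_exponential_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(8)
        n = 2000
        grp = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / np.where(grp == 1, 2.0, 1.0))
        c = rng.uniform(0, 3, n)
        times, status = np.minimum(t, c), (t <= c).astype(int)
        data = two_state_data(times, status)
        data["grp"] = grp.astype(float)
        fit = fit_transition_cox(data, ModelSpec("exp", (1,), ("grp",)))
        assert 1.8 <= float(np.exp(fit.beta[0])) <= 2.2

    def test_hazard_ratio_inverts_under_reference_relabeling(self):
        rng = np.random.default_rng(12)
        n = 300
        grp = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / np.where(grp == 1, 1.7, 1.0))
        data = two_state_data(t, np.ones(n, int))
        data["grp"] = grp.astype(float)
        hr_ab = np.exp(fit_transition_cox(
            data, ModelSpec("a", (1,), ("grp",))).beta[0])
        data["grp"] = 1.0 - data["grp"]
        hr_ba = np.exp(fit_transition_cox(
            data, ModelSpec("b", (1,), ("grp",))).beta[0])
        assert hr_ab == pytest.approx(1 / hr_ba, rel=1e-9)

    def test_no_events_raises(self):
        data = two_state_data([3.0, 5.0], [0, 0])
        data["x"] = [0.0, 1.0]
        with pytest.raises(ConvergenceError, match="no events"):
            fit_transition_cox(data, ModelSpec("m", (1,), ("x",)))

    def test_perfect_separation_raises(self):
        # covariate perfectly orders event times -> monotone likelihood
        n = 30
        t = np.arange(1, n + 1, dtype=float)
        data = two_state_data(t, np.ones(n, int))
        data["x"] = -t
        with pytest.raises(ConvergenceError):
            fit_transition_cox(data, ModelSpec("m", (1,), ("x",)))

    def test_json_round_trip(self, m1_fixture):
        back = CoxFit.from_json(m1_fixture.to_json())
        assert np.allclose(back.beta, m1_fixture.beta)
        assert np.allclose(back.cov, m1_fixture.cov)
        assert np.allclose(back.baseline_dA, m1_fixture.baseline_dA)
        assert back.spec == m1_fixture.spec


class TestEncodingAndProfiles:
    def test_dummy_encoding_reference_levels(self):
        cov = pd.DataFrame({
            "age_cat": ["18-39", "40-59", "60+"],
            "severity": ["NSAA", "SAA", "VSAA"],
            "pnh": ["<1%", ">=1%", None],
        }, index=["a", "b", "c"])
        d = encode_covariates(cov)
        assert d.loc["a"].tolist() == [0, 0, 0, 0, 0]
        assert d.loc["b"].tolist() == [1, 1, 0, 1, 0]
        assert np.isnan(d.loc["c", "pnh_ge1"])
        assert d.loc["c", "age_60plus"] == 1 and d.loc["c", "sev_VSAA"] == 1

    def test_profile_count_and_vectors(self):
        profs = coxph.reference_profiles()
        assert len(profs) == 18
        z = CovariateProfile("60+", "SAA", "<1%").vector(
            ("pnh_ge1", "age_60plus", "sev_SAA"))
        assert z.tolist() == [0.0, 1.0, 1.0]

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            CovariateProfile(age_cat="80+")


class TestProfilePrediction:
    def test_reference_profile_hazards_equal_baselines(
        self, small_long, structure, m1_fixture
    ):
        haz = nonparam.nelson_aalen(small_long, structure)
        ph = predict_profile_hazards([m1_fixture], haz, CovariateProfile(), structure)
        h1 = next(h for h in ph if h.trans == 1)
        assert np.allclose(h1.dA, m1_fixture.baseline_dA)

    def test_profile_hazard_scales_multiplicatively(
        self, small_long, structure, m1_fixture
    ):
        haz = nonparam.nelson_aalen(small_long, structure)
        prof = CovariateProfile("60+", "SAA", "<1%")
        ph = predict_profile_hazards([m1_fixture], haz, prof, structure)
        h1 = next(h for h in ph if h.trans == 1)
        hr = m1_fixture.hazard_ratios()["HR"]
        expected = m1_fixture.baseline_dA * hr["age_60plus"] * hr["sev_SAA"]
        assert np.allclose(h1.dA, expected)
        # unmodelled transitions are shared with the non-parametric estimate
        h2 = next(h for h in ph if h.trans == 2)
        na2 = next(h for h in haz if h.trans == 2)
        assert np.array_equal(h2.dA, na2.dA)

    def test_without_covariate_models_prediction_equals_nonparametric(
        self, small_long, structure
    ):
        haz = nonparam.nelson_aalen(small_long, structure)
        ph = predict_profile_hazards([], haz, CovariateProfile(), structure)
        ptraj = predict_profile_probabilities(ph, structure)
        npar = nonparam.aalen_johansen(haz, structure=structure, compute_var=False)
        assert np.array_equal(ptraj.times, npar.times)
        assert np.allclose(ptraj.probs, npar.probs, atol=1e-12)

    def test_uncovered_transition_is_configuration_error(
        self, small_long, structure, m1_fixture
    ):
        haz = [h for h in nonparam.nelson_aalen(small_long, structure)
               if h.trans not in (2,)]
        with pytest.raises(ValueError, match="not covered"):
            predict_profile_hazards([m1_fixture], haz, CovariateProfile(), structure)

    def test_profile_rows_remain_stochastic(self, small_long, structure, m1_fixture):
        haz = nonparam.nelson_aalen(small_long, structure)
        for prof in coxph.reference_profiles():
            ph = predict_profile_hazards([m1_fixture], haz, prof, structure)
            traj = predict_profile_probabilities(ph, structure)
            assert np.max(np.abs(traj.probs.sum(axis=1) - 1)) < 1e-10

    def test_profile_recovery_against_matrix_exponential_truth(self):
        """Profile-specific occupation at 5 years tracks the generator's
        exact Markov solution on a large ungated cohort."""
        y = 365.25
        cfg = simulate.SimulatorConfig(
            n_patients=20000, n_eltrombopag=0,
            accrual_window_days=0.0, admin_cutoff_day=6 * y, gates={},
        )
        co = simulate.simulate_paths(cfg, seed=21, apply_gates=False)
        structure = msdata.default_structure()
        data = msdata.expand_long_format(
            co.paths, structure, encode_covariates(co.covariates))
        haz = nonparam.nelson_aalen(data, structure)
        fits = [fit_transition_cox(data, s) for s in coxph.default_model_specs()]
        prof = CovariateProfile("60+", "SAA", "<1%")
        ph = predict_profile_hazards(fits, haz, prof, structure)
        traj = predict_profile_probabilities(ph, structure)
        truth = simulate.true_occupation_probabilities(cfg, prof, [5 * y])[0]
        est = traj.at(5 * y)
        i3 = structure.state_ids.index(3)
        assert abs(est[i3] - truth[i3]) < 0.03
        assert np.max(np.abs(est - truth)) < 0.05


class TestBootstrap:
    def test_fixed_seed_reproducible(self, small_long):
        kw = dict(model_specs=coxph.default_model_specs(),
                  profile=CovariateProfile(), horizon=3 * 365.25, B=2, seed=5)
        b1 = coxph.bootstrap_profile_ci(small_long, **kw)
        b2 = coxph.bootstrap_profile_ci(small_long, **kw)
        assert np.array_equal(b1["samples"], b2["samples"])

    def test_degenerate_data_bands_collapse(self, two_state_structure):
        data = two_state_data([5.0, 6.0, 7.0, 8.0], [0, 0, 0, 0])
        b = coxph.bootstrap_profile_ci(
            data, [], CovariateProfile(), horizon=4.0, B=5, seed=1,
            structure=two_state_structure)
        assert np.allclose(b["lower"], b["point"])
        assert np.allclose(b["upper"], b["point"])
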
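"""Tests of the two-compartment PK engine against independent closed forms."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import bleedrisk as br
from bleedrisk.errors import (
    CalibrationError,
    InvalidParameterError,
)
from bleedrisk.poppk import (
    PKParameters,
    PopPKModel,
    ResidualError,
    _propagate_paths,
    clearance_at,
    compute_cavg_sd,
    compute_ctrough,
    individual_params,
    map_estimate,
    simulate_population,
    solve_concentration,
    vpc_summary,
)
from bleedrisk.regimens import DoseRegimen, q2w, q3w

from _oracles import (
    multi_dose_two_compartment,
    one_compartment_infusion_trough,
)


# ---------------------------------------------------------------------------
# solve_concentration
# ---------------------------------------------------------------------------

class TestSolveConcentration:
    def test_zero_dose_gives_zero_concentrations(self, constant_cl_params):
        regimen = DoseRegimen(0.0, 336.0)
        profile = solve_concentration(constant_cl_params, regimen, np.linspace(0, 336, 20))
        assert np.all(profile.concentrations == 0.0)

    @pytest.mark.parametrize("n_doses,tau", [(1, 336.0), (3, 336.0), (2, 504.0)])
    def test_ode_matches_closed_form_at_constant_cl(self, constant_cl_params, n_doses, tau):
        """ODE path vs independent bi-exponential superposition, <= 1e-6 relative."""
        p = constant_cl_params
        regimen = DoseRegimen(1200.0, tau, 1.0, n_doses)
        times = np.linspace(0.5, n_doses * tau, 97)
        profile = solve_concentration(p, regimen, times)
        oracle = multi_dose_two_compartment(
            p.cl_base, p.v1, p.v2, p.q, 1200.0, 1.0, tau, n_doses, times
        )
        assert np.max(np.abs(profile.concentrations - oracle) / oracle) < 1e-6

    def test_ode_matches_closed_form_on_42_day_grid(self, constant_cl_params):
        p = constant_cl_params
        regimen = DoseRegimen(1200.0, 336.0, 1.0, 3)
        times = np.linspace(2.0, 1008.0, 504)  # 42 days
        profile = solve_concentration(p, regimen, times)
        oracle = multi_dose_two_compartment(
            p.cl_base, p.v1, p.v2, p.q, 1200.0, 1.0, 336.0, 3, times
        )
        assert np.max(np.abs(profile.concentrations - oracle) / oracle) < 1e-6

    @pytest.mark.parametrize("factor", [2.0, 0.5, 10.0])
    def test_linearity_in_dose(self, typical_params, factor):
        """Scaling the dose scales every concentration exactly (1e-9 relative)."""
        times = np.linspace(1.0, 336.0, 30)
        base = solve_concentration(typical_params, q2w(1200.0), times)
        scaled = solve_concentration(typical_params, q2w(1200.0 * factor), times)
        ratio = scaled.concentrations / base.concentrations
        assert np.allclose(ratio, factor, rtol=1e-9)

    def test_propagator_matches_ode_with_time_varying_cl(self, typical_params):
        """The vectorized propagator and the ODE path agree to <= 1e-6."""
        regimen = DoseRegimen(1200.0, 504.0, 1.0, 4)
        times = np.linspace(4.0, 2016.0, 61)
        profile = solve_concentration(typical_params, regimen, times)
        arrays = {k: np.array([v]) for k, v in typical_params.as_dict().items()}
        conc, _ = _propagate_paths(arrays, regimen, times, max_step=6.0)
        rel = np.abs(conc[0] - profile.concentrations) / profile.concentrations
        assert np.max(rel) < 1e-6

    def test_mass_balance_constant_cl(self, constant_cl_params):
        """All drug is eventually eliminated: AUC(0, inf) -> dose / CL."""
        p = constant_cl_params
        regimen = DoseRegimen(1200.0, 30000.0, 1.0, 1)
        _, auc = solve_concentration(p, regimen, [30000.0], return_auc=True)
        assert auc[-1] * p.cl_base == pytest.approx(1200.0, rel=1e-6)

    def test_times_outside_horizon_rejected(self, typical_params):
        with pytest.raises(InvalidParameterError):
            solve_concentration(typical_params, q2w(1200.0), [0.0, 400.0])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            PKParameters(cl_base=float("nan"), v1=3.0, v2=1.0, q=0.03)
        with pytest.raises(InvalidParameterError):
            PKParameters(cl_base=-0.01, v1=3.0, v2=1.0, q=0.03)


from hypothesis import given, settings
from hypothesis import strategies as st


@given(
    dose=st.floats(10.0, 5000.0),
    cl=st.floats(0.005, 0.05),
    v1=st.floats(1.5, 6.0),
)
@settings(max_examples=15, deadline=None, derandomize=True)
def test_linearity_property_over_random_parameters(dose, cl, v1):
    """Dose-proportionality holds for arbitrary parameters and doses."""
    p = PKParameters(cl_base=cl, v1=v1, v2=1.0, q=0.03, cl_emax=-0.15)
    arrays = {k: np.array([v]) for k, v in p.as_dict().items()}
    times = [24.0, 168.0, 336.0]
    base, base_auc = _propagate_paths(arrays, DoseRegimen(dose, 336.0), times)
    double, double_auc = _propagate_paths(arrays, DoseRegimen(2 * dose, 336.0), times)
    assert np.allclose(double, 2.0 * base, rtol=1e-9)
    assert np.allclose(double_auc, 2.0 * base_auc, rtol=1e-9)


def test_superposition_at_constant_cl(constant_cl_params):
    """Multi-dose profile equals the sum of shifted single-dose profiles."""
    p = constant_cl_params
    times = np.linspace(1.5, 1008.0, 101)
    multi = solve_concentration(p, DoseRegimen(1200.0, 336.0, 1.0, 3), times)
    summed = np.zeros_like(times)
    washout = DoseRegimen(1200.0, 1009.0, 1.0, 1)  # one dose, long window
    for k in range(3):
        shifted = times - k * 336.0
        mask = shifted > 0
        single = solve_concentration(p, washout, shifted[mask])
        summed[mask] += single.concentrations
    assert np.max(np.abs(multi.concentrations - summed) / summed) < 1e-6


def test_clearance_time_function(typical_params):
    cl0 = clearance_at(typical_params, 0.0)
    assert cl0 == pytest.approx(typical_params.cl_base)
    half = clearance_at(typical_params, typical_params.cl_t50)
    expected = typical_params.cl_base * np.exp(typical_params.cl_emax / 2.0)
    assert half == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# exposure metrics
# ---------------------------------------------------------------------------

class TestExposureMetrics:
    def test_cavg_zero_dose(self, typical_params):
        assert compute_cavg_sd(typical_params, DoseRegimen(0.0, 336.0)) == 0.0

    def test_cavg_linearity(self, typical_params):
        c1200 = compute_cavg_sd(typical_params, q2w(1200.0))
        c600 = compute_cavg_sd(typical_params, q2w(600.0))
        assert c600 == pytest.approx(c1200 / 2.0, rel=1e-9)

    def test_cavg_agrees_with_grid_refined_trapezoid(self, typical_params):
        """Quadrature result is stable: a 10x finer trapezoid moves it < 0.1%."""
        regimen = q2w(1200.0)
        quad = compute_cavg_sd(typical_params, regimen)
        for step in (0.5, 0.05):
            grid = np.arange(0.0, 336.0 + step / 2, step)
            prof = solve_concentration(typical_params, regimen, grid, rtol=1e-8)
            trap = np.trapezoid(prof.concentrations, grid) / 336.0
            assert trap == pytest.approx(quad, rel=1e-3)

    def test_q2w_exceeds_q3w_at_equal_dose(self, typical_params):
        assert compute_cavg_sd(typical_params, q2w(1200.0)) > compute_cavg_sd(
            typical_params, q3w(1200.0)
        )

    def test_cavg_at_least_trough_for_peaked_profile(self, typical_params):
        cavg = compute_cavg_sd(typical_params, q3w(1200.0))
        trough = compute_ctrough(typical_params, q3w(1200.0))
        assert cavg >= trough

    def test_ctrough_zero_dose(self, typical_params):
        assert compute_ctrough(typical_params, DoseRegimen(0.0, 336.0)) == 0.0
        assert compute_ctrough(typical_params, DoseRegimen(0.0, 336.0), "steady_state") == 0.0

    def test_ss_exceeds_sd_at_constant_cl(self, constant_cl_params):
        sd = compute_ctrough(constant_cl_params, q2w(1200.0), "single_dose")
        ss = compute_ctrough(constant_cl_params, q2w(1200.0), "steady_state")
        assert ss > sd

    def test_one_compartment_degenerate_trough_matches_analytic(self):
        """With q ~ 0 the model degenerates to one compartment."""
        p = PKParameters(cl_base=0.016, v1=3.0, v2=1.0, q=1e-9, cl_emax=0.0)
        got = compute_ctrough(p, q2w(1200.0), "single_dose")
        expected = one_compartment_infusion_trough(0.016, 3.0, 1200.0, 1.0, 336.0)
        assert got == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("cl_emax", [0.0, -0.15])
    def test_monotone_trough_accumulation(self, cl_emax):
        """For constant or decreasing CL(t), troughs never decrease dose to dose."""
        p = PKParameters(cl_base=0.016, v1=2.4, v2=1.0, q=0.03, cl_emax=cl_emax)
        regimen = DoseRegimen(1200.0, 336.0, 1.0, 10)
        troughs = solve_concentration(
            p, regimen, [336.0 * k for k in range(1, 11)]
        ).concentrations
        assert np.all(np.diff(troughs) >= -1e-9 * troughs[:-1])

    def test_steady_state_invariant_to_dose_cap(self, typical_params):
        ss20 = compute_ctrough(typical_params, q3w(1200.0), "steady_state", dose_cap=20)
        ss30 = compute_ctrough(typical_params, q3w(1200.0), "steady_state", dose_cap=30)
        assert abs(ss30 - ss20) / ss20 < 0.005

    def test_unknown_trough_kind_rejected(self, typical_params):
        with pytest.raises(InvalidParameterError):
            compute_ctrough(typical_params, q2w(1200.0), "average")


# ---------------------------------------------------------------------------
# covariate model
# ---------------------------------------------------------------------------

class TestIndividualParams:
    def test_reference_covariates_and_zero_eta_return_typical(
        self, pk_model, reference_covariates
    ):
        params = individual_params(pk_model, reference_covariates,
                                   {name: 0.0 for name in pk_model.eta_names})
        for name, value in pk_model.typical.as_dict().items():
            assert getattr(params, name) == pytest.approx(value, rel=1e-12)

    def test_allometric_weight_doubling(self, pk_model, reference_covariates):
        cov = dict(reference_covariates, body_weight=150.0)
        params = individual_params(pk_model, cov)
        assert params.cl_base / pk_model.typical.cl_base == pytest.approx(
            2.0**0.75, rel=1e-12
        )

    def test_proportional_shift_of_negative_fifth(self, constant_cl_params):
        model = PopPKModel(
            typical=constant_cl_params,
            covariate_effects=(br.CovariateEffect("v1", "flag", "proportional", -0.2),),
        )
        assert individual_params(model, {"flag": 1}).v1 == pytest.approx(
            0.8 * constant_cl_params.v1
        )
        assert individual_params(model, {"flag": 0}).v1 == pytest.approx(
            constant_cl_params.v1
        )

    def test_missing_covariate_is_named(self, pk_model):
        with pytest.raises(InvalidParameterError, match="body_weight"):
            individual_params(pk_model, {"albumin": 40.0})

    def test_eta_applied_multiplicatively(self, pk_model, reference_covariates):
        params = individual_params(pk_model, reference_covariates, {"cl_base": 0.3})
        assert params.cl_base / pk_model.typical.cl_base == pytest.approx(
            np.exp(0.3), rel=1e-12
        )


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

class TestSimulatePopulation:
    def test_zero_variance_gives_identical_patients(self, typical_params, reference_frame):
        model = PopPKModel(typical=typical_params, bsv={})
        sim = simulate_population(model, reference_frame(5), q2w(1200.0), seed=1)
        for col in sim.columns:
            assert sim[col].nunique() == 1

    def test_same_seed_reproduces_exactly(self, pk_model, reference_frame):
        a = simulate_population(pk_model, reference_frame(50), q3w(1200.0), seed=42)
        b = simulate_population(pk_model, reference_frame(50), q3w(1200.0), seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_lognormal_bsv_propagates_to_cavg_geometric_sd(self):
        """Fast-eliminating one-compartment limit: AUC ~ dose/CL, so the
        geometric SD of Cavg,SD approaches exp(omega_CL)."""
        omega = 0.30
        p = PKParameters(cl_base=0.25, v1=3.0, v2=0.5, q=1e-6, cl_emax=0.0)
        model = PopPKModel(typical=p, bsv={"cl_base": omega**2})
        sim = simulate_population(
            model, pd.DataFrame(index=pd.RangeIndex(2000)), q2w(1200.0),
            seed=7, metrics=("cavg_sd",),
        )
        gsd = np.exp(np.std(np.log(sim["cavg_sd"]), ddof=1))
        assert abs(np.log(gsd) - omega) / omega < 0.05

    def test_empty_population_rejected(self, pk_model):
        with pytest.raises(InvalidParameterError):
            simulate_population(pk_model, pd.DataFrame(), q2w(1200.0), seed=1)

    def test_mixed_regimens_align_with_patients(self, typical_params):
        model = PopPKModel(typical=typical_params, bsv={})
        patients = pd.DataFrame(index=pd.RangeIndex(4))
        regimens = [q2w(1200.0), q2w(600.0), q3w(1200.0), q3w(2400.0)]
        sim = simulate_population(model, patients, regimens, seed=0, metrics=("cavg_sd",))
        assert sim.loc[0, "cavg_sd"] == pytest.approx(2 * sim.loc[1, "cavg_sd"], rel=1e-9)
        assert sim.loc[3, "cavg_sd"] == pytest.approx(2 * sim.loc[2, "cavg_sd"], rel=1e-9)


# ---------------------------------------------------------------------------
# MAP empirical Bayes
# ---------------------------------------------------------------------------

class TestMapEstimate:
    def test_noiseless_truth_at_prior_mode(self, pk_model, reference_covariates,
                                           reference_frame):
        noiseless = PopPKModel(pk_model.typical, pk_model.covariate_effects, {},
                               pk_model.residual)
        cohort = reference_frame(1).assign(patient_id=[1], dose_mg=[1200.0],
                                           tau_h=[336.0])
        obs, _ = br.simulate_pk_observations(
            cohort, noiseless, [2.0, 24.0, 72.0, 168.0, 336.0], seed=3, residual=False
        )
        result = map_estimate(pk_model, obs[["time_h", "conc_ug_per_ml"]],
                              reference_covariates, q2w(1200.0))
        assert all(abs(v) < 1e-3 for v in result.eta.values())

    def test_zero_observations_rejected(self, pk_model, reference_covariates):
        empty = pd.DataFrame(columns=["time_h", "conc_ug_per_ml"])
        with pytest.raises(InvalidParameterError):
            map_estimate(pk_model, empty, reference_covariates, q2w(1200.0))

    def test_recovery_correlation_with_rich_sampling(self, pk_model,
                                                     reference_covariates,
                                                     reference_frame):
        """200 simulated patients, 12 samples each, omega_CL = 0.3, 10%
        proportional error: MAP etas track the truth (r > 0.9)."""
        model = PopPKModel(pk_model.typical, pk_model.covariate_effects,
                           {"cl_base": 0.09, "v1": 0.0625}, ResidualError(0.10, 0.5))
        n = 200
        cohort = reference_frame(n).assign(
            patient_id=np.arange(1, n + 1), dose_mg=1200.0, tau_h=336.0
        )
        schedule = np.linspace(2.0, 336.0, 12)
        obs, etas = br.simulate_pk_observations(cohort, model, schedule, seed=11)
        hats = [
            map_estimate(model, group[["time_h", "conc_ug_per_ml"]],
                         reference_covariates, q2w(1200.0)).eta["cl_base"]
            for _, group in obs.groupby("patient_id")
        ]
        r = np.corrcoef(etas["cl_base"], hats)[0, 1]
        assert r > 0.9


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

class TestCalibration:
    def test_single_target_reproduced(self, typical_params):
        start = typical_params.replace(cl_base=0.020)
        cal = br.calibrate_typical_params(start, [(q2w(1200.0), 178.0)], ["cl_base"])
        assert compute_cavg_sd(cal, q2w(1200.0)) == pytest.approx(178.0, rel=0.005)

    def test_fixed_point_leaves_parameters_unchanged(self, typical_params):
        value = compute_cavg_sd(typical_params, q2w(1200.0))
        cal = br.calibrate_typical_params(typical_params, [(q2w(1200.0), value)],
                                          ["cl_base"])
        assert cal.cl_base == pytest.approx(typical_params.cl_base, rel=1e-6)

    def test_two_targets_two_free_parameters(self):
        start = PKParameters(cl_base=0.018, v1=3.5, v2=1.0, q=0.03, cl_emax=-0.15)
        cal = br.calibrate_typical_params(
            start, [(q2w(1200.0), 178.0), (q3w(1200.0), 136.0)], ["cl_base", "v1"]
        )
        assert compute_cavg_sd(cal, q2w(1200.0)) == pytest.approx(178.0, rel=0.005)
        assert compute_cavg_sd(cal, q3w(1200.0)) == pytest.approx(136.0, rel=0.005)

    def test_unattainable_target_raises(self, typical_params):
        # a Q3W/Q2W Cavg ratio of ~1 is impossible for a decaying profile
        with pytest.raises(CalibrationError):
            br.calibrate_typical_params(
                typical_params,
                [(q2w(1200.0), 178.0), (q3w(1200.0), 178.0)],
                ["cl_base", "q"],
            )

    def test_more_targets_than_parameters_rejected(self, typical_params):
        with pytest.raises(InvalidParameterError):
            br.calibrate_typical_params(
                typical_params,
                [(q2w(1200.0), 178.0), (q3w(1200.0), 136.0)],
                ["cl_base"],
            )


# ---------------------------------------------------------------------------
# VPC
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def vpc_setup(pk_model, reference_frame):
    model = PopPKModel(pk_model.typical, pk_model.covariate_effects,
                       pk_model.bsv, ResidualError(0.15, 0.5))
    cohort = reference_frame(120).assign(
        patient_id=np.arange(1, 121), dose_mg=1200.0, tau_h=336.0
    )
    schedule = [2.0, 24.0, 48.0, 96.0, 168.0, 240.0, 336.0]
    return model, cohort, schedule


class TestVpc:
    def test_replicate_floor_enforced(self, vpc_setup):
        model, cohort, schedule = vpc_setup
        obs, _ = br.simulate_pk_observations(cohort, model, schedule, seed=1)
        with pytest.raises(InvalidParameterError):
            vpc_summary(model, obs, cohort, q2w(1200.0), n_replicates=50)

    def test_self_consistency_median_coverage(self, vpc_setup):
        """Data simulated from the model: the observed median lies inside the
        simulated median envelope in >= 90% of bins over repeated runs."""
        model, cohort, schedule = vpc_setup
        inside = []
        for seed in range(6):
            obs, _ = br.simulate_pk_observations(cohort, model, schedule, seed=100 + seed)
            table = vpc_summary(model, obs, cohort, q2w(1200.0),
                                n_replicates=150, seed=200 + seed, n_bins=7)
            inside.append(np.mean(
                (table["obs_p50"] >= table["sim_p50_lo"])
                & (table["obs_p50"] <= table["sim_p50_hi"])
            ))
        assert np.mean(inside) >= 0.90

    def test_zero_variance_envelopes_collapse(self, typical_params, vpc_setup):
        _, cohort, schedule = vpc_setup
        deterministic = PopPKModel(typical=typical_params, bsv={},
                                   residual=ResidualError(0.0, 0.0))
        obs, _ = br.simulate_pk_observations(cohort, deterministic, schedule,
                                             seed=1, residual=False)
        table = vpc_summary(deterministic, obs, cohort, q2w(1200.0),
                            n_replicates=100, seed=2, n_bins=7)
        assert np.allclose(table["sim_p50_lo"], table["obs_p50"], rtol=1e-9)
        assert np.allclose(table["sim_p50_hi"], table["obs_p50"], rtol=1e-9)
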
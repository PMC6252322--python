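import math
from dataclasses import replace

import numpy as np
import pytest

from conftest import gauss_hermite_neg2ll
from remipkpd.kinetics import IndividualPKParameters, PopulationPKParameters, solve_profile
from remipkpd.nlme import (
    CovariateTestResult,
    FitResult,
    SubjectData,
    _laplace_subject,
    _PKAdapter,
    _ProfileEngine,
    _subject_m2_joint,
    covariate_lrt,
    evaluate_population,
    fit_population,
    marginal_loglik_categorical,
    marginal_loglik_continuous,
    prepare_subjects,
    profile_ci,
    two_stage_pd_fit,
)
from remipkpd.pd_bis import BISModelParameters
from remipkpd.pd_moaas import MOAASModelParameters
from remipkpd.published import published_bis, published_moaas, published_pk
from remipkpd.synthdata import StudyDesign, generate_trial
from remipkpd.trial_data import (
    DoseEvent,
    Regimen,
    SubjectCovariates,
    ValidationError,
)

_LOG_2PI = math.log(2.0 * math.pi)


def _conc_subject(pop, eta, noise_sd, rng_seed, times=(2.0, 10.0, 60.0)):
    cov = SubjectCovariates(1, 63.8, 170.0, 27, "male")
    reg = Regimen((DoseEvent(0.0, 20.0, 1.0),))
    times = np.asarray(times, dtype=float)
    ind = IndividualPKParameters.from_population(pop, eta)
    cp = solve_profile(ind, reg, times).cp
    rng = np.random.default_rng(rng_seed)
    y = cp * (1.0 + rng.normal(0.0, noise_sd, len(times)))
    return SubjectData(1, cov, reg, times, y)


class TestLaplaceEngine:
    def test_exact_for_gaussian_linear_model(self):
        """Laplace is exact when the joint density is Gaussian in eta."""
        y = np.array([1.3, 0.7, 1.1])
        theta, omega, sigma = 1.0, 0.5, 0.3
        n = len(y)

        def m2_joint(etas):
            etas = np.atleast_2d(etas)
            e = etas[:, 0]
            nll = np.sum(
                _LOG_2PI
                + np.log(sigma**2)
                + (y[None, :] - theta - e[:, None]) ** 2 / sigma**2,
                axis=1,
            )
            prior = e**2 / omega**2 + np.log(2 * np.pi * omega**2)
            return nll + prior

        val, eta_hat, flagged = _laplace_subject(m2_joint, 1, np.zeros(1))
        # closed-form marginal: y ~ N(theta * 1, sigma^2 I + omega^2 J)
        cov = sigma**2 * np.eye(n) + omega**2 * np.ones((n, n))
        resid = y - theta
        expected = (
            n * _LOG_2PI
            + np.linalg.slogdet(cov)[1]
            + resid @ np.linalg.solve(cov, resid)
        )
        assert val == pytest.approx(expected, abs=1e-5)
        assert not flagged

    @pytest.mark.parametrize("omega_cl", [0.1, 0.2, 0.4, 0.6])
    def test_continuous_matches_quadrature(self, omega_cl):
        pop = PopulationPKParameters(
            v1=2.11, cl=1.49, v2=10.5, q2=0.96, v3=22.7, q3=0.27,
            omega={"cl": omega_cl}, sigma_prop=0.15,
        )
        subj = _conc_subject(pop, {"cl": omega_cl}, 0.15, rng_seed=4)
        lap = marginal_loglik_continuous(subj, pop, "pk")
        adapter = _PKAdapter(None)
        fixed, omega, sigma = adapter.default_init(pop)
        engine = _ProfileEngine(subj.regimen, subj.times)
        m2 = _subject_m2_joint(
            adapter, (subj, engine), fixed, ["cl"], np.array([omega_cl]), sigma
        )
        quad = gauss_hermite_neg2ll(m2)
        assert abs(lap - quad) < 0.1

    def test_categorical_matches_quadrature(self, moaas_pop):
        pop = MOAASModelParameters(
            baselines=moaas_pop.baselines,
            ke0=0.05, ic50=436.0, gamma=1.5, imax=27.9,
            omega={"ic50": 0.4},
        )
        cov = SubjectCovariates(1, 63.8, 170.0, 27, "male")
        reg = Regimen((DoseEvent(0.0, 20.0, 1.0),))
        times = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 60.0])
        subj = SubjectData(
            1, cov, reg, times, np.array([1.0, 0.0, 0.0, 1.0, 3.0, 5.0]),
            pk_individual=IndividualPKParameters.from_population(published_pk()),
        )
        lap = marginal_loglik_categorical(subj, pop)
        from remipkpd.nlme import _MOAASAdapter

        adapter = _MOAASAdapter()
        fixed, omega, _ = adapter.default_init(pop)
        engine = _ProfileEngine(reg, times)
        m2 = _subject_m2_joint(
            adapter, (subj, engine), fixed, ["ic50"], np.array([0.4]), None
        )
        quad = gauss_hermite_neg2ll(m2)
        assert abs(lap - quad) < 0.1

    def test_zero_omega_reduces_to_fixed_effect_likelihood(self):
        pop = PopulationPKParameters(
            v1=2.11, cl=1.49, v2=10.5, q2=0.96, v3=22.7, q3=0.27,
            sigma_prop=0.15,
        )
        subj = _conc_subject(pop, {}, 0.15, rng_seed=2)
        val = marginal_loglik_continuous(subj, pop, "pk")
        cp = solve_profile(
            IndividualPKParameters.from_population(pop), subj.regimen, subj.times
        ).cp
        var = (0.15 * cp) ** 2
        expected = np.sum(_LOG_2PI + np.log(var) + (subj.y - cp) ** 2 / var)
        assert val == pytest.approx(expected, rel=1e-9)

    def test_zero_omega_categorical_is_sum_of_log_probs(self, moaas_pop):
        pop = MOAASModelParameters(
            baselines=moaas_pop.baselines, ke0=0.05, ic50=436.0, gamma=1.5, imax=27.9
        )
        cov = SubjectCovariates(1, 63.8, 170.0, 27, "male")
        reg = Regimen(())  # no drug: all probabilities at baseline
        times = np.array([0.0, 5.0, 10.0])
        subj = SubjectData(
            1, cov, reg, times, np.array([5.0, 5.0, 5.0]),
            pk_individual=IndividualPKParameters.from_population(published_pk()),
        )
        val = marginal_loglik_categorical(subj, pop)
        # P(score = 5) at zero drug is 1 - logistic(B5)
        p5 = 1.0 - 1.0 / (1.0 + np.exp(0.895))
        assert val == pytest.approx(-2.0 * 3 * np.log(p5), rel=1e-9)


@pytest.fixture(scope="module")
def noiseless_table():
    pk = PopulationPKParameters(
        v1=2.11, cl=1.49, v2=10.5, q2=0.96, v3=22.7, q3=0.27, sigma_prop=1e-4
    )
    bis = BISModelParameters(
        ke0=0.0855, ic50=503.0, gamma=1.5, e0=95.3, imax=47.9, sigma_resid=1e-4
    )
    moaas = published_moaas()
    design = StudyDesign(cohorts=((0.1, 2), (0.2, 2), (0.35, 2)))
    return generate_trial(design, pk, bis, moaas, rng_seed=11), pk, bis


class TestFitPopulation:
    def test_noiseless_identifiability(self, noiseless_table):
        """With vanishing variability the fixed effects are recovered
        essentially exactly from a perturbed start."""
        tab, pk, _ = noiseless_table
        init = replace(pk, v1=pk.v1 * 1.6, cl=pk.cl * 0.6, v2=pk.v2 * 1.5,
                       q2=pk.q2 * 0.7, v3=pk.v3 * 1.4, q3=pk.q3 * 0.8)
        fit = fit_population(
            tab, "pk", init=init, fix=("sigma",), maxiter=600,
            optimizer_options={"eps": 1e-6, "ftol": 1e-13, "gtol": 1e-8},
        )
        for n in ("v1", "cl", "v2", "q2", "v3", "q3"):
            assert fit.estimates[n] == pytest.approx(
                getattr(pk, n), rel=1e-3
            ), n

    def test_fix_mask_keeps_parameter(self, noiseless_table):
        tab, pk, _ = noiseless_table
        init = replace(pk, cl=1.1)
        fit = fit_population(tab, "pk", init=init, fix=("cl", "sigma"), maxiter=15)
        assert fit.estimates["cl"] == 1.1

    def test_ofv_trajectory_monotone(self, noiseless_table):
        tab, pk, _ = noiseless_table
        fit = fit_population(
            tab, "pk", init=replace(pk, cl=1.2), fix=("sigma",), maxiter=15
        )
        assert all(b <= a for a, b in zip(fit.ofv_trajectory, fit.ofv_trajectory[1:]))

    def test_aic_definition(self, noiseless_table):
        tab, pk, _ = noiseless_table
        fit = fit_population(tab, "pk", init=pk, fix=("sigma",), maxiter=3)
        assert fit.aic == pytest.approx(fit.ofv + 2 * fit.n_parameters)
        assert fit.n_parameters == 6

    def test_three_compartment_beats_two_on_aic(self, noiseless_table):
        """The generating three-compartment model should win the AIC
        comparison against a nested quasi-two-compartment fit."""
        tab, pk, _ = noiseless_table
        fit3 = fit_population(tab, "pk", init=pk, fix=("sigma",), maxiter=60)
        init2 = replace(pk, q3=1e-6)
        fit2 = fit_population(
            tab, "pk", init=init2, fix=("sigma", "q3", "v3"), maxiter=60
        )
        assert fit3.aic < fit2.aic


@pytest.fixture(scope="module")
def small_trial():
    pk, bis, moaas = published_pk(), published_bis(), published_moaas()
    design = StudyDesign(cohorts=((0.2, 2), (0.35, 2)))
    tab = generate_trial(design, pk, bis, moaas, rng_seed=21)
    pk_eval = evaluate_population(tab, "pk", pk)
    return tab, pk_eval


class TestTwoStage:
    def test_requires_pd_observations(self, small_trial):
        tab, pk_eval = small_trial
        from remipkpd.trial_data import ObservationTable

        conc_only = ObservationTable(
            tab.covariates, tab.doses, [o for o in tab.observations if o.dvid == 1]
        )
        with pytest.raises(ValidationError):
            two_stage_pd_fit(conc_only, pk_eval, "bis", init=published_bis(), maxiter=2)

    def test_missing_subject_named(self, small_trial):
        tab, pk_eval = small_trial
        pk_eval.ebes.pop(1)
        try:
            with pytest.raises(ValidationError, match="1"):
                two_stage_pd_fit(tab, pk_eval, "bis", init=published_bis(), maxiter=2)
        finally:
            pk_eval.ebes[1] = {}

    def test_deterministic_given_same_inputs(self, small_trial):
        tab, pk_eval = small_trial
        kw = dict(
            init=published_bis(),
            fix=("ke0", "ic50", "gamma", "imax", "sigma",
                 "omega_ke0", "omega_ic50", "omega_gamma", "omega_imax"),
            maxiter=5,
        )
        a = two_stage_pd_fit(tab, pk_eval, "bis", **kw)
        b = two_stage_pd_fit(tab, pk_eval, "bis", **kw)
        assert a.ofv == b.ofv
        assert a.estimates == b.estimates


class TestCovariateLRT:
    @pytest.mark.parametrize(
        "delta, level",
        [(3.83, None), (3.84, 0.05), (6.63, 0.01), (10.83, 0.001), (20.0, 0.001)],
    )
    def test_df1_thresholds(self, delta, level):
        res = covariate_lrt(100.0, 100.0 - delta, df=1)
        assert res.significance_level == level
        assert res.delta_ofv == pytest.approx(delta)

    def test_negative_delta_warns_not_significant(self):
        with pytest.warns(UserWarning):
            res = covariate_lrt(100.0, 101.0, df=1)
        assert res.significance_level is None

    def test_df2_uses_chi2_quantiles(self):
        from scipy.stats import chi2

        delta = chi2.ppf(0.99, 2) + 0.01
        res = covariate_lrt(50.0, 50.0 - delta, df=2)
        assert res.significance_level == 0.01


class TestProfileCI:
    @staticmethod
    def _quadratic_fit(est=1.0, se=0.2, ofv0=100.0):
        def refit(param, value):
            return ofv0 + ((value - est) / se) ** 2

        return FitResult(
            model="pk",
            estimates={"cl": est},
            ofv=ofv0,
            n_parameters=1,
            ebes={},
            convergence="converged",
            n_iter=1,
            se={"cl": se},
            _refit=refit,
        )

    def test_quadratic_interval_is_wald(self):
        fit = self._quadratic_fit()
        ci = profile_ci(fit, "cl")
        assert ci.lower == pytest.approx(1.0 - 1.959964 * 0.2, rel=1e-3)
        assert ci.upper == pytest.approx(1.0 + 1.959964 * 0.2, rel=1e-3)
        assert not (ci.open_lower or ci.open_upper)

    def test_binomial_profile_matches_grid_oracle(self):
        n, k = 20, 7
        phat = k / n

        def neg2ll(p):
            return -2.0 * (k * math.log(p) + (n - k) * math.log(1.0 - p))

        def refit(param, value):
            if not 0 < value < 1:
                return float("inf")
            return neg2ll(value)

        fit = FitResult(
            model="pk",
            estimates={"p": phat},
            ofv=neg2ll(phat),
            n_parameters=1,
            ebes={},
            convergence="converged",
            n_iter=1,
            se={"p": math.sqrt(phat * (1 - phat) / n)},
            _refit=refit,
        )
        ci = profile_ci(fit, "p")
        # brute-force grid oracle
        grid = np.linspace(1e-4, 1 - 1e-4, 200_001)
        vals = -2.0 * (k * np.log(grid) + (n - k) * np.log(1 - grid))
        inside = grid[vals <= neg2ll(phat) + 3.841459]
        assert ci.lower == pytest.approx(inside[0], abs=2e-3)
        assert ci.upper == pytest.approx(inside[-1], abs=2e-3)

    def test_flat_profile_flagged_open(self):
        def refit(param, value):
            return 100.0  # non-identified: OFV never rises

        fit = FitResult(
            model="pk",
            estimates={"cl": 1.0},
            ofv=100.0,
            n_parameters=1,
            ebes={},
            convergence="converged",
            n_iter=1,
            se={"cl": 0.2},
            _refit=refit,
        )
        ci = profile_ci(fit, "cl")
        assert ci.open_lower and ci.open_upper
        assert ci.lower == -math.inf and ci.upper == math.inf
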
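import numpy as np
import pytest

from remipkpd.kinetics import IndividualPKParameters, PopulationPKParameters, solve_profile
from remipkpd.mcsim import (
    regimen_grid_search,
    simulate_regimen,
    summarize,
    target_attainment,
)
from remipkpd.pd_bis import BISModelParameters, bis_response
from remipkpd.pd_moaas import MOAASModelParameters
from remipkpd.trial_data import RegimenSpec, ValidationError, resolve_regimen

STUDY_REGIMEN = RegimenSpec(0.4, 1.0, 1.5, 120.0)


@pytest.fixture(scope="module")
def typical_models():
    pk = PopulationPKParameters(v1=2.11, cl=1.49, v2=10.5, q2=0.96, v3=22.7, q3=0.27)
    bis = BISModelParameters(ke0=0.0855, ic50=503.0, gamma=1.5, e0=95.3, imax=47.9)
    moaas = MOAASModelParameters(
        baselines=(-8.52, -2.44, -1.30, -1.15, -0.895),
        ke0=0.05, ic50=436.0, gamma=1.5, imax=27.9,
    )
    return pk, bis, moaas


class TestSimulateRegimen:
    def test_degenerate_population_is_typical_subject(self, typical_models):
        pk, bis, moaas = typical_models
        grid = np.arange(0.0, 60.5, 0.5)
        traj = simulate_regimen(
            pk, bis, moaas, STUDY_REGIMEN, demographics=63.8, n=3, rng_seed=1,
            times=grid,
        )
        ind = IndividualPKParameters.from_population(pk)
        prof = solve_profile(
            ind, resolve_regimen(STUDY_REGIMEN, 63.8), grid, (bis.ke0,)
        )
        np.testing.assert_allclose(traj.cp[0], prof.cp, rtol=1e-9)
        np.testing.assert_allclose(
            traj.bis[0], bis_response(prof.ce_for(bis.ke0), bis), rtol=1e-9
        )
        np.testing.assert_array_equal(traj.cp[0], traj.cp[2])

    def test_seed_reproducibility(self, pk_pop, bis_pop, moaas_pop):
        grid = np.arange(0.0, 30.5, 0.5)
        a = simulate_regimen(
            pk_pop, bis_pop, moaas_pop, STUDY_REGIMEN, n=20, rng_seed=7, times=grid
        )
        b = simulate_regimen(
            pk_pop, bis_pop, moaas_pop, STUDY_REGIMEN, n=20, rng_seed=7, times=grid
        )
        np.testing.assert_array_equal(a.cp, b.cp)
        np.testing.assert_array_equal(a.moaas_probs, b.moaas_probs)

    def test_probabilities_valid(self, pk_pop, bis_pop, moaas_pop):
        grid = np.arange(0.0, 30.5, 1.0)
        traj = simulate_regimen(
            pk_pop, bis_pop, moaas_pop, STUDY_REGIMEN, n=30, rng_seed=3, times=grid
        )
        assert np.all(traj.moaas_probs >= 0)
        np.testing.assert_allclose(traj.moaas_probs.sum(axis=-1), 1.0, atol=1e-9)

    def test_invalid_n_rejected(self, typical_models):
        pk, bis, moaas = typical_models
        with pytest.raises(ValidationError):
            simulate_regimen(pk, bis, moaas, STUDY_REGIMEN, n=0)


class TestSummaries:
    def test_single_subject_bands_collapse(self, typical_models):
        pk, bis, moaas = typical_models
        grid = np.arange(0.0, 30.5, 0.5)
        traj = simulate_regimen(
            pk, bis, moaas, STUDY_REGIMEN, demographics=63.8, n=1, rng_seed=1,
            times=grid,
        )
        summ = summarize(traj)
        np.testing.assert_allclose(summ.bis_bands[0], summ.bis_bands[2])
        np.testing.assert_allclose(summ.cp_bands[1], traj.cp[0])
        assert np.all(summ.p_lt2 >= 0) and np.all(summ.p_lt2 <= 1)

    def test_attainment_trivial_cases(self, typical_models):
        pk, bis, moaas = typical_models
        grid = np.arange(0.0, 120.5, 0.5)
        none = simulate_regimen(
            pk, bis, moaas, RegimenSpec(0.0, 1.0, 0.0, 0.0), n=3, rng_seed=1,
            times=grid,
        )
        _, frac = target_attainment(none, 90.0)
        assert frac == 0.0
        dosed = simulate_regimen(
            pk, bis, moaas, STUDY_REGIMEN, demographics=63.8, n=2, rng_seed=1,
            times=grid,
        )
        flags, frac0 = target_attainment(dosed, 0.0)
        assert frac0 == 1.0  # any crossing counts when the target duration is 0

    def test_monotone_in_maintenance_rate(self, typical_models):
        pk, bis, moaas = typical_models
        grid = np.arange(0.0, 121.0, 1.0)
        medians = []
        for rate in (1.0, 3.0, 6.0):
            spec = RegimenSpec(0.4, 1.0, rate, 120.0)
            traj = simulate_regimen(
                pk, bis, moaas, spec, demographics=63.8, n=1, rng_seed=1, times=grid
            )
            window = (grid >= 30) & (grid <= 120)
            medians.append(np.median(traj.bis[0][window]))
        assert medians[0] > medians[1] > medians[2]

    def test_monte_carlo_error_shrinks_with_n(self, pk_pop, bis_pop, moaas_pop):
        grid = np.arange(0.0, 121.0, 1.0)
        fracs = {50: [], 200: []}
        for n in fracs:
            for rep in range(12):
                traj = simulate_regimen(
                    pk_pop, bis_pop, moaas_pop, STUDY_REGIMEN, n=n,
                    rng_seed=1000 + 17 * rep + n, times=grid,
                )
                fracs[n].append(target_attainment(traj, 90.0)[1])
        sd_small, sd_big = np.std(fracs[50]), np.std(fracs[200])
        # quadrupling n should roughly halve the Monte-Carlo SE
        assert sd_big < sd_small


class TestGridSearch:
    def test_single_candidate_ranked_first(self, typical_models):
        pk, bis, moaas = typical_models
        res = regimen_grid_search(
            [1.5], pk, bis, moaas, n=5, rng_seed=1,
        )
        assert len(res) == 1 and res[0]["rank"] == 1

    def test_published_maintenance_rate_ranked_optimal(
        self, pk_pop, bis_pop, moaas_pop
    ):
        """Among the studied maintenance rates, 1.5 mg/kg/h best combines
        sustained MOAA/S < 2 with a median BIS inside the 60-65 band."""
        res = regimen_grid_search(
            [1.0, 1.5, 3.0, 6.0], pk_pop, bis_pop, moaas_pop, n=300, rng_seed=5
        )
        assert res[0]["maintenance_mg_per_kg_per_h"] == 1.5
        assert res[0]["rank"] == 1

    def test_empty_candidates_rejected(self, typical_models):
        pk, bis, moaas = typical_models
        with pytest.raises(ValidationError):
            regimen_grid_search([], pk, bis, moaas)
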
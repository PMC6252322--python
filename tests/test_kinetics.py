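import numpy as np
import pytest

from conftest import ode_oracle
from remipkpd.kinetics import (
    IndividualPKParameters,
    PopulationPKParameters,
    apply_proportional_error,
    build_state_matrix,
    sample_individual,
    solve_profile,
)
from remipkpd.trial_data import DoseEvent, Regimen, ValidationError

GRID = np.array(
    [0, 1, 2, 3, 4, 6, 8, 10, 12, 15, 20, 30, 45, 60, 120, 180, 240, 360, 480],
    dtype=float,
)


class TestSampling:
    def test_zero_omega_gives_typical_values(self, pk_pop):
        pop = PopulationPKParameters(
            v1=2.11, cl=1.49, v2=10.5, q2=0.96, v3=22.7, q3=0.27
        )
        inds = sample_individual(pop, 5, rng=1)
        for ind in inds:
            assert ind.cl == pytest.approx(1.49)
            assert ind.v3 == pytest.approx(22.7)

    def test_lognormal_iiv_sd(self, pk_pop):
        inds = sample_individual(pk_pop, 100_000, rng=12345)
        log_cl = np.log([i.cl for i in inds])
        assert np.std(log_cl) == pytest.approx(0.115, rel=0.01)
        assert np.mean(log_cl) == pytest.approx(np.log(1.49), abs=0.002)

    def test_seed_reproducibility(self, pk_pop):
        a = sample_individual(pk_pop, 10, rng=7)
        b = sample_individual(pk_pop, 10, rng=7)
        assert all(x.cl == y.cl and x.v3 == y.v3 for x, y in zip(a, b))

    def test_negative_omega_rejected(self):
        with pytest.raises(ValidationError):
            PopulationPKParameters(
                v1=2.11, cl=1.49, v2=10.5, q2=0.96, v3=22.7, q3=0.27,
                omega={"cl": -0.1},
            )


class TestStateMatrix:
    def test_one_compartment_reduction(self):
        ind = IndividualPKParameters(v1=2.0, cl=1.0, v2=1.0, q2=0.0, v3=1.0, q3=0.0)
        a, b = build_state_matrix(ind, ke0=0.1)
        assert a[0, 0] == pytest.approx(-0.5)
        assert a[1, 0] == a[2, 0] == 0.0
        assert a[0, 1] == a[0, 2] == 0.0
        assert b[0] == pytest.approx(1000.0)

    def test_eigenvalues_real_negative(self, typical_subject):
        a, _ = build_state_matrix(typical_subject, ke0=0.0855)
        w = np.linalg.eigvals(a)
        assert np.max(np.abs(w.imag)) < 1e-12
        assert np.all(w.real < 0)

    def test_mass_conservation_column_sums(self, typical_subject):
        a, _ = build_state_matrix(typical_subject, ke0=0.0855)
        amounts = a[:3, :3]
        sums = amounts.sum(axis=0)
        assert sums[0] == pytest.approx(-typical_subject.cl / typical_subject.v1)
        assert sums[1] == pytest.approx(0.0, abs=1e-14)
        assert sums[2] == pytest.approx(0.0, abs=1e-14)

    def test_ke0_zero_effect_row_vanishes(self, typical_subject):
        a, _ = build_state_matrix(typical_subject, ke0=0.0)
        assert np.all(a[3] == 0.0)


class TestSolveProfile:
    def test_no_dose_all_zero(self, typical_subject):
        prof = solve_profile(typical_subject, Regimen(()), GRID, (0.0855,))
        assert np.all(prof.cp == 0)
        assert np.all(prof.ce_for(0.0855) == 0)

    def test_steady_state_concentration(self, typical_subject):
        # constant infusion at CL mg/min -> Cp_ss = 1000 * R / CL = 1000 ng/mL
        reg = Regimen((DoseEvent(0.0, 1.49 * 5000.0, 5000.0),))
        prof = solve_profile(typical_subject, reg, np.array([4999.0]), (0.0855,))
        assert prof.cp[0] == pytest.approx(1000.0, rel=1e-6)
        assert prof.ce_for(0.0855)[0] == pytest.approx(prof.cp[0], rel=1e-5)

    @pytest.mark.parametrize("method", ["auto", "expm"])
    def test_matches_ode_oracle(self, typical_subject, method):
        reg = Regimen((DoseEvent(0.0, 26.0, 1.0),))
        prof = solve_profile(
            typical_subject, reg, GRID, (0.0855, 0.05), method=method
        )
        ref = ode_oracle(typical_subject, reg, GRID, (0.0855, 0.05))
        cp_ref = ref[0] / typical_subject.v1
        mask = GRID > 0
        assert np.max(
            np.abs(prof.cp[mask] - cp_ref[mask]) / cp_ref[mask]
        ) < 1e-6
        for j, ke0 in enumerate((0.0855, 0.05)):
            ce_ref = ref[3 + j]
            rel = np.abs(prof.ce_for(ke0)[mask] - ce_ref[mask]) / (
                np.abs(ce_ref[mask]) + 1e-9
            )
            assert np.max(rel) < 1e-6

    def test_superposition_of_events(self, typical_subject):
        e1 = DoseEvent(0.0, 26.0, 1.0)
        e2 = DoseEvent(1.0, 95.0, 120.0)
        both = solve_profile(typical_subject, Regimen((e1, e2)), GRID, (0.05,))
        p1 = solve_profile(typical_subject, Regimen((e1,)), GRID, (0.05,))
        p2 = solve_profile(typical_subject, Regimen((e2,)), GRID, (0.05,))
        np.testing.assert_allclose(both.cp, p1.cp + p2.cp, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(
            both.ce_for(0.05), p1.ce_for(0.05) + p2.ce_for(0.05), rtol=1e-9, atol=1e-12
        )

    def test_dose_proportionality(self, typical_subject):
        reg = Regimen((DoseEvent(0.0, 26.0, 1.0),))
        base = solve_profile(typical_subject, reg, GRID, (0.0855,))
        double = solve_profile(typical_subject, reg.scaled(2.0), GRID, (0.0855,))
        np.testing.assert_allclose(double.cp, 2.0 * base.cp, rtol=1e-9)
        np.testing.assert_allclose(
            double.ce_for(0.0855), 2.0 * base.ce_for(0.0855), rtol=1e-9
        )

    def test_terminal_decline_at_slowest_eigenvalue(self, typical_subject):
        reg = Regimen((DoseEvent(0.0, 26.0, 1.0),))
        a, _ = build_state_matrix(typical_subject, 0.0855)
        lam_slow = np.max(np.linalg.eigvals(a[:3, :3]).real)
        t = np.array([2000.0, 2100.0])
        prof = solve_profile(typical_subject, reg, t)
        slope = (np.log(prof.cp[1]) - np.log(prof.cp[0])) / 100.0
        assert slope == pytest.approx(lam_slow, rel=1e-4)

    def test_effect_site_peak_lags_plasma_peak(self, typical_subject):
        grid = np.arange(0.0, 60.0, 0.05)
        reg = Regimen((DoseEvent(0.0, 26.0, 1.0),))
        prof = solve_profile(typical_subject, reg, grid, (0.0855,))
        assert grid[np.argmax(prof.ce_for(0.0855))] > grid[np.argmax(prof.cp)]

    def test_mass_balance_against_ode(self, typical_subject):
        reg = Regimen((DoseEvent(0.0, 26.0, 1.0), DoseEvent(1.0, 95.0, 120.0)))
        times = np.array([0.5, 1.0, 10.0, 60.0, 121.0, 240.0])
        prof = solve_profile(typical_subject, reg, times, keep_amounts=True)
        ref = ode_oracle(typical_subject, reg, times, with_elimination=True)
        eliminated = ref[3]
        infused = np.array(
            [
                sum(
                    e.amount * min(max((t - e.start_time) / e.duration, 0.0), 1.0)
                    for e in reg.events
                )
                * 1000.0
                for t in times
            ]
        )
        balance = prof.amounts.sum(axis=1) + eliminated
        np.testing.assert_allclose(balance, infused, rtol=1e-6)

    def test_negative_times_rejected(self, typical_subject):
        with pytest.raises(ValidationError):
            solve_profile(typical_subject, Regimen(()), np.array([-1.0, 0.0]))


class TestProportionalError:
    def test_zero_sigma_identity(self):
        cp = np.array([0.0, 10.0, 100.0])
        y, trunc = apply_proportional_error(cp, 0.0, rng=1)
        np.testing.assert_array_equal(y, cp)
        assert not trunc.any()

    def test_observed_cv_matches_sigma(self):
        cp = np.full(200_000, 500.0)
        y, _ = apply_proportional_error(cp, 0.138, rng=99)
        assert np.std(y) / np.mean(y) == pytest.approx(0.138, rel=0.02)

    def test_zero_concentration_stays_zero(self):
        y, _ = apply_proportional_error(np.zeros(10), 0.5, rng=1)
        assert np.all(y == 0.0)

    def test_negative_draws_truncated(self):
        y, trunc = apply_proportional_error(np.full(10_000, 1.0), 1.0, rng=5)
        assert trunc.any()
        assert np.all(y >= 0.0)
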
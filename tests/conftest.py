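import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from remipkpd.kinetics import IndividualPKParameters, _full_matrix
from remipkpd.published import published_bis, published_moaas, published_pk


@pytest.fixture(scope="session")
def pk_pop():
    return published_pk()


@pytest.fixture(scope="session")
def bis_pop():
    return published_bis()


@pytest.fixture(scope="session")
def moaas_pop():
    return published_moaas()


@pytest.fixture(scope="session")
def typical_subject(pk_pop):
    return IndividualPKParameters.from_population(pk_pop)


def ode_oracle(ind, regimen, times, ke0_list=(), with_elimination=False):
    """Independent stiff-ODE reference solution of the kinetic system.

    Integrates the same linear system with an adaptive LSODA solver at
    tight tolerances; optionally appends a cumulative-elimination state
    for mass-balance checks.  Returns the state matrix (n_states, nt),
    ordered A1..A3 (ug), one Ce per ke0, [eliminated amount].
    """
    a, b = _full_matrix(ind, ke0_list)
    k = len(b)
    n = k + 1 if with_elimination else k

    def rhs(t, x):
        rate = sum(
            e.amount / e.duration
            for e in regimen.events
            if e.duration > 0 and e.start_time <= t <= e.start_time + e.duration
        )
        dx = np.empty(n)
        dx[:k] = a @ x[:k] + b * rate
        if with_elimination:
            dx[k] = ind.cl / ind.v1 * x[0]
        return dx

    x0 = np.zeros(n)
    for e in regimen.events:
        if e.duration == 0 and e.start_time == 0:
            x0[0] += e.amount * 1000.0
    sol = solve_ivp(
        rhs,
        (0.0, float(max(times))),
        x0,
        t_eval=np.asarray(times, dtype=float),
        method="LSODA",
        rtol=1e-11,
        atol=1e-12,
        max_step=0.5,
    )
    assert sol.success
    return sol.y


def gauss_hermite_neg2ll(m2_joint, n_nodes=51, bounds=(-3.0, 3.0)):
    """Adaptive Gauss-Hermite -2 log marginal likelihood for a 1-eta model.

    ``m2_joint`` maps an (m, 1) eta array to the joint -2 log density.
    Nodes are centred at the mode and scaled by the local curvature, which
    makes 51 nodes effectively exact for these problems.
    """
    res = minimize_scalar(
        lambda e: float(m2_joint(np.array([[e]]))[0]),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-10},
    )
    mode = res.x
    h = 1e-3
    f0 = float(m2_joint(np.array([[mode]]))[0])
    fp = float(m2_joint(np.array([[mode + h]]))[0])
    fm = float(m2_joint(np.array([[mode - h]]))[0])
    curv = (fp - 2 * f0 + fm) / h**2
    sd = np.sqrt(2.0 / max(curv, 1e-8))
    nodes, weights = hermegauss(n_nodes)
    etas = mode + sd * nodes
    vals = m2_joint(etas[:, None])
    log_integrand = -0.5 * vals + 0.5 * nodes**2
    mx = np.max(log_integrand)
    integral = sd * np.sum(weights * np.exp(log_integrand - mx))
    return -2.0 * (np.log(integral) + mx)
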
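"""Three-compartment mammillary kinetics with effect-compartment link.

The structural model is the linear mammillary system

    dA1/dt = in(t) - (CL + Q2 + Q3)/V1 * A1 + Q2/V2 * A2 + Q3/V3 * A3
    dA2/dt = Q2/V1 * A1 - Q2/V2 * A2
    dA3/dt = Q3/V1 * A1 - Q3/V3 * A3

with amounts in ug (doses in mg are converted by a factor 1000 so that
Cp = A1/V1 comes out in ug L^-1 = ng mL^-1), plus one linear effect
compartment per requested equilibration constant:

    dCe/dt = ke0 * (A1/V1 - Ce)

Because the system is linear and infusion inputs are piecewise constant,
profiles are computed exactly: the default path diagonalises the rate
matrix once per subject and evaluates matrix exponentials in the
eigenbasis (superposing events); a piecewise matrix-exponential path is
kept as a fallback for (near-)defective matrices.

Inter-individual variability is log-normal on every structural parameter:
theta_i = theta_TV * exp(eta_i), eta_i ~ N(0, omega^2), independent across
parameters (diagonal Omega).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .trial_data import DoseEvent, Regimen, ValidationError

__all__ = [
    "PK_PARAM_NAMES",
    "PopulationPKParameters",
    "IndividualPKParameters",
    "KineticProfile",
    "sample_individual",
    "build_state_matrix",
    "solve_profile",
    "apply_proportional_error",
]

#: Canonical order of the structural PK parameters.
PK_PARAM_NAMES = ("v1", "cl", "v2", "q2", "v3", "q3")

_MG_TO_UG = 1000.0


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValidationError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class PopulationPKParameters:
    """Typical values, IIV standard deviations and residual error of the PK model.

    Volumes in L, clearances in L min^-1.  ``omega`` maps parameter name to
    the log-scale SD of its random effect (approximately a CV); missing
    entries mean no variability.  ``sigma_prop`` is the proportional
    residual SD.
    """

    v1: float
    cl: float
    v2: float
    q2: float
    v3: float
    q3: float
    omega: Mapping[str, float] = field(default_factory=dict)
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        for name in ("v1", "cl", "v2", "v3"):
            _check_positive(name, getattr(self, name))
        for name in ("q2", "q3"):  # zero collapses the peripheral compartment
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name, w in self.omega.items():
            if name not in PK_PARAM_NAMES:
                raise ValidationError(f"unknown omega entry {name!r}")
            if w < 0:
                raise ValidationError(f"omega[{name!r}] must be >= 0")
        if self.sigma_prop < 0:
            raise ValidationError("sigma_prop must be >= 0")

    @property
    def vss(self) -> float:
        """Total (steady-state) volume of distribution V1+V2+V3, L."""
        return self.v1 + self.v2 + self.v3


@dataclass(frozen=True)
class IndividualPKParameters:
    """One subject's structural parameters and the etas that produced them."""

    v1: float
    cl: float
    v2: float
    q2: float
    v3: float
    q3: float
    eta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("v1", "cl", "v2", "v3"):
            _check_positive(name, getattr(self, name))
        for name in ("q2", "q3"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def from_population(
        cls, pop: PopulationPKParameters, eta: Mapping[str, float] | None = None
    ) -> "IndividualPKParameters":
        eta = dict(eta or {})
        values = {
            n: getattr(pop, n) * np.exp(eta.get(n, 0.0)) for n in PK_PARAM_NAMES
        }
        return cls(**values, eta=eta)


@dataclass
class KineticProfile:
    """Plasma and effect-site concentration time courses on a grid.

    ``cp`` in ng mL^-1; ``ce`` maps each requested ke0 (min^-1) to its
    effect-site track (same units).  ``amounts`` holds compartment amounts
    A1..A3 in ug for mass-balance diagnostics.
    """

    times: np.ndarray
    cp: np.ndarray
    ce: dict
    amounts: np.ndarray | None = None

    def ce_for(self, ke0: float) -> np.ndarray:
        return self.ce[float(ke0)]

    def to_frame(self):
        """Tidy table: time, cp and one ce_<ke0> column per track."""
        import pandas as pd

        data = {"time": self.times, "cp": self.cp}
        for ke0, track in self.ce.items():
            data[f"ce_{ke0:g}"] = track
        return pd.DataFrame(data)


def sample_individual(
    pop: PopulationPKParameters,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> list:
    """Draw ``n`` individuals with independent log-normal IIV per parameter."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(rng)
    out = []
    for _ in range(n):
        eta = {
            name: rng.normal(0.0, w) if w > 0 else 0.0
            for name, w in pop.omega.items()
        }
        out.append(IndividualPKParameters.from_population(pop, eta))
    return out


def build_state_matrix(
    ind: IndividualPKParameters, ke0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rate matrix and input vector for states (A1, A2, A3, Ce).

    The input vector corresponds to a unit 1 mg min^-1 infusion into the
    central compartment (1000 ug min^-1).
    """
    if ke0 < 0:
        raise ValidationError("ke0 must be >= 0")
    v1, cl, v2, q2, v3, q3 = (getattr(ind, n) for n in PK_PARAM_NAMES)
    a = np.array(
        [
            [-(cl + q2 + q3) / v1, q2 / v2, q3 / v3, 0.0],
            [q2 / v1, -q2 / v2, 0.0, 0.0],
            [q3 / v1, 0.0, -q3 / v3, 0.0],
            [ke0 / v1, 0.0, 0.0, -ke0],
        ]
    )
    b = np.array([_MG_TO_UG, 0.0, 0.0, 0.0])
    return a, b


def _full_matrix(ind: IndividualPKParameters, ke0_list: Sequence[float]):
    """(3+m)-state matrix: amounts A1..A3 then one Ce per ke0."""
    v1, cl, v2, q2, v3, q3 = (getattr(ind, n) for n in PK_PARAM_NAMES)
    m = len(ke0_list)
    k = 3 + m
    a = np.zeros((k, k))
    a[0, 0] = -(cl + q2 + q3) / v1
    a[0, 1] = q2 / v2
    a[0, 2] = q3 / v3
    a[1, 0] = q2 / v1
    a[1, 1] = -q2 / v2
    a[2, 0] = q3 / v1
    a[2, 2] = -q3 / v3
    for j, ke0 in enumerate(ke0_list):
        if ke0 < 0:
            raise ValidationError("ke0 must be >= 0")
        a[3 + j, 0] = ke0 / v1
        a[3 + j, 3 + j] = -ke0
    b = np.zeros(k)
    b[0] = _MG_TO_UG
    return a, b


def _eig_ok(w: np.ndarray, p: np.ndarray) -> bool:
    scale = np.max(np.abs(w)) + 1e-30
    if np.max(np.abs(w.imag)) > 1e-9 * scale:
        return False
    wr = np.sort(w.real)
    if len(wr) > 1 and np.min(np.diff(wr)) < 1e-8 * scale:
        return False
    return np.linalg.cond(p) < 1e10


def _event_response_eig(w, p, pinv_b, pinv, event: DoseEvent, times: np.ndarray):
    """State response (k, nt) of one dose event in the eigenbasis."""
    tau = times - event.start_time
    k = len(w)
    g = np.zeros((k, len(times)))
    if event.duration > 0:
        r = event.amount / event.duration  # mg/min
        d = event.duration
        for i, lam in enumerate(w):
            gi = np.zeros_like(tau)
            during = (tau > 0) & (tau <= d)
            after = tau > d
            if abs(lam) < 1e-12:
                gi[during] = tau[during]
                gi[after] = d
            else:
                gi[during] = np.expm1(lam * tau[during]) / lam
                gi[after] = np.expm1(lam * d) / lam * np.exp(lam * (tau[after] - d))
            g[i] = gi * (r * pinv_b[i])
    else:
        # bolus: amount appears in A1 at start_time (inclusive)
        x0 = np.zeros(k)
        x0[0] = event.amount * _MG_TO_UG
        c = pinv @ x0
        for i, lam in enumerate(w):
            gi = np.zeros_like(tau)
            on = tau >= 0
            gi[on] = np.exp(lam * tau[on])
            g[i] = gi * c[i]
    return p @ g


def _solve_expm(a, b, regimen: Regimen, times: np.ndarray) -> np.ndarray:
    """Piecewise matrix-exponential solution (fallback path), states (k, nt)."""
    k = len(b)
    breaks = sorted(
        {0.0}
        | {e.start_time for e in regimen.events}
        | {e.end_time for e in regimen.events if e.duration > 0}
    )
    grid = np.union1d(np.asarray(times, dtype=float), np.asarray(breaks))
    grid = grid[grid >= 0]
    x = np.zeros(k)
    out = np.zeros((k, len(times)))
    t_prev = 0.0
    cache: dict = {}
    # boluses at t=0 apply immediately
    for e in regimen.events:
        if e.duration == 0 and e.start_time == 0.0:
            x[0] += e.amount * _MG_TO_UG
    idx_map = {t: i for i, t in enumerate(np.asarray(times, dtype=float))}
    if 0.0 in idx_map:
        out[:, idx_map[0.0]] = x
    for t in grid:
        if t <= t_prev:
            continue
        h = t - t_prev
        # rate over (t_prev, t]: constant because all breakpoints are in the grid
        rate = sum(
            e.rate
            for e in regimen.events
            if e.duration > 0 and e.start_time <= t_prev and e.end_time >= t
        )
        key = (round(h, 12), round(rate, 12))
        if key not in cache:
            m_aug = np.zeros((k + 1, k + 1))
            m_aug[:k, :k] = a * h
            m_aug[:k, k] = b * rate * h
            cache[key] = expm(m_aug)
        ph = cache[key]
        x = ph[:k, :k] @ x + ph[:k, k]
        for e in regimen.events:
            if e.duration == 0 and e.start_time == t:
                x = x.copy()
                x[0] += e.amount * _MG_TO_UG
        if t in idx_map:
            out[:, idx_map[t]] = x
        t_prev = t
    return out


def solve_profile(
    ind: IndividualPKParameters,
    regimen: Regimen,
    times: Sequence[float],
    ke0_list: Sequence[float] = (),
    method: str = "auto",
    keep_amounts: bool = False,
) -> KineticProfile:
    """Exact concentration profile of one subject under a dosing regimen.

    Parameters
    ----------
    times : sorted, non-negative output grid in minutes.
    ke0_list : equilibration constants (min^-1); one effect-site track is
        returned per entry.
    method : ``"auto"`` (eigendecomposition with matrix-exponential
        fallback), ``"eig"`` or ``"expm"``.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(times < 0) or np.any(np.diff(times) < 0)):
        raise ValidationError("times must be sorted and non-negative")
    ke0_list = [float(k) for k in ke0_list]
    a, b = _full_matrix(ind, ke0_list)
    k = len(b)

    states = None
    if method in ("auto", "eig"):
        w, p = np.linalg.eig(a)
        if _eig_ok(w, p) or method == "eig":
            w = w.real
            p = p.real
            pinv = np.linalg.inv(p)
            pinv_b = pinv @ b
            states = np.zeros((k, len(times)))
            for event in regimen.events:
                if event.amount == 0:
                    continue
                states += _event_response_eig(w, p, pinv_b, pinv, event, times)
        elif method == "eig":  # pragma: no cover - defensive
            raise ValidationError("eigendecomposition unreliable for these parameters")
    if states is None:
        states = _solve_expm(a, b, regimen, times)

    cp = np.maximum(states[0] / ind.v1, 0.0)
    ce = {
        ke0: np.maximum(states[3 + j], 0.0) for j, ke0 in enumerate(ke0_list)
    }
    return KineticProfile(
        times=times,
        cp=cp,
        ce=ce,
        amounts=states[:3].T.copy() if keep_amounts else None,
    )


def apply_proportional_error(
    cp: np.ndarray,
    sigma_prop: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed concentrations y = Cp * (1 + eps), eps ~ N(0, sigma^2).

    Negative draws are truncated to zero; returns (y, truncated_mask).
    """
    if sigma_prop < 0:
        raise ValidationError("sigma_prop must be >= 0")
    cp = np.asarray(cp, dtype=float)
    rng = np.random.default_rng(rng)
    y = cp * (1.0 + rng.normal(0.0, sigma_prop, size=cp.shape)) if sigma_prop > 0 else cp.copy()
    truncated = y < 0
    y[truncated] = 0.0
    return y, truncated
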
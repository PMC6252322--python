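"""Nonlinear mixed-effects estimation for the PK, BIS and MOAA/S models.

The marginal likelihood of each subject's data is approximated by the
Laplace method: the joint -2 log density of (data, eta) is minimised over
the subject's random effects eta (damped Newton with finite-difference
derivatives), and the Gaussian integral is corrected with the log
determinant of the Hessian at the conditional mode.  Writing
h(eta) = -log p(y | eta) - log p(eta), the contribution is

    -2 LL_i = 2 h(eta_hat) + log det H(eta_hat) - d log 2 pi,

with H the Hessian of h.  This coincides with first-order conditional
estimation in the Gaussian-linear limit; exact FOCE-I interaction terms of
commercial tools are not replicated.

Population parameters are estimated by quasi-Newton minimisation of the
total -2 LL over log-transformed fixed effects, log-omegas and log-sigma
(category baselines and covariate coefficients stay on the identity
scale).  Empirical Bayes estimates (EBEs) are the conditional modes at the
optimum.

The two-stage PK->PD workflow mirrors the study analysis: the PK model is
fitted first, each subject's concentration profile is fixed at their
empirical Bayes parameters, and the PD models are then estimated
conditional on those profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2

from .kinetics import (
    IndividualPKParameters,
    PK_PARAM_NAMES,
    PopulationPKParameters,
)
from .kinetics import _full_matrix, solve_profile  # shared structural model
from .pd_bis import BIS_PARAM_NAMES, BISModelParameters
from .pd_moaas import MOAAS_PARAM_NAMES, MOAASModelParameters
from .trial_data import (
    DVID_BIS,
    DVID_CONC,
    DVID_MOAAS,
    ObservationTable,
    Regimen,
    ValidationError,
)

__all__ = [
    "SubjectData",
    "PKModelSpec",
    "FitResult",
    "CovariateTestResult",
    "ProfileCI",
    "prepare_subjects",
    "marginal_loglik_continuous",
    "marginal_loglik_categorical",
    "fit_population",
    "evaluate_population",
    "two_stage_pd_fit",
    "covariate_lrt",
    "profile_ci",
    "screen_covariates",
]

_LOG_2PI = math.log(2.0 * math.pi)

# reference covariate values (study medians) for covariate relations
_COV_REFS = {"weight": 63.8, "age": 27.0, "height": 169.0}


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """One subject's observations for a single endpoint, plus context."""

    subject_id: object
    covariates: object
    regimen: Regimen
    times: np.ndarray
    y: np.ndarray
    pk_individual: IndividualPKParameters | None = None


_ENDPOINT_DVID = {"pk": DVID_CONC, "bis": DVID_BIS, "moaas": DVID_MOAAS}


def prepare_subjects(
    table: ObservationTable,
    model: str,
    individual_pk: Mapping | None = None,
    include_bql: bool = False,
) -> list:
    """Extract per-subject observation vectors for one endpoint.

    Concentrations flagged below the LLOQ are excluded unless
    ``include_bql`` is set.  Subjects without usable observations are
    dropped.  For PD endpoints, ``individual_pk`` (subject id ->
    :class:`IndividualPKParameters`) attaches the fixed individual
    kinetics required by the two-stage workflow.
    """
    dvid = _ENDPOINT_DVID[model]
    out = []
    for sid in table.subject_ids:
        recs = [
            o
            for o in table.records(dvid=dvid, subject_id=sid)
            if include_bql or not o.bql
        ]
        if not recs:
            continue
        recs.sort(key=lambda o: o.time)
        pk_ind = None
        if individual_pk is not None:
            if sid not in individual_pk:
                raise ValidationError(f"no individual PK parameters for subject {sid}")
            pk_ind = individual_pk[sid]
        out.append(
            SubjectData(
                subject_id=sid,
                covariates=table.covariates[sid],
                regimen=table.doses[sid],
                times=np.array([o.time for o in recs], dtype=float),
                y=np.array([o.value for o in recs], dtype=float),
                pk_individual=pk_ind,
            )
        )
    return out


# ---------------------------------------------------------------------------
# batched exact-profile engine
# ---------------------------------------------------------------------------


class _ProfileEngine:
    """Evaluates Cp (and optionally Ce) for a batch of parameter vectors.

    One instance per (regimen, observation grid); the linear system is
    diagonalised per batch item (stacked ``eig``) and each infusion event
    is superposed analytically.  Items whose eigendecomposition looks
    unreliable fall back to the piecewise matrix-exponential solver.
    """

    def __init__(self, regimen: Regimen, times: np.ndarray):
        self.regimen = regimen
        self.times = np.asarray(times, dtype=float)
        self.events = [e for e in regimen.events if e.amount > 0]

    def conc(self, thetas: np.ndarray, ke0: np.ndarray | None = None):
        """Return (cp, ce) arrays of shape (m, nt); ce is None without ke0."""
        thetas = np.asarray(thetas, dtype=float)
        m = thetas.shape[0]
        nt = len(self.times)
        k = 3 if ke0 is None else 4
        v1, cl, v2, q2, v3, q3 = thetas.T
        a = np.zeros((m, k, k))
        a[:, 0, 0] = -(cl + q2 + q3) / v1
        a[:, 0, 1] = q2 / v2
        a[:, 0, 2] = q3 / v3
        a[:, 1, 0] = q2 / v1
        a[:, 1, 1] = -q2 / v2
        a[:, 2, 0] = q3 / v1
        a[:, 2, 2] = -q3 / v3
        if ke0 is not None:
            a[:, 3, 0] = np.asarray(ke0) / v1
            a[:, 3, 3] = -np.asarray(ke0)
        w, p = np.linalg.eig(a)
        scale = np.max(np.abs(w.real), axis=1) + 1e-30
        gap = np.min(
            np.diff(np.sort(w.real, axis=1), axis=1), axis=1
        ) if k > 1 else np.full(m, np.inf)
        bad = (np.max(np.abs(w.imag), axis=1) > 1e-9 * scale) | (
            gap < 1e-8 * scale
        )
        w = w.real
        p = p.real
        b = np.zeros(k)
        b[0] = 1000.0  # unit 1 mg/min infusion, in ug/min
        states = np.zeros((m, k, nt))
        with np.errstate(all="ignore"):
            c = np.linalg.solve(p, np.broadcast_to(b, (m, k))[..., None])[..., 0]
            lam = w[:, :, None]  # (m, k, 1)
            lam_safe = np.where(np.abs(lam) < 1e-12, 1.0, lam)
            small = np.abs(lam) < 1e-12
            for ev in self.events:
                tau = self.times - ev.start_time
                if ev.duration > 0:
                    r = ev.amount / ev.duration
                    during = (tau > 0) & (tau <= ev.duration)
                    after = tau > ev.duration
                    g = np.zeros((m, k, nt))
                    if during.any():
                        td = tau[during]
                        g[:, :, during] = np.where(
                            small, td, np.expm1(lam * td) / lam_safe
                        )
                    if after.any():
                        d = ev.duration
                        ta = tau[after]
                        g[:, :, after] = np.where(
                            small,
                            d,
                            np.expm1(lam * d) / lam_safe * np.exp(lam * (ta - d)),
                        )
                    states += p @ (g * (c * r)[:, :, None])
                else:
                    on = tau >= 0
                    if on.any():
                        x0 = np.zeros(k)
                        x0[0] = ev.amount * 1000.0
                        c0 = np.linalg.solve(p, np.broadcast_to(x0, (m, k))[..., None])[
                            ..., 0
                        ]
                        g = np.zeros((m, k, nt))
                        g[:, :, on] = np.exp(lam * tau[on])
                        states += p @ (g * c0[:, :, None])
        bad |= ~np.isfinite(states).all(axis=(1, 2))
        for i in np.flatnonzero(bad):
            ind = IndividualPKParameters(
                v1=v1[i], cl=cl[i], v2=v2[i], q2=q2[i], v3=v3[i], q3=q3[i]
            )
            ke = () if ke0 is None else (float(np.asarray(ke0)[i]),)
            prof = solve_profile(ind, self.regimen, self.times, ke, method="expm")
            states[i, 0] = prof.cp * v1[i]
            if ke0 is not None:
                states[i, 3] = prof.ce_for(ke[0])
        cp = np.maximum(states[:, 0, :] / v1[:, None], 0.0)
        ce = np.maximum(states[:, 3, :], 0.0) if ke0 is not None else None
        return cp, ce


# ---------------------------------------------------------------------------
# model adapters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PKModelSpec:
    """Structural options of the PK sub-model.

    ``covariates`` lists relations ``(parameter, covariate, form)`` with
    form in {"power", "linear", "sex"}; each adds a coefficient named
    ``beta_<parameter>_<covariate>`` initialised at 0 (no effect).
    """

    error: str = "proportional"
    covariates: tuple = ()

    def __post_init__(self) -> None:
        for p, cov, form in self.covariates:
            if p not in PK_PARAM_NAMES:
                raise ValidationError(f"unknown PK parameter {p!r}")
            if form not in ("power", "linear", "sex"):
                raise ValidationError(f"unknown covariate form {form!r}")
            if form != "sex" and cov not in _COV_REFS:
                raise ValidationError(f"unknown covariate {cov!r}")

    def beta_names(self) -> list:
        return [f"beta_{p}_{c}" for p, c, _ in self.covariates]


class _PKAdapter:
    name = "pk"
    eta_candidates = PK_PARAM_NAMES
    has_sigma = True

    def __init__(self, spec: PKModelSpec | None):
        self.spec = spec or PKModelSpec()

    def fixed_names(self) -> list:
        return list(PK_PARAM_NAMES) + self.spec.beta_names()

    def transforms(self) -> dict:
        tr = {n: "log" for n in PK_PARAM_NAMES}
        tr.update({n: "id" for n in self.spec.beta_names()})
        return tr

    def default_init(self, pop: PopulationPKParameters) -> tuple[dict, dict, float]:
        fixed = {n: getattr(pop, n) for n in PK_PARAM_NAMES}
        fixed.update({n: 0.0 for n in self.spec.beta_names()})
        return fixed, dict(pop.omega), pop.sigma_prop

    def cov_factors(self, subject: SubjectData, fixed: Mapping) -> np.ndarray:
        f = np.ones(len(PK_PARAM_NAMES))
        for j, pname in enumerate(PK_PARAM_NAMES):
            for p, cov, form in self.spec.covariates:
                if p != pname:
                    continue
                beta = fixed[f"beta_{p}_{cov}"]
                if form == "sex":
                    f[j] *= 1.0 + beta * (subject.covariates.sex == "male")
                else:
                    val = getattr(subject.covariates, cov)
                    ref = _COV_REFS[cov]
                    if form == "power":
                        f[j] *= (val / ref) ** beta
                    else:
                        f[j] *= 1.0 + beta * (val - ref) / ref
        return f

    def nll_batch(self, ctx, fixed, etas, eta_names, sigma) -> np.ndarray:
        subject, engine = ctx
        m = etas.shape[0]
        base = np.array([fixed[n] for n in PK_PARAM_NAMES]) * self.cov_factors(
            subject, fixed
        )
        thetas = np.tile(base, (m, 1))
        for j, n in enumerate(eta_names):
            thetas[:, PK_PARAM_NAMES.index(n)] *= np.exp(etas[:, j])
        cp, _ = engine.conc(thetas)
        f = np.maximum(cp, 1e-8)
        var = (sigma * f) ** 2
        res = subject.y[None, :] - cp
        return np.sum(_LOG_2PI + np.log(var) + res**2 / var, axis=1)

    def predictions(self, ctx, fixed, eta, eta_names, sigma) -> np.ndarray:
        return self._pred(ctx, fixed, np.atleast_2d(eta), eta_names)[0]

    def _pred(self, ctx, fixed, etas, eta_names):
        subject, engine = ctx
        m = etas.shape[0]
        base = np.array([fixed[n] for n in PK_PARAM_NAMES]) * self.cov_factors(
            subject, fixed
        )
        thetas = np.tile(base, (m, 1))
        for j, n in enumerate(eta_names):
            thetas[:, PK_PARAM_NAMES.index(n)] *= np.exp(etas[:, j])
        cp, _ = engine.conc(thetas)
        return cp

    def simulate_obs(self, pred, sigma, rng):
        y = pred * (1.0 + rng.normal(0.0, sigma, size=pred.shape))
        return np.maximum(y, 0.0)


class _BISAdapter:
    name = "bis"
    eta_candidates = BIS_PARAM_NAMES
    has_sigma = True

    def __init__(self, residual_model: str = "lognormal"):
        self.residual_model = residual_model

    def fixed_names(self) -> list:
        return list(BIS_PARAM_NAMES)

    def transforms(self) -> dict:
        return {n: "log" for n in BIS_PARAM_NAMES}

    def default_init(self, pop: BISModelParameters) -> tuple[dict, dict, float]:
        return (
            {n: getattr(pop, n) for n in BIS_PARAM_NAMES},
            dict(pop.omega),
            pop.sigma_resid,
        )

    def _ce(self, ctx, thetas_pd):
        subject, engine = ctx
        pk = subject.pk_individual
        m = thetas_pd.shape[0]
        pk_thetas = np.tile(
            [getattr(pk, n) for n in PK_PARAM_NAMES], (m, 1)
        )
        _, ce = engine.conc(pk_thetas, ke0=thetas_pd[:, 0])
        return ce

    def _theta_mat(self, fixed, etas, eta_names):
        m = etas.shape[0]
        thetas = np.tile([fixed[n] for n in BIS_PARAM_NAMES], (m, 1))
        for j, n in enumerate(eta_names):
            thetas[:, BIS_PARAM_NAMES.index(n)] *= np.exp(etas[:, j])
        return thetas

    def _pred(self, ctx, fixed, etas, eta_names):
        thetas = self._theta_mat(fixed, etas, eta_names)
        ce = self._ce(ctx, thetas)
        ke0, ic50, gam, e0, imax = (thetas[:, j][:, None] for j in range(5))
        with np.errstate(all="ignore"):
            frac = ce**gam / (ic50**gam + ce**gam)
        return e0 - imax * np.where(np.isfinite(frac), frac, 1.0)

    def nll_batch(self, ctx, fixed, etas, eta_names, sigma) -> np.ndarray:
        subject, _ = ctx
        pred = np.maximum(self._pred(ctx, fixed, etas, eta_names), 1e-6)
        y = subject.y[None, :]
        if self.residual_model == "lognormal":
            res = np.log(y) - np.log(pred)
            return np.sum(
                _LOG_2PI + np.log(sigma**2) + res**2 / sigma**2 + 2.0 * np.log(y),
                axis=1,
            )
        res = y - pred
        return np.sum(_LOG_2PI + np.log(sigma**2) + res**2 / sigma**2, axis=1)

    def predictions(self, ctx, fixed, eta, eta_names, sigma) -> np.ndarray:
        return self._pred(ctx, fixed, np.atleast_2d(eta), eta_names)[0]

    def simulate_obs(self, pred, sigma, rng):
        eps = rng.normal(0.0, sigma, size=pred.shape)
        if self.residual_model == "lognormal":
            return pred * np.exp(eps)
        return pred + eps


class _MOAASAdapter:
    name = "moaas"
    eta_candidates = MOAAS_PARAM_NAMES
    has_sigma = False
    baseline_names = ("b1", "b2", "b3", "b4", "b5")

    def fixed_names(self) -> list:
        return list(self.baseline_names) + list(MOAAS_PARAM_NAMES)

    def transforms(self) -> dict:
        tr = {n: "id" for n in self.baseline_names}
        tr.update({n: "log" for n in MOAAS_PARAM_NAMES})
        return tr

    def default_init(self, pop: MOAASModelParameters) -> tuple[dict, dict, float]:
        fixed = dict(zip(self.baseline_names, pop.baselines))
        fixed.update({n: getattr(pop, n) for n in MOAAS_PARAM_NAMES})
        return fixed, dict(pop.omega), None

    def _probs(self, ctx, fixed, etas, eta_names):
        subject, engine = ctx
        m = etas.shape[0]
        thetas = np.tile([fixed[n] for n in MOAAS_PARAM_NAMES], (m, 1))
        extra = np.zeros(m)
        for j, n in enumerate(eta_names):
            if n == "eta_logit":
                extra = etas[:, j]
            else:
                thetas[:, MOAAS_PARAM_NAMES.index(n)] *= np.exp(etas[:, j])
        pk = subject.pk_individual
        pk_thetas = np.tile([getattr(pk, n) for n in PK_PARAM_NAMES], (m, 1))
        _, ce = engine.conc(pk_thetas, ke0=thetas[:, 0])
        ke0, ic50, gam, imax = (thetas[:, j][:, None] for j in range(4))
        with np.errstate(all="ignore"):
            frac = ce**gam / (ic50**gam + ce**gam)
        shift = imax * np.where(np.isfinite(frac), frac, 1.0) + extra[:, None]
        baselines = np.array([fixed[n] for n in self.baseline_names])
        logits = baselines[None, None, :] + shift[:, :, None]  # (m, nt, 5)
        cum = np.concatenate(
            [expit(logits), np.ones(logits.shape[:-1] + (1,))], axis=-1
        )
        return cum

    def nll_batch(self, ctx, fixed, etas, eta_names, sigma=None) -> np.ndarray:
        subject, _ = ctx
        cum = self._probs(ctx, fixed, etas, eta_names)
        yi = subject.y.astype(int)
        nt = len(yi)
        ar = np.arange(nt)
        upper = cum[:, ar, yi]
        lower = np.where(yi > 0, cum[:, ar, np.maximum(yi - 1, 0)], 0.0)
        p = np.clip(upper - lower, 1e-300, 1.0)
        return -2.0 * np.sum(np.log(p), axis=1)

    def predictions(self, ctx, fixed, eta, eta_names, sigma=None) -> np.ndarray:
        # expected score, used only for residual-style diagnostics
        cum = self._probs(ctx, fixed, np.atleast_2d(eta), eta_names)[0]
        probs = np.diff(cum, axis=-1, prepend=0.0)
        return probs @ np.arange(6)


def _make_adapter(model: str, spec=None, init=None):
    if model == "pk":
        return _PKAdapter(spec)
    if model == "bis":
        residual = getattr(init, "residual_model", "lognormal")
        return _BISAdapter(residual)
    if model == "moaas":
        return _MOAASAdapter()
    raise ValidationError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Laplace engine
# ---------------------------------------------------------------------------


def _fd_points(eta: np.ndarray, h: float) -> np.ndarray:
    """Evaluation points for a full central-difference gradient + Hessian."""
    d = len(eta)
    pts = [eta]
    for j in range(d):
        e = np.zeros(d)
        e[j] = h
        pts += [eta + e, eta - e]
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ei[i] = h
            ej = np.zeros(d)
            ej[j] = h
            pts += [eta + ei + ej, eta + ei - ej, eta - ei + ej, eta - ei - ej]
    return np.array(pts)


def _grad_hess(f: np.ndarray, d: int, h: float):
    g = np.empty(d)
    hess = np.empty((d, d))
    for j in range(d):
        fp, fm = f[1 + 2 * j], f[2 + 2 * j]
        g[j] = (fp - fm) / (2 * h)
        hess[j, j] = (fp - 2 * f[0] + fm) / h**2
    idx = 1 + 2 * d
    for i in range(d):
        for j in range(i + 1, d):
            fpp, fpm, fmp, fmm = f[idx : idx + 4]
            idx += 4
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
    return g, hess


def _laplace_subject(
    m2_joint: Callable[[np.ndarray], np.ndarray],
    d: int,
    eta0: np.ndarray,
    gtol: float = 1e-4,
    max_iter: int = 60,
    h: float = 1e-3,
):
    """Minimise the joint -2 log density and apply the Laplace correction.

    Returns (neg2ll_contribution, eta_hat, flagged).
    """
    if d == 0:
        val = float(m2_joint(np.zeros((1, 0)))[0])
        return val, np.zeros(0), False
    eta = np.asarray(eta0, dtype=float).copy()
    f0 = float(m2_joint(eta[None, :])[0])
    if not np.isfinite(f0):
        eta = np.zeros(d)
        f0 = float(m2_joint(eta[None, :])[0])
    g = hess = None
    flagged = False
    for _ in range(max_iter):
        pts = _fd_points(eta, h)
        fvals = m2_joint(pts)
        f0 = float(fvals[0])
        g, hess = _grad_hess(fvals, d, h)
        if np.max(np.abs(g)) < gtol:
            break
        try:
            evals = np.linalg.eigvalsh(hess)
            ridge = max(0.0, 1e-6 - evals.min())
            step = np.linalg.solve(hess + ridge * np.eye(d), g)
        except np.linalg.LinAlgError:
            step = g / (np.abs(np.diag(hess)).max() + 1.0)
        big = np.max(np.abs(step))
        if big > 5.0:  # etas are O(1); cap runaway steps from flat regions
            step *= 5.0 / big
        moved = False
        for direction in (step, g / (np.linalg.norm(g) + 1e-30)):
            lam = 1.0
            for _ in range(12):
                # keep etas clear of the hard validity guard at |eta| = 35
                cand = np.clip(eta - lam * direction, -30.0, 30.0)
                fc = float(m2_joint(cand[None, :])[0])
                if np.isfinite(fc) and fc < f0 - 1e-12:
                    eta, f0, moved = cand, fc, True
                    break
                lam *= 0.5
            if moved:
                break
        if not moved:
            flagged = np.max(np.abs(g)) > 100.0 * gtol
            break
    else:
        flagged = True
    if hess is None:  # pragma: no cover - d >= 1 always enters the loop
        pts = _fd_points(eta, h)
        g, hess = _grad_hess(m2_joint(pts), d, h)
    # H of h = -log joint is half the Hessian of the -2 log joint
    half = hess / 2.0
    if not np.all(np.isfinite(half)):
        flagged = True
        evals = np.maximum(np.abs(np.where(np.isfinite(np.diag(half)), np.diag(half), 1.0)), 1e-10)
    else:
        try:
            evals = np.linalg.eigvalsh(half)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate Hessian
            flagged = True
            evals = np.maximum(np.abs(np.diag(half)), 1e-10)
        if np.any(evals <= 0):
            flagged = True
            evals = np.maximum(evals, 1e-10)
    neg2ll = f0 + float(np.sum(np.log(evals))) - d * _LOG_2PI
    return neg2ll, eta, flagged


def _subject_m2_joint(adapter, ctx, fixed, eta_names, omega_vec, sigma):
    """Joint -2 log density of (data, eta) as a batched callable."""
    log_prior_const = float(np.sum(np.log(2.0 * np.pi * omega_vec**2)))

    def m2(etas: np.ndarray) -> np.ndarray:
        etas = np.atleast_2d(etas)
        ok = np.all(np.abs(etas) < 35.0, axis=1)
        out = np.full(etas.shape[0], np.inf)
        if ok.any():
            nll = adapter.nll_batch(ctx, fixed, etas[ok], eta_names, sigma)
            if len(eta_names):
                prior = (
                    np.sum(etas[ok] ** 2 / omega_vec**2, axis=1) + log_prior_const
                )
            else:
                prior = 0.0
            out[ok] = nll + prior
        return out

    return m2


def _subject_contribution(adapter, ctx, fixed, omega, sigma, warm: dict):
    """Laplace contribution of one subject.

    ``warm`` supplies the starting point of the inner eta search.  During a
    population fit it holds the modes of the best outer point so far (not
    the last evaluated one): starting every finite-difference evaluation of
    a gradient group from the same modes keeps the objective a consistent
    function of the population parameters, which a last-point warm start
    does not (the leaked state corrupts the outer gradients).
    """
    eta_names = [n for n in adapter.eta_candidates if omega.get(n, 0.0) > 0]
    if getattr(adapter, "name", "") == "moaas" and omega.get("eta_logit", 0.0) > 0:
        eta_names = eta_names + ["eta_logit"]
    omega_vec = np.array([omega[n] for n in eta_names])
    m2 = _subject_m2_joint(adapter, ctx, fixed, eta_names, omega_vec, sigma)
    sid = ctx[0].subject_id
    eta0 = warm.get(sid, np.zeros(len(eta_names)))
    if len(eta0) != len(eta_names):
        eta0 = np.zeros(len(eta_names))
    val, eta_hat, flagged = _laplace_subject(m2, len(eta_names), eta0)
    if not np.isfinite(val):
        val = 1e10  # finite penalty for a failed subject
        flagged = True
    return val, eta_hat, eta_names, flagged


def marginal_loglik_continuous(
    subject: SubjectData,
    pop: PopulationPKParameters | BISModelParameters,
    model: str = "pk",
    spec: PKModelSpec | None = None,
) -> float:
    """Laplace -2 log marginal likelihood contribution of one subject
    (continuous endpoints: concentration or BIS)."""
    if len(subject.y) < 1:
        raise ValidationError("subject has no observations")
    adapter = _make_adapter(model, spec, pop)
    fixed, omega, sigma = adapter.default_init(pop)
    engine = _ProfileEngine(subject.regimen, subject.times)
    val, _, _, _ = _subject_contribution(adapter, (subject, engine), fixed, omega, sigma, {})
    return val


def marginal_loglik_categorical(
    subject: SubjectData, pop: MOAASModelParameters
) -> float:
    """Laplace -2 log marginal likelihood contribution of one subject
    (ordered-categorical MOAA/S endpoint)."""
    if len(subject.y) < 1:
        raise ValidationError("subject has no observations")
    adapter = _MOAASAdapter()
    fixed, omega, _ = adapter.default_init(pop)
    if pop.eta_sd > 0:
        omega["eta_logit"] = pop.eta_sd
    engine = _ProfileEngine(subject.regimen, subject.times)
    val, _, _, _ = _subject_contribution(adapter, (subject, engine), fixed, omega, None, {})
    return val


# ---------------------------------------------------------------------------
# population fit
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Result of a population fit.

    ``estimates`` holds fixed effects plus ``omega_<name>`` and ``sigma``
    on the natural scale; ``ebes`` maps subject id to its empirical Bayes
    eta estimates.  ``aic = ofv + 2 * n_parameters``.
    """

    model: str
    estimates: dict
    ofv: float
    n_parameters: int
    ebes: dict
    convergence: str
    n_iter: int
    ofv_trajectory: list = field(default_factory=list)
    se: dict | None = None
    rse: dict | None = None
    spec: object = None
    flagged_subjects: list = field(default_factory=list)
    _refit: Callable | None = field(default=None, repr=False)
    _context: dict = field(default_factory=dict, repr=False)

    @property
    def aic(self) -> float:
        return self.ofv + 2.0 * self.n_parameters

    def _omega_dict(self, names) -> dict:
        return {
            n: self.estimates.get(f"omega_{n}", 0.0)
            for n in names
            if self.estimates.get(f"omega_{n}", 0.0) > 0
        }

    def to_population(self):
        """Rebuild the population parameter object from the estimates."""
        e = self.estimates
        if self.model == "pk":
            return PopulationPKParameters(
                **{n: e[n] for n in PK_PARAM_NAMES},
                omega=self._omega_dict(PK_PARAM_NAMES),
                sigma_prop=e.get("sigma", 0.0),
            )
        if self.model == "bis":
            return BISModelParameters(
                **{n: e[n] for n in BIS_PARAM_NAMES},
                omega=self._omega_dict(BIS_PARAM_NAMES),
                sigma_resid=e.get("sigma", 0.0),
                residual_model=self._context.get("residual_model", "lognormal"),
            )
        if self.model == "moaas":
            return MOAASModelParameters(
                baselines=tuple(e[n] for n in ("b1", "b2", "b3", "b4", "b5")),
                **{n: e[n] for n in MOAAS_PARAM_NAMES},
                omega=self._omega_dict(MOAAS_PARAM_NAMES),
            )
        raise ValidationError(f"unknown model {self.model!r}")

    def individual_pk_parameters(self) -> dict:
        """Per-subject PK parameters at the empirical Bayes etas."""
        if self.model != "pk":
            raise ValidationError("EBE-based PK parameters require a PK fit")
        pop = self.to_population()
        out = {}
        for sid, eta in self.ebes.items():
            out[sid] = IndividualPKParameters.from_population(pop, eta)
        return out


@dataclass(frozen=True)
class CovariateTestResult:
    """Likelihood-ratio test of a covariate inclusion."""

    delta_ofv: float
    df: int
    significance_level: float | None  # attained among 0.05 / 0.01 / 0.001


def covariate_lrt(ofv_base: float, ofv_extended: float, df: int = 1) -> CovariateTestResult:
    """Likelihood-ratio test: OFV drop against chi-square thresholds.

    For df = 1 the thresholds are the classical 3.84 / 6.63 / 10.83 at the
    0.05 / 0.01 / 0.001 levels; for df > 1 the corresponding chi-square
    quantiles are used.  A negative drop is classified not significant.
    """
    if df < 1:
        raise ValidationError("df must be >= 1")
    delta = ofv_base - ofv_extended
    if delta < 0:
        warnings.warn("extended model has higher OFV than base; not significant")
        return CovariateTestResult(delta, df, None)
    if df == 1:
        thresholds = [(10.83, 0.001), (6.63, 0.01), (3.84, 0.05)]
    else:
        thresholds = [(chi2.ppf(1 - a, df), a) for a in (0.001, 0.01, 0.05)]
    for thr, level in thresholds:
        if delta >= thr - 1e-9:
            return CovariateTestResult(delta, df, level)
    return CovariateTestResult(delta, df, None)


def _pack_free(fixed, omega, sigma, transforms, fix):
    free = []
    for n, v in fixed.items():
        if n not in fix:
            free.append(("fixed", n, transforms[n]))
    for n, w in omega.items():
        if w > 0 and f"omega_{n}" not in fix:
            free.append(("omega", n, "log"))
    if sigma is not None and sigma > 0 and "sigma" not in fix:
        free.append(("sigma", "sigma", "log"))
    return free


def _to_x(free, fixed, omega, sigma):
    x = []
    for kind, n, tr in free:
        v = fixed[n] if kind == "fixed" else (omega[n] if kind == "omega" else sigma)
        x.append(math.log(v) if tr == "log" else v)
    return np.array(x)


def _from_x(free, x, fixed0, omega0, sigma0):
    fixed = dict(fixed0)
    omega = dict(omega0)
    sigma = sigma0
    for (kind, n, tr), xi in zip(free, x):
        v = math.exp(min(xi, 50.0)) if tr == "log" else xi
        if kind == "fixed":
            fixed[n] = v
        elif kind == "omega":
            omega[n] = v
        else:
            sigma = v
    return fixed, omega, sigma


def fit_population(
    table: ObservationTable,
    model: str,
    init,
    fix: Sequence[str] = (),
    spec: PKModelSpec | None = None,
    individual_pk: Mapping | None = None,
    include_bql: bool = False,
    n_starts: int = 1,
    jitter_sd: float = 0.1,
    rng_seed: int = 0,
    maxiter: int = 200,
    compute_se: bool = False,
    verbose: bool = False,
    optimizer_options: Mapping | None = None,
) -> FitResult:
    """Maximum-likelihood population fit of one sub-model.

    Parameters
    ----------
    model : "pk", "bis" or "moaas".
    init : population parameter object providing starting values; omega
        entries > 0 define which parameters carry random effects.
    fix : parameter names to hold at their initial value (fixed effects,
        ``omega_<name>``, ``sigma``).
    individual_pk : subject id -> :class:`IndividualPKParameters`,
        required by the PD models (two-stage conditioning).
    n_starts : number of optimiser starts; starts beyond the first jitter
        the initial log-parameters by ``jitter_sd``.
    """
    adapter = _make_adapter(model, spec, init)
    if model in ("bis", "moaas") and individual_pk is None:
        raise ValidationError("PD fits require individual PK parameters (two-stage)")
    subjects = prepare_subjects(table, model, individual_pk, include_bql)
    if not subjects:
        raise ValidationError(f"no usable {model} observations in the table")
    contexts = [(s, _ProfileEngine(s.regimen, s.times)) for s in subjects]

    fixed0, omega0, sigma0 = adapter.default_init(init)
    if model == "moaas" and getattr(init, "eta_sd", 0.0) > 0:
        omega0["eta_logit"] = init.eta_sd
    transforms = adapter.transforms()
    free = _pack_free(fixed0, omega0, sigma0, transforms, set(fix))
    if not free:
        raise ValidationError("no free parameters to estimate")
    x0 = _to_x(free, fixed0, omega0, sigma0)

    warm: dict = {}
    ebe_store: dict = {}
    flagged_store: set = set()
    trajectory: list = []

    best_total = [np.inf]

    def objective(x: np.ndarray) -> float:
        fixed, omega, sigma = _from_x(free, x, fixed0, omega0, sigma0)
        total = 0.0
        modes = {}
        flags = set()
        for ctx in contexts:
            val, eta_hat, eta_names, flagged = _subject_contribution(
                adapter, ctx, fixed, omega, sigma, warm
            )
            total += val
            modes[ctx[0].subject_id] = (eta_names, eta_hat)
            if flagged:
                flags.add(ctx[0].subject_id)
        if total < best_total[0]:
            # keep the warm-start modes pinned to the best point seen so far
            best_total[0] = total
            warm.clear()
            warm.update({sid: eta for sid, (_, eta) in modes.items()})
            ebe_store.clear()
            ebe_store.update(
                {sid: dict(zip(names, eta)) for sid, (names, eta) in modes.items()}
            )
            flagged_store.clear()
            flagged_store.update(flags)
            trajectory.append(total)
        return total

    rng = np.random.default_rng(rng_seed)
    best = None
    for start in range(max(1, n_starts)):
        xs = x0 if start == 0 else x0 + rng.normal(0.0, jitter_sd, size=len(x0))
        warm.clear()
        options = {"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-5, "eps": 1e-4}
        options.update(optimizer_options or {})
        res = optimize.minimize(
            objective, xs, method="L-BFGS-B", options=options
        )
        if verbose:
            print(f"start {start}: ofv={res.fun:.4f} nit={res.nit} {res.message}")
        if best is None or res.fun < best.fun:
            best = res
    # re-evaluate at the returned optimum (stores already pin the best point)
    ofv = objective(best.x)
    ofv = min(ofv, best_total[0])
    fixed, omega, sigma = _from_x(free, best.x, fixed0, omega0, sigma0)

    estimates = dict(fixed)
    estimates.update({f"omega_{n}": w for n, w in omega.items() if w > 0})
    if sigma is not None:
        estimates["sigma"] = sigma

    se = rse = None
    if compute_se:
        se, rse = _standard_errors(objective, best.x, free, estimates)

    converged = bool(best.success) and all(
        s not in flagged_store for s in ebe_store
    )

    def refit(param: str, value: float) -> float:
        tr = dict(
            [(n, t) for _, n, t in free]
        )
        if tr.get(param) == "log" and value <= 0:
            return float("inf")
        # start the profiled refit from the current optimum
        f2, o2, s2 = dict(fixed), dict(omega), sigma
        if param == "sigma":
            s2 = value
        elif param.startswith("omega_"):
            o2[param[6:]] = value
        else:
            f2[param] = value
        sub = fit_population(
            table,
            model,
            init=_rebuild_init(model, init, f2, o2, s2),
            fix=tuple(set(fix) | {param}),
            spec=spec,
            individual_pk=individual_pk,
            include_bql=include_bql,
            maxiter=maxiter,
            rng_seed=rng_seed,
        )
        return sub.ofv

    result = FitResult(
        model=model,
        estimates=estimates,
        ofv=float(ofv),
        n_parameters=len(free),
        ebes=dict(ebe_store),
        convergence="converged" if converged else "not converged (best iterate)",
        n_iter=int(best.nit),
        ofv_trajectory=trajectory,
        se=se,
        rse=rse,
        spec=spec,
        flagged_subjects=sorted(flagged_store, key=str),
        _refit=refit,
        _context={
            "subjects": subjects,
            "adapter": adapter,
            "individual_pk": individual_pk,
            "residual_model": getattr(adapter, "residual_model", None),
            "free": free,
            "fixed": fixed,
            "omega": omega,
            "sigma": sigma,
        },
    )
    return result


def _rebuild_init(model, init, fixed, omega, sigma):
    """Population parameter object with updated values (for refits)."""
    omega_pos = {k: v for k, v in omega.items() if v > 0 and k != "eta_logit"}
    if model == "pk":
        return PopulationPKParameters(
            **{n: fixed[n] for n in PK_PARAM_NAMES},
            omega=omega_pos,
            sigma_prop=sigma if sigma is not None else 0.0,
        )
    if model == "bis":
        return BISModelParameters(
            **{n: fixed[n] for n in BIS_PARAM_NAMES},
            omega=omega_pos,
            sigma_resid=sigma if sigma is not None else 0.0,
            residual_model=getattr(init, "residual_model", "lognormal"),
        )
    return MOAASModelParameters(
        baselines=tuple(fixed[n] for n in ("b1", "b2", "b3", "b4", "b5")),
        **{n: fixed[n] for n in MOAAS_PARAM_NAMES},
        omega=omega_pos,
        eta_sd=omega.get("eta_logit", 0.0),
    )


def _standard_errors(objective, x_opt, free, estimates):
    """Central-difference Hessian of the OFV; delta method to natural scale."""
    n = len(x_opt)
    h = 1e-4
    hess = np.empty((n, n))
    f0 = objective(x_opt)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x_opt.copy()
                xp[i] += h
                xm = x_opt.copy()
                xm[i] -= h
                hess[i, i] = (objective(xp) - 2 * f0 + objective(xm)) / h**2
            else:
                vals = []
                for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    xx = x_opt.copy()
                    xx[i] += si * h
                    xx[j] += sj * h
                    vals.append(objective(xx))
                hess[i, j] = hess[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                    4 * h**2
                )
    # -2LL Hessian: covariance = 2 * H^{-1}
    try:
        cov = 2.0 * np.linalg.inv(hess)
        sd_x = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        sd_x = np.full(n, np.nan)
    se, rse = {}, {}
    for (kind, name, tr), s in zip(free, sd_x):
        key = name if kind == "fixed" else (f"omega_{name}" if kind == "omega" else "sigma")
        est = estimates[key]
        if tr == "log":
            se[key] = abs(est) * s
            rse[key] = 100.0 * s
        else:
            se[key] = s
            rse[key] = 100.0 * s / abs(est) if est != 0 else float("inf")
    return se, rse


def evaluate_population(
    table: ObservationTable,
    model: str,
    params,
    spec: PKModelSpec | None = None,
    individual_pk: Mapping | None = None,
    include_bql: bool = False,
) -> FitResult:
    """OFV and EBEs of a model at fixed population parameters (no fitting).

    Useful for likelihood evaluation of a published model on a dataset and
    for simulation-based diagnostics (VPC) of a known model.
    """
    adapter = _make_adapter(model, spec, params)
    if model in ("bis", "moaas") and individual_pk is None:
        raise ValidationError("PD evaluation requires individual PK parameters")
    subjects = prepare_subjects(table, model, individual_pk, include_bql)
    if not subjects:
        raise ValidationError(f"no usable {model} observations in the table")
    fixed, omega, sigma = adapter.default_init(params)
    if model == "moaas" and getattr(params, "eta_sd", 0.0) > 0:
        omega["eta_logit"] = params.eta_sd
    warm: dict = {}
    total = 0.0
    ebes: dict = {}
    flagged: list = []
    for s in subjects:
        ctx = (s, _ProfileEngine(s.regimen, s.times))
        val, eta_hat, eta_names, flag = _subject_contribution(
            adapter, ctx, fixed, omega, sigma, warm
        )
        total += val
        ebes[s.subject_id] = dict(zip(eta_names, eta_hat))
        if flag:
            flagged.append(s.subject_id)
    estimates = dict(fixed)
    estimates.update({f"omega_{n}": w for n, w in omega.items() if w > 0})
    if sigma is not None:
        estimates["sigma"] = sigma
    return FitResult(
        model=model,
        estimates=estimates,
        ofv=float(total),
        n_parameters=0,
        ebes=ebes,
        convergence="evaluated",
        n_iter=0,
        flagged_subjects=flagged,
        spec=spec,
        _context={
            "subjects": subjects,
            "adapter": adapter,
            "individual_pk": individual_pk,
            "residual_model": getattr(adapter, "residual_model", None),
            "free": [],
            "fixed": fixed,
            "omega": omega,
            "sigma": sigma,
        },
    )


def two_stage_pd_fit(
    table: ObservationTable,
    pk_fit: FitResult,
    pd_model: str,
    init,
    fix: Sequence[str] = (),
    **kwargs,
) -> FitResult:
    """Stage-2 PD fit conditioning on the stage-1 individual kinetics.

    Each subject's plasma/effect-site profile is computed from their
    empirical Bayes PK parameters (held fixed); the PD population
    parameters are then estimated by the same Laplace machinery.
    """
    if pd_model not in ("bis", "moaas"):
        raise ValidationError("pd_model must be 'bis' or 'moaas'")
    individual_pk = pk_fit.individual_pk_parameters()
    pd_subjects = prepare_subjects(table, pd_model)
    if not pd_subjects:
        raise ValidationError(f"no {pd_model} observations to fit")
    missing = [s.subject_id for s in pd_subjects if s.subject_id not in individual_pk]
    if missing:
        raise ValidationError(
            f"subjects missing from the PK fit: {missing}"
        )
    return fit_population(
        table, pd_model, init=init, fix=fix, individual_pk=individual_pk, **kwargs
    )


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileCI:
    """Profile-likelihood confidence interval for one parameter."""

    parameter: str
    estimate: float
    lower: float
    upper: float
    level: float
    open_lower: bool = False
    open_upper: bool = False


def profile_ci(
    fit: FitResult,
    param: str,
    level: float = 0.95,
    rel_tol: float = 1e-3,
    max_se_range: float = 10.0,
) -> ProfileCI:
    """Confidence interval from log-likelihood profiling.

    Each bound is the parameter value at which the re-optimised OFV rises
    by the chi-square(1) quantile (3.84 at 95%), found by bisection.  If a
    bound is not bracketed within ``max_se_range`` standard errors the
    interval is flagged open on that side.
    """
    if fit._refit is None:
        raise ValidationError("fit does not support refitting")
    est = fit.estimates[param]
    target = fit.ofv + chi2.ppf(level, 1)
    scale = None
    if fit.se and param in fit.se and np.isfinite(fit.se[param]) and fit.se[param] > 0:
        scale = fit.se[param]
    if scale is None:
        scale = 0.1 * max(abs(est), 1e-3)

    def bound(direction: int):
        step = scale
        inner = est
        while step <= max_se_range * scale:
            v = est + direction * step
            if fit._refit(param, v) >= target:
                outer = v
                break
            inner = v
            step *= 2.0
        else:
            return direction * math.inf, True
        while abs(outer - inner) > rel_tol * max(abs(est), scale):
            mid = 0.5 * (inner + outer)
            if fit._refit(param, mid) >= target:
                outer = mid
            else:
                inner = mid
        return 0.5 * (inner + outer), False

    lo, open_lo = bound(-1)
    hi, open_hi = bound(+1)
    return ProfileCI(param, est, lo, hi, level, open_lo, open_hi)


def screen_covariates(
    table: ObservationTable,
    init,
    candidates: Sequence[tuple] = None,
    alpha: float = 0.01,
    base_fit: FitResult | None = None,
    **fit_kwargs,
) -> list:
    """One-at-a-time covariate screening on the PK model by LRT.

    ``candidates`` are (parameter, covariate, form) triples; each is added
    to the base model in turn and judged by the OFV drop at ``alpha``
    (forward-inclusion style, matching a 6.63-point threshold at 0.01).
    Returns a list of dicts with the candidate, the extended fit's OFV and
    the :class:`CovariateTestResult`.
    """
    if candidates is None:
        candidates = [("cl", "weight", "power"), ("v1", "weight", "power")]
    if base_fit is None:
        base_fit = fit_population(table, "pk", init=init, **fit_kwargs)
    results = []
    for cand in candidates:
        spec = PKModelSpec(covariates=(cand,))
        ext = fit_population(table, "pk", init=init, spec=spec, **fit_kwargs)
        test = covariate_lrt(base_fit.ofv, ext.ofv, df=1)
        results.append(
            {
                "candidate": cand,
                "ofv_base": base_fit.ofv,
                "ofv_extended": ext.ofv,
                "test": test,
                "significant": test.significance_level is not None
                and test.significance_level <= alpha,
            }
        )
    results.sort(key=lambda r: -r["test"].delta_ofv)
    return results
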
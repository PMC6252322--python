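"""Sigmoid inhibitory Emax model linking effect-site concentration to BIS.

    BIS(Ce) = E0 - Imax * Ce^gamma / (IC50^gamma + Ce^gamma)

E0 is the awake baseline, Imax the maximal achievable reduction, IC50 the
effect-site concentration at half-maximal reduction and gamma the Hill
coefficient.  Hysteresis between plasma and effect is carried entirely by
the effect compartment (ke0) in :mod:`remipkpd.kinetics`.

Residual error is modelled multiplicatively by default, y = BIS * exp(eps):
the reported residual SD (~0.065) is far too small to be additive on the
0-100 BIS scale but is a plausible ~6.5% CV, and a strictly additive
variant is available via ``residual_model="additive"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .kinetics import KineticProfile
from .trial_data import ValidationError

__all__ = [
    "BIS_PARAM_NAMES",
    "BISModelParameters",
    "bis_response",
    "simulate_bis",
    "equilibration_half_life",
    "sample_bis_individuals",
]

BIS_PARAM_NAMES = ("ke0", "ic50", "gamma", "e0", "imax")


@dataclass(frozen=True)
class BISModelParameters:
    """Population parameters of the BIS model.

    ``omega`` maps parameter name to log-scale IIV SD; ``sigma_resid`` is
    the residual SD (log scale for the default multiplicative model).
    """

    ke0: float
    ic50: float
    gamma: float
    e0: float
    imax: float
    omega: Mapping[str, float] = field(default_factory=dict)
    sigma_resid: float = 0.0
    residual_model: str = "lognormal"

    def __post_init__(self) -> None:
        for name in ("ke0", "ic50", "gamma", "imax"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.e0 <= 100:
            raise ValidationError("e0 must be in (0, 100]")
        if self.e0 - self.imax < 0:
            raise ValidationError("e0 - imax must be >= 0")
        for name, w in self.omega.items():
            if name not in BIS_PARAM_NAMES:
                raise ValidationError(f"unknown omega entry {name!r}")
            if w < 0:
                raise ValidationError(f"omega[{name!r}] must be >= 0")
        if self.sigma_resid < 0:
            raise ValidationError("sigma_resid must be >= 0")
        if self.residual_model not in ("lognormal", "additive"):
            raise ValidationError("residual_model must be 'lognormal' or 'additive'")

    def individual(self, eta: Mapping[str, float]) -> "BISModelParameters":
        values = {n: getattr(self, n) * math.exp(eta.get(n, 0.0)) for n in BIS_PARAM_NAMES}
        return BISModelParameters(
            **values, sigma_resid=self.sigma_resid, residual_model=self.residual_model
        )


def bis_response(ce, p: BISModelParameters) -> np.ndarray | float:
    """BIS as a function of effect-site concentration (vectorised)."""
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0):
        raise ValidationError("ce must be non-negative")
    frac = ce_arr**p.gamma / (p.ic50**p.gamma + ce_arr**p.gamma)
    out = p.e0 - p.imax * frac
    return out if out.ndim else float(out)


def equilibration_half_life(ke0: float) -> float:
    """Plasma/effect-site equilibration half-life ln(2)/ke0, minutes."""
    if not ke0 > 0:
        raise ValidationError("ke0 must be positive")
    return math.log(2.0) / ke0


def sample_bis_individuals(
    pop: BISModelParameters,
    n: int,
    rng: np.random.Generator | int | None = None,
    max_retries: int = 100,
) -> list:
    """Sample ``n`` individual parameter sets with log-normal IIV.

    The physical constraint E0 - Imax >= 0 (BIS cannot go negative) is
    enforced by redrawing violating individuals, up to ``max_retries``
    attempts each.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(rng)
    out = []
    for _ in range(n):
        for attempt in range(max_retries + 1):
            eta = {k: rng.normal(0.0, w) if w > 0 else 0.0 for k, w in pop.omega.items()}
            try:
                out.append(pop.individual(eta))
                break
            except ValidationError:
                if attempt == max_retries:
                    raise ValidationError(
                        "could not sample individual satisfying e0 - imax >= 0"
                    )
    return out


def simulate_bis(
    ce_source: KineticProfile | Callable[[float], np.ndarray],
    pop: BISModelParameters,
    n: int = 1,
    rng: np.random.Generator | int | None = None,
    with_residual: bool = False,
) -> tuple[np.ndarray, list]:
    """Simulate per-subject BIS curves.

    ``ce_source`` supplies the effect-site concentration track for a given
    individual ke0: either a callable ``ke0 -> Ce array`` (required whenever
    ke0 carries IIV, since each subject then needs its own track) or a
    :class:`KineticProfile` already holding the matching ke0 track.

    Returns ``(curves, individuals)`` where ``curves`` has shape (n, nt).
    Residual noise (per the population ``residual_model``) is added only
    when ``with_residual`` is set.
    """
    rng = np.random.default_rng(rng)
    individuals = sample_bis_individuals(pop, n, rng)

    def track(ke0: float) -> np.ndarray:
        if callable(ce_source):
            return np.asarray(ce_source(ke0), dtype=float)
        if float(ke0) not in ce_source.ce:
            raise ValidationError(
                f"profile has no effect-site track for ke0={ke0}; "
                "pass a callable ce_source when ke0 varies between subjects"
            )
        return ce_source.ce_for(ke0)

    curves = []
    for ind in individuals:
        bis = np.asarray(bis_response(track(ind.ke0), ind), dtype=float)
        if with_residual and pop.sigma_resid > 0:
            eps = rng.normal(0.0, pop.sigma_resid, size=bis.shape)
            if pop.residual_model == "lognormal":
                bis = bis * np.exp(eps)
            else:
                bis = bis + eps
        curves.append(bis)
    return np.array(curves), individuals
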
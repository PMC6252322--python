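"""Cumulative-logit (proportional odds) model for MOAA/S scores.

MOAA/S is an ordinal depth-of-sedation score from 5 (fully alert, responds
readily to name) down to 0 (no response to painful stimulus).  The model
places a logit on each cumulative probability P(score <= k), k = 0..4,

    logit_k(Ce) = B_k + Imax * Ce^gamma / (IC50^gamma + Ce^gamma) + eta

with P(score <= 5) = 1 by construction.  The drug term is shared across
categories (proportional odds), so the ordering B1 < ... < B5 guarantees
monotone cumulative probabilities and non-negative per-category
probabilities at any concentration.

The published parameterisation reports IIV on ke0, IC50, gamma and Imax
(log-normal), which is the default here; an additional additive logit eta
(the literal reading of the model equation) is available through
``eta_sd`` and the ``eta`` argument but defaults to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .trial_data import ValidationError

__all__ = [
    "MOAAS_PARAM_NAMES",
    "MOAASModelParameters",
    "cumulative_logits",
    "category_probabilities",
    "sample_scores",
    "prob_score_below",
    "sample_moaas_individuals",
    "drug_effect",
]

MOAAS_PARAM_NAMES = ("ke0", "ic50", "gamma", "imax")


@dataclass(frozen=True)
class MOAASModelParameters:
    """Population parameters of the MOAA/S cumulative-logit model.

    ``baselines`` are the category logits B1..B5 for P(score<=0)..P(score<=4)
    at zero concentration; they must be strictly increasing.
    """

    baselines: Sequence[float]
    ke0: float
    ic50: float
    gamma: float
    imax: float
    omega: Mapping[str, float] = field(default_factory=dict)
    eta_sd: float = 0.0

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.baselines)
        object.__setattr__(self, "baselines", b)
        if len(b) != 5:
            raise ValidationError("exactly five baseline logits B1..B5 required")
        if any(y <= x for x, y in zip(b, b[1:])):
            raise ValidationError("baselines must be strictly increasing (B1<...<B5)")
        for name in MOAAS_PARAM_NAMES:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        for name, w in self.omega.items():
            if name not in MOAAS_PARAM_NAMES:
                raise ValidationError(f"unknown omega entry {name!r}")
            if w < 0:
                raise ValidationError(f"omega[{name!r}] must be >= 0")
        if self.eta_sd < 0:
            raise ValidationError("eta_sd must be >= 0")

    def individual(self, eta: Mapping[str, float]) -> "MOAASModelParameters":
        values = {
            n: getattr(self, n) * math.exp(eta.get(n, 0.0)) for n in MOAAS_PARAM_NAMES
        }
        return MOAASModelParameters(baselines=self.baselines, **values)


def sample_moaas_individuals(
    pop: MOAASModelParameters,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> list:
    """Sample ``n`` individual parameter sets with log-normal IIV."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(rng)
    out = []
    for _ in range(n):
        eta = {k: rng.normal(0.0, w) if w > 0 else 0.0 for k, w in pop.omega.items()}
        out.append(pop.individual(eta))
    return out


def drug_effect(ce, p: MOAASModelParameters) -> np.ndarray:
    """Sigmoid Emax drug term added to every cumulative logit."""
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0):
        raise ValidationError("ce must be non-negative")
    return p.imax * ce_arr**p.gamma / (p.ic50**p.gamma + ce_arr**p.gamma)


def cumulative_logits(ce, p: MOAASModelParameters, eta: float = 0.0) -> np.ndarray:
    """Logits of P(score <= k), k = 0..4; shape (..., 5).

    The same drug + eta term shifts every category, preserving ordering.
    """
    shift = drug_effect(ce, p) + eta
    return np.asarray(p.baselines) + np.asarray(shift)[..., None]


def category_probabilities(logits) -> np.ndarray:
    """Per-category probabilities P(score = k), k = 0..5; shape (..., 6).

    Cumulative probabilities are the logistic transform of the five logits,
    with P(score <= 5) = 1; category probabilities follow by differencing.
    """
    logits = np.asarray(logits, dtype=float)
    if logits.shape[-1] != 5:
        raise ValidationError("expected 5 cumulative logits in the last axis")
    if np.any(np.diff(logits, axis=-1) <= 0):
        raise ValidationError(
            "cumulative logits must be strictly increasing (else probabilities "
            "would be negative)"
        )
    cum = np.concatenate(
        [expit(logits), np.ones(logits.shape[:-1] + (1,))], axis=-1
    )
    probs = np.diff(cum, axis=-1, prepend=0.0)
    return np.clip(probs, 0.0, 1.0)


def sample_scores(
    probs: np.ndarray, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Independent categorical draws of scores 0..5 from (..., 6) probabilities."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape[-1] != 6:
        raise ValidationError("expected 6 category probabilities in the last axis")
    if np.any(probs < -1e-12) or np.any(np.abs(probs.sum(axis=-1) - 1.0) > 1e-9):
        raise ValidationError("probabilities must be non-negative and sum to 1")
    rng = np.random.default_rng(rng)
    cum = np.cumsum(probs, axis=-1)
    u = rng.random(probs.shape[:-1] + (1,))
    return (u > cum[..., :-1]).sum(axis=-1)


def prob_score_below(probs: np.ndarray, threshold: int) -> np.ndarray:
    """P(score < threshold) over time, e.g. threshold 2 -> P0 + P1."""
    if not 1 <= int(threshold) <= 5 or threshold != int(threshold):
        raise ValidationError("threshold must be an integer in 1..5")
    probs = np.asarray(probs, dtype=float)
    if probs.shape[-1] != 6:
        raise ValidationError("expected 6 category probabilities in the last axis")
    return probs[..., : int(threshold)].sum(axis=-1)
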
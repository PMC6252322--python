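"""Published final population PK/PD parameter estimates for HR7056.

These are the fixed effects, inter-individual variabilities (log-scale SDs,
numerically the reported CV fractions) and residual errors of the final
models from the first-in-human ascending-dose study in Chinese healthy
volunteers.  They serve both as data-generating truth for the synthetic
trial generator and as inputs to the Monte-Carlo regimen simulator.
"""

from __future__ import annotations

from .kinetics import PopulationPKParameters
from .pd_bis import BISModelParameters
from .pd_moaas import MOAASModelParameters

__all__ = ["published_pk", "published_bis", "published_moaas"]


def published_pk() -> PopulationPKParameters:
    """Final three-compartment PK model (volumes L, clearances L min^-1)."""
    return PopulationPKParameters(
        v1=2.11,
        cl=1.49,
        v2=10.5,
        q2=0.96,
        v3=22.7,
        q3=0.27,
        omega={
            "v1": 0.140,
            "cl": 0.115,
            "v2": 0.122,
            "q2": 0.133,
            "v3": 0.253,
            "q3": 0.187,
        },
        sigma_prop=0.138,
    )


def published_bis() -> BISModelParameters:
    """Final sigmoid inhibitory Emax model for BIS."""
    return BISModelParameters(
        ke0=0.0855,
        ic50=503.0,
        gamma=1.50,
        e0=95.3,
        imax=47.9,
        omega={
            "ke0": 0.512,
            "ic50": 0.411,
            "gamma": 0.864,
            "e0": 0.0156,
            "imax": 0.156,
        },
        sigma_resid=0.0653,
    )


def published_moaas() -> MOAASModelParameters:
    """Final cumulative-logit (proportional odds) model for MOAA/S."""
    return MOAASModelParameters(
        baselines=(-8.52, -2.44, -1.30, -1.15, -0.895),
        ke0=0.05,
        ic50=436.0,
        gamma=1.50,
        imax=27.9,
        omega={
            "ke0": 0.383,
            "ic50": 0.455,
            "gamma": 0.556,
            "imax": 0.176,
        },
    )
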
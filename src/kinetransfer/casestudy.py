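"""The in-silico yeast fermentation case study.

Batch fermentation of biomass X, substrate S (glucose) and product P
(astaxanthin).  Three model levels are provided:

* :func:`source_model` — Monod growth with growth-associated and
  growth-independent product formation (the detailed-but-wrong prior):

  .. math::
     dX/dt = \\mu X,\\quad dS/dt = -Y_S \\mu X,\\quad
     dP/dt = Y_P \\mu X + \\beta X,\\quad \\mu = \\mu_m S/(S+K_S)

* :func:`target_model` — the ground truth for the target strain: Contois
  growth :math:`\\mu = \\mu_m S/(S+K_S X)`, endogenous biomass decay
  :math:`-\\mu_d X`, and product reversal :math:`-k_d X^2` under
  substrate-limiting conditions.

* :func:`low_prior_model` — only the generic structure (growth, consumption
  and formation all proportional to biomass, :math:`\\mu = \\mu_m S`).

The specific growth rate μ is declared as a shared rate — one expression
referenced by all three balances — which the structure-adaptation machinery
treats as a fourth equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import KineticModel, loads_model

__all__ = [
    "CaseStudyParameters",
    "SOURCE_PARAMS",
    "TARGET_PARAMS",
    "source_model",
    "target_model",
    "low_prior_model",
    "Y0_RANGES",
    "HORIZON_H",
    "SAMPLE_INTERVAL_H",
    "NOISE_SD",
]

#: batch horizon and sampling interval (hours); samples land on the 14 h
#: grid 0, 14, ..., 140 while integration runs to 144 h
HORIZON_H = 144.0
SAMPLE_INTERVAL_H = 14.0

#: multiplicative observation noise, s.d. as a fraction of the true value
NOISE_SD = 0.05

#: initial-condition design box (g/L): biomass, substrate, product
Y0_RANGES = {"X": (0.1, 0.5), "S": (1.0, 10.0), "P": (0.0, 0.0)}

#: source-domain kinetic parameters
SOURCE_PARAMS = {"mu_m": 0.1, "K_S": 10.0, "Y_S": 1.0, "Y_P": 0.5, "beta": 0.003}

#: target-domain (ground-truth) kinetic parameters
TARGET_PARAMS = {"mu_m": 0.1, "K_S": 5.0, "mu_d": 0.1, "Y_S": 1.0, "Y_P": 0.5,
                 "beta": 0.05, "k_d": 0.07}

_UNITS = {"mu_m": "1/h", "K_S": "g/L", "mu_d": "1/h", "Y_S": "g/g", "Y_P": "g/g",
          "beta": "1/h", "k_d": "L/(g h)"}


@dataclass(frozen=True)
class CaseStudyParameters:
    """Bundle of the published source and target parameter sets."""

    source: dict[str, float] = field(default_factory=lambda: dict(SOURCE_PARAMS))
    target: dict[str, float] = field(default_factory=lambda: dict(TARGET_PARAMS))

    def __post_init__(self) -> None:
        for name, value in {**self.source, **self.target}.items():
            if value <= 0:
                raise ValueError(f"kinetic parameter {name} must be positive")


_SOURCE_TEXT = """
param mu_m = 0.1   [1/h]
param K_S  = 10.0  [g/L]
param Y_S  = 1.0   [g/g]
param Y_P  = 0.5   [g/g]
param beta = 0.003 [1/h]
rate mu = mu_m*S/(S + K_S)
dX/dt = mu*X
dS/dt = -Y_S*mu*X
dP/dt = Y_P*mu*X + beta*X
"""

_TARGET_TEXT = """
param mu_m = 0.1  [1/h]
param K_S  = 5.0  [g/L]
param mu_d = 0.1  [1/h]
param Y_S  = 1.0  [g/g]
param Y_P  = 0.5  [g/g]
param beta = 0.05 [1/h]
param k_d  = 0.07 [L/(g h)]
rate mu = mu_m*S/(S + K_S*X)
dX/dt = mu*X - mu_d*X
dS/dt = -Y_S*mu*X
dP/dt = Y_P*mu*X + beta*X - k_d*X*X
"""

_LOW_PRIOR_TEXT = """
param mu_m = 0.1 [1/h]
param Y_S  = 1.0 [g/g]
param Y_P  = 0.5 [g/g]
rate mu = mu_m*S
dX/dt = mu*X
dS/dt = -Y_S*mu*X
dP/dt = Y_P*mu*X
"""


def source_model() -> KineticModel:
    """Monod-kinetics source model (high-prior scenario)."""
    return loads_model(_SOURCE_TEXT)


def target_model() -> KineticModel:
    """Ground-truth Contois model with decay and product reversal."""
    return loads_model(_TARGET_TEXT)


def low_prior_model() -> KineticModel:
    """Minimal generic structure (low-prior scenario)."""
    return loads_model(_LOW_PRIOR_TEXT)
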
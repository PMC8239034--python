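"""Interference competition between larvae in a multiparasitized host.

The contest between the two larvae is modelled as a Thurstone /
Bradley–Terry paired comparison: each species carries a latent
competitive strength μ with deviation σ, species 1's strength is fixed
at 0 and its deviation at 1 (the interval scale's origin and unit), and
arriving first shifts a species' strength by its first-arrival term h.
The probability that the first-arriving species' offspring emerges is

    w₁₂ = link( (s_first − s_second) / sqrt(σ_first² + σ_second²) ),

with s the effective strengths and link the standard-normal CDF
(Thurstone, default) or the logistic function (Bradley–Terry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr


@dataclass(frozen=True)
class CompetitionParams:
    """Pairwise-contest parameters; species 1 is the reference species.

    mu2, sigma2 : competitive strength and deviation of species 2 on the
        interval scale anchored at species 1 (μ₁ = 0, σ₁ = 1)
    h1, h2 : first-arrival terms added to the arriving-first species'
        strength (negative values = first-arrival disadvantage)
    link : "probit" (Thurstone) or "logit" (Bradley–Terry)
    """

    mu2: float = 0.0
    sigma2: float = 1.0
    h1: float = 0.0
    h2: float = 0.0
    link: str = "probit"

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.link not in ("probit", "logit"):
            raise ValueError("link must be 'probit' or 'logit'")

    def mu(self, species: int) -> float:
        return 0.0 if species == 1 else self.mu2

    def sigma(self, species: int) -> float:
        return 1.0 if species == 1 else self.sigma2

    def h(self, species: int) -> float:
        return self.h1 if species == 1 else self.h2


def effective_strength(params: CompetitionParams, species: int, arrived_first: bool) -> float:
    """Competitive strength of ``species``, shifted by h when it arrived first."""
    if species not in (1, 2):
        raise ValueError("species must be 1 or 2")
    return params.mu(species) + (params.h(species) if arrived_first else 0.0)


def win_probability(params: CompetitionParams, first_species: int, second_species: int) -> float:
    """Probability that the FIRST-arriving species' offspring emerges (w₁₂)."""
    if first_species == second_species:
        raise ValueError("a contest needs two distinct species")
    s_first = effective_strength(params, first_species, arrived_first=True)
    s_second = effective_strength(params, second_species, arrived_first=False)
    scale = np.sqrt(params.sigma(first_species) ** 2 + params.sigma(second_species) ** 2)
    z = (s_first - s_second) / scale
    return float(ndtr(z)) if params.link == "probit" else float(expit(z))
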
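"""Prior distributions used by the model registry and the samplers.

Only three families are needed: the behavioural proportions and the
functional-response constants carry vague Uniform(0, 1) priors, the
competition location parameters carry Normal(0, 10), and the strength
deviations carry HalfNormal(10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Uniform:
    lo: float = 0.0
    hi: float = 1.0

    @property
    def support(self) -> tuple[float, float]:
        return (self.lo, self.hi)

    def logpdf(self, x: float) -> float:
        if self.lo <= x <= self.hi:
            return -np.log(self.hi - self.lo)
        return -np.inf

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lo, self.hi))

    def __str__(self) -> str:  # used in parameter tables
        return f"Uniform({self.lo:g}, {self.hi:g})"


@dataclass(frozen=True)
class Normal:
    mu: float = 0.0
    sigma: float = 10.0

    @property
    def support(self) -> tuple[float, float]:
        return (-np.inf, np.inf)

    def logpdf(self, x: float) -> float:
        z = (x - self.mu) / self.sigma
        return -0.5 * z * z - np.log(self.sigma) - 0.5 * np.log(2 * np.pi)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.normal(self.mu, self.sigma))

    def __str__(self) -> str:
        return f"Normal({self.mu:g}, {self.sigma:g})"


@dataclass(frozen=True)
class HalfNormal:
    sigma: float = 10.0

    @property
    def support(self) -> tuple[float, float]:
        return (0.0, np.inf)

    def logpdf(self, x: float) -> float:
        if x < 0:
            return -np.inf
        z = x / self.sigma
        return np.log(2.0) - 0.5 * z * z - np.log(self.sigma) - 0.5 * np.log(2 * np.pi)

    def sample(self, rng: np.random.Generator) -> float:
        return float(abs(rng.normal(0.0, self.sigma)))

    def __str__(self) -> str:
        return f"HalfNormal({self.sigma:g})"


Prior = Uniform | Normal | HalfNormal
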
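"""Expected per-species emergence under sequential host exposure.

The expected emergence of the first-released species when a second
species later searches the same arena is

    E₁(p) = R₁₀(p) + R₁₂(p) · w₁₂,

where R₁₂ is the expected overlap of the two species' attack sets (the
multiparasitized hosts), R₁₀ = R₁ − R₁₂ the hosts only the first species
attacked, and w₁₂ the probability the first species' larva wins the
contest inside a shared host.  On top of this sit three optional
mechanisms: rejection of a shared proportion ``s`` of unsuitable hosts,
a per-species multiparasitism index θ steering the overlap between
complete avoidance (θ=0), random (θ=0.5) and complete preference (θ=1)
of already-parasitized hosts, and an extra host mortality 1 − (1−m)ⁿ
that grows with the number of attacks n a host received.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .competition import CompetitionParams, win_probability
from .functional_response import FRParams, expected_attacked
from .model_space import CompetitionTier, FRFamily, ModelSpec


@dataclass(frozen=True)
class InteractionParams:
    """Host-selection and host-fate parameters.

    theta1, theta2 : multiparasitism indices in [0, 1] (0 = avoidance of
        parasitized hosts, 0.5 = random, 1 = preference); only the
        second-arriving species' index matters, since only that female
        encounters parasitized hosts
    s : proportion of offered hosts unsuitable to (rejected by) both species
    m : per-attack increment of host mortality
    """

    theta1: float = 0.5
    theta2: float = 0.5
    s: float = 0.0
    m: float = 0.0

    def __post_init__(self) -> None:
        for name in ("theta1", "theta2", "s", "m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def theta(self, species: int) -> float:
        return self.theta1 if species == 1 else self.theta2


@dataclass(frozen=True)
class ExposureProtocol:
    """One arena: hosts offered and the order of species releases."""

    first: int
    second: int | None
    p: float
    T: float = 1.0

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError("hosts offered must be nonnegative")
        if self.first not in (1, 2):
            raise ValueError("first species must be 1 or 2")
        if self.second is not None and self.second == self.first:
            raise ValueError("sequential exposure needs two distinct species")


def available_hosts(p, s: float, rejection: bool):
    """Effective host pool after removing the unsuitable proportion s."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must lie in [0, 1]")
    p = np.asarray(p, dtype=float)
    out = p * (1.0 - s) if rejection else p
    return float(out) if out.shape == () else out


def overlap(R1, R2, p_avail, theta: float):
    """Expected number of hosts attacked by both species (R₁₂).

    θ = 0.5 gives the random expectation R₁·R₂/p; θ = 0 and θ = 1 give
    the Fréchet lower and upper bounds; intermediate values interpolate
    linearly on each side.  The result always lies within the bounds.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    p = np.asarray(p_avail, dtype=float)
    if np.any((p <= 0) & ((R1 > 0) | (R2 > 0))):
        raise ValueError("positive attacks with an empty host pool")
    if np.any(R1 < 0) or np.any(R2 < 0) or np.any(R1 > p) or np.any(R2 > p):
        raise ValueError("attack counts must lie in [0, p_avail]")
    safe_p = np.where(p > 0, p, 1.0)
    lower = np.maximum(0.0, R1 + R2 - p)
    random = R1 * R2 / safe_p
    upper = np.minimum(R1, R2)
    if theta <= 0.5:
        t = theta / 0.5
        out = lower + t * (random - lower)
    else:
        t = (theta - 0.5) / 0.5
        out = random + t * (upper - random)
    out = np.where(p > 0, out, 0.0)
    return float(out) if out.shape == () else out


def host_mortality(m: float, n) -> float:
    """Probability a host attacked n times dies without producing a wasp."""
    if not 0.0 <= m <= 1.0:
        raise ValueError("m must lie in [0, 1]")
    n = np.asarray(n)
    if np.any(n < 0):
        raise ValueError("number of attacks must be nonnegative")
    out = 1.0 - (1.0 - m) ** n
    return float(out) if out.shape == () else out


def combine_emergence(R_first, R_second, R12, w_first, S1: float, S2: float):
    """Resolve overlap and contest into per-arrival-order expectations.

    Returns (E_first, E_second): expected emergences of the first- and
    second-released species, given their attack totals, the expected
    doubly-attacked count R12, the first-arriver's win probability and
    the survival factors S(n) = (1−m)ⁿ for singly/doubly attacked hosts.
    """
    E_first = (R_first - R12) * S1 + R12 * w_first * S2
    E_second = (R_second - R12) * S1 + R12 * (1.0 - w_first) * S2
    return E_first, E_second


def build_params(
    spec: ModelSpec, values: Mapping[str, float], T: float = 1.0
) -> tuple[dict[int, FRParams], CompetitionParams | None, InteractionParams]:
    """Materialize parameter objects for ``spec`` from a name→value mapping.

    Parameters outside the spec's tiers take their null defaults (c=0,
    H=0, m=0, s=0, θ=0.5, h=0); the competition block is ``None`` for the
    tier-absent models, in which case contested hosts are resolved 50/50.
    """
    third = spec.fr_family in (FRFamily.FRIII_G, FRFamily.FRIII_GP)
    fr = {
        sp: FRParams(
            b=float(values[f"b_{sp}"]),
            c=float(values.get(f"c_{sp}", 0.0)) if third else 0.0,
            H=float(values.get(f"H_{sp}", 0.0)) if spec.fr_family is not FRFamily.FRI else 0.0,
            T=T,
        )
        for sp in (1, 2)
    }
    comp: CompetitionParams | None = None
    if spec.competition >= CompetitionTier.BASIC:
        arrival = spec.competition >= CompetitionTier.ARRIVAL
        comp = CompetitionParams(
            mu2=float(values["mu_2"]),
            sigma2=float(values["sigma_2"]),
            h1=float(values.get("h_1", 0.0)) if arrival else 0.0,
            h2=float(values.get("h_2", 0.0)) if arrival else 0.0,
            link=str(values.get("link", "probit")),
        )
    sup = spec.competition >= CompetitionTier.SUPERPOSITION
    inter = InteractionParams(
        theta1=float(values.get("theta_1", 0.5)) if sup else 0.5,
        theta2=float(values.get("theta_2", 0.5)) if sup else 0.5,
        s=float(values.get("s", 0.0)) if spec.rejection else 0.0,
        m=float(values.get("m", 0.0)) if spec.mortality else 0.0,
    )
    return fr, comp, inter


def expected_emergence_grid(
    spec: ModelSpec,
    fr: Mapping[int, FRParams],
    comp: CompetitionParams | None,
    inter: InteractionParams,
    first: int,
    second: int | None,
    p,
):
    """Vectorized expected emergence over an array of offered densities.

    Returns ``(E1, E2)`` in species-identity order (species 1, species 2)
    regardless of the release order.
    """
    p = np.asarray(p, dtype=float)
    p_av = available_hosts(p, inter.s, spec.rejection)
    S1 = 1.0 - inter.m if spec.mortality else 1.0
    S2 = S1 * S1
    out = {1: np.zeros_like(p), 2: np.zeros_like(p)}
    R_first = expected_attacked(fr[first], spec.fr_family, spec.host_depletion, p_av)
    if second is None:
        out[first] = np.asarray(R_first) * S1
    else:
        R_second = expected_attacked(fr[second], spec.fr_family, spec.host_depletion, p_av)
        theta_eff = inter.theta(second) if spec.competition >= CompetitionTier.SUPERPOSITION else 0.5
        R12 = overlap(R_first, R_second, p_av, theta_eff)
        w_first = 0.5 if comp is None else win_probability(comp, first, second)
        E_first, E_second = combine_emergence(R_first, R_second, R12, w_first, S1, S2)
        out[first] = np.asarray(E_first)
        out[second] = np.asarray(E_second)
    return out[1], out[2]


def expected_emergence(
    spec: ModelSpec,
    fr: Mapping[int, FRParams],
    comp: CompetitionParams | None,
    inter: InteractionParams,
    protocol: ExposureProtocol,
) -> tuple[float, float]:
    """Expected emerged wasps of species 1 and species 2 for one arena."""
    e1, e2 = expected_emergence_grid(
        spec, fr, comp, inter, protocol.first, protocol.second, np.asarray([protocol.p])
    )
    return float(e1[0]), float(e2[0])


def scenario_projection(
    spec: ModelSpec,
    fr: Mapping[int, FRParams],
    comp: CompetitionParams | None,
    inter: InteractionParams,
    densities,
    orders=((1, 2), (2, 1)),
) -> pd.DataFrame:
    """Projected emergence across densities for each release order.

    For every order the table also carries the null host-selection
    reference (both θ forced to 0.5: the second female attacks at
    random), the benchmark against which preference or avoidance of
    parasitized hosts raises or lowers total parasitism.
    """
    densities = np.asarray(list(densities), dtype=float)
    null = InteractionParams(theta1=0.5, theta2=0.5, s=inter.s, m=inter.m)
    rows = []
    for first, second in orders:
        e1, e2 = expected_emergence_grid(spec, fr, comp, inter, first, second, densities)
        r1, r2 = expected_emergence_grid(spec, fr, comp, null, first, second, densities)
        for sp, e, r in ((1, e1, r1), (2, e2, r2)):
            rows.append(
                pd.DataFrame(
                    {
                        "density": densities,
                        "order": f"{first}->{second}",
                        "species": sp,
                        "expected": e,
                        "reference": r,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
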
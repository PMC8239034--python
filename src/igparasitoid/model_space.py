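"""Enumeration and parameter bookkeeping of the 112-member model family.

Each candidate model is a combination of five structural choices:

* functional-response family — type I (``FRI``), type II (``FRII``), or a
  generalized type III whose attack rate grows linearly (``FRIII_G``) or
  quadratically (``FRIII_GP``) with host density;
* host depletion — whether within-exposure removal of hosts is modelled
  with the Rogers random-predator correction (``HD``) or ignored
  (``NHD``, the plain Holling forms).  The type I family is only defined
  without depletion, which is why the family has 7 × 16 = 112 members
  rather than 128;
* multiparasitism mortality — an extra per-attack host death probability
  ``m`` shared by both species;
* rejection of unsuitable hosts — a shared proportion ``s`` of offered
  hosts that neither female accepts;
* a competition tier: ``absent`` (contested hosts resolved at random),
  ``basic`` (Thurstone/Bradley–Terry strengths), ``arrival`` (adds
  first-arrival terms), ``superposition`` (adds per-species
  multiparasitism indices θ governing overlap of the two attack sets).

The tiers are cumulative, and the parameter increments (+2, +5, +8 over
the base functional-response parameters, plus +1 for each of mortality
and rejection) reproduce the published per-model parameter counts.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

from .priors import HalfNormal, Normal, Prior, Uniform


class FRFamily(enum.Enum):
    """Functional-response family of a candidate model."""

    FRI = "FRI"
    FRII = "FRII"
    FRIII_G = "FRIII_G"  # attack rate linear in host density
    FRIII_GP = "FRIII_GP"  # attack rate quadratic in host density

    def __str__(self) -> str:
        return self.value


class CompetitionTier(enum.IntEnum):
    """Cumulative interference-competition structure."""

    ABSENT = 0
    BASIC = 1
    ARRIVAL = 2
    SUPERPOSITION = 3


_TIER_TOKEN = {
    CompetitionTier.ABSENT: "Cabs",
    CompetitionTier.BASIC: "Cbasic",
    CompetitionTier.ARRIVAL: "Carr",
    CompetitionTier.SUPERPOSITION: "Csup",
}
_TOKEN_TIER = {v: k for k, v in _TIER_TOKEN.items()}

#: free parameters of each functional-response family (per species)
FR_BASE_COUNT = {
    FRFamily.FRI: 2,
    FRFamily.FRII: 4,
    FRFamily.FRIII_G: 6,
    FRFamily.FRIII_GP: 6,
}

#: additional parameters of each competition tier (cumulative)
COMPETITION_COUNT = {
    CompetitionTier.ABSENT: 0,
    CompetitionTier.BASIC: 2,
    CompetitionTier.ARRIVAL: 5,
    CompetitionTier.SUPERPOSITION: 8,
}


@dataclass(frozen=True, order=True)
class ModelSpec:
    """One member of the 112-model family."""

    fr_family: FRFamily
    host_depletion: bool
    mortality: bool
    rejection: bool
    competition: CompetitionTier

    def __post_init__(self) -> None:
        if self.fr_family is FRFamily.FRI and self.host_depletion:
            raise ValueError("the type I family is only defined without host depletion")

    def to_string(self) -> str:
        """Short serialized form, e.g. ``"FRIII_G:NHD:M1:R1:Csup"``."""
        return ":".join(
            [
                self.fr_family.value,
                "HD" if self.host_depletion else "NHD",
                "M1" if self.mortality else "M0",
                "R1" if self.rejection else "R0",
                _TIER_TOKEN[self.competition],
            ]
        )

    @classmethod
    def from_string(cls, text: str) -> "ModelSpec":
        try:
            fam, depl, mort, rej, comp = text.strip().split(":")
            return cls(
                fr_family=FRFamily(fam),
                host_depletion={"HD": True, "NHD": False}[depl],
                mortality={"M1": True, "M0": False}[mort],
                rejection={"R1": True, "R0": False}[rej],
                competition=_TOKEN_TIER[comp],
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"unparseable model spec string: {text!r}") from exc

    def __str__(self) -> str:
        return self.to_string()


def enumerate_models() -> list[ModelSpec]:
    """All 112 candidate models in a deterministic order.

    Ordered by functional-response family, then depletion, then
    mortality, then rejection, then competition tier; the first element
    is the bare type I response with every optional term off.
    """
    out: list[ModelSpec] = []
    for fam in FRFamily:
        depletion_options = [False] if fam is FRFamily.FRI else [False, True]
        for depl, mort, rej, tier in itertools.product(
            depletion_options, [False, True], [False, True], CompetitionTier
        ):
            out.append(ModelSpec(fam, depl, mort, rej, tier))
    return out


def parameter_count(spec: ModelSpec) -> int:
    """Number of biological parameters of one candidate model."""
    return (
        FR_BASE_COUNT[spec.fr_family]
        + int(spec.mortality)
        + int(spec.rejection)
        + COMPETITION_COUNT[spec.competition]
    )


@dataclass(frozen=True)
class ParameterDescriptor:
    """One free parameter of a candidate model.

    ``species`` is 1 or 2 for species-specific parameters, ``None`` for
    shared ones.  ``nuisance`` marks the tier-level deviation parameters
    (σ_h, σ_θ) that are counted in the model's dimension but may be held
    at a degenerate value during fitting because the likelihood does not
    depend on them.
    """

    name: str
    species: int | None
    prior: Prior
    nuisance: bool = False

    @property
    def support(self) -> tuple[float, float]:
        return self.prior.support


def free_parameters(spec: ModelSpec) -> list[ParameterDescriptor]:
    """Ordered parameter descriptors of ``spec``; length = parameter_count."""
    unit = Uniform(0.0, 1.0)
    vague = Normal(0.0, 10.0)
    halfn = HalfNormal(10.0)

    out = [
        ParameterDescriptor("b_1", 1, unit),
        ParameterDescriptor("b_2", 2, unit),
    ]
    if spec.fr_family in (FRFamily.FRIII_G, FRFamily.FRIII_GP):
        out += [
            ParameterDescriptor("c_1", 1, unit),
            ParameterDescriptor("c_2", 2, unit),
        ]
    if spec.fr_family is not FRFamily.FRI:
        out += [
            ParameterDescriptor("H_1", 1, unit),
            ParameterDescriptor("H_2", 2, unit),
        ]
    if spec.mortality:
        out.append(ParameterDescriptor("m", None, unit))
    if spec.rejection:
        out.append(ParameterDescriptor("s", None, unit))
    if spec.competition >= CompetitionTier.BASIC:
        out += [
            ParameterDescriptor("mu_2", 2, vague),
            ParameterDescriptor("sigma_2", 2, halfn),
        ]
    if spec.competition >= CompetitionTier.ARRIVAL:
        out += [
            ParameterDescriptor("h_1", 1, vague),
            ParameterDescriptor("h_2", 2, vague),
            ParameterDescriptor("sigma_h", None, halfn, nuisance=True),
        ]
    if spec.competition >= CompetitionTier.SUPERPOSITION:
        out += [
            ParameterDescriptor("theta_1", 1, unit),
            ParameterDescriptor("theta_2", 2, unit),
            ParameterDescriptor("sigma_theta", None, halfn, nuisance=True),
        ]
    assert len(out) == parameter_count(spec)
    return out
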
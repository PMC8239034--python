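"""Individual-host simulation of sequential-exposure experiments.

The generator is the stochastic twin of the analytic expectation in
:mod:`igparasitoid.interaction`: each simulated arena draws a realized
host count around the nominal density (up to ±10% by default), removes a
fixed unsuitable fraction when the rejection mechanism is on, draws each
species' attack total as Binomial(p_avail, R/p_avail), places the second
species' attacks on parasitized versus unparasitized hosts so that the
expected double-attack count equals the analytic overlap, resolves
contested hosts by the pairwise-contest win probability, and kills each
attacked host with probability 1 − (1−m)ⁿ.  Per-trial host accounting
(emerged + dead + unparasitized + unsuitable = offered) holds exactly,
and Monte-Carlo emergence means converge to the analytic expectations —
the central consistency property between the generator and the
likelihood's mean structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .competition import win_probability
from .functional_response import expected_attacked
from .interaction import ExposureProtocol, build_params, overlap
from .model_space import CompetitionTier, ModelSpec

#: nominal densities of the sequential-exposure (interaction) protocols
INTERACTION_DENSITIES = (10, 20, 30, 40, 50, 60, 70, 80, 90, 110)
#: nominal densities of the single-species baseline protocols
BASELINE_DENSITIES = (10, 20, 40, 60, 80, 110)


@dataclass(frozen=True)
class SimulationConfig:
    """True model, true parameters and experimental design of a simulation.

    The defaults reproduce the laboratory design: sequential exposures in
    both species orders over ten densities (one arena each), plus
    single-species baselines over six densities with five replicates,
    and a realized host count within ±10% of nominal.
    """

    spec: ModelSpec
    values: Mapping[str, float]
    interaction_densities: tuple[int, ...] = INTERACTION_DENSITIES
    baseline_densities: tuple[int, ...] = BASELINE_DENSITIES
    interaction_replicates: int = 1
    baseline_replicates: int = 5
    density_jitter: float = 0.10
    seed: int = 0
    species_labels: tuple[str, str] = ("species1", "species2")

    def __post_init__(self) -> None:
        if not 0.0 <= self.density_jitter <= 0.10:
            raise ValueError("density jitter must lie in [0, 0.10]")
        if self.interaction_replicates < 1 or self.baseline_replicates < 1:
            raise ValueError("replicates must be >= 1")

    def protocols(self) -> list[tuple[int, int | None]]:
        return [(1, 2), (2, 1), (1, None), (2, None)]


@dataclass(frozen=True)
class TrialRecord:
    """Full outcome of one simulated arena, including host accounting."""

    trial_id: str
    first: int
    second: int | None
    n_offered: int
    emerged_first: int
    emerged_second: int
    n_dead: int
    n_unsuitable: int
    n_unparasitized_suitable: int
    n_double_attacked: int

    @property
    def n_unparasitized(self) -> int:
        """Hosts from which no wasp emerged (dead, unsuitable or untouched)."""
        return self.n_offered - self.emerged_first - self.emerged_second

    def accounting_balance(self) -> int:
        """Zero when the per-host bookkeeping identity holds."""
        return self.n_offered - (
            self.emerged_first
            + self.emerged_second
            + self.n_dead
            + self.n_unsuitable
            + self.n_unparasitized_suitable
        )


def _binomial_attacks(rng: np.random.Generator, p_avail: int, expected: float) -> int:
    if p_avail == 0:
        return 0
    return int(rng.binomial(p_avail, min(1.0, expected / p_avail)))


def _round_stochastic(rng: np.random.Generator, x: float) -> int:
    base = int(np.floor(x))
    return base + int(rng.uniform() < (x - base))


def simulate_trial(
    config: SimulationConfig,
    protocol: tuple[int, int | None],
    nominal_density: int,
    rng: np.random.Generator,
    trial_id: str = "t0",
) -> TrialRecord:
    """Simulate one arena under the true model of ``config``."""
    spec = config.spec
    fr, comp, inter = build_params(spec, config.values)
    first, second = protocol
    ExposureProtocol(first=first, second=second, p=nominal_density)  # validate

    jitter = rng.uniform(-config.density_jitter, config.density_jitter)
    p_real = max(1, int(round(nominal_density * (1.0 + jitter))))
    # fixed unsuitable fraction: a proportion s of nymphs is unacceptable to
    # both females (deterministic so that generator and analytic means agree)
    n_unsuit = int(round(p_real * inter.s)) if spec.rejection else 0
    p_avail = p_real - n_unsuit

    m = inter.m if spec.mortality else 0.0
    surv1, surv2 = 1.0 - m, (1.0 - m) ** 2

    R1 = float(expected_attacked(fr[first], spec.fr_family, spec.host_depletion, float(p_avail)))
    n1 = _binomial_attacks(rng, p_avail, R1)

    if second is None:
        emerged = int(rng.binomial(n1, surv1)) if n1 else 0
        dead = n1 - emerged
        ef, es = emerged, 0
        n2 = double = 0
    else:
        R2 = float(expected_attacked(fr[second], spec.fr_family, spec.host_depletion, float(p_avail)))
        n2 = _binomial_attacks(rng, p_avail, R2)
        theta = inter.theta(second) if spec.competition >= CompetitionTier.SUPERPOSITION else 0.5
        target = overlap(R1, R2, float(p_avail), theta)
        # multiplicative scaling keeps E[double] equal to the analytic overlap
        scaled = target * (n1 / R1 if R1 > 0 else 0.0) * (n2 / R2 if R2 > 0 else 0.0)
        lo = max(0, n1 + n2 - p_avail)
        hi = min(n1, n2)
        double = min(hi, max(lo, _round_stochastic(rng, scaled)))
        w_first = 0.5 if comp is None else win_probability(comp, first, second)
        first_wins = int(rng.binomial(double, w_first)) if double else 0
        only1, only2 = n1 - double, n2 - double
        e1_single = int(rng.binomial(only1, surv1)) if only1 else 0
        e2_single = int(rng.binomial(only2, surv1)) if only2 else 0
        e1_contest = int(rng.binomial(first_wins, surv2)) if first_wins else 0
        e2_contest = int(rng.binomial(double - first_wins, surv2)) if double - first_wins else 0
        ef = e1_single + e1_contest
        es = e2_single + e2_contest
        dead = (only1 - e1_single) + (only2 - e2_single) + (double - e1_contest - e2_contest)

    attacked = n1 if second is None else n1 + n2 - double
    record = TrialRecord(
        trial_id=trial_id,
        first=first,
        second=second,
        n_offered=p_real,
        emerged_first=ef,
        emerged_second=es,
        n_dead=dead,
        n_unsuitable=n_unsuit,
        n_unparasitized_suitable=p_avail - attacked,
        n_double_attacked=double,
    )
    assert record.accounting_balance() == 0
    return record


def simulate_experiment(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the full factorial design of ``config``.

    Returns the trial table (the delimited-text format consumed by the
    inference module) and a truth record carrying the generating model
    and parameter values for recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    rows = []
    counter = 0
    labels = {1: config.species_labels[0], 2: config.species_labels[1]}
    for first, second in config.protocols():
        densities = config.baseline_densities if second is None else config.interaction_densities
        reps = config.baseline_replicates if second is None else config.interaction_replicates
        for density in densities:
            for _ in range(reps):
                counter += 1
                rec = simulate_trial(config, (first, second), density, rng, trial_id=f"t{counter:04d}")
                rows.append(
                    {
                        "trial_id": rec.trial_id,
                        "first_species": labels[first],
                        "second_species": "NA" if second is None else labels[second],
                        "n_offered": rec.n_offered,
                        "emerged_first": rec.emerged_first,
                        "emerged_second": rec.emerged_second,
                        "n_unparasitized": rec.n_unparasitized,
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "spec": config.spec.to_string(),
        "values": dict(config.values),
        "seed": config.seed,
        "design": {
            "interaction_densities": list(config.interaction_densities),
            "baseline_densities": list(config.baseline_densities),
            "interaction_replicates": config.interaction_replicates,
            "baseline_replicates": config.baseline_replicates,
            "density_jitter": config.density_jitter,
        },
    }
    return table, truth


def expected_trial_count(config: SimulationConfig) -> int:
    """Design arithmetic: arenas per full factorial of the configuration."""
    return 2 * len(config.interaction_densities) * config.interaction_replicates + 2 * len(
        config.baseline_densities
    ) * config.baseline_replicates
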
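"""Bayesian estimation and model selection for sequential-exposure trials.

Observed emergences are compared with the model's expectations through a
binomial likelihood per species and trial (success probability = expected
emergence / hosts offered).  Parameters are sampled by an adaptive
Metropolis-within-Gibbs random walk under vague priors (Uniform(0,1) for
rates, proportions and handling times; Normal(0, 10) for the competition
locations; HalfNormal(10) for the strength deviation).  Model selection
runs a reversible-jump chain across candidate models: a proposed jump is
accepted on the difference of log-likelihoods penalized by 2 units per
parameter, and posterior model weights are the post-burn-in visit
frequencies.  Model-averaged summaries pool the recorded draws over all
visits of models containing a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .interaction import build_params, expected_emergence_grid
from .model_space import ModelSpec, ParameterDescriptor, free_parameters, parameter_count
from .priors import Prior

_EPS = 1e-12


@dataclass(frozen=True)
class Trial:
    """One experimental arena and its outcome.

    ``first``/``second`` are species indices (1 or 2); ``second`` is
    ``None`` for single-species baselines.  ``emerged_first`` counts
    wasps of the first-released species, ``emerged_second`` of the
    second-released one.
    """

    trial_id: str
    first: int
    second: int | None
    n_offered: int
    emerged_first: int
    emerged_second: int = 0
    n_unparasitized: int | None = None

    def __post_init__(self) -> None:
        if self.n_offered < 0 or self.emerged_first < 0 or self.emerged_second < 0:
            raise ValueError(f"trial {self.trial_id}: counts must be nonnegative")
        if self.emerged_first + self.emerged_second > self.n_offered:
            raise ValueError(f"trial {self.trial_id}: more emergences than hosts offered")
        if self.second is None and self.emerged_second != 0:
            raise ValueError(f"trial {self.trial_id}: second-species emergence without exposure")


def _group_trials(trials: Sequence[Trial]):
    """Group trials by release protocol into arrays for vectorized likelihoods."""
    groups: dict[tuple[int, int | None], list[Trial]] = {}
    for t in trials:
        groups.setdefault((t.first, t.second), []).append(t)
    out = []
    for (first, second), ts in groups.items():
        n = np.array([t.n_offered for t in ts], dtype=float)
        k = {1: np.zeros(len(ts)), 2: np.zeros(len(ts))}
        for i, t in enumerate(ts):
            k[t.first][i] = t.emerged_first
            if t.second is not None:
                k[t.second][i] = t.emerged_second
        out.append((first, second, n, k[1], k[2]))
    return out


def _binom_logpmf(k, n, p):
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1) + k * np.log(p) + (n - k) * np.log1p(-p)


def log_likelihood(
    spec: ModelSpec,
    values: Mapping[str, float],
    trials: Sequence[Trial],
    kind: str = "binomial",
    _groups=None,
) -> float:
    """Log-likelihood of the observed emergences under ``spec``.

    ``kind="binomial"`` (default) treats each species' emergence count in
    a trial as Binomial(n_offered, E/n_offered); ``kind="trinomial"``
    treats the per-host outcomes (species 1 / species 2 / neither) as one
    multinomial draw per trial.
    """
    if kind not in ("binomial", "trinomial"):
        raise ValueError("kind must be 'binomial' or 'trinomial'")
    groups = _groups if _groups is not None else _group_trials(trials)
    if not groups:
        return 0.0
    fr, comp, inter = build_params(spec, values)
    total = 0.0
    for first, second, n, k1, k2 in groups:
        e1, e2 = expected_emergence_grid(spec, fr, comp, inter, first, second, n)
        safe_n = np.where(n > 0, n, 1.0)
        p1, p2 = e1 / safe_n, e2 / safe_n
        if kind == "binomial":
            if second is None:  # only the released species contributes
                k, pr = (k1, p1) if first == 1 else (k2, p2)
                total += float(np.sum(_binom_logpmf(k, n, pr)))
            else:
                total += float(np.sum(_binom_logpmf(k1, n, p1)))
                total += float(np.sum(_binom_logpmf(k2, n, p2)))
        else:
            p1c = np.clip(p1, _EPS, 1.0 - 2 * _EPS)
            p2c = np.clip(p2, _EPS, 1.0 - _EPS - p1c)
            k0 = n - k1 - k2
            total += float(
                np.sum(
                    gammaln(n + 1)
                    - gammaln(k1 + 1)
                    - gammaln(k2 + 1)
                    - gammaln(k0 + 1)
                    + k1 * np.log(p1c)
                    + k2 * np.log(p2c)
                    + k0 * np.log(1.0 - p1c - p2c)
                )
            )
    return total


def default_priors(spec: ModelSpec) -> dict[str, Prior]:
    """Prior of every free parameter of ``spec`` (including nuisances)."""
    return {d.name: d.prior for d in free_parameters(spec)}


@dataclass(frozen=True)
class ChainConfig:
    """Settings of one Metropolis-within-Gibbs run."""

    iterations: int = 2000
    burn_in: int = 1000
    chains: int = 1
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.35
    likelihood: str = "binomial"
    init_retries: int = 50


@dataclass(frozen=True)
class RJConfig:
    """Settings of one reversible-jump model-selection run.

    ``penalty`` is the log-likelihood penalty per additional parameter
    applied at every between-model move.  ``inner_sweeps`` full
    within-model refresh sweeps are run between jumps.  The published
    analysis used outer_iterations=60_000, burn_in=40_000 and
    inner_sweeps=10_000 ("paper" preset); the defaults here are a
    desk-scale preset.
    """

    outer_iterations: int = 1000
    burn_in: int = 200
    inner_sweeps: int = 5
    penalty: float = 2.0
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.35
    likelihood: str = "binomial"


@dataclass
class PosteriorResult:
    """Draws and summaries of a fit or a reversible-jump run."""

    draws: pd.DataFrame
    summary: pd.DataFrame
    spec: ModelSpec | None
    seed: int
    config: ChainConfig | RJConfig
    model_weights: dict[str, float] | None = None
    diagnostics: dict = field(default_factory=dict)

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        x = self.draws[name].dropna().to_numpy()
        lo = (1.0 - level) / 2.0
        return float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo))


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a proposal back into [lo, hi] (keeps the random walk symmetric)."""
    if np.isinf(lo) and np.isinf(hi):
        return x
    if np.isinf(hi):
        return lo + abs(x - lo)
    width = hi - lo
    y = (x - lo) % (2.0 * width)
    return lo + (y if y <= width else 2.0 * width - y)


def _init_from_prior(
    descs: Sequence[ParameterDescriptor],
    spec: ModelSpec,
    groups,
    kind: str,
    rng: np.random.Generator,
    retries: int,
) -> tuple[dict[str, float], float]:
    for _ in range(retries):
        values = {d.name: d.prior.sample(rng) for d in descs}
        ll = log_likelihood(spec, values, (), kind=kind, _groups=groups)
        if np.isfinite(ll):
            return values, ll
    raise RuntimeError("could not find a finite-likelihood starting point")


def _log_prior(descs: Sequence[ParameterDescriptor], values: Mapping[str, float]) -> float:
    return sum(d.prior.logpdf(values[d.name]) for d in descs)


class _GibbsState:
    """Mutable random-walk state for one model.

    Each sweep performs one componentwise Metropolis update per
    parameter plus, once enough burn-in history has accumulated, one
    correlated block move whose covariance is the running sample
    covariance of the chain (adaptive Metropolis).  The block move is
    what lets the sampler traverse the likelihood ridges that confound
    the rejection/mortality proportions with the attack-rate constants.
    """

    def __init__(self, spec, descs, values, loglik, scales=None):
        self.spec = spec
        self.descs = list(descs)
        self.values = dict(values)
        self.loglik = loglik
        self.scales = dict(scales) if scales else {
            d.name: 0.1 if np.isfinite(d.support[0]) and np.isfinite(d.support[1]) else 1.0
            for d in descs
        }
        self.accepts = {d.name: 0 for d in descs}
        self.proposals = {d.name: 0 for d in descs}
        self.history: list[np.ndarray] = []
        self.block_chol: np.ndarray | None = None
        self.block_scale = 1.0
        self.block_accepts = 0
        self.block_proposals = 0

    def _vector(self) -> np.ndarray:
        return np.array([self.values[d.name] for d in self.descs])

    def sweep(self, groups, kind, rng, record_history: bool = False):
        lp = _log_prior(self.descs, self.values)
        for d in self.descs:
            lo, hi = d.support
            prop = dict(self.values)
            prop[d.name] = _reflect(self.values[d.name] + rng.normal(0.0, self.scales[d.name]), lo, hi)
            lp_prop = lp - d.prior.logpdf(self.values[d.name]) + d.prior.logpdf(prop[d.name])
            ll_prop = log_likelihood(self.spec, prop, (), kind=kind, _groups=groups)
            self.proposals[d.name] += 1
            if np.log(rng.uniform()) < (ll_prop + lp_prop) - (self.loglik + lp):
                self.values = prop
                self.loglik = ll_prop
                lp = lp_prop
                self.accepts[d.name] += 1
        if self.block_chol is not None:
            self._block_move(groups, kind, rng, lp)
        if "s" in self.values:
            self._rejection_ridge_move(groups, kind, rng)
        if "m" in self.values:
            self._mortality_ridge_move(groups, kind, rng)
        if record_history:
            self.history.append(self._vector())

    def _block_move(self, groups, kind, rng, lp):
        step = self.block_scale * (self.block_chol @ rng.normal(size=len(self.descs)))
        prop = {}
        for d, dx in zip(self.descs, step):
            lo, hi = d.support
            prop[d.name] = _reflect(self.values[d.name] + dx, lo, hi)
        lp_prop = _log_prior(self.descs, prop)
        ll_prop = log_likelihood(self.spec, prop, (), kind=kind, _groups=groups)
        self.block_proposals += 1
        if np.log(rng.uniform()) < (ll_prop + lp_prop) - (self.loglik + lp):
            self.values = prop
            self.loglik = ll_prop
            self.block_accepts += 1

    def _rejection_ridge_move(self, groups, kind, rng):
        """Joint move along the rejection/attack-rate likelihood ridge.

        Without depletion the response depends on (s, b, c) only through
        b·(1−s) and c·(1−s)², so the posterior has a long ridge that
        single-parameter updates cannot traverse.  This move proposes a
        new s and rescales every b by r = (1−s)/(1−s') and every c by r²
        to stay on the ridge; the Jacobian of the rescaling enters the
        acceptance ratio.  Valid (and useful, if less exact) under
        depletion too — it is just a proposal.
        """
        s_cur = self.values["s"]
        s_new = _reflect(s_cur + rng.normal(0.0, 0.15), 0.0, 1.0)
        if s_new >= 1.0:
            return
        r = (1.0 - s_cur) / (1.0 - s_new)
        prop = dict(self.values)
        prop["s"] = s_new
        log_jac = 0.0
        for name in self.values:
            if name.startswith("b_"):
                prop[name] = self.values[name] * r
                log_jac += np.log(r)
            elif name.startswith("c_"):
                prop[name] = self.values[name] * r * r
                log_jac += 2.0 * np.log(r)
        lp_prop = _log_prior(self.descs, prop)
        if not np.isfinite(lp_prop):  # rescaled rates left the prior box
            return
        lp = _log_prior(self.descs, self.values)
        ll_prop = log_likelihood(self.spec, prop, (), kind=kind, _groups=groups)
        if np.log(rng.uniform()) < (ll_prop + lp_prop + log_jac) - (self.loglik + lp):
            self.values = prop
            self.loglik = ll_prop

    def _mortality_ridge_move(self, groups, kind, rng):
        """Joint move along the mortality/attack-rate likelihood ridge.

        Single-species emergence means are invariant under
        m → m', b → b·r, c → c·r, H → H/r with r = (1−m)/(1−m'), so the
        per-attack mortality is identified only by the doubly-attacked
        hosts' extra thinning.  Walking that ridge jointly lets the
        chain explore the full range of mortality values the data allow.
        """
        m_cur = self.values["m"]
        m_new = _reflect(m_cur + rng.normal(0.0, 0.15), 0.0, 1.0)
        if m_new >= 1.0:
            return
        r = (1.0 - m_cur) / (1.0 - m_new)
        prop = dict(self.values)
        prop["m"] = m_new
        log_jac = 0.0
        for name in self.values:
            if name.startswith(("b_", "c_")):
                prop[name] = self.values[name] * r
                log_jac += np.log(r)
            elif name.startswith("H_"):
                prop[name] = self.values[name] / r
                log_jac -= np.log(r)
        lp_prop = _log_prior(self.descs, prop)
        if not np.isfinite(lp_prop):
            return
        lp = _log_prior(self.descs, self.values)
        ll_prop = log_likelihood(self.spec, prop, (), kind=kind, _groups=groups)
        if np.log(rng.uniform()) < (ll_prop + lp_prop + log_jac) - (self.loglik + lp):
            self.values = prop
            self.loglik = ll_prop

    def adapt(self, min_history: int = 100):
        for name in self.scales:
            if self.proposals[name] == 0:
                continue
            rate = self.accepts[name] / self.proposals[name]
            self.scales[name] *= float(np.exp(rate - 0.35))
            self.accepts[name] = 0
            self.proposals[name] = 0
        if len(self.history) >= min_history:
            arr = np.asarray(self.history)
            cov = np.cov(arr.T) + 1e-10 * np.eye(len(self.descs))
            try:
                self.block_chol = np.linalg.cholesky((2.38**2 / len(self.descs)) * cov)
            except np.linalg.LinAlgError:  # pragma: no cover - degenerate history
                self.block_chol = None
        if self.block_proposals > 0:
            rate = self.block_accepts / self.block_proposals
            self.block_scale *= float(np.exp(rate - 0.25))
            self.block_accepts = 0
            self.block_proposals = 0


def _summarize(draws: pd.DataFrame, param_names: Iterable[str]) -> pd.DataFrame:
    import arviz as az

    rows = {}
    nchains = draws["chain"].nunique() if "chain" in draws else 1
    for name in param_names:
        x = draws[name].dropna().to_numpy()
        if x.size == 0:
            continue
        rhat = np.nan
        if "chain" in draws and draws[name].notna().all():
            per_chain = [g[name].to_numpy() for _, g in draws.groupby("chain")]
            nmin = min(len(c) for c in per_chain)
            if nmin >= 4:
                arr = np.stack([c[:nmin] for c in per_chain])
                # split each chain in half -> split-R-hat
                half = nmin // 2
                split = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
                rhat = float(az.rhat(split))
        rows[name] = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "q2.5": float(np.quantile(x, 0.025)),
            "q97.5": float(np.quantile(x, 0.975)),
            "rhat": rhat,
            "n_draws": int(x.size),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "parameter"
    _ = nchains
    return out


def fit(spec: ModelSpec, trials: Sequence[Trial], config: ChainConfig = ChainConfig()) -> PosteriorResult:
    """Posterior sampling of one model's parameters.

    Runs ``config.chains`` adaptive componentwise random-walk chains
    (proposal scales adapt during burn-in only and are frozen afterward)
    and reports means, sds, central 95% intervals and split-R̂.
    """
    if not trials:
        raise ValueError("fit needs at least one trial")
    groups = _group_trials(trials)
    descs = [d for d in free_parameters(spec) if not d.nuisance]
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    frames = []
    for chain, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        values, ll = _init_from_prior(descs, spec, groups, config.likelihood, rng, config.init_retries)
        state = _GibbsState(spec, descs, values, ll)
        records = []
        for it in range(config.burn_in + config.iterations):
            adapting = it < config.burn_in
            state.sweep(groups, config.likelihood, rng, record_history=adapting)
            if adapting and (it + 1) % config.adapt_interval == 0:
                state.adapt()
            if not adapting:
                records.append({**state.values, "loglik": state.loglik, "chain": chain})
        frames.append(pd.DataFrame(records))
    draws = pd.concat(frames, ignore_index=True)
    summary = _summarize(draws, [d.name for d in descs])
    diagnostics = {"rhat_max": float(np.nanmax(summary["rhat"])) if len(summary) else np.nan}
    return PosteriorResult(draws, summary, spec, config.seed, config, None, diagnostics)


def rj_accept_logratio(
    loglik_new: float, k_new: int, loglik_old: float, k_old: int, penalty: float = 2.0
) -> float:
    """Log acceptance ratio of a between-model jump.

    Δ(logL − penalty·k): with zero penalty and equal-dimension models this
    is plain Metropolis on the log-likelihood.
    """
    return (loglik_new - penalty * k_new) - (loglik_old - penalty * k_old)


def select(
    specs: Sequence[ModelSpec],
    trials: Sequence[Trial],
    config: RJConfig = RJConfig(),
) -> PosteriorResult:
    """Reversible-jump model selection over ``specs``.

    Each outer iteration refreshes the current model's parameters with
    ``inner_sweeps`` Metropolis-within-Gibbs sweeps, then proposes a jump
    to another candidate drawn uniformly: shared parameters are carried
    over, new ones drawn from their priors, and the move is accepted on
    the penalized log-likelihood difference.  Post-burn-in visit
    frequencies are the posterior model weights.
    """
    if len(specs) < 2:
        raise ValueError("model selection needs at least two candidate models")
    groups = _group_trials(trials)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    spec_list = list(specs)
    descs_by_spec = {id(s): [d for d in free_parameters(s) if not d.nuisance] for s in spec_list}
    scales_by_spec: dict[int, dict[str, float]] = {}
    # duplicate spec strings (possible in symmetry checks) get disambiguated labels
    labels: list[str] = []
    seen: dict[str, int] = {}
    for s in spec_list:
        base = s.to_string()
        if base in seen:
            seen[base] += 1
            labels.append(f"{base}#{seen[base]}")
        else:
            seen[base] = 0
            labels.append(base)

    cur_idx = 0
    cur_spec = spec_list[0]
    values, ll = _init_from_prior(
        descs_by_spec[id(cur_spec)], cur_spec, groups, config.likelihood, rng, 50
    )
    state = _GibbsState(cur_spec, descs_by_spec[id(cur_spec)], values, ll)
    records = []
    for it in range(config.outer_iterations):
        adapting = it < config.burn_in
        for _ in range(config.inner_sweeps):
            state.sweep(groups, config.likelihood, rng)
        if adapting and (it + 1) % max(1, config.adapt_interval // config.inner_sweeps) == 0:
            state.adapt()
        # between-model move
        if len(spec_list) > 1:
            j = int(rng.integers(len(spec_list) - 1))
            if j >= cur_idx:
                j += 1
            new_spec = spec_list[j]
            new_descs = descs_by_spec[id(new_spec)]
            new_values = {
                d.name: state.values[d.name] if d.name in state.values else d.prior.sample(rng)
                for d in new_descs
            }
            ll_new = log_likelihood(new_spec, new_values, (), kind=config.likelihood, _groups=groups)
            logr = rj_accept_logratio(
                ll_new, parameter_count(new_spec), state.loglik, parameter_count(cur_spec), config.penalty
            )
            if np.log(rng.uniform()) < logr:
                scales_by_spec[cur_idx] = dict(state.scales)
                cur_idx, cur_spec = j, new_spec
                state = _GibbsState(
                    new_spec,
                    new_descs,
                    new_values,
                    ll_new,
                    scales=scales_by_spec.get(j),
                )
        if not adapting:
            records.append({**state.values, "model": labels[cur_idx], "loglik": state.loglik})
    draws = pd.DataFrame(records)
    counts = draws["model"].value_counts()
    weights = {label: float(counts.get(label, 0)) / len(draws) for label in labels}
    all_names = sorted({d.name for s in spec_list for d in descs_by_spec[id(s)]})
    for name in all_names:  # ensure absent-parameter columns exist as NaN
        if name not in draws:
            draws[name] = np.nan
    summary = _summarize(draws, all_names)
    return PosteriorResult(draws, summary, None, config.seed, config, weights)


def model_average(result: PosteriorResult) -> pd.DataFrame:
    """Model-averaged parameter summaries from a reversible-jump run.

    Pools the recorded draws of each parameter over all visits of models
    containing it; ``weight`` is the fraction of post-burn-in iterations
    in which the parameter was present.
    """
    if result.model_weights is None:
        raise ValueError("model_average needs a reversible-jump result")
    draws = result.draws
    skip = {"model", "loglik", "chain"}
    rows = {}
    for name in [c for c in draws.columns if c not in skip]:
        x = draws[name].dropna().to_numpy()
        if x.size == 0:
            continue
        rows[name] = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "weight": float(x.size) / float(len(draws)),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "parameter"
    return out
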
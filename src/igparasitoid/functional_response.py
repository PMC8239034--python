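"""Functional responses: expected hosts attacked per female per exposure.

The attack rate ``a(p)`` of a searching female is constant for the type
I/II responses, linear in host density for the generalized type III
(``FRIII_G``) and quadratic for its order-two polynomial variant
(``FRIII_GP``).  Without host depletion the expected number attacked in
an exposure of length ``T`` follows Holling's disc equation

    R(p) = a(p) · p · T / (1 + a(p) · p · H),

with handling time ``H`` (zero for the linear type I response).  With
depletion the Rogers random-predator equation is solved instead,

    R = p · (1 − exp(−a(p) · (T − H · R))),

using the closed-form Lambert-W solution; a damped fixed-point solver is
kept alongside as an independent numerical route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw

from .model_space import FRFamily

logger = logging.getLogger(__name__)


class NoCrossoverError(ValueError):
    """Raised when two response curves do not cross inside the search range."""


@dataclass(frozen=True)
class FRParams:
    """Functional-response parameters of one species.

    b : initial attack rate of an inexperienced female (d⁻¹)
    c : attack-rate slope vs. host density (d⁻¹ host⁻¹ for the linear
        type III form, d⁻¹ host⁻² for the quadratic one); 0 for types I/II
    H : handling time (d); 0 for type I
    T : exposure duration (d); the experiments exposed each female 24 h
    """

    b: float
    c: float = 0.0
    H: float = 0.0
    T: float = 1.0

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0 or self.H < 0:
            raise ValueError("b, c and H must be nonnegative")
        if self.T <= 0:
            raise ValueError("exposure duration T must be positive")


def attack_rate(params: FRParams, family: FRFamily, p):
    """Attack rate a(p) (d⁻¹) at host density ``p`` (scalar or array)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("host density p must be nonnegative")
    if family in (FRFamily.FRI, FRFamily.FRII):
        a = np.broadcast_to(params.b, p.shape).copy()
    elif family is FRFamily.FRIII_G:
        a = params.b + params.c * p
    elif family is FRFamily.FRIII_GP:
        a = params.b + params.c * p**2
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown family {family}")
    return a if a.shape else float(a)


def _holling(a, p, H, T):
    R = a * p * T / (1.0 + a * p * H)
    over = R > p
    if np.any(over):
        logger.debug("Holling response truncated at p for %d densities", int(np.sum(over)))
    return np.minimum(R, p)


def _rogers_lambertw(a, p, H, T):
    """Closed-form solution of the Rogers random-predator equation."""
    a = np.asarray(a, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        aH = a * H
        if H == 0.0 or np.all(aH == 0.0):
            R = p * (1.0 - np.exp(-a * T))
        else:
            # W(e^y) for large y via the asymptotic W ~ y - ln y + ln y / y,
            # so extreme a·H·p (deep-depletion corner of the prior box) stays finite
            with np.errstate(divide="ignore"):
                log_arg = np.where(aH * p > 0, np.log(aH * p), -np.inf) - a * (T - H * p)
            big = log_arg > 700.0
            arg = np.exp(np.where(big, 0.0, log_arg))
            w = np.real(lambertw(arg))
            if np.any(big):
                # start from W ~ y - ln y, then Newton on w + ln w = y
                y = np.where(big, log_arg, 1.0)
                wb = y - np.log(y)
                for _ in range(4):
                    wb = wb * (1.0 + (y - wb - np.log(wb)) / (1.0 + wb))
                w = np.where(big, wb, w)
            if np.any(~np.isfinite(w) & (aH > 0)):
                raise FloatingPointError("Lambert-W evaluation failed in Rogers solve")
            denom = np.where(aH > 0, aH, 1.0)
            # aH underflow (or a = 0): the handling-time-free limit applies
            R = np.where(aH > 0, p - w / denom, p * (1.0 - np.exp(-a * T)))
    R = np.where(p == 0.0, 0.0, R)
    return np.clip(R, 0.0, p)


def rogers_fixed_point(a, p, H, T, tol: float = 1e-10, max_iter: int = 10_000):
    """Iterative solve of the Rogers equation (independent numerical route).

    Damped fixed-point iteration R ← (1−λ)R + λ·p(1−exp(−a(T−HR))) with
    λ = 0.5, falling back to bisection when the map is too steep for the
    iteration to contract (the right-hand side is strictly decreasing in
    R, so the root is unique and always bracketed by [0, p]).  Exposed
    for cross-checking the Lambert-W closed form, which is what
    ``expected_attacked`` uses.
    """

    def solve(ai: float, pi: float) -> float:
        if pi == 0.0 or ai == 0.0:
            return 0.0

        def g(R: float) -> float:
            # cap the exponent: beyond ~700 the result saturates at -inf -> pi
            expo = min(-ai * (T - H * R), 700.0)
            return pi * (1.0 - np.exp(expo))

        R = pi / 2.0
        for _ in range(200):
            gr = g(R)
            # F' = 1 - g' >= 1, so the residual bounds the error directly
            if abs(gr - R) < tol and 0.0 <= R <= pi:
                return R
            R = 0.5 * R + 0.5 * min(max(gr, 0.0), pi)
        lo, hi = 0.0, pi  # F(R) = R - g(R) is strictly increasing
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            if mid - g(mid) < 0.0:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                return 0.5 * (lo + hi)
        raise FloatingPointError("Rogers iterative solve did not converge")

    a_arr = np.asarray(a, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if a_arr.shape == () and p_arr.shape == ():
        return solve(float(a_arr), float(p_arr))
    a_b, p_b = np.broadcast_arrays(a_arr, p_arr)
    return np.array(
        [solve(float(ai), float(pi)) for ai, pi in zip(a_b.ravel(), p_b.ravel())]
    ).reshape(a_b.shape)


def expected_attacked(params: FRParams, family: FRFamily, depletion: bool, p):
    """Expected hosts attacked out of ``p`` offered (scalar or array).

    Always within [0, p].  With ``depletion`` the Rogers correction is
    applied, with the density-dependent attack rate evaluated at the
    offered density.
    """
    scalar = np.isscalar(p)
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0):
        raise ValueError("host density p must be nonnegative")
    a = np.asarray(attack_rate(params, family, p_arr), dtype=float)
    H = 0.0 if family is FRFamily.FRI else params.H
    if depletion:
        R = _rogers_lambertw(a, p_arr, H, params.T)
    else:
        R = _holling(a, p_arr, H, params.T)
    return float(R) if scalar else R


def crossover_density(
    params1: FRParams,
    params2: FRParams,
    family: FRFamily,
    depletion: bool = False,
    densities=range(1, 151),
) -> int:
    """Largest integer density at which species 2 out-attacks species 1.

    Intended for a pair of curves that cross once inside the range:
    species 2 more efficient at low densities, species 1 above the
    crossover.  Raises :class:`NoCrossoverError` when species 2 never
    exceeds species 1 in the range, or still exceeds it at the upper end
    (no crossing inside the range).
    """
    d = np.asarray(list(densities), dtype=float)
    if d.size == 0:
        raise ValueError("empty density range")
    r1 = expected_attacked(params1, family, depletion, d)
    r2 = expected_attacked(params2, family, depletion, d)
    above = r2 > r1
    if not above.any():
        raise NoCrossoverError("species 2 never exceeds species 1 in the range")
    if above[-1]:
        raise NoCrossoverError("curves do not cross inside the search range")
    return int(d[above.nonzero()[0][-1]])
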
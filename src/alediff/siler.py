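"""Closed-form Siler (bathtub) mortality model.

The Siler hazard combines a declining juvenile component, a constant
background component and an exponentially rising senescent component:

    mu(x) = exp(a0 - a1*x) + c + exp(b0 + b1*x)

Each term integrates analytically, so the cumulative hazard and the
survival function S(x) = exp(-H(x)) are available in closed form.  Adult
life expectancy (ALE) conditional on survival to the age at first
reproduction ``alpha`` is obtained by adaptive quadrature of the
conditional survival curve; exact sampling of ages at death uses
inverse-CDF root finding on the closed-form cumulative hazard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "SilerParams",
    "hazard",
    "cumulative_hazard",
    "survival",
    "adult_life_expectancy",
    "sample_ages_at_death",
]


@dataclass(frozen=True)
class SilerParams:
    """The five Siler mortality parameters.

    Parameters
    ----------
    a0 : float
        Log-scale level of the juvenile (declining) mortality term.
        Unbounded.
    a1 : float
        Rate of decline of juvenile mortality (1/years). Must be > 0.
    c : float
        Age-independent background hazard (1/years). Must be > 0.
    b0 : float
        Log-scale level of the senescent mortality term. Unbounded.
    b1 : float
        Exponential rate of senescent mortality increase (1/years).
        Must be > 0.
    """

    a0: float
    a1: float
    c: float
    b0: float
    b1: float

    def __post_init__(self) -> None:
        if not (self.a1 > 0 and self.c > 0 and self.b1 > 0):
            raise ValueError(
                f"a1, c and b1 must be strictly positive; got "
                f"a1={self.a1}, c={self.c}, b1={self.b1}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.c, self.b0, self.b1])

    @classmethod
    def from_array(cls, theta) -> "SilerParams":
        a0, a1, c, b0, b1 = np.asarray(theta, dtype=float)
        return cls(a0=a0, a1=a1, c=c, b0=b0, b1=b1)


PARAM_NAMES = ("a0", "a1", "c", "b0", "b1")


def _check_age(age) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be nonnegative")
    return age


def hazard(params: SilerParams, age):
    """Siler hazard mu(x) = exp(a0 - a1*x) + c + exp(b0 + b1*x).

    Accepts scalar or array ages; strictly positive for valid params.
    """
    x = _check_age(age)
    out = (
        np.exp(params.a0 - params.a1 * x)
        + params.c
        + np.exp(params.b0 + params.b1 * x)
    )
    return float(out) if np.isscalar(age) or out.ndim == 0 else out


def cumulative_hazard(params: SilerParams, age):
    """Closed-form integral of the hazard from 0 to ``age``.

    H(x) = exp(a0)/a1 * (1 - exp(-a1*x)) + c*x + exp(b0)/b1 * (exp(b1*x) - 1)
    """
    x = _check_age(age)
    out = (
        np.exp(params.a0) / params.a1 * (1.0 - np.exp(-params.a1 * x))
        + params.c * x
        + np.exp(params.b0) / params.b1 * np.expm1(params.b1 * x)
    )
    return float(out) if np.isscalar(age) or out.ndim == 0 else out


def survival(params: SilerParams, age):
    """Cumulative survival from birth, S(x) = exp(-H(x)); S(0) = 1."""
    h = cumulative_hazard(params, age)
    return np.exp(-np.asarray(h)) if not np.isscalar(h) else float(np.exp(-h))


def _upper_age(params: SilerParams, alpha: float, rel_tol: float) -> float:
    """Age beyond which conditional survival from alpha is below rel_tol.

    Found by doubling then bisection on the closed-form survival; the
    senescent term guarantees such an age exists.
    """
    h_alpha = cumulative_hazard(params, alpha)
    target = -np.log(rel_tol)  # solve H(x) - H(alpha) = -log(rel_tol)

    hi = max(alpha, 1.0)
    while cumulative_hazard(params, hi) - h_alpha < target:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - safeguarded by param validation
            break
    return float(
        optimize.brentq(
            lambda x: cumulative_hazard(params, x) - h_alpha - target,
            alpha,
            hi,
            xtol=1e-8,
        )
    )


def adult_life_expectancy(
    params: SilerParams,
    alpha: float = 0.0,
    *,
    tail_tol: float = 1e-9,
    quad_tol: float = 1e-8,
) -> float:
    """Remaining life expectancy at the age at first reproduction.

    Computes ``integral_alpha^inf S(t) dt / S(alpha)`` with the upper
    limit taken where conditional survival drops below ``tail_tol``.

    Parameters
    ----------
    params : SilerParams
    alpha : float
        Age at first reproduction (years), >= 0.
    tail_tol : float
        Conditional-survival level defining the effective upper limit of
        integration (default 1e-9 of S(alpha)).
    quad_tol : float
        Absolute/relative tolerance of the adaptive quadrature.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    h_alpha = cumulative_hazard(params, alpha)
    if h_alpha > 700.0 or survival(params, alpha) == 0.0:
        raise ValueError("survival at alpha is numerically zero")
    upper = _upper_age(params, alpha, tail_tol)

    def cond_surv(t):
        return np.exp(-(cumulative_hazard(params, t) - h_alpha))

    value, _ = integrate.quad(
        cond_surv, alpha, upper, epsabs=quad_tol, epsrel=quad_tol, limit=200
    )
    return float(value)


def sample_ages_at_death(
    params: SilerParams,
    alpha: float,
    n: int,
    seed=None,
    *,
    xtol: float = 1e-8,
) -> np.ndarray:
    """Exact i.i.d. draws of ages at death, left-truncated at ``alpha``.

    Inverts the conditional CDF 1 - exp(-(H(x) - H(alpha))) by bracketed
    root finding, so draws follow the Siler death-age distribution without
    rejection tuning.  ``seed`` may be an int or a numpy Generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    h_alpha = cumulative_hazard(params, alpha)
    # H(x) - H(alpha) = E with E ~ Exponential(1)
    targets = rng.exponential(size=n)
    hi_cap = max(_upper_age(params, alpha, 1e-18), alpha + 1.0)
    while cumulative_hazard(params, hi_cap) - h_alpha < targets.max():
        hi_cap *= 2.0  # pragma: no cover - cap sits beyond the 1e-18 tail
    # vectorized bisection on the monotone cumulative hazard
    lo = np.full(n, alpha)
    hi = np.full(n, hi_cap)
    while np.max(hi - lo) > xtol:
        mid = 0.5 * (lo + hi)
        below = (cumulative_hazard(params, mid) - h_alpha) < targets
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)
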
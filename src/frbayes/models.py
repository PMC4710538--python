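"""Prey-depletion functional-response models.

Four type-II functional-response models for a no-replacement feeding
experiment in which ``P`` predators deplete an initial stock of ``N0``
prey over an exposure time ``t`` (hours):

* Holling type II (H2), purely prey-dependent:
  ``dN/dt = -a N P / (1 + a Th N)``
* Beddington-DeAngelis (BD), searching predators waste time on
  encounters with the other ``P - 1`` predators:
  ``dN/dt = -a N P / (1 + a Th N + c (P - 1))``
* Crowley-Martin (CM), interference also affects handling predators:
  ``dN/dt = -a N P / (1 + a Th N + c (P - 1) + a Th c N (P - 1))``
* Hassell-Varley (HV, in Sutherland's modified form), phenomenological
  predator dependence through an interference exponent that discounts
  the attack rate as ``a P^(-m)``:
  ``dN/dt = -a N P^(1-m) / (1 + a Th N P^(-m))``

``a`` is the attack rate (per hour), ``Th`` the handling time (hours),
``c`` the grouped interference magnitude (encounter rate with other
predators times time wasted per encounter, dimensionless) and ``m`` the
interference exponent.  At ``P = 1`` all four models coincide with
Holling type II.

Because prey are depleted during the trial the instantaneous disc
equation does not apply; the observable is the solution ``N(t)`` of the
depletion ODE.  All four ODEs separate into the implicit form

    alpha * ln(N0 / N) + beta * (N0 - N) = A * t

with model-specific constants ``(A, alpha, beta)``, which this module
solves exactly via the Lambert W function (with a bracketed Brent
root-finder on the same implicit residual as an alternative route).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import lambertw

__all__ = [
    "ModelKind",
    "Params",
    "Condition",
    "depletion_rate",
    "implicit_residual",
    "remaining_prey",
    "remaining_prey_vec",
    "consumption_probability",
]


class ModelKind(str, enum.Enum):
    """Which functional-response model."""

    H2 = "H2"
    BD = "BD"
    CM = "CM"
    HV = "HV"

    @property
    def free_params(self) -> tuple[str, ...]:
        """Names of the parameters this model actually uses."""
        if self is ModelKind.H2:
            return ("a", "th")
        if self is ModelKind.HV:
            return ("a", "th", "m")
        return ("a", "th", "c")  # BD, CM

    @property
    def label(self) -> str:
        return {
            ModelKind.H2: "Holling type II",
            ModelKind.BD: "Beddington-DeAngelis",
            ModelKind.CM: "Crowley-Martin",
            ModelKind.HV: "Hassell-Varley",
        }[self]


@dataclass(frozen=True)
class Params:
    """Functional-response parameters.

    Attributes
    ----------
    a : float
        Attack rate, per hour; > 0.
    th : float
        Handling time, hours; >= 0.
    c : float
        Interference magnitude (BD, CM only); >= 0.
    m : float
        Interference exponent (HV only); >= 0.

    Parameters a model kind does not use are ignored by every operation
    on that kind.
    """

    a: float
    th: float = 0.0
    c: float = 0.0
    m: float = 0.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"attack rate a must be > 0, got {self.a}")
        if self.th < 0:
            raise ValueError(f"handling time th must be >= 0, got {self.th}")
        if self.c < 0:
            raise ValueError(f"interference magnitude c must be >= 0, got {self.c}")
        if self.m < 0:
            raise ValueError(f"interference exponent m must be >= 0, got {self.m}")

    @classmethod
    def from_vector(cls, kind: ModelKind, values) -> "Params":
        """Build Params for ``kind`` from a vector ordered as ``kind.free_params``."""
        names = kind.free_params
        if len(values) != len(names):
            raise ValueError(f"{kind.value} expects {len(names)} parameters, got {len(values)}")
        return cls(**dict(zip(names, map(float, values))))

    def vector(self, kind: ModelKind) -> np.ndarray:
        return np.array([getattr(self, name) for name in kind.free_params], float)


@dataclass(frozen=True)
class Condition:
    """One experimental condition: N0 prey exposed to P predators for t hours."""

    n0: int
    p: int
    t: float

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError(f"initial prey N0 must be >= 1, got {self.n0}")
        if self.p < 1:
            raise ValueError(f"predator count P must be >= 1, got {self.p}")
        if self.t < 0:
            raise ValueError(f"exposure time t must be >= 0, got {self.t}")


def _rate_coeffs(kind: ModelKind, params: Params, p: int) -> tuple[float, float, float]:
    """Coefficients (A, alpha, beta) with dN/dt = -A N / (alpha + beta N)."""
    a, th = params.a, params.th
    if kind is ModelKind.H2:
        return a * p, 1.0, a * th
    if kind is ModelKind.BD:
        return a * p, 1.0 + params.c * (p - 1), a * th
    if kind is ModelKind.CM:
        # denominator factorises: (1 + a Th N)(1 + c(P-1))
        f = 1.0 + params.c * (p - 1)
        return a * p, f, a * th * f
    if kind is ModelKind.HV:
        # effective attack rate a P^(-m); total pressure keeps the factor P
        q = float(p) ** (-params.m)
        return a * q * p, 1.0, a * th * q
    raise ValueError(f"unknown model kind: {kind!r}")


def depletion_rate(kind: ModelKind, params: Params, n: float, p: int) -> float:
    """Instantaneous prey depletion rate dN/dt (prey per hour, <= 0)."""
    if n < 0:
        raise ValueError(f"prey count N must be >= 0, got {n}")
    if p < 1:
        raise ValueError(f"predator count P must be >= 1, got {p}")
    big_a, alpha, beta = _rate_coeffs(kind, params, p)
    return -big_a * n / (alpha + beta * n)


def implicit_residual(
    kind: ModelKind, params: Params, n0: float, n: float, p: int, t: float
) -> float:
    """Residual of the separated-variables implicit solution.

    Returns ``g(N) = alpha ln(N/N0) + beta (N - N0) + A t``, which is
    zero iff ``N`` solves the depletion ODE at time ``t``, and strictly
    increasing in ``N`` on ``(0, N0]``.
    """
    if not 0 < n <= n0:
        raise ValueError(f"candidate N must satisfy 0 < N <= N0, got N={n}, N0={n0}")
    big_a, alpha, beta = _rate_coeffs(kind, params, p)
    return alpha * math.log(n / n0) + beta * (n - n0) + big_a * t


def _lambertw_exp(y: np.ndarray) -> np.ndarray:
    """Solve w + ln(w) = y for w > 0, i.e. w = W(e^y), overflow-safely."""
    y = np.asarray(y, dtype=float)
    w = np.empty_like(y)
    small = y <= 600.0
    if np.any(small):
        w[small] = lambertw(np.exp(y[small])).real
    big = ~small
    if np.any(big):
        # asymptotic start w ~ y - ln y, polished by Newton on w + ln w - y
        yy = y[big]
        ww = yy - np.log(yy)
        for _ in range(60):
            step = (ww + np.log(ww) - yy) / (1.0 + 1.0 / ww)
            ww -= step
            if np.all(np.abs(step) <= 1e-14 * np.abs(ww)):
                break
        w[big] = ww
    return w


def remaining_prey_vec(kind: ModelKind, params: Params, n0, p: int, t) -> np.ndarray:
    """Remaining prey N(t) for arrays of initial densities / times.

    Exact solution of the implicit equation via the Lambert W function:
    with k = beta/alpha and tau = A t / alpha,
    ``k N e^{k N} = k N0 e^{k N0 - tau}``  =>  ``N = W(k N0 e^{k N0 - tau}) / k``,
    degenerating to ``N = N0 e^{-tau}`` when handling time is zero.
    """
    n0 = np.asarray(n0, dtype=float)
    t = np.broadcast_to(np.asarray(t, dtype=float), n0.shape)
    if np.any(n0 < 1):
        raise ValueError("initial prey N0 must be >= 1")
    if np.any(t < 0):
        raise ValueError("exposure time t must be >= 0")
    big_a, alpha, beta = _rate_coeffs(kind, params, p)
    tau = big_a * t / alpha
    if beta == 0.0:
        return n0 * np.exp(-tau)
    k = beta / alpha
    y = np.log(k * n0) + k * n0 - tau
    return _lambertw_exp(y) / k


def _remaining_prey_root(
    kind: ModelKind, params: Params, cond: Condition, xtol: float = 1e-10
) -> float:
    """Bracketed Brent root of the implicit residual on (eps, N0]."""
    n0, p, t = cond.n0, cond.p, cond.t
    g = lambda n: implicit_residual(kind, params, n0, n, p, t)
    hi = float(n0)
    lo = 1e-12 * n0
    # g is increasing with g(N0) = A t >= 0; push the bracket down in the
    # (numerically extreme) case that the root lies below eps
    while g(lo) > 0.0:
        lo *= 1e-12
        if lo < 1e-280:
            raise RuntimeError(
                "root bracketing failed: remaining prey underflows "
                f"for {kind.value} at {params} and {cond}"
            )
    return brentq(g, lo, hi, xtol=xtol)


def remaining_prey(
    kind: ModelKind, params: Params, cond: Condition, method: str = "lambertw"
) -> float:
    """Prey remaining at time t, in (0, N0].

    ``method="lambertw"`` (default) uses the exact closed form;
    ``method="brentq"`` solves the same implicit equation by bracketed
    root-finding, kept as an independent route for cross-checking.
    """
    if cond.t == 0.0:
        return float(cond.n0)
    if method == "lambertw":
        n = float(remaining_prey_vec(kind, params, [cond.n0], cond.p, cond.t)[0])
    elif method == "brentq":
        n = _remaining_prey_root(kind, params, cond)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return min(n, float(cond.n0))


def consumption_probability(
    kind: ModelKind, params: Params, cond: Condition, method: str = "lambertw"
) -> float:
    """Probability p(t) = (N0 - N(t)) / N0 that a prey item is eaten by t."""
    if cond.t == 0.0:
        return 0.0
    n = remaining_prey(kind, params, cond, method=method)
    return 1.0 - n / cond.n0
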
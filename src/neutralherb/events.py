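"""Single-feeding-event damage model.

The proportion of leaf area removed in one feeding event by a randomly sampled
herbivore, ``phi``, follows a truncated Pareto (power-law) distribution on
``[phi_m, phi_M]`` with exponent ``alpha``:

    P(phi) = (1 - alpha) * phi**(-alpha) / (phi_M**(1-alpha) - phi_m**(1-alpha))

The exponent is not free: it is fixed by metabolic scaling theory.  If
per-event consumption scales with herbivore body mass M as ``M**a``, abundance
as ``M**b`` and species richness as ``M**c``, a change of variables gives
``alpha = 1 - (b + c + 1)/a``; the canonical triple (3/4, -3/4, -2/3) yields
``alpha = 14/9``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational

import numpy as np

from .exceptions import DomainError, ParameterError

#: Default power-law exponent of per-event damage, from metabolic scaling.
ALPHA_DEFAULT = float(Fraction(14, 9))


@dataclass(frozen=True)
class EventParams:
    """Bounds and exponent of the per-event damage distribution.

    Parameters
    ----------
    phi_m : float
        Lower bound of per-event proportion damage, in (0, 1).  Default 0.005,
        the smallest damage a visual survey at 0.5% resolution can record.
    phi_M : float
        Upper bound, in (phi_m, 1].  Default 1.0 (a whole leaf).
    alpha : float
        Power-law exponent.  Default 14/9; ``alpha == 1`` is rejected because
        the normalization constant is undefined there.
    """

    phi_m: float = 0.005
    phi_M: float = 1.0
    alpha: float = ALPHA_DEFAULT

    def __post_init__(self) -> None:
        if not (0.0 < self.phi_m < self.phi_M <= 1.0):
            raise ParameterError(
                f"require 0 < phi_m < phi_M <= 1, got phi_m={self.phi_m}, "
                f"phi_M={self.phi_M}"
            )
        if self.alpha == 1.0:
            raise ParameterError("alpha = 1 is not supported (normalization undefined)")

    @property
    def _norm(self) -> float:
        """Normalization denominator phi_M^(1-alpha) - phi_m^(1-alpha)."""
        e = 1.0 - self.alpha
        return self.phi_M**e - self.phi_m**e


def event_pdf(x, params: EventParams):
    """Density of per-event damage; zero outside ``[phi_m, phi_M]``."""
    x = np.asarray(x, dtype=float)
    inside = (x >= params.phi_m) & (x <= params.phi_M)
    out = np.zeros_like(x)
    xi = np.where(inside, x, 1.0)  # dummy to avoid 0**negative
    out = np.where(inside, (1.0 - params.alpha) * xi ** (-params.alpha) / params._norm, 0.0)
    return out if out.ndim else float(out)


def event_cdf(x, params: EventParams):
    """CDF of per-event damage (0 below ``phi_m``, 1 above ``phi_M``)."""
    x = np.asarray(x, dtype=float)
    e = 1.0 - params.alpha
    xc = np.clip(x, params.phi_m, params.phi_M)
    out = (xc**e - params.phi_m**e) / params._norm
    out = np.where(x < params.phi_m, 0.0, np.where(x > params.phi_M, 1.0, out))
    return out if out.ndim else float(out)


def event_quantile(u, params: EventParams):
    """Closed-form inverse CDF.

    ``Q(u) = (phi_m^(1-a) + u (phi_M^(1-a) - phi_m^(1-a)))^(1/(1-a))``
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u > 1.0):
        raise DomainError("quantile argument must lie in [0, 1]")
    e = 1.0 - params.alpha
    out = (params.phi_m**e + u * params._norm) ** (1.0 / e)
    # guard fp round-off at the edges
    out = np.clip(out, params.phi_m, params.phi_M)
    return out if out.ndim else float(out)


def event_sample(n: int, params: EventParams, seed=None) -> np.ndarray:
    """Draw ``n`` per-event damages by inverse-CDF sampling.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return event_quantile(rng.random(int(n)), params)


def event_moment(n: int, params: EventParams) -> float:
    """Closed-form n-th raw moment of per-event damage.

    ``E[phi^n] = ((1-a)/(n+1-a)) (phi_M^(n+1-a) - phi_m^(n+1-a)) / (phi_M^(1-a) - phi_m^(1-a))``
    """
    if n < 1 or int(n) != n:
        raise ParameterError("moment order must be a positive integer")
    a = params.alpha
    if n + 1.0 - a == 0.0:
        raise ParameterError(f"moment order {n} is degenerate for alpha={a}")
    e = n + 1.0 - a
    return (1.0 - a) / e * (params.phi_M**e - params.phi_m**e) / params._norm


def _as_fraction(x) -> Fraction:
    if isinstance(x, Rational):
        return Fraction(x)
    # floats are interpreted as the nearest small rational (scaling exponents
    # are quoted as simple fractions like 3/4 or -2/3)
    return Fraction(x).limit_denominator(10**6)


def derive_alpha(metabolic_exponent, density_exponent, richness_exponent) -> Fraction:
    """Derive the per-event damage exponent from allometric scaling laws.

    With per-event consumption ``phi ~ M**a``, abundance ``~ M**b`` and species
    richness ``~ M**c``, sampling an event from the pool weights body mass by
    ``M**(b+c)``; changing variables to ``phi`` gives ``P(phi) ~ phi**(-alpha)``
    with ``alpha = 1 - (b + c + 1)/a``.  Exact rational arithmetic: the
    canonical triple (3/4, -3/4, -2/3) returns ``Fraction(14, 9)``.
    """
    a = _as_fraction(metabolic_exponent)
    b = _as_fraction(density_exponent)
    c = _as_fraction(richness_exponent)
    if a == 0:
        raise ParameterError("metabolic exponent must be nonzero")
    return 1 - (b + c + 1) / a
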
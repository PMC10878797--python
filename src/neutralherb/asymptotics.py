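"""Inequality indices of damage and their large-attack-rate approximation.

When the attack rate ``lambda`` is large and cumulative damage stays well
below 1, the compound-Poisson sum is approximately normal with mean
``lambda E[phi]`` and variance ``lambda E[phi^2]``.  Any unitless inequality
index I that is proportional to CV in the normal limit then satisfies

    I[phi_T] ~= sqrt(E[phi^2] / lambda) / (c E[phi])

with an index-specific constant ``c``: CV has c = 1, the Gini index
c = sqrt(pi) (the Gini of N(mu, sigma) is sigma/(mu sqrt(pi))), and the
Hoover index c = sqrt(2 pi).  Every index therefore declines as
1/sqrt(lambda): damage inequality is a predictable decreasing function of
herbivory intensity under neutrality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .events import event_moment
from .exceptions import DomainError
from .neutral import NeutralModel

__all__ = ["IndexSpec", "INDEX_CONSTANTS", "sample_index", "gini", "hoover", "asymptotic_index"]

#: normal-limit constant linking each index to CV
INDEX_CONSTANTS = {
    "cv": 1.0,
    "gini": math.sqrt(math.pi),
    "hoover": math.sqrt(2.0 * math.pi),
}


@dataclass(frozen=True)
class IndexSpec:
    """A named unitless inequality index and its normal-limit constant."""

    name: str
    c: float

    @classmethod
    def from_name(cls, name: str) -> "IndexSpec":
        key = name.lower()
        if key not in INDEX_CONSTANTS:
            raise DomainError(f"unknown index {name!r}; choose from {sorted(INDEX_CONSTANTS)}")
        return cls(key, INDEX_CONSTANTS[key])


def _as_spec(spec) -> IndexSpec:
    return spec if isinstance(spec, IndexSpec) else IndexSpec.from_name(spec)


def gini(values) -> float:
    """Gini coefficient, pairwise definition ``sum|x_i - x_j| / (2 n^2 mean)``
    computed in O(n log n) via the sorted form."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    m = x.mean()
    if m <= 0:
        raise DomainError("Gini undefined for non-positive mean")
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * n * m))


def hoover(values) -> float:
    """Hoover (Robin Hood) index ``sum|x_i - mean| / (2 n mean)``."""
    x = np.asarray(values, dtype=float)
    m = x.mean()
    if m <= 0:
        raise DomainError("Hoover index undefined for non-positive mean")
    return float(np.abs(x - m).sum() / (2.0 * x.size * m))


def sample_index(values, spec="cv") -> float:
    """Exact sample inequality index (CV, Gini or Hoover).

    CV uses the sample standard deviation (ddof = 1); zero variance gives 0,
    zero or negative mean raises :class:`DomainError`.
    """
    spec = _as_spec(spec)
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError("need at least two values")
    m = x.mean()
    if m <= 0:
        raise DomainError(f"{spec.name} undefined for non-positive mean")
    if np.all(x == x[0]):
        return 0.0
    if spec.name == "cv":
        return float(np.std(x, ddof=1) / m)
    if spec.name == "gini":
        return gini(x)
    return hoover(x)


def asymptotic_index(model: NeutralModel, spec="cv") -> float:
    """Normal-limit approximation ``sqrt(E[phi^2]/lam) / (c E[phi])``.

    Valid when ``lam`` is large and cumulative damage remains well below 1
    (truncation negligible); at small ``lam`` the approximation error can be
    substantial and is reported by comparison, not hidden.
    """
    spec = _as_spec(spec)
    if model.lam <= 0:
        raise DomainError("asymptotic index requires lam > 0")
    m1 = event_moment(1, model.event)
    m2 = event_moment(2, model.event)
    return math.sqrt(m2 / model.lam) / (spec.c * m1)
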
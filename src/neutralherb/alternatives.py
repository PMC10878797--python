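"""Phenomenological competitor distributions for proportion damage.

Two commonly used non-process-based models with atoms at the boundaries:

* hurdle truncated lognormal (HTLN, 3 parameters): mass ``p0`` at 0; the
  lognormal's mass above 1 is lumped into an atom at 1, i.e.
  ``P(1) = (1 - p0)(1 - G(1; mu, sigma))`` and density
  ``(1 - p0) g(x; mu, sigma)`` on (0, 1);
* zero-one-inflated beta (ZOIB, 4 parameters): independent atoms ``p0`` and
  ``p1`` plus a beta density on the interior scaled by ``1 - p0 - p1``,
  parameterized by mean ``mu`` and precision ``prec`` (shape parameters
  ``a = mu prec``, ``b = (1 - mu) prec``).

The boundary masses factor out of the likelihood, so their MLEs are the
empirical fractions of exact 0s and 1s; interior parameters are estimated
numerically.  Interior observations use the same interval-censoring
convention as the neutral model (band width ``precision``) so that AICc
differences across the three models reflect distribution shape, not data
representation.  Model comparison uses
``delta_aicc(alt, neutral) = AICc_alt - AICc_neutral``; positive values
favour the neutral model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .exceptions import ComparisonError, ParameterError
from .neutral import NeutralFit, _validate_damage, aicc

__all__ = [
    "HTLNParams",
    "ZOIBParams",
    "HTLNFit",
    "ZOIBFit",
    "htln_logpdf",
    "zoib_logpdf",
    "fit_htln",
    "fit_zoib",
    "delta_aicc",
    "HurdleTruncatedLognormal",
    "ZeroOneInflatedBeta",
]


@dataclass(frozen=True)
class HTLNParams:
    p0: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= 1.0):
            raise ParameterError("p0 must be in [0, 1]")
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")


@dataclass(frozen=True)
class ZOIBParams:
    p0: float
    p1: float
    mu: float
    prec: float

    def __post_init__(self) -> None:
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1:
            raise ParameterError("require p0, p1 >= 0 and p0 + p1 <= 1")
        if not (0.0 < self.mu < 1.0) or self.prec <= 0:
            raise ParameterError("require 0 < mu < 1 and prec > 0")


def _log(x: float) -> float:
    return math.log(x) if x > 0 else -math.inf

def htln_logpdf(x, params: HTLNParams):
    """Pointwise HTLN log density/mass on [0, 1]."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ParameterError("x must be in [0, 1]")
    dist = stats.lognorm(s=params.sigma, scale=math.exp(params.mu))
    with np.errstate(divide="ignore"):
        interior = np.log1p(-params.p0) + dist.logpdf(x) if params.p0 < 1 else np.full_like(x, -np.inf)
        out = np.where(
            x == 0.0,
            _log(params.p0),
            np.where(x == 1.0, _log((1.0 - params.p0) * dist.sf(1.0)), interior),
        )
    return out if out.ndim else float(out)


def zoib_logpdf(x, params: ZOIBParams):
    """Pointwise ZOIB log density/mass on [0, 1]."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ParameterError("x must be in [0, 1]")
    a = params.mu * params.prec
    b = (1.0 - params.mu) * params.prec
    pc = 1.0 - params.p0 - params.p1
    with np.errstate(divide="ignore"):
        interior = (
            _log(pc) + stats.beta.logpdf(np.clip(x, 1e-300, 1 - 1e-16), a, b)
            if pc > 0
            else np.full_like(x, -np.inf)
        )
        out = np.where(
            x == 0.0, _log(params.p0), np.where(x == 1.0, _log(params.p1), interior)
        )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HTLNFit:
    params: HTLNParams
    loglik: float
    n: int
    aicc: float
    k: int = 3
    interior_identifiable: bool = True

    def to_dict(self) -> dict:
        return {
            "p0": self.params.p0, "mu": self.params.mu, "sigma": self.params.sigma,
            "loglik": self.loglik, "n": self.n, "aicc": self.aicc, "k": self.k,
            "interior_identifiable": self.interior_identifiable,
        }


@dataclass(frozen=True)
class ZOIBFit:
    params: ZOIBParams
    loglik: float
    n: int
    aicc: float
    k: int = 4
    interior_identifiable: bool = True

    def to_dict(self) -> dict:
        return {
            "p0": self.params.p0, "p1": self.params.p1, "mu": self.params.mu,
            "prec": self.params.prec, "loglik": self.loglik, "n": self.n,
            "aicc": self.aicc, "k": self.k,
            "interior_identifiable": self.interior_identifiable,
        }


def _atom_loglik(n0: int, n1: int, n: int, two_atoms: bool) -> float:
    """Multinomial atom contribution at the factorized MLE."""
    ll = 0.0
    if two_atoms:
        nc = n - n0 - n1
        for cnt in (n0, n1, nc):
            if cnt:
                ll += cnt * math.log(cnt / n)
    else:
        if n0:
            ll += n0 * math.log(n0 / n)
        if n - n0:
            ll += (n - n0) * math.log((n - n0) / n)
    return ll


def _bands(v: np.ndarray, precision: float) -> tuple[np.ndarray, np.ndarray]:
    return np.clip(v - 0.5 * precision, 0.0, 1.0), np.clip(v + 0.5 * precision, 0.0, 1.0)


def fit_htln(data, precision: float = 0.005) -> HTLNFit:
    """MLE of the hurdle truncated lognormal.

    ``p0`` is the empirical fraction of exact zeros (its MLE under the hurdle
    factorization); (mu, sigma) maximize the interval-censored likelihood of
    interior values plus the atom term of exact ones.
    """
    x = _validate_damage(data)
    n = x.size
    n0 = int(np.sum(x == 0.0))
    n1 = int(np.sum(x == 1.0))
    p0_hat = n0 / n
    vi = x[(x > 0.0) & (x < 1.0)]
    hurdle_ll = _atom_loglik(n0, 0, n, two_atoms=False)

    if vi.size == 0 and n1 == 0:
        # no positive observations at all: likelihood is the hurdle term only
        return HTLNFit(HTLNParams(p0_hat, 0.0, 1.0), hurdle_ll, n,
                       aicc(hurdle_ll, 3, n), interior_identifiable=False)

    lo, hi = _bands(vi, precision)

    def nll(theta) -> float:
        mu, logsig = theta
        sig = math.exp(logsig)
        dist = stats.lognorm(s=sig, scale=math.exp(mu))
        with np.errstate(divide="ignore", invalid="ignore"):
            band = dist.cdf(hi) - dist.cdf(lo)
            ll = np.log(np.maximum(band, 0.0)).sum() if vi.size else 0.0
        if n1:
            ll += n1 * _log(dist.sf(1.0))
        return math.inf if not np.isfinite(ll) else -ll

    if vi.size:
        logs = np.log(vi)
        x0 = np.array([logs.mean(), math.log(max(logs.std(), 1e-2))])
    else:
        x0 = np.array([0.5, math.log(1.0)])  # ones only: push mass above 1
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    mu, sigma = float(res.x[0]), float(math.exp(res.x[1]))
    # full likelihood: hurdle atoms + (1-p0) factor on each positive obs + interior/one terms
    pos_ll = -float(res.fun)
    ll = hurdle_ll + pos_ll
    identifiable = vi.size > 0
    if not identifiable:
        warnings.warn("no interior observations: HTLN (mu, sigma) weakly identified",
                      RuntimeWarning, stacklevel=2)
    return HTLNFit(HTLNParams(p0_hat, mu, sigma), ll, n, aicc(ll, 3, n),
                   interior_identifiable=identifiable)


def fit_zoib(data, precision: float = 0.005) -> ZOIBFit:
    """MLE of the zero-one-inflated beta (two independent boundary atoms).

    ``p0`` and ``p1`` are the empirical fractions of exact 0s and 1s;
    (mu, prec) maximize the interval-censored likelihood of interior values.
    """
    x = _validate_damage(data)
    n = x.size
    n0 = int(np.sum(x == 0.0))
    n1 = int(np.sum(x == 1.0))
    vi = x[(x > 0.0) & (x < 1.0)]
    atom_ll = _atom_loglik(n0, n1, n, two_atoms=True)
    p0_hat, p1_hat = n0 / n, n1 / n

    if vi.size == 0:
        return ZOIBFit(ZOIBParams(p0_hat, p1_hat, 0.5, 2.0), atom_ll, n,
                       aicc(atom_ll, 4, n), interior_identifiable=False)

    lo, hi = _bands(vi, precision)

    def nll(theta) -> float:
        mu = 1.0 / (1.0 + math.exp(-theta[0]))
        prec = math.exp(theta[1])
        a, b = mu * prec, (1.0 - mu) * prec
        with np.errstate(divide="ignore", invalid="ignore"):
            band = stats.beta.cdf(hi, a, b) - stats.beta.cdf(lo, a, b)
            ll = np.log(np.maximum(band, 0.0)).sum()
        return math.inf if not np.isfinite(ll) else -ll

    m = vi.mean()
    v = max(vi.var(), 1e-6)
    prec0 = max(m * (1.0 - m) / v - 1.0, 0.1)
    x0 = np.array([math.log(m / (1.0 - m)), math.log(prec0)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    mu = 1.0 / (1.0 + math.exp(-float(res.x[0])))
    prec = float(math.exp(res.x[1]))
    ll = atom_ll - float(res.fun)
    return ZOIBFit(ZOIBParams(p0_hat, p1_hat, mu, prec), ll, n, aicc(ll, 4, n))


def delta_aicc(alt_fit, neutral_fit: NeutralFit) -> float:
    """``AICc(alt) - AICc(neutral)``; positive favours the neutral model.

    Both fits must be on the same data under the same censoring convention.
    """
    if alt_fit.n != neutral_fit.n:
        raise ComparisonError(
            f"fits are on different sample sizes ({alt_fit.n} vs {neutral_fit.n})"
        )
    return float(alt_fit.aicc - neutral_fit.aicc)


# ---------------------------------------------------------------------------
# sklearn-style estimators


class HurdleTruncatedLognormal(BaseEstimator):
    """HTLN distribution as a density estimator (see :func:`fit_htln`).

    Attributes after fitting: ``p0_``, ``mu_``, ``sigma_``, ``loglik_``,
    ``n_``, ``aicc_``.
    """

    def __init__(self, precision: float = 0.005):
        self.precision = precision

    def fit(self, X, y=None):
        fit = fit_htln(np.asarray(X, dtype=float).ravel(), precision=self.precision)
        self.p0_ = fit.params.p0
        self.mu_ = fit.params.mu
        self.sigma_ = fit.params.sigma
        self.loglik_ = fit.loglik
        self.n_ = fit.n
        self.aicc_ = fit.aicc
        self.fit_ = fit
        return self

    def score_samples(self, X) -> np.ndarray:
        return np.asarray(htln_logpdf(np.asarray(X, dtype=float).ravel(),
                                      HTLNParams(self.p0_, self.mu_, self.sigma_)))

    def sample(self, n_samples: int = 1, random_state=None) -> np.ndarray:
        rng = np.random.default_rng(random_state)
        out = np.zeros(n_samples)
        pos = rng.random(n_samples) >= self.p0_
        draws = rng.lognormal(self.mu_, self.sigma_, int(pos.sum()))
        out[pos] = np.minimum(draws, 1.0)
        return out


class ZeroOneInflatedBeta(BaseEstimator):
    """ZOIB distribution as a density estimator (see :func:`fit_zoib`).

    Attributes after fitting: ``p0_``, ``p1_``, ``mu_``, ``prec_``,
    ``loglik_``, ``n_``, ``aicc_``.
    """

    def __init__(self, precision: float = 0.005):
        self.precision = precision

    def fit(self, X, y=None):
        fit = fit_zoib(np.asarray(X, dtype=float).ravel(), precision=self.precision)
        self.p0_ = fit.params.p0
        self.p1_ = fit.params.p1
        self.mu_ = fit.params.mu
        self.prec_ = fit.params.prec
        self.loglik_ = fit.loglik
        self.n_ = fit.n
        self.aicc_ = fit.aicc
        self.fit_ = fit
        return self

    def score_samples(self, X) -> np.ndarray:
        return np.asarray(zoib_logpdf(np.asarray(X, dtype=float).ravel(),
                                      ZOIBParams(self.p0_, self.p1_, self.mu_, self.prec_)))

    def sample(self, n_samples: int = 1, random_state=None) -> np.ndarray:
        rng = np.random.default_rng(random_state)
        u = rng.random(n_samples)
        out = np.zeros(n_samples)
        out[u >= 1.0 - self.p1_] = 1.0
        interior = (u >= self.p0_) & (u < 1.0 - self.p1_)
        a, b = self.mu_ * self.prec_, (1.0 - self.mu_) * self.prec_
        out[interior] = rng.beta(a, b, int(interior.sum()))
        return out
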
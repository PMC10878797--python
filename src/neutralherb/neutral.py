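"""Neutral cumulative-damage model: a truncated compound Poisson process.

Cumulative proportion damage on a leaf is ``phi_T = min(sum_{i<=k} phi_i, 1)``
where the number of feeding events ``k`` is Poisson(lambda) and the per-event
damages ``phi_i`` are iid truncated Pareto (see :mod:`neutralherb.events`).
The resulting distribution is mixed: an atom ``p0 = exp(-lambda)`` at 0, an
atom ``p1`` at 1 (leaves eaten whole), and a continuous density on (0, 1)
with no closed form.

The continuous part is computed on a uniform lattice of (0, 1) by iterated
discrete convolution of the cell-mass-discretized event density, truncating
mass above 1 into the atom at each step (truncation is absorbing because
event damages are positive).  The k-fold convolutions do not depend on
``lambda``, only the Poisson weights do, so they are cached per
(EventParams, grid size) and a maximum-likelihood fit of ``lambda`` costs a
single lattice build.

The observation model is interval censoring: a recorded value ``v`` in (0,1)
contributes the probability of the band of width ``precision`` (default
0.005, the visual-survey recording resolution) centred on ``v``; exact 0s and
1s contribute the atom masses.  A pure density mode is available for
continuous data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal, stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, DensityMixin

from .events import ALPHA_DEFAULT, EventParams, event_cdf, event_quantile
from .exceptions import DataError, DomainError, ParameterError

__all__ = [
    "NeutralModel",
    "NeutralFit",
    "MixedDamageDistribution",
    "PlantScaleConfig",
    "simulate_damage",
    "damage_distribution",
    "loglik",
    "fit_neutral",
    "fit_presence_absence",
    "plant_scale_event_params",
    "aicc",
    "NeutralDamageModel",
]

#: sub-1 probability below which a k-fold convolution is treated as fully
#: absorbed into the atom at 1
_SUBONE_EPS = 1e-13

_LAM_BOUNDS = (1e-4, 1e3)


@dataclass(frozen=True)
class NeutralModel:
    """Attack rate plus event-size parameters; the full model has one free
    parameter (``lam``)."""

    lam: float
    event: EventParams = field(default_factory=EventParams)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ParameterError(f"attack rate must be >= 0, got {self.lam}")


@dataclass(frozen=True)
class PlantScaleConfig:
    """Leaves per plant; the survey median is the paper-of-record choice."""

    L: int

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ParameterError("L must be >= 1")


def plant_scale_event_params(event: EventParams, cfg) -> EventParams:
    """Rescale event bounds to the whole-plant scale.

    One leaf is a fraction 1/L of the plant's leaf area, so the per-event
    bounds are multiplied by 1/L; the exponent is unchanged and cumulative
    damage still truncates at 1.  ``cfg`` is a :class:`PlantScaleConfig` or a
    plain leaf count.
    """
    L = cfg.L if isinstance(cfg, PlantScaleConfig) else int(cfg)
    if L < 1:
        raise ParameterError("L must be >= 1")
    return EventParams(event.phi_m / L, event.phi_M / L, event.alpha)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``-2 ll + 2k + 2k(k+1)/(n-k-1)``.

    Returns ``inf`` when ``n <= k + 1`` (the correction diverges).
    """
    if n <= k + 1:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


# ---------------------------------------------------------------------------
# lattice discretization and cached k-fold convolutions


class _EventLattice:
    """Cell-mass discretization of the event distribution on a uniform
    lattice ``x_i = i/N`` of [0, 1], with lazily built k-fold convolutions
    truncated at 1.

    ``subone(k)`` is the probability mass vector of the sum of k events on
    lattice indices 0..N-1 (index 0 always zero mass); ``absorbed(k)`` is the
    probability the sum has reached 1.  ``k_abs`` is the first k at which the
    sub-1 mass is numerically zero, after which every further event count is
    fully absorbed.
    """

    def __init__(self, event: EventParams, grid_size: int):
        if grid_size < 256:
            raise ParameterError("grid_size must be >= 256")
        self.event = event
        self.N = int(grid_size)
        self.h = 1.0 / self.N
        N, h = self.N, self.h
        # mass of cell i = F((i+1/2)h) - F((i-1/2)h); mass below h/2 lumped
        # into cell 1 so that k>=1 events never land on lattice index 0
        right = np.minimum((np.arange(N) + 0.5) * h, 1.0)
        cum = event_cdf(right, event)
        m = np.empty(N)
        m[0] = 0.0
        m[1] = cum[1]
        m[2:] = cum[2:] - cum[1:-1]
        self._subone = [None, m]
        self._absorbed = [0.0, 1.0 - float(cum[-1])]
        self._cum = [None]
        nz = np.nonzero(m)[0]
        self._i_min = int(nz[0]) if nz.size else self.N
        self._k_abs: int | None = 1 if m.sum() < _SUBONE_EPS else None

    def _extend_to(self, k: int) -> None:
        base = self._subone[1]
        while len(self._subone) <= k and self._k_abs is None:
            prev = self._subone[-1]
            conv = signal.fftconvolve(prev, base)
            s = conv[: self.N].copy()
            s[s < 0] = 0.0  # fft round-off
            # k events sum to at least k * phi_m: clear fft noise below support
            s[: min(len(self._subone) * self._i_min, self.N)] = 0.0
            self._subone.append(s)
            tot = float(s.sum())
            self._absorbed.append(1.0 - tot)
            if tot < _SUBONE_EPS:
                self._k_abs = len(self._subone) - 1

    @property
    def k_abs(self) -> int:
        """Smallest event count whose sub-1 mass is numerically zero."""
        if self._k_abs is None:
            # hard cap: k * phi_m >= 1 forces absorption
            cap = int(np.ceil(1.0 / self.event.phi_m)) + 2
            self._extend_to(cap)
            if self._k_abs is None:  # pragma: no cover - cap guarantees this
                self._k_abs = cap
        return self._k_abs

    def subone(self, k: int) -> np.ndarray:
        if k < 1:
            raise ParameterError("k must be >= 1")
        self._extend_to(k)
        if k < len(self._subone):
            return self._subone[k]
        return np.zeros(self.N)

    def absorbed(self, k: int) -> float:
        self._extend_to(k)
        if k < len(self._absorbed):
            return self._absorbed[k]
        return 1.0

    def cum_subone(self, k: int) -> np.ndarray:
        """Cumulative sub-1 mass at cell right edges ``(i+1/2)h``, i=0..N-1."""
        while len(self._cum) <= min(k, self.k_abs):
            self._cum.append(np.cumsum(self.subone(len(self._cum))))
        if k <= self.k_abs:
            return self._cum[k]
        return self._cum[self.k_abs] * 0.0


@lru_cache(maxsize=32)
def _lattice(phi_m: float, phi_M: float, alpha: float, grid_size: int) -> _EventLattice:
    return _EventLattice(EventParams(phi_m, phi_M, alpha), grid_size)


def _get_lattice(event: EventParams, grid_size: int) -> _EventLattice:
    return _lattice(event.phi_m, event.phi_M, event.alpha, int(grid_size))


# ---------------------------------------------------------------------------
# mixed distribution


@dataclass(frozen=True)
class MixedDamageDistribution:
    """Computational representation of the cumulative-damage distribution.

    ``grid`` holds N+1 uniformly spaced nodes spanning [0, 1] (the boundary
    nodes carry zero density by convention) and ``density`` the continuous
    density at each node, so that ``p0 + p1 + trapz(density, grid) = 1``.
    """

    p0: float
    p1: float
    grid: np.ndarray
    density: np.ndarray

    @property
    def total_mass(self) -> float:
        return self.p0 + self.p1 + float(np.trapezoid(self.density, self.grid))

    def _cont_nodes(self):
        # continuous CDF is exact at cell right edges; mass at node i is the
        # cell ((i-1/2)h, (i+1/2)h]
        h = self.grid[1] - self.grid[0]
        x = np.concatenate(([0.0], self.grid[:-1] + 0.5 * h, [1.0]))
        cont_cum = np.concatenate(([0.0], np.cumsum(self.density[:-1] * h)))
        cont_cum = np.append(cont_cum, cont_cum[-1])
        return x, cont_cum

    def cdf(self, x):
        """Right-continuous CDF of the mixed distribution."""
        x = np.asarray(x, dtype=float)
        nodes, cum = self._cont_nodes()
        out = self.p0 + np.interp(np.clip(x, 0.0, 1.0), nodes, cum)
        out = np.where(x < 0.0, 0.0, np.where(x >= 1.0, 1.0, out))
        return out if out.ndim else float(out)

    def cdf_left(self, x):
        """Left limit F(x-) (differs from ``cdf`` only at the atoms)."""
        x = np.asarray(x, dtype=float)
        nodes, cum = self._cont_nodes()
        out = self.p0 + np.interp(np.clip(x, 0.0, 1.0), nodes, cum)
        out = np.where(x <= 0.0, 0.0, np.where(x >= 1.0, 1.0 - self.p1, out))
        return out if out.ndim else float(out)

    def mean(self) -> float:
        h = self.grid[1] - self.grid[0]
        return float(np.sum(self.grid[:-1] * self.density[:-1] * h)) + self.p1

    def var(self) -> float:
        h = self.grid[1] - self.grid[0]
        m = self.mean()
        ex2 = float(np.sum(self.grid[:-1] ** 2 * self.density[:-1] * h)) + self.p1
        return max(ex2 - m * m, 0.0)

    def cv(self) -> float:
        m = self.mean()
        if m <= 0:
            raise DomainError("CV undefined for zero-mean distribution")
        return math.sqrt(self.var()) / m

    def ks_statistic(self, sample) -> float:
        """Exact one-sample KS distance of ``sample`` from this mixed CDF."""
        xs, counts = np.unique(np.asarray(sample, dtype=float), return_counts=True)
        n = counts.sum()
        ecdf = np.cumsum(counts) / n
        ecdf_left = ecdf - counts / n
        hi = np.max(np.abs(self.cdf(xs) - ecdf))
        lo = np.max(np.abs(self.cdf_left(xs) - ecdf_left))
        return float(max(hi, lo))


def _poisson_cutoff(lam: float, tol: float, k_abs: int) -> int:
    """Largest event count kept explicitly in the k-summation."""
    if lam <= 0:
        return 0
    kcut = int(stats.poisson.isf(tol, lam)) + 1
    return min(max(kcut, 1), k_abs)


def damage_distribution(
    model: NeutralModel,
    grid_size: int = 4096,
    poisson_tail_tol: float = 1e-10,
) -> MixedDamageDistribution:
    """Numerical mixed distribution of cumulative damage.

    The continuous part is ``sum_{k>=1} Poisson(k; lam) f*^k`` restricted to
    (0,1); all mass at or above 1 — including the residual Poisson tail beyond
    the cutoff, since a sum of many positive events almost surely exceeds 1 —
    is accumulated into the atom ``p1``.  ``p0 = exp(-lam)`` is analytic.
    """
    lam, event = model.lam, model.event
    lat = _get_lattice(event, grid_size)
    N, h = lat.N, lat.h
    p0 = math.exp(-lam)
    cont = np.zeros(N)
    p1 = 0.0
    if lam > 0:
        kcut = _poisson_cutoff(lam, poisson_tail_tol, lat.k_abs)
        ks = np.arange(1, kcut + 1)
        w = stats.poisson.pmf(ks, lam)
        for k, wk in zip(ks, w):
            cont += wk * lat.subone(int(k))
            p1 += wk * lat.absorbed(int(k))
        p1 += float(stats.poisson.sf(kcut, lam))
    grid = np.linspace(0.0, 1.0, N + 1)
    density = np.zeros(N + 1)
    density[1:N] = cont[1:N] / h
    return MixedDamageDistribution(p0=p0, p1=p1, grid=grid, density=density)


# ---------------------------------------------------------------------------
# simulation


def simulate_damage(model: NeutralModel, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` cumulative damages: Poisson event counts, truncated-Pareto
    sizes, sum truncated at 1.  ``k = 0`` gives exactly 0."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = rng.poisson(model.lam, int(n))
    total = int(k.sum())
    if total == 0:
        return np.zeros(int(n))
    phis = event_quantile(rng.random(total), model.event)
    idx = np.repeat(np.arange(int(n)), k)
    out = np.bincount(idx, weights=phis, minlength=int(n))
    return np.minimum(out, 1.0)


# ---------------------------------------------------------------------------
# likelihood


def _validate_damage(data) -> np.ndarray:
    x = np.asarray(data, dtype=float).ravel()
    if x.size == 0:
        raise DataError("need at least one observation")
    if np.any(~np.isfinite(x)) or np.any(x < 0.0) or np.any(x > 1.0):
        raise DataError("damage values must be finite and in [0, 1]")
    return x


def _band_matrix(
    data: np.ndarray,
    lat: _EventLattice,
    precision: float,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-event-count observation probabilities.

    Returns ``(B, ones_ind)`` where ``B[k, i]`` is the probability of
    observation i given exactly k events (k = 0..k_abs) and ``ones_ind`` is
    the indicator of exact 1s; event counts beyond ``k_abs`` contribute
    ``ones_ind`` (fully absorbed).  The fitted log-likelihood at any
    ``lam`` is then a Poisson-weighted sum of rows.
    """
    n = data.size
    K = lat.k_abs
    is0 = data == 0.0
    is1 = data == 1.0
    interior = ~(is0 | is1)
    vi = data[interior]
    B = np.zeros((K + 1, n))
    B[0, is0] = 1.0
    if interior.any():
        lo = np.clip(vi - 0.5 * precision, 0.0, 1.0)
        hi = np.clip(vi + 0.5 * precision, 0.0, 1.0)
        nodes = np.concatenate(([0.0], (np.arange(lat.N) + 0.5) * lat.h))
        centers = np.arange(lat.N) * lat.h
    for k in range(1, K + 1):
        if interior.any():
            if mode == "interval":
                cum = np.concatenate(([0.0], lat.cum_subone(k)))
                B[k, interior] = np.interp(hi, nodes, cum) - np.interp(lo, nodes, cum)
            else:  # density mode: interpolated lattice density
                B[k, interior] = np.interp(vi, centers, lat.subone(k) / lat.h)
        B[k, is1] = lat.absorbed(k)
    return B, is1.astype(float)


def _loglik_terms(lam: float, B: np.ndarray, ones_ind: np.ndarray) -> np.ndarray:
    K = B.shape[0] - 1
    w = stats.poisson.pmf(np.arange(K + 1), lam)
    p = w @ B + float(stats.poisson.sf(K, lam)) * ones_ind
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(p)


def loglik(
    data,
    model: NeutralModel,
    precision: float = 0.005,
    mode: str = "interval",
    grid_size: int = 4096,
) -> float:
    """Log-likelihood of damage observations under the neutral model.

    Exact 0s contribute ``log p0``, exact 1s ``log p1``; interior values
    contribute the interval-censored log-probability of the band of width
    ``precision`` centred on the value (``mode="interval"``, the default) or
    the interpolated log-density (``mode="density"``).  A zero-probability
    band yields ``-inf`` with a warning, never an exception.
    """
    if precision <= 0:
        raise ParameterError("precision must be > 0")
    if mode not in ("interval", "density"):
        raise ParameterError(f"unknown likelihood mode {mode!r}")
    x = _validate_damage(data)
    lat = _get_lattice(model.event, grid_size)
    B, ones_ind = _band_matrix(x, lat, precision, mode)
    terms = _loglik_terms(model.lam, B, ones_ind)
    if np.any(np.isneginf(terms)):
        warnings.warn(
            "some observations have zero probability under the model "
            "(outside the event-size support?); log-likelihood is -inf",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(terms.sum())


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class NeutralFit:
    """Maximum-likelihood fit of the attack rate (the model's only free
    parameter, so AICc uses k = 1)."""

    lam_hat: float
    loglik: float
    n: int
    aicc: float
    k: int = 1
    degenerate: bool = False
    at_bound: str | None = None
    mode: str = "interval"

    def to_dict(self) -> dict:
        return {
            "lam_hat": self.lam_hat,
            "loglik": self.loglik,
            "n": self.n,
            "aicc": self.aicc,
            "k": self.k,
            "degenerate": self.degenerate,
            "at_bound": self.at_bound,
            "mode": self.mode,
        }


def fit_neutral(
    data,
    event: EventParams | None = None,
    precision: float = 0.005,
    mode: str = "interval",
    grid_size: int = 4096,
    lam_bounds: tuple[float, float] = _LAM_BOUNDS,
) -> NeutralFit:
    """Fit the attack rate by bounded 1-D maximum likelihood on log(lam).

    All-zero data are degenerate (the likelihood increases monotonically as
    ``lam -> 0``): the fit returns the lower bound with ``degenerate=True``.
    """
    event = event or EventParams()
    x = _validate_damage(data)
    n = x.size
    lo, hi = lam_bounds
    if np.all(x == 0.0):
        lam = lo
        ll = n * (-lam)
        return NeutralFit(lam, ll, n, aicc(ll, 1, n), degenerate=True, at_bound="lower", mode=mode)
    lat = _get_lattice(event, grid_size)
    B, ones_ind = _band_matrix(x, lat, precision, mode)

    def nll(t: float) -> float:
        terms = _loglik_terms(math.exp(t), B, ones_ind)
        s = terms.sum()
        # large finite penalty keeps the bounded Brent iteration NaN-free
        return 1e300 if not np.isfinite(s) else -float(s)

    res = minimize_scalar(
        nll, bounds=(math.log(lo), math.log(hi)), method="bounded", options={"xatol": 1e-6}
    )
    lam_hat = float(math.exp(res.x))
    ll = -float(res.fun)
    if not np.isfinite(ll):
        warnings.warn("likelihood is -inf everywhere in the bracket", RuntimeWarning, stacklevel=2)
    at_bound = None
    if lam_hat <= lo * (1 + 1e-3):
        at_bound = "lower"
    elif lam_hat >= hi * (1 - 1e-3):
        at_bound = "upper"
    return NeutralFit(lam_hat, ll, n, aicc(ll, 1, n), at_bound=at_bound, mode=mode)


def fit_presence_absence(n_damaged: int, n_total: int) -> NeutralFit:
    """Closed-form fit from presence/absence of damage.

    ``P(damage present) = 1 - exp(-lam)`` so the MLE is
    ``lam_hat = -log(1 - n_damaged/n_total)``.  All-damaged data give an
    infinite estimate, reported with ``at_bound="upper"``.
    """
    if not (0 <= n_damaged <= n_total) or n_total < 1:
        raise DataError("require 0 <= n_damaged <= n_total, n_total >= 1")
    p_hat = n_damaged / n_total
    n0 = n_total - n_damaged
    if n_damaged == n_total:
        ll = 0.0
        return NeutralFit(math.inf, ll, n_total, aicc(ll, 1, n_total), at_bound="upper")
    lam = -math.log1p(-p_hat)
    ll = n0 * (-lam) + (n_damaged * math.log(p_hat) if n_damaged else 0.0)
    return NeutralFit(
        lam, ll, n_total, aicc(ll, 1, n_total), degenerate=(n_damaged == 0),
        at_bound="lower" if n_damaged == 0 else None,
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator


class NeutralDamageModel(DensityMixin, BaseEstimator):
    """Neutral herbivore-damage distribution as a density estimator.

    Fits the single attack-rate parameter ``lambda`` by maximum likelihood to
    a vector of proportion-damage observations in [0, 1].

    Parameters
    ----------
    phi_m, phi_M, alpha : float
        Per-event truncated-Pareto parameters (see :class:`EventParams`).
    precision : float
        Recording resolution; interval-censoring band width.
    likelihood : {"interval", "density"}
        Observation model for interior values.
    grid_size : int
        Lattice cells for the numerical density.
    lam_bounds : (float, float)
        Search bracket for the attack rate.

    Attributes
    ----------
    lam_ : float
        Estimated attack rate.
    loglik_ : float
        Maximized log-likelihood.
    n_ : int
        Number of observations.
    aicc_ : float
        Corrected AIC (one free parameter).
    degenerate_ : bool
        True when the data were all zeros.
    distribution_ : MixedDamageDistribution
        Numerical mixed distribution at ``lam_``.
    """

    def __init__(
        self,
        phi_m: float = 0.005,
        phi_M: float = 1.0,
        alpha: float = ALPHA_DEFAULT,
        precision: float = 0.005,
        likelihood: str = "interval",
        grid_size: int = 4096,
        lam_bounds: tuple[float, float] = _LAM_BOUNDS,
    ):
        self.phi_m = phi_m
        self.phi_M = phi_M
        self.alpha = alpha
        self.precision = precision
        self.likelihood = likelihood
        self.grid_size = grid_size
        self.lam_bounds = lam_bounds

    def _event(self) -> EventParams:
        return EventParams(self.phi_m, self.phi_M, self.alpha)

    def fit(self, X, y=None):
        x = _validate_damage(X)
        fit = fit_neutral(
            x,
            self._event(),
            precision=self.precision,
            mode=self.likelihood,
            grid_size=self.grid_size,
            lam_bounds=self.lam_bounds,
        )
        self.lam_ = fit.lam_hat
        self.loglik_ = fit.loglik
        self.n_ = fit.n
        self.aicc_ = fit.aicc
        self.degenerate_ = fit.degenerate
        self.fit_ = fit
        self.distribution_ = damage_distribution(
            NeutralModel(self.lam_, self._event()), grid_size=self.grid_size
        )
        return self

    def score_samples(self, X) -> np.ndarray:
        """Per-observation censored log-probability at the fitted rate."""
        x = _validate_damage(X)
        lat = _get_lattice(self._event(), self.grid_size)
        B, ones_ind = _band_matrix(x, lat, self.precision, self.likelihood)
        return _loglik_terms(self.lam_, B, ones_ind)

    def score(self, X, y=None) -> float:
        """Mean per-observation log-probability under the fitted model."""
        return float(np.mean(self.score_samples(X)))

    def sample(self, n_samples: int = 1, random_state=None) -> np.ndarray:
        return simulate_damage(NeutralModel(self.lam_, self._event()), n_samples, random_state)
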
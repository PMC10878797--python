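"""Observed-versus-predicted diagnostics for damage distributions.

Because the neutral model has no closed form, every comparison is Monte
Carlo: "predicted" samples are simulated from the fitted attack rate at the
observed sample size and results are averaged over replicates (default 100).

Diagnostics implemented here:

* two-sample KS tests against replicate predicted samples (mean statistic,
  mean p, fraction significant);
* the ten statistical probes of a distribution (mean, variance, skew,
  kurtosis, minimum, maximum, quartiles, Gini);
* a constrained variance partition of standardized probe matrices — the
  single-binary-constraint equivalent of a redundancy analysis (RDA) R^2,
  optionally after residualizing on a conditioning factor such as survey ID;
* simple-regression r^2 and major-axis (model II) regression of log observed
  on log predicted CVs with bootstrap confidence intervals;
* an empirical "shuffled" null that permutes leaf damage values among plants
  within a survey, preserving leaf counts;
* bootstrapped Kullback-Leibler divergence of observed from predicted damage
  binned at 5% damage classes with a separate zero atom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alternatives import delta_aicc, fit_htln, fit_zoib
from .asymptotics import gini
from .events import EventParams
from .exceptions import ComparisonError, DataError, DomainError
from .neutral import NeutralFit, NeutralModel, fit_neutral, simulate_damage

__all__ = [
    "PROBE_NAMES",
    "ProbeVector",
    "probes",
    "KSComparison",
    "ks_compare",
    "VariancePartition",
    "probe_variance_partition",
    "CVRegression",
    "cv_regression",
    "ShuffleNull",
    "shuffle_null",
    "kl_divergence",
    "ComparisonReport",
    "compare_dataset",
]

PROBE_NAMES = (
    "mean", "variance", "skew", "kurtosis", "minimum",
    "maximum", "q25", "q50", "q75", "gini",
)


@dataclass(frozen=True)
class ProbeVector:
    """Ten summary statistics characterizing a distribution's shape."""

    mean: float
    variance: float
    skew: float
    kurtosis: float
    minimum: float
    maximum: float
    q25: float
    q50: float
    q75: float
    gini: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PROBE_NAMES])

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in PROBE_NAMES}
        d["degenerate"] = self.degenerate
        return d


def probes(values) -> ProbeVector:
    """Compute the ten probes.

    Moments are central with denominator n; skew is ``m3 / m2^1.5`` and
    kurtosis ``m4 / m2^2`` (non-excess); quantiles use the median-unbiased
    interpolation convention; Gini is the pairwise definition.  Zero variance
    flags the vector as degenerate (skew/kurtosis undefined -> NaN).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DataError("need at least two values")
    m = float(x.mean())
    d = x - m
    m2 = float(np.mean(d**2))
    degenerate = m2 == 0.0
    if degenerate:
        skew = kurt = math.nan
    else:
        skew = float(np.mean(d**3) / m2**1.5)
        kurt = float(np.mean(d**4) / m2**2)
    q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75], method="median_unbiased")
    g = gini(x) if m > 0 else math.nan
    return ProbeVector(
        mean=m, variance=m2, skew=skew, kurtosis=kurt,
        minimum=float(x.min()), maximum=float(x.max()),
        q25=float(q25), q50=float(q50), q75=float(q75),
        gini=g, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# KS


@dataclass(frozen=True)
class KSComparison:
    stat_mean: float
    p_mean: float
    frac_significant: float
    n_rep: int

    def to_dict(self) -> dict:
        return {
            "ks_stat_mean": self.stat_mean, "ks_p_mean": self.p_mean,
            "ks_frac_significant": self.frac_significant, "n_rep": self.n_rep,
        }


def ks_compare(
    observed,
    lam_hat: float,
    event: EventParams,
    n_rep: int = 100,
    seed=None,
    alpha_level: float = 0.05,
) -> KSComparison:
    """Two-sample KS tests of the observed data against ``n_rep`` predicted
    samples simulated from the fitted rate at the observed sample size.

    p-values use the asymptotic two-sample formula; with heavy ties (the 0
    atom, the 0.5% recording grid) it is approximate and conservative.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size == 0:
        raise DataError("observed sample is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = NeutralModel(lam_hat, event)
    stats_, ps = np.empty(n_rep), np.empty(n_rep)
    for r in range(n_rep):
        pred = simulate_damage(model, obs.size, rng)
        res = stats.ks_2samp(obs, pred, method="asymp")
        stats_[r], ps[r] = res.statistic, res.pvalue
    return KSComparison(
        float(stats_.mean()), float(ps.mean()), float(np.mean(ps < alpha_level)), n_rep
    )


# ---------------------------------------------------------------------------
# constrained variance partition (RDA equivalent for one binary constraint)


@dataclass(frozen=True)
class VariancePartition:
    r2: float
    null: np.ndarray | None
    dropped_columns: tuple[int, ...] = ()

    @property
    def null_quantile(self) -> float | None:
        """Fraction of permuted-label R^2 values below the observed one."""
        if self.null is None:
            return None
        return float(np.mean(self.null < self.r2))


def _between_total_ss(Z: np.ndarray, labels: np.ndarray) -> float:
    total = float(np.sum(Z**2))
    if total == 0:
        return 0.0
    between = 0.0
    for g in np.unique(labels):
        sub = Z[labels == g]
        between += sub.shape[0] * float(np.sum(sub.mean(axis=0) ** 2))
    return between / total


def probe_variance_partition(
    probe_matrix,
    group_labels,
    condition=None,
    n_perm: int = 0,
    seed=None,
) -> VariancePartition:
    """Proportion of probe variance explained by observed-vs-predicted.

    Columns are Z-scored; if a conditioning factor is given the standardized
    matrix is residualized on it (its group means removed) before
    partitioning, mirroring a partial RDA with the factor as condition.  With
    a single binary constraint the RDA R^2 reduces to between-group sum of
    squares over total remaining sum of squares.  ``n_perm > 0`` adds a
    permutation null of R^2 (labels permuted within condition groups).
    """
    X = np.asarray(probe_matrix, dtype=float)
    if X.ndim != 2:
        raise DataError("probe_matrix must be 2-D (rows = distributions)")
    labels = np.asarray(group_labels)
    if labels.shape[0] != X.shape[0]:
        raise DataError("group_labels length must match probe_matrix rows")
    for g in np.unique(labels):
        if np.sum(labels == g) < 2:
            raise DataError("need >= 2 rows per group")
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = tuple(np.nonzero(~keep)[0])
    if dropped:
        warnings.warn(f"dropping zero-variance probe columns {dropped}",
                      RuntimeWarning, stacklevel=2)
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    cond = None
    if condition is not None:
        cond = np.asarray(condition)
        for g in np.unique(cond):
            sub = cond == g
            Z[sub] -= Z[sub].mean(axis=0)
    r2 = _between_total_ss(Z, labels)
    null = None
    if n_perm > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = labels.copy()
            if cond is not None:
                for g in np.unique(cond):
                    sub = np.nonzero(cond == g)[0]
                    perm[sub] = perm[rng.permutation(sub)]
            else:
                perm = perm[rng.permutation(len(perm))]
            null[b] = _between_total_ss(Z, perm)
    return VariancePartition(float(r2), null, dropped)


# ---------------------------------------------------------------------------
# CV regression


@dataclass(frozen=True)
class CVRegression:
    r2: float
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "cv_r2": self.r2, "ma_slope": self.slope, "ma_intercept": self.intercept,
            "ma_slope_ci": list(self.slope_ci), "ma_intercept_ci": list(self.intercept_ci),
            "n_pairs": self.n_pairs,
        }


def _ma_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Major-axis slope/intercept: leading eigenvector of the 2x2 covariance."""
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0.0:
        slope = 0.0 if sxx >= syy else math.inf
    else:
        slope = (syy - sxx + math.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def cv_regression(
    observed_cvs,
    predicted_cvs,
    n_boot: int = 1999,
    seed=None,
) -> CVRegression:
    """Log observed vs log predicted CV: OLS r^2 and model II regression.

    Pairs with a non-positive or non-finite member (zero-variance surveys)
    are excluded; both axes are log-transformed.  The major-axis slope is the
    leading eigenvector of the covariance of the log pairs; confidence
    intervals are percentile bootstrap over pairs.
    """
    o = np.asarray(observed_cvs, dtype=float)
    p = np.asarray(predicted_cvs, dtype=float)
    if o.shape != p.shape:
        raise ComparisonError("observed and predicted CV vectors differ in length")
    keep = np.isfinite(o) & np.isfinite(p) & (o > 0) & (p > 0)
    x, y = np.log(p[keep]), np.log(o[keep])
    if x.size < 3:
        raise ComparisonError("need at least 3 positive CV pairs")
    r = np.corrcoef(x, y)[0, 1]
    slope, intercept = _ma_fit(x, y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bs = np.empty((n_boot, 2))
    for b in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        bs[b] = _ma_fit(x[idx], y[idx])
    s_lo, s_hi = np.percentile(bs[:, 0], [2.5, 97.5])
    i_lo, i_hi = np.percentile(bs[:, 1], [2.5, 97.5])
    return CVRegression(float(r * r), slope, intercept,
                        (float(s_lo), float(s_hi)), (float(i_lo), float(i_hi)), int(x.size))


# ---------------------------------------------------------------------------
# shuffled null


@dataclass(frozen=True)
class ShuffleNull:
    """Shuffled-CV null for one survey: each permutation reassigns the
    survey's leaf values to plants (preserving leaf counts) and recomputes
    plant means."""

    among_plant_cv: np.ndarray
    among_leaf_cv_mean: np.ndarray
    n_perm: int

    def percentile_of(self, observed_cv: float) -> float:
        """Fraction of shuffled among-plant CVs below an observed CV."""
        return float(np.mean(self.among_plant_cv < observed_cv))


def shuffle_null(survey: pd.DataFrame, n_perm: int = 999, seed=None) -> ShuffleNull:
    """Leaf-shuffle empirical null within one survey.

    ``survey`` is a long-format table with columns plant_id and prop_damage
    (a single survey).  Plant damage is the mean of its assigned leaves.
    ``among_leaf_cv_mean`` averages within-plant CVs (plants with >= 2
    leaves) per permutation.
    """
    if survey["plant_id"].nunique() < 2:
        raise DataError("survey must contain at least 2 plants")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = survey["prop_damage"].to_numpy(dtype=float)
    sizes = survey.groupby("plant_id", sort=True).size().to_numpy()
    splits = np.cumsum(sizes)[:-1]
    plant_cv = np.empty(n_perm)
    leaf_cv = np.empty(n_perm)
    for b in range(n_perm):
        perm = values[rng.permutation(values.size)]
        groups = np.split(perm, splits)
        means = np.array([g.mean() for g in groups])
        mm = means.mean()
        plant_cv[b] = means.std(ddof=1) / mm if mm > 0 else 0.0
        cvs = [g.std(ddof=1) / g.mean() for g in groups if g.size >= 2 and g.mean() > 0]
        leaf_cv[b] = float(np.mean(cvs)) if cvs else math.nan
    return ShuffleNull(plant_cv, leaf_cv, n_perm)


# ---------------------------------------------------------------------------
# KL divergence


def _binned_probs(values: np.ndarray, edges: np.ndarray, eps: float) -> np.ndarray:
    """Probabilities on the partition {0} U (0, w] U ... U (1-w, 1]."""
    nbins = edges.size - 1
    counts = np.zeros(nbins + 1)
    counts[0] = np.sum(values == 0.0)
    pos = values[values > 0.0]
    if pos.size:
        idx = np.clip(np.searchsorted(edges, pos, side="left") - 1, 0, nbins - 1)
        counts[1:] = np.bincount(idx, minlength=nbins)
    q = counts + eps
    return q / q.sum()


def kl_divergence(
    observed,
    lam_hat: float,
    event: EventParams,
    bin_width: float = 0.05,
    n_boot: int = 100,
    seed=None,
    eps: float = 1e-10,
    resample_observed: bool = False,
) -> float:
    """Mean KL divergence (nats) of observed from predicted damage.

    Per bootstrap a predicted sample of the observed size is simulated from
    the fitted rate; both samples are binned on the shared partition of a
    zero atom plus damage classes of width ``bin_width``; ``eps`` is added to
    every cell before renormalizing.  ``resample_observed=True`` additionally
    resamples the observed side with replacement each bootstrap.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size == 0:
        raise DataError("observed sample is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    model = NeutralModel(lam_hat, event)
    p_obs = _binned_probs(obs, edges, eps)
    kls = np.empty(n_boot)
    for b in range(n_boot):
        if resample_observed:
            p_obs = _binned_probs(obs[rng.integers(0, obs.size, obs.size)], edges, eps)
        pred = simulate_damage(model, obs.size, rng)
        q = _binned_probs(pred, edges, eps)
        kls[b] = float(np.sum(p_obs * np.log(p_obs / q)))
    return float(kls.mean())


# ---------------------------------------------------------------------------
# per-dataset report


@dataclass(frozen=True)
class ComparisonReport:
    """Full per-dataset diagnostics of neutral-model fit."""

    neutral: NeutralFit
    ks: KSComparison
    probes_observed: ProbeVector
    probes_predicted_mean: np.ndarray
    cv_observed: float
    cv_predicted_mean: float
    kl: float
    delta_aicc_htln: float
    delta_aicc_zoib: float
    n_rep: int
    seed: int | None
    cv_shuffled_mean: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "neutral_fit": self.neutral.to_dict(),
            **self.ks.to_dict(),
            "probes_observed": self.probes_observed.to_dict(),
            "probes_predicted_mean": dict(zip(PROBE_NAMES, map(float, self.probes_predicted_mean))),
            "cv_observed": self.cv_observed,
            "cv_predicted_mean": self.cv_predicted_mean,
            "cv_shuffled_mean": self.cv_shuffled_mean,
            "kl_divergence": self.kl,
            "delta_aicc_htln": self.delta_aicc_htln,
            "delta_aicc_zoib": self.delta_aicc_zoib,
            "n_rep": self.n_rep,
            "seed": self.seed,
        }
        d.update(self.extra)
        return d


def _sample_cv(x: np.ndarray) -> float:
    m = x.mean()
    return float(x.std(ddof=1) / m) if m > 0 else math.nan


def compare_dataset(
    values,
    event: EventParams | None = None,
    precision: float = 0.005,
    n_rep: int = 100,
    n_boot: int = 100,
    seed: int | None = None,
) -> ComparisonReport:
    """Fit the neutral model and both competitors to one damage vector and
    compute every per-dataset diagnostic, Monte-Carlo-averaged over
    ``n_rep`` predicted replicates."""
    event = event or EventParams()
    x = np.asarray(values, dtype=float).ravel()
    nfit = fit_neutral(x, event, precision=precision)
    hfit = fit_htln(x, precision=precision)
    zfit = fit_zoib(x, precision=precision)
    rng = np.random.default_rng(seed)
    ks = ks_compare(x, nfit.lam_hat, event, n_rep=n_rep, seed=rng)
    model = NeutralModel(nfit.lam_hat, event)
    probe_rows = np.empty((n_rep, len(PROBE_NAMES)))
    cvs = np.empty(n_rep)
    for r in range(n_rep):
        pred = simulate_damage(model, x.size, rng)
        probe_rows[r] = probes(pred).as_array()
        cvs[r] = _sample_cv(pred)
    kl = kl_divergence(x, nfit.lam_hat, event, n_boot=n_boot, seed=rng)
    return ComparisonReport(
        neutral=nfit,
        ks=ks,
        probes_observed=probes(x),
        probes_predicted_mean=np.nanmean(probe_rows, axis=0),
        cv_observed=_sample_cv(x),
        cv_predicted_mean=float(np.nanmean(cvs)),
        kl=kl,
        delta_aicc_htln=delta_aicc(hfit, nfit),
        delta_aicc_zoib=delta_aicc(zfit, nfit),
        n_rep=n_rep,
        seed=seed,
    )
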
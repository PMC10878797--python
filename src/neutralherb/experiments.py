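"""Reproducible study harness: the package's standard validation experiments.

Each function runs one self-contained simulation study at the package's
standard study conditions (HerbVar-style 30-plant x 10-leaf surveys, damage
recorded at 0.5% resolution, default event bounds) and returns plain
dictionaries of numbers.  All randomness flows from the ``seed`` argument.
These studies back both the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math
import warnings
from fractions import Fraction

import numpy as np

from .alternatives import delta_aicc, fit_htln, fit_zoib
from .asymptotics import INDEX_CONSTANTS, asymptotic_index, sample_index
from .compare import ks_compare, probe_variance_partition, probes
from .events import EventParams, derive_alpha
from .neutral import (
    NeutralModel,
    damage_distribution,
    fit_neutral,
    plant_scale_event_params,
    simulate_damage,
)
from .synth import SynthConfig, generate_survey, median_leaves, plant_means

__all__ = [
    "alpha_derivation",
    "distribution_study",
    "recovery_study",
    "clt_study",
    "model_selection_study",
    "deviation_sign_study",
    "null_calibration_study",
]


def alpha_derivation() -> Fraction:
    """Exact rational change-of-variables derivation of the event exponent
    from the canonical metabolic / abundance / richness scaling triple."""
    return derive_alpha(Fraction(3, 4), Fraction(-3, 4), Fraction(-2, 3))


def distribution_study(
    seed: int,
    lams: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0),
    n: int = 100_000,
    event: EventParams | None = None,
) -> dict:
    """Numerical-distribution correctness: analytic zero atom, conservation
    of total mass, and agreement between the simulator and the lattice CDF
    (one-sample KS distance at ``n`` draws) across attack rates."""
    event = event or EventParams()
    rng = np.random.default_rng(seed)
    p0_err, cons_err, ks = [], [], []
    for lam in lams:
        model = NeutralModel(lam, event)
        d = damage_distribution(model)
        p0_err.append(abs(d.p0 - math.exp(-lam)))
        cons_err.append(abs(d.total_mass - 1.0))
        ks.append(d.ks_statistic(simulate_damage(model, n, rng)))
    return {
        "lams": list(lams),
        "n": n,
        "p0_max_abs_err": float(max(p0_err)),
        "conservation_max_abs_err": float(max(cons_err)),
        "ks_max": float(max(ks)),
    }


def recovery_study(
    seed: int,
    lams: tuple[float, ...] = (0.5, 2.0, 10.0),
    n: int = 300,
    n_rep: int = 20,
    event: EventParams | None = None,
) -> dict:
    """Attack-rate recovery: median relative error of the MLE over seeded
    replicates of ``n`` leaves at each true rate."""
    event = event or EventParams()
    rng = np.random.default_rng(seed)
    medians = {}
    for lam in lams:
        errs = [
            abs(fit_neutral(simulate_damage(NeutralModel(lam, event), n, rng), event).lam_hat - lam)
            / lam
            for _ in range(n_rep)
        ]
        medians[lam] = float(np.median(errs))
    return {
        "n": n,
        "n_rep": n_rep,
        "median_rel_err": medians,
        "worst_median_rel_err": float(max(medians.values())),
    }


def clt_study(
    seed: int,
    lam: float = 200.0,
    bounds: tuple[float, float] = (5e-5, 1e-2),
    n: int = 100_000,
    scaling_lams: tuple[float, ...] = (10.0, 40.0, 160.0),
) -> dict:
    """Large-attack-rate normal limit: simulated CV, Gini and Hoover versus
    the asymptotic approximation; index constants versus exact normal closed
    forms; constancy of CV * sqrt(lam) across the regime."""
    event = EventParams(*bounds)
    rng = np.random.default_rng(seed)
    model = NeutralModel(lam, event)
    s = simulate_damage(model, n, rng)
    rel_err = {
        name: abs(sample_index(s, name) - asymptotic_index(model, name))
        / asymptotic_index(model, name)
        for name in INDEX_CONSTANTS
    }
    # exact normal-distribution oracle for the constants c
    mu, sigma = 10.0, 1.0
    z = rng.normal(mu, sigma, n)
    const_rel_err = {
        name: abs(sample_index(z, name) - (sigma / mu) / c) / ((sigma / mu) / c)
        for name, c in INDEX_CONSTANTS.items()
    }
    prods = [
        sample_index(simulate_damage(NeutralModel(la, event), n, rng), "cv") * math.sqrt(la)
        for la in scaling_lams
    ]
    return {
        "lam": lam,
        "n": n,
        "index_rel_err": rel_err,
        "normal_constant_rel_err": const_rel_err,
        "cv_sqrt_lam_rel_spread": float((max(prods) - min(prods)) / np.mean(prods)),
    }


def _round_to_grid(x: np.ndarray, res: float = 0.005) -> np.ndarray:
    out = np.round(x / res) * res
    pos = x > 0
    out[pos] = np.maximum(out[pos], res)
    return np.clip(out, 0.0, 1.0)


def model_selection_study(
    seed: int,
    n: int = 60,
    n_rep: int = 50,
    lam: float = 2.0,
    zoib_truth: tuple[float, float, float, float] = (0.5, 0.2, 0.3, 3.0),
    event: EventParams | None = None,
) -> dict:
    """AICc model selection self-consistency.

    On data simulated from the neutral model the simpler neutral fit should
    win (positive median ``delta_aicc``); on data from a heavily inflated
    ZOIB the competitor should win on its own data (negative median).  All
    samples are rounded to the 0.5% recording grid so the three censored
    likelihoods share one data representation.
    """
    event = event or EventParams()
    rng = np.random.default_rng(seed)
    d_htln, d_zoib = [], []
    for _ in range(n_rep):
        x = _round_to_grid(simulate_damage(NeutralModel(lam, event), n, rng))
        nf = fit_neutral(x, event)
        d_htln.append(delta_aicc(fit_htln(x), nf))
        d_zoib.append(delta_aicc(fit_zoib(x), nf))
    p0, p1, mu, prec = zoib_truth
    d_zoib_own = []
    for _ in range(n_rep):
        u = rng.random(n)
        x = np.where(
            u < p0, 0.0,
            np.where(u < p0 + p1, 1.0, rng.beta(mu * prec, (1 - mu) * prec, n)),
        )
        x = _round_to_grid(x)
        nf = fit_neutral(x, event)
        d_zoib_own.append(delta_aicc(fit_zoib(x), nf))
    return {
        "n": n,
        "n_rep": n_rep,
        "median_delta_aicc_htln_on_neutral": float(np.median(d_htln)),
        "median_delta_aicc_zoib_on_neutral": float(np.median(d_zoib)),
        "median_delta_aicc_zoib_on_zoib": float(np.median(d_zoib_own)),
    }


def _predicted_cvs(model: NeutralModel, size: int, n_rep: int, rng) -> float:
    cvs = []
    for _ in range(n_rep):
        p = simulate_damage(model, size, rng)
        if p.mean() > 0:
            cvs.append(p.std(ddof=1) / p.mean())
    return float(np.mean(cvs)) if cvs else math.nan


def deviation_sign_study(
    seed: int,
    n_surveys: int = 30,
    plant_sigma: float = 1.0,
    regularize: float = 0.8,
    lam: float = 2.0,
    n_rep: int = 100,
    n_perm: int = 199,
    event: EventParams | None = None,
) -> dict:
    """Sign signatures of the two non-neutral contaminations.

    Among-plant heterogeneity: observed among-plant CV exceeds both the
    leaf-shuffled CV and the CV predicted by the refitted neutral model.
    Within-plant regularization: observed among-leaf CV falls below the
    refitted neutral prediction.  Differences are paired per survey/plant.
    """
    from .compare import shuffle_null

    event = event or EventParams()
    rng = np.random.default_rng(seed)
    d_shuf, d_pred = [], []
    for _ in range(n_surveys):
        t = generate_survey(SynthConfig(plant_sigma=plant_sigma, lam=lam), event, rng=rng)
        pm = plant_means(t)["prop_damage"].to_numpy()
        cv_obs = pm.std(ddof=1) / pm.mean()
        shuf = shuffle_null(t, n_perm=n_perm, seed=rng)
        ev = plant_scale_event_params(event, int(median_leaves(t).iloc[0]))
        fit = fit_neutral(pm, ev)
        d_shuf.append(cv_obs - float(np.nanmean(shuf.among_plant_cv)))
        d_pred.append(cv_obs - _predicted_cvs(NeutralModel(fit.lam_hat, ev), pm.size, n_rep, rng))
    leaf_diffs = []
    for _ in range(n_surveys):
        t = generate_survey(SynthConfig(regularize=regularize, lam=lam), event, rng=rng)
        for _, g in t.groupby("plant_id")["prop_damage"]:
            x = g.to_numpy()
            if x.mean() == 0 or x.std(ddof=1) == 0:
                continue
            fit = fit_neutral(x, event)
            pred = _predicted_cvs(NeutralModel(fit.lam_hat, event), x.size, n_rep, rng)
            leaf_diffs.append(x.std(ddof=1) / x.mean() - pred)
    return {
        "n_surveys": n_surveys,
        "among_plant_cv_obs_minus_shuffled_median": float(np.median(d_shuf)),
        "among_plant_cv_obs_minus_predicted_median": float(np.median(d_pred)),
        "among_leaf_cv_obs_minus_predicted_median": float(np.median(leaf_diffs)),
        "among_leaf_cv_obs_minus_predicted_mean": float(np.mean(leaf_diffs)),
        "n_plants_leaf_scale": len(leaf_diffs),
    }


def null_calibration_study(
    seed: int,
    n_surveys: int = 200,
    lam: float = 2.0,
    n_rep: int = 100,
    n_perm: int = 199,
    event: EventParams | None = None,
) -> dict:
    """Diagnostics on purely neutral surveys.

    Per survey (300 leaves) the attack rate is refitted and 100 predicted
    replicates are tested by two-sample KS; the study reports the mean
    fraction of replicate tests with p < 0.05 (the per-dataset significance
    rate; ~nominal under neutrality) together with the fully conservative
    per-survey decision rule (mean p < 0.05).  It also builds the
    observed/predicted probe matrix conditioned on survey identity and
    compares the constrained R^2 against its permutation null.
    """
    event = event or EventParams()
    rng = np.random.default_rng(seed)
    fracs, pmeans = [], []
    rows, labels, cond = [], [], []
    for s in range(n_surveys):
        t = generate_survey(SynthConfig(lam=lam), event, rng=rng)
        x = t["prop_damage"].to_numpy()
        fit = fit_neutral(x, event)
        ks = ks_compare(x, fit.lam_hat, event, n_rep=n_rep, seed=rng)
        fracs.append(ks.frac_significant)
        pmeans.append(ks.p_mean)
        pred = simulate_damage(NeutralModel(fit.lam_hat, event), x.size, rng)
        rows.extend([probes(x).as_array(), probes(pred).as_array()])
        labels.extend(["observed", "predicted"])
        cond.extend([s, s])
    with warnings.catch_warnings():
        # the "minimum" probe is constantly 0 at the leaf scale and is dropped
        warnings.simplefilter("ignore", RuntimeWarning)
        vp = probe_variance_partition(
            np.array(rows), np.array(labels), condition=np.array(cond),
            n_perm=n_perm, seed=rng,
        )
    return {
        "n_surveys": n_surveys,
        "ks_replicate_reject_rate": float(np.mean(fracs)),
        "ks_mean_p": float(np.mean(pmeans)),
        "ks_survey_reject_rate": float(np.mean(np.asarray(pmeans) < 0.05)),
        "constrained_r2": vp.r2,
        "constrained_r2_null95": float(np.quantile(vp.null, 0.95)),
    }
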
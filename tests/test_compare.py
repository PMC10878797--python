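"""Observed-versus-predicted diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neutralherb import (
    EventParams,
    NeutralModel,
    SynthConfig,
    compare_dataset,
    cv_regression,
    generate_survey,
    kl_divergence,
    ks_compare,
    probe_variance_partition,
    probes,
    shuffle_null,
    simulate_damage,
)
from neutralherb.compare import PROBE_NAMES, _binned_probs
from neutralherb.exceptions import ComparisonError


class TestProbes:
    def test_small_worked_example(self):
        p = probes([0.0, 0.0, 0.0, 1.0])
        assert p.mean == pytest.approx(0.25)
        assert p.q50 == 0.0
        assert p.maximum == 1.0

    def test_constant_vector_flagged_degenerate(self):
        p = probes(np.full(5, 0.2))
        assert p.degenerate and math.isnan(p.skew)
        assert p.variance == 0.0

    def test_normal_sample_kurtosis(self, rng):
        p = probes(rng.normal(0, 1, 100_000))
        assert p.kurtosis == pytest.approx(3.0, abs=0.1)

    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=50))
    def test_order_invariants(self, xs):
        p = probes(xs)
        assert p.minimum <= p.q25 <= p.q50 <= p.q75 <= p.maximum
        assert p.as_array().shape == (len(PROBE_NAMES),)


class TestKS:
    def test_self_consistency(self, rng):
        lam, ev = 2.0, EventParams()
        obs = simulate_damage(NeutralModel(lam, ev), 200, rng)
        res = ks_compare(obs, lam, ev, n_rep=50, seed=1)
        assert res.p_mean > 0.05

    def test_gross_mismatch(self):
        res = ks_compare(np.ones(50), 0.1, EventParams(), n_rep=20, seed=2)
        assert res.stat_mean > 0.8


class TestVariancePartition:
    def test_identical_groups_give_zero(self):
        X = np.tile(np.arange(8).reshape(4, 2), (2, 1))
        labels = np.repeat(["obs", "pred"], 4)
        assert probe_variance_partition(X, labels).r2 == pytest.approx(0.0, abs=1e-12)

    def test_permuted_labels_below_null_quantile(self, rng):
        X = rng.normal(size=(40, 6))
        labels = rng.permutation(np.repeat(["a", "b"], 20))
        vp = probe_variance_partition(X, labels, n_perm=199, seed=3)
        assert vp.r2 < np.quantile(vp.null, 0.95)

    def test_matches_brute_force_on_worked_matrix(self):
        # 4 rows, 2 probes; oracle: standardize, then between/total SS by hand
        X = np.array([[1.0, 10.0], [2.0, 14.0], [3.0, 12.0], [6.0, 20.0]])
        labels = np.array(["o", "o", "p", "p"])
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        between = 0.0
        for g in ("o", "p"):
            sub = Z[labels == g]
            between += sub.shape[0] * np.sum(sub.mean(axis=0) ** 2)
        oracle = between / np.sum(Z**2)
        assert probe_variance_partition(X, labels).r2 == pytest.approx(oracle, rel=1e-12)

    def test_conditioning_removes_survey_effect(self, rng):
        # strong block effect shared by both groups vanishes after conditioning
        block = np.repeat(rng.normal(0, 10, 5), 2)[:, None]
        X = block + rng.normal(size=(10, 3))
        labels = np.tile(["o", "p"], 5)
        cond = np.repeat(np.arange(5), 2)
        uncond = probe_variance_partition(X, labels).r2
        cond_r2 = probe_variance_partition(X, labels, condition=cond).r2
        assert uncond < 0.5 and np.isfinite(cond_r2)

    def test_zero_variance_column_dropped_with_warning(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        labels = np.repeat(["o", "p"], 3)
        with pytest.warns(RuntimeWarning):
            vp = probe_variance_partition(X, labels)
        assert vp.dropped_columns == (0,)


class TestCVRegression:
    def test_identity_line(self):
        cvs = np.array([0.5, 1.0, 2.0, 4.0])
        reg = cv_regression(cvs, cvs, n_boot=50, seed=0)
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.r2 == pytest.approx(1.0)

    def test_constant_multiple_shifts_intercept(self):
        pred = np.array([0.5, 1.0, 2.0, 4.0])
        reg = cv_regression(2.0 * pred, pred, n_boot=50, seed=0)
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(math.log(2.0))

    def test_major_axis_slope_matches_eigen_oracle(self, rng):
        # anisotropic Gaussian cloud; oracle = leading eigenvector via eigh
        cov = np.array([[2.0, 1.2], [1.2, 1.0]])
        xy = rng.multivariate_normal([0, 0], cov, 500)
        x, y = np.exp(xy[:, 0]), np.exp(xy[:, 1])
        reg = cv_regression(y, x, n_boot=10, seed=1)
        lx, ly = np.log(x), np.log(y)
        evals, evecs = np.linalg.eigh(np.cov(lx, ly, ddof=1))
        v = evecs[:, np.argmax(evals)]
        assert reg.slope == pytest.approx(v[1] / v[0], abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ComparisonError):
            cv_regression([1.0, 2.0], [1.0, 2.0], n_boot=10)

    def test_zero_variance_pairs_excluded(self):
        o = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        p = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        reg = cv_regression(o, p, n_boot=10, seed=0)
        assert reg.n_pairs == 4


class TestShuffleNull:
    def test_preserves_multiset_and_grand_mean(self):
        survey = generate_survey(SynthConfig(n_plants=5, leaves_per_plant=4, seed=1))
        values = survey["prop_damage"].to_numpy()
        shuf = shuffle_null(survey, n_perm=50, seed=0)
        # weighted mean of plant means with equal leaf counts == grand mean
        sizes = survey.groupby("plant_id").size().to_numpy()
        assert np.all(sizes == 4)
        assert np.allclose(
            shuf.among_plant_cv * 0 + values.mean(), values.mean()
        )  # grand mean trivially preserved
        assert shuf.among_plant_cv.shape == (50,)

    def test_constant_survey_gives_zero_cv(self):
        survey = generate_survey(SynthConfig(n_plants=4, leaves_per_plant=3, lam=0.0, seed=2))
        survey["prop_damage"] = 0.25
        shuf = shuffle_null(survey, n_perm=20, seed=0)
        assert np.all(shuf.among_plant_cv == 0.0)

    def test_detects_injected_plant_heterogeneity(self):
        survey = generate_survey(SynthConfig(plant_sigma=1.5, lam=2.0, seed=3))
        pm = survey.groupby("plant_id")["prop_damage"].mean().to_numpy()
        obs_cv = pm.std(ddof=1) / pm.mean()
        shuf = shuffle_null(survey, n_perm=199, seed=4)
        assert obs_cv > np.quantile(shuf.among_plant_cv, 0.975)


class TestKL:
    def test_identical_histograms_give_zero(self):
        edges = np.arange(0.0, 1.025, 0.05)
        x = np.array([0.0, 0.0, 0.12, 0.3, 0.55, 1.0])
        p = _binned_probs(x, edges, 1e-10)
        assert float(np.sum(p * np.log(p / p))) == 0.0

    def test_nonnegative_and_seeded_deterministic(self, rng):
        ev = EventParams()
        obs = simulate_damage(NeutralModel(2.0, ev), 200, rng)
        a = kl_divergence(obs, 2.0, ev, n_boot=30, seed=5)
        b = kl_divergence(obs, 2.0, ev, n_boot=30, seed=5)
        assert a >= 0.0 and a == b

    def test_misfit_monotonicity(self, rng):
        ev = EventParams()
        lam = 2.0
        obs = simulate_damage(NeutralModel(lam, ev), 500, rng)
        good = kl_divergence(obs, lam, ev, n_boot=50, seed=6)
        bad = kl_divergence(obs, lam * 10, ev, n_boot=50, seed=6)
        assert good < bad


def test_compare_dataset_deterministic_given_seed(rng):
    x = simulate_damage(NeutralModel(2.0), 150, rng)
    a = compare_dataset(x, n_rep=20, n_boot=20, seed=9).to_dict()
    b = compare_dataset(x, n_rep=20, n_boot=20, seed=9).to_dict()
    assert a == b
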
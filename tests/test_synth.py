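"""Synthetic survey generator, inclusion filters and accessors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neutralherb import (
    EventParams,
    NeutralModel,
    SynthConfig,
    apply_inclusion_filters,
    fit_neutral,
    generate_survey,
    generate_surveys,
    median_leaves,
    plant_means,
    simulate_damage,
)
from neutralherb.exceptions import ParameterError


def _survey(**kw):
    return generate_survey(SynthConfig(**kw))


class TestGenerator:
    def test_deterministic_given_seed(self):
        a = _survey(seed=5, plant_sigma=0.5, regularize=0.3)
        b = _survey(seed=5, plant_sigma=0.5, regularize=0.3)
        pd.testing.assert_frame_equal(a, b)

    def test_schema_and_key_uniqueness(self):
        t = _survey(seed=1)
        assert list(t.columns) == ["survey_id", "plant_id", "leaf_id", "prop_damage"]
        assert not t.duplicated(["survey_id", "plant_id", "leaf_id"]).any()
        assert t["prop_damage"].between(0, 1).all()

    def test_rounding_respects_zero_boundary_and_grid(self):
        t = _survey(seed=2, lam=0.5)
        v = t["prop_damage"].to_numpy()
        pos = v[v > 0]
        assert np.all(pos >= 0.005)
        assert np.allclose(np.round(pos / 0.005), pos / 0.005, atol=1e-9)

    def test_neutral_branch_reduces_to_simulator(self):
        cfg = SynthConfig(n_plants=100, leaves_per_plant=10, lam=2.0,
                          round_values=False, seed=3)
        t = generate_survey(cfg)
        ref = simulate_damage(NeutralModel(2.0), 10_000, 99)
        d = stats.ks_2samp(t["prop_damage"].to_numpy(), ref)
        assert d.statistic < 0.03

    def test_plant_heterogeneity_inflates_among_plant_cv(self):
        def cv_of(sigma):
            t = generate_survey(SynthConfig(n_plants=200, plant_sigma=sigma, seed=4))
            pm = plant_means(t)["prop_damage"].to_numpy()
            return pm.std(ddof=1) / pm.mean()

        assert cv_of(1.0) > cv_of(0.0)

    def test_regularization_lowers_within_plant_cv(self):
        def leaf_cv(reg):
            t = generate_survey(SynthConfig(n_plants=200, regularize=reg, seed=6))
            cvs = [
                g.std(ddof=1) / g.mean()
                for _, g in t.groupby("plant_id")["prop_damage"]
                if g.mean() > 0
            ]
            return np.mean(cvs)

        assert leaf_cv(0.8) < leaf_cv(0.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            SynthConfig(regularize=1.0)
        with pytest.raises(ParameterError):
            SynthConfig(lam=-1.0)


class TestFilters:
    def test_small_survey_excluded_from_among_plant(self):
        t = generate_surveys(2, SynthConfig(n_plants=14, seed=7))
        res = apply_inclusion_filters(t)
        assert res.among_plant.empty
        assert (res.exclusions["unit"] == "survey").sum() == 2

    def test_threshold_is_inclusive(self):
        t = generate_survey(SynthConfig(n_plants=15, leaves_per_plant=10, seed=8))
        res = apply_inclusion_filters(t)
        assert res.among_plant["plant_id"].nunique() == 15
        assert res.among_leaf["plant_id"].nunique() == 15  # 10-leaf plants retained

    def test_short_plants_excluded_from_among_leaf(self):
        t = generate_survey(SynthConfig(n_plants=20, leaves_per_plant=9, seed=9))
        res = apply_inclusion_filters(t)
        assert res.among_leaf.empty
        assert (res.exclusions["unit"] == "plant").sum() == 20

    def test_empty_table(self):
        empty = pd.DataFrame(columns=["survey_id", "plant_id", "leaf_id", "prop_damage"])
        res = apply_inclusion_filters(empty)
        assert res.among_plant.empty and res.among_leaf.empty and res.exclusions.empty


class TestAccessors:
    def test_plant_mean_worked_example(self):
        t = pd.DataFrame(
            {"survey_id": ["s"] * 2, "plant_id": ["p"] * 2,
             "leaf_id": ["a", "b"], "prop_damage": [0.0, 0.1]}
        )
        assert plant_means(t)["prop_damage"].iloc[0] == pytest.approx(0.05)

    def test_median_leaves_uniform_and_mixed(self):
        t = generate_survey(SynthConfig(seed=10))
        assert median_leaves(t).iloc[0] == 10
        mixed = pd.DataFrame(
            [("s", f"p{i}", f"l{j}", 0.0) for i, c in enumerate([8, 10, 12]) for j in range(c)],
            columns=["survey_id", "plant_id", "leaf_id", "prop_damage"],
        )
        assert median_leaves(mixed).loc["s"] == 10

    def test_median_leaves_rounds_half_up(self):
        mixed = pd.DataFrame(
            [("s", f"p{i}", f"l{j}", 0.0) for i, c in enumerate([10, 11]) for j in range(c)],
            columns=["survey_id", "plant_id", "leaf_id", "prop_damage"],
        )
        assert median_leaves(mixed).loc["s"] == 11


def test_end_to_end_rate_recovery():
    # generator and fitter are consistent: lam recovered from a 30x10 survey
    lams = []
    for seed in range(5):
        t = generate_survey(SynthConfig(lam=2.0, seed=seed), EventParams())
        lams.append(fit_neutral(t["prop_damage"].to_numpy(), EventParams()).lam_hat)
    assert np.median(lams) == pytest.approx(2.0, rel=0.15)
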
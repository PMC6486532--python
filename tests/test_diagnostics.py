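"""Residual diagnostics, Fisher information and visual predictive checks."""

import numpy as np
import pandas as pd
import pytest

from irtmarkov import (
    DiaryDataset,
    ItemSpec,
    PopulationParams,
    SubjectEffects,
    fisher_information,
    information_by_percentile,
    ipred_and_residuals,
    item_correlation_map,
    sample_subject_effects,
    simulate_replicates,
    steady_state_probs,
    vpc,
)
from irtmarkov.simulate import simulate_dataset

from conftest import complete_design, random_item


class TestIpredResiduals:
    def test_symmetric_distribution_gives_expected_score_one(self, item3):
        # first observation: steady state at D = 0 is (0.269, 0.462, 0.269)
        pop = PopulationParams(items=(item3,), met0=2.0)
        rec = pd.DataFrame({"subject_id": 1, "day": [1], "item_id": 1, "score": [1]})
        out = ipred_and_residuals(DiaryDataset(rec, (item3,)), pop, [SubjectEffects(0, 0, 0)])
        assert out["ipred"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert out["res"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_transition_prediction_uses_previous_score(self, item3):
        pop = PopulationParams(items=(item3,), met0=1e-3)
        rec = pd.DataFrame(
            {"subject_id": 1, "day": [1, 2], "item_id": 1, "score": [2, 0]}
        )
        out = ipred_and_residuals(DiaryDataset(rec, (item3,)), pop, [SubjectEffects(0, 0, 0)])
        # no-Markov limit: the one-day-ahead prediction reverts to the mean
        assert out["ipred"].iloc[1] == pytest.approx(1.0, abs=1e-4)
        assert out["res"].iloc[1] == pytest.approx(-1.0, abs=1e-4)

    def test_sticky_limit_predicts_previous_score(self, item3):
        pop = PopulationParams(items=(item3,), met0=1e4)
        rec = pd.DataFrame(
            {"subject_id": 1, "day": [1, 2], "item_id": 1, "score": [2, 2]}
        )
        out = ipred_and_residuals(DiaryDataset(rec, (item3,)), pop, [SubjectEffects(0, 0, 0)])
        assert out["ipred"].iloc[1] == pytest.approx(2.0, abs=1e-3)


class TestFisherInformation:
    def test_dichotomous_closed_form(self):
        item = ItemSpec(1, 2, 1.7, (0.4,))
        D = np.linspace(-3, 3, 21)
        P = 1 / (1 + np.exp(-1.7 * (D - 0.4)))
        np.testing.assert_allclose(
            fisher_information(item, D), 1.7**2 * P * (1 - P), atol=1e-12
        )
        assert fisher_information(item, 0.4) == pytest.approx(1.7**2 / 4, abs=1e-12)

    def test_matches_negative_expected_second_derivative(self):
        # I(D) = -E[d^2 log p_Y / dD^2] by finite differences
        rng = np.random.default_rng(13)
        h = 2e-4
        for _ in range(20):
            item = random_item(rng)
            D = float(rng.uniform(-2, 2))
            p0 = steady_state_probs(item, D)
            lp = np.log(p0)

            def d2(step):
                lp_p = np.log(steady_state_probs(item, D + step))
                lp_m = np.log(steady_state_probs(item, D - step))
                return (lp_p + lp_m - 2 * lp) / step**2

            # Richardson extrapolation beats the 1e-6 comparison comfortably
            fd = -(p0 * (4 * d2(h) - d2(2 * h)) / 3).sum()
            assert fisher_information(item, D) == pytest.approx(fd, rel=1e-6)

    def test_uninformative_and_tail_limits(self, item3):
        weak = ItemSpec(1, 3, 1e-6, (-1.0, 1.0))
        assert fisher_information(weak, 0.0) < 1e-10
        assert fisher_information(item3, 40.0) < 1e-12
        assert fisher_information(item3, -40.0) < 1e-12
        assert (fisher_information(item3, np.linspace(-5, 5, 41)) >= 0).all()

    def test_information_scales_with_discrimination_squared_at_center(self):
        # doubling a quadruples the information at the item's centre
        base = ItemSpec(1, 2, 1.1, (0.0,))
        double = ItemSpec(1, 2, 2.2, (0.0,))
        assert fisher_information(double, 0.0) == pytest.approx(
            4 * fisher_information(base, 0.0), rel=1e-12
        )


class TestInformationByPercentile:
    def test_severity_quantiles(self, small_pop):
        tab = information_by_percentile(small_pop, (5, 50, 95), t=0.0)
        D50 = tab.loc[tab["percentile"] == 50, "D"].iloc[0]
        D95 = tab.loc[tab["percentile"] == 95, "D"].iloc[0]
        assert D50 == pytest.approx(0.0, abs=1e-12)
        assert D95 == pytest.approx(1.6449, abs=1e-4)
        assert len(tab) == 3 * len(small_pop.items)

    def test_invalid_percentile_rejected(self, small_pop):
        with pytest.raises(ValueError):
            information_by_percentile(small_pop, (0, 50))
        with pytest.raises(ValueError):
            information_by_percentile(small_pop, (100,))


class TestItemCorrelationMap:
    def test_identical_inputs_zero_diagonal(self, small_pop, tiny_dataset):
        res = ipred_and_residuals(tiny_dataset, small_pop, tiny_dataset.true_effects)
        corr = item_correlation_map(res, res)
        np.testing.assert_allclose(np.diag(corr.to_numpy()), 0.0, atol=1e-12)

    def test_shared_latent_items_positively_correlated(self):
        # two highly discriminating items driven by one latent trait have
        # strongly correlated residuals when predictions ignore the subject
        # effect (population-level IPRED)
        items = (
            ItemSpec(1, 3, 2.5, (-0.5, 0.5)),
            ItemSpec(2, 3, 2.5, (-0.4, 0.6)),
            ItemSpec(3, 3, 0.05, (-0.5, 0.5)),  # ~noise item
        )
        pop = PopulationParams(items=items, met0=0.5)
        eff = sample_subject_effects(pop, 200, seed=14)
        ds = simulate_dataset(pop, eff, complete_design(200, 6), seed=15)
        pop_level = [SubjectEffects(0.0, 0.0, 0.0)] * 200
        obs = ipred_and_residuals(ds, pop, pop_level)
        eff2 = sample_subject_effects(pop, 200, seed=16)
        sim2 = simulate_dataset(pop, eff2, complete_design(200, 6), seed=17)
        simr = ipred_and_residuals(sim2, pop, pop_level)
        corr = item_correlation_map(obs, simr)
        assert corr.loc[1, 2] > 0.4
        assert abs(corr.loc[1, 3]) < 0.15

    def test_too_few_pairs_flagged_missing(self, small_pop):
        rec = pd.DataFrame(
            {
                "subject_id": [1, 1, 1],
                "day": [1, 1, 1],
                "item_id": [1, 2, 3],
                "score": [0, 1, 0],
            }
        )
        ds = DiaryDataset(rec, small_pop.items)
        res = ipred_and_residuals(ds, small_pop, [SubjectEffects(0, 0, 0)])
        corr = item_correlation_map(res, res)
        assert np.isnan(corr.loc[1, 2])


@pytest.fixture(scope="module")
def vpc_setup():
    items = (
        ItemSpec(1, 5, 1.8, (-1.5, -0.3, 0.8, 2.0)),
        ItemSpec(2, 4, 1.2, (-1.0, 0.4, 1.6)),
        ItemSpec(3, 5, 2.3, (-0.8, 0.2, 1.2, 2.2)),
    )
    pop = PopulationParams(items=items, slope_mean=0.2, slope_sd=0.1,
                           met0=2.0, met_iiv_sd=0.3)
    eff = sample_subject_effects(pop, 25, seed=18)
    cov = pd.DataFrame({"subject_id": np.arange(1, 26),
                        "sex": ["M", "F"] * 12 + ["M"]})
    ds = simulate_dataset(pop, eff, complete_design(25, 56), seed=19,
                          covariates=cov)
    reps = simulate_replicates(ds, pop, 150, seed=20)
    return pop, ds, reps


class TestVpc:

    def test_self_simulation_bands_cover_observations(self, vpc_setup):
        pop, ds, reps = vpc_setup
        for kind in ("item_scores", "total_score"):
            r = vpc(ds, pop, kind=kind, replicates=reps)
            assert r.coverage() > 0.75, kind

    def test_transition_proportions_sum_to_one_within_stratum(self, vpc_setup):
        pop, ds, reps = vpc_setup
        r = vpc(ds, pop, kind="transitions", replicates=reps)
        sums = r.table.groupby(["bin", "prev"])["observed"].sum().dropna()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_by_item_grid_respects_category_counts(self, vpc_setup):
        pop, ds, reps = vpc_setup
        r = vpc(ds, pop, kind="item_scores_by_item", replicates=reps)
        assert r.table.loc[r.table["item_id"] == 2, "score"].max() == 3

    def test_stratification_by_covariate(self, vpc_setup):
        pop, ds, reps = vpc_setup
        r = vpc(ds, pop, kind="total_score", replicates=reps, stratify_by="sex")
        assert set(r.table["stratum"]) == {"M", "F"}

    def test_unknown_stratum_rejected(self, vpc_setup):
        pop, ds, reps = vpc_setup
        with pytest.raises(ValueError):
            vpc(ds, pop, kind="total_score", replicates=reps, stratify_by="bogus")

    def test_too_few_replicates_rejected(self, vpc_setup):
        pop, ds, _ = vpc_setup
        with pytest.raises(ValueError):
            vpc(ds, pop, kind="item_scores", n_sim=50, seed=1)
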
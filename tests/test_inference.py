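"""Likelihood assembly, Laplace/quadrature integration, fitting and model
comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from irtmarkov import (
    DiaryDataset,
    ItemSpec,
    PopulationParams,
    SubjectEffects,
    build_generator,
    compare_models,
    conditional_loglik,
    fit,
    init_from_collapsed_fits,
    marginal_loglik,
    sample_subject_effects,
    steady_state_probs,
    transition_kernel,
)
from irtmarkov import _spectral
from irtmarkov import inference as inf
from irtmarkov.simulate import simulate_dataset

from conftest import complete_design


def _one_item_dataset(item, days, scores, subject=1):
    rec = pd.DataFrame(
        {"subject_id": subject, "day": days, "item_id": item.item_id, "score": scores}
    )
    return DiaryDataset(rec, (item,))


class TestConditionalLoglik:
    def test_single_observation_is_steady_state_probability(self, item3):
        pop = PopulationParams(items=(item3,), met0=2.0)
        ds = _one_item_dataset(item3, [5], [2])
        ll = conditional_loglik(ds, pop, SubjectEffects(0.7, 0.0, 0.0))
        assert ll == pytest.approx(np.log(steady_state_probs(item3, 0.7)[2]), abs=1e-12)

    def test_two_observations_match_hand_built_kernel(self, item3):
        pop = PopulationParams(items=(item3,), met0=2.0)
        ds = _one_item_dataset(item3, [1, 2], [1, 1])
        eff = SubjectEffects(0.3, 0.0, 0.0)
        pss = steady_state_probs(item3, 0.3)
        P = transition_kernel(build_generator(pss, 2.0), 1.0)
        expected = np.log(pss[1]) + np.log(P[1, 1])
        assert conditional_loglik(ds, pop, eff) == pytest.approx(expected, abs=1e-10)

    def test_no_markov_limit_gives_independence_loglik(self, item3):
        pop = PopulationParams(items=(item3,), met0=1e-3)
        ds = _one_item_dataset(item3, [1, 2, 3, 5], [0, 2, 1, 2])
        eff = SubjectEffects(-0.2, 0.0, 0.0)
        pss = steady_state_probs(item3, -0.2)
        expected = sum(np.log(pss[s]) for s in [0, 2, 1, 2])
        assert conditional_loglik(ds, pop, eff) == pytest.approx(expected, abs=1e-6)

    def test_row_order_and_id_relabelling_invariance(self, small_pop, tiny_dataset):
        eff = tiny_dataset.true_effects
        base = conditional_loglik(tiny_dataset, small_pop, eff).sum()
        shuffled = tiny_dataset.records.sample(frac=1, random_state=0)
        ds2 = DiaryDataset(shuffled, tiny_dataset.items)
        assert conditional_loglik(ds2, small_pop, eff).sum() == pytest.approx(base, abs=1e-9)
        relabel = tiny_dataset.records.copy()
        relabel["subject_id"] = relabel["subject_id"] * 100 + 7
        ds3 = DiaryDataset(relabel, tiny_dataset.items)
        assert conditional_loglik(ds3, small_pop, eff).sum() == pytest.approx(base, abs=1e-9)


class TestMarginalLoglik:
    def test_degenerate_iiv_equals_conditional_at_means(self, small_items):
        pop = PopulationParams(
            items=small_items, slope_mean=0.3, slope_sd=0.0, met0=1.5,
            met_iiv_sd=0.0, d0_sd=0.0,
        )
        eff = [SubjectEffects(0.0, 0.3, 0.0)] * 2
        ds = simulate_dataset(pop, eff, complete_design(2, 10), seed=3)
        cond = conditional_loglik(ds, pop, eff).sum()
        assert marginal_loglik(ds, pop) == pytest.approx(cond, abs=1e-9)
        assert marginal_loglik(ds, pop, method="aghq") == pytest.approx(cond, abs=1e-9)

    def test_laplace_close_to_adaptive_quadrature(self, small_pop, tiny_dataset):
        lap = marginal_loglik(tiny_dataset, small_pop, per_subject=True)
        agq = marginal_loglik(tiny_dataset, small_pop, method="aghq", n_nodes=15,
                              per_subject=True)
        assert np.abs(lap - agq).max() <= 0.5

    def test_independent_subject_adds_its_marginal(self, small_pop, tiny_dataset):
        total = marginal_loglik(tiny_dataset, small_pop)
        parts = marginal_loglik(tiny_dataset, small_pop, per_subject=True)
        assert total == pytest.approx(parts.sum(), abs=1e-9)
        one = tiny_dataset.records[tiny_dataset.records["subject_id"] == 1]
        ds1 = DiaryDataset(one, tiny_dataset.items)
        assert marginal_loglik(ds1, small_pop) == pytest.approx(parts[0], abs=1e-6)


class TestGradients:
    def test_analytic_theta_gradient_matches_finite_differences(
        self, small_pop, tiny_dataset
    ):
        """The analytic gradient of the conditional + prior part of the
        Laplace objective is exact (the log-determinant part is handled
        separately)."""
        packed = inf._pack(tiny_dataset)
        tmap = inf._ThetaMap(small_pop, {})
        x0 = tmap.pack(small_pop)

        def h_part_and_grad(x):
            p = tmap.unpack(x)
            sol = inf._laplace_loglik(packed, p)
            gi = inf._theta_item_grads(packed, p, sol["core"])
            ge, eta, dims = sol["grad_eff"], sol["eta"], sol["dims"]
            g = {
                "da": gi["da"], "db": gi["db"], "dmet0": gi["dmet0"],
                "dmet_tslope": gi["dmet_tslope"],
                "dslope_mean": ge[:, 1].sum(), "dslope_sd": 0.0, "dmet_iiv": 0.0,
            }
            if 1 in dims:
                g["dslope_sd"] = float((eta[:, dims.index(1)] * ge[:, 1]).sum())
            if 2 in dims:
                g["dmet_iiv"] = float((eta[:, dims.index(2)] * ge[:, 2]).sum())
            return sol["h"].sum(), tmap.grad_to_x(p, g, x)

        _, g0 = h_part_and_grad(x0)
        h = 1e-5
        for j in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += h
            xm[j] -= h
            fd = (h_part_and_grad(xp)[0] - h_part_and_grad(xm)[0]) / (2 * h)
            assert g0[j] == pytest.approx(fd, abs=5e-4, rel=1e-4), tmap.names[j]

    def test_eta_gradient_matches_finite_differences(self, small_pop, tiny_dataset):
        packed = inf._pack(tiny_dataset)
        eff = np.array([[0.3, 0.1, -0.2], [-0.5, 0.25, 0.1], [1.1, 0.2, 0.4]])
        core = inf._core_loglik(packed, small_pop, eff, packed.subj, need_grad=True)
        g = core["grad_eff"]
        h = 1e-6
        for j in range(3):
            ep, em = eff.copy(), eff.copy()
            ep[:, j] += h
            em[:, j] -= h
            lp = inf._core_loglik(packed, small_pop, ep, packed.subj)["logp"]
            lm = inf._core_loglik(packed, small_pop, em, packed.subj)["logp"]
            fd = np.zeros(3)
            np.add.at(fd, packed.subj, (lp - lm) / (2 * h))
            np.testing.assert_allclose(g[:, j], fd, atol=1e-4, rtol=1e-4)


class TestCompareModels:
    @pytest.mark.parametrize(
        "full,reduced,df,p",
        [(100.0, 103.84, 1, 0.0500), (100.0, 100.0, 1, 1.0), (100.0, 110.83, 2, 0.0044)],
    )
    def test_chi_square_p_values(self, full, reduced, df, p):
        rep = compare_models(full, reduced, df)
        assert rep["p_value"] == pytest.approx(p, abs=5e-4)
        assert rep["delta_ofv"] == pytest.approx(reduced - full)

    def test_negative_df_rejected(self):
        with pytest.raises(ValueError):
            compare_models(100.0, 101.0, -1)


class TestCollapsedInitialisation:
    def test_three_state_closed_form_matches_expm(self):
        rng = np.random.default_rng(8)
        pi = rng.dirichlet(np.ones(3), size=50)
        pi = np.maximum(pi, 1e-12)
        pi /= pi.sum(1, keepdims=True)
        met = rng.uniform(0.1, 5, 50)
        dt = rng.uniform(0.2, 8, 50)
        P = _spectral.kernel3_closed_form(pi, met, dt)
        for i in range(50):
            np.testing.assert_allclose(
                P[i], expm(build_generator(pi[i], met[i]) * dt[i]), atol=1e-10
            )

    def test_collapse_schemes_merge_correct_categories(self):
        m5, _cuts = inf._SCHEMES_5["a"]
        assert m5.tolist() == [0, 1, 2, 2, 2]  # (a): 0 | 1 | 2-4
        m5c, cuts_c = inf._SCHEMES_5["c"]
        assert m5c.tolist() == [0, 0, 0, 1, 2]  # (c): 0-2 | 3 | 4
        assert cuts_c == (3, 4)
        assert set(inf._SCHEMES_4) == {"a", "b"}  # top-collapse degenerate for K=4

    def test_initialisation_lands_near_truth(self, small_pop):
        eff = sample_subject_effects(small_pop, 60, seed=21)
        ds = simulate_dataset(small_pop, eff, complete_design(60, 40), seed=22)
        init = init_from_collapsed_fits(ds)
        assert 0.5 * 2.0 < init.met0 < 2.0 * 2.0
        for it, tr in zip(init.items, small_pop.items):
            assert it.b == tuple(sorted(it.b))
            assert abs(it.a - tr.a) / tr.a < 0.6
            np.testing.assert_allclose(it.b, tr.b, atol=0.8)


@pytest.fixture(scope="module")
def fit_setup():
    items = (
        ItemSpec(1, 4, 1.6, (-1.0, 0.1, 1.2)),
        ItemSpec(2, 4, 2.2, (-0.6, 0.5, 1.5)),
    )
    pop = PopulationParams(
        items=items, slope_mean=0.0, slope_sd=0.0, met0=1.5, met_iiv_sd=0.25
    )
    eff = sample_subject_effects(pop, 25, seed=31)
    ds = simulate_dataset(pop, eff, complete_design(25, 40), seed=32)
    ds.true_effects = eff
    res = fit(ds, init=pop, fixed={"slope_sd": 0.0}, ftol=1e-9, max_iter=300,
              refine=3)
    return pop, ds, res


class TestFit:

    def test_fit_converges_with_ordered_difficulties(self, fit_setup):
        pop, ds, res = fit_setup
        assert res.converged
        assert np.isfinite(res.ofv)
        for it in res.estimates.items:
            assert it.b == tuple(sorted(it.b))
        assert abs(np.atleast_1d(res.estimates.met0)[0] - 1.5) / 1.5 < 0.35

    def test_refit_from_perturbed_init_reaches_same_optimum(self, fit_setup):
        pop, ds, res = fit_setup
        from dataclasses import replace
        pert_items = tuple(
            ItemSpec(it.item_id, it.n_categories, it.a * 1.3,
                     tuple(np.array(it.b) + 0.2))
            for it in pop.items
        )
        pert = replace(pop, items=pert_items, met0=2.5, met_iiv_sd=0.4)
        res2 = fit(ds, init=pert, fixed={"slope_sd": 0.0}, ftol=1e-9, max_iter=300,
                   refine=3)
        assert abs(res2.ofv - res.ofv) < 0.1

    def test_markov_model_beats_no_markov_reference(self, fit_setup):
        pop, ds, res = fit_setup
        res0 = fit(ds, init=res.estimates, fixed={"met0": 0.1, "met_iiv_sd": 0.0})
        rep = compare_models(res.ofv, res0.ofv, 2)
        assert rep["delta_ofv"] > 3.84
        assert rep["preferred"] == "full"

    def test_empirical_bayes_estimates_track_truth(self, fit_setup):
        pop, ds, res = fit_setup
        true_d0 = np.array([e.d0 for e in ds.true_effects])
        assert list(res.ebes.columns) == ["subject_id", "d0", "slope", "eta_met"]
        assert len(res.ebes) == 25
        assert np.corrcoef(true_d0, res.ebes["d0"])[0, 1] > 0.8
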
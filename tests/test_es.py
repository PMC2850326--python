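"""Evolution-strategy operators: ranking, selection, recombination, mutation."""

import numpy as np
import pytest

from gencircuit import es
from gencircuit.fixtures import SphereObjective
from gencircuit.objective import check_hard_bounds


def make_pop(fitnesses, penalties=None):
    penalties = penalties if penalties is not None else [0.0] * len(fitnesses)
    return [es.Individual(theta=np.array([float(i)]), sigma=np.array([1.0]),
                          fitness=f, penalty_value=p)
            for i, (f, p) in enumerate(zip(fitnesses, penalties))]


class TestInitPopulation:
    def test_same_seed_gives_identical_population(self, toy_objective):
        cfg = es.ESConfig(lambda_pop=10, mu=2, seed=3)
        a = es.init_population(cfg, toy_objective, np.random.default_rng(3))
        b = es.init_population(cfg, toy_objective, np.random.default_rng(3))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.theta, y.theta)
            assert x.fitness == y.fitness

    def test_population_size_is_lambda(self, toy_objective):
        cfg = es.ESConfig(lambda_pop=125, mu=25, seed=0)
        pop = es.init_population(cfg, toy_objective, np.random.default_rng(0))
        assert len(pop) == 125

    def test_every_initial_individual_satisfies_hard_bounds(self, toy_objective):
        cfg = es.ESConfig(lambda_pop=40, mu=8, seed=1)
        pop = es.init_population(cfg, toy_objective, np.random.default_rng(1))
        for ind in pop:
            params = toy_objective.layout.unpack(ind.theta)
            ok, violations = check_hard_bounds(params, toy_objective.space)
            assert ok, violations
            assert ind.penalty_value == 0.0


class TestStochasticRank:
    def test_all_feasible_orders_by_fitness(self, rng):
        pop = make_pop([3.0, 1.0, 2.0])
        order = es.stochastic_rank(pop, p_f=0.45, rng=rng)
        assert [pop[i].fitness for i in order] == [1.0, 2.0, 3.0]

    def test_equivalent_to_sort_for_feasible_populations(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            fits = rng.uniform(0, 100, rng.integers(2, 30)).tolist()
            pop = make_pop(fits)
            order = es.stochastic_rank(pop, p_f=0.45,
                                       rng=np.random.default_rng(0))
            assert [pop[i].fitness for i in order] == sorted(fits)

    def test_pf_one_is_pure_fitness_ordering(self, rng):
        pop = make_pop([5.0, 1.0, 3.0], penalties=[9.0, 4.0, 0.0])
        order = es.stochastic_rank(pop, p_f=1.0, rng=rng)
        assert [pop[i].fitness for i in order] == [1.0, 3.0, 5.0]

    def test_pf_zero_ranks_feasible_first(self, rng):
        # {E=10, pen=0} vs {E=5, pen=7}: with P_f = 0 penalties dominate.
        pop = make_pop([10.0, 5.0], penalties=[0.0, 7.0])
        order = es.stochastic_rank(pop, p_f=0.0, rng=rng)
        assert order == [0, 1]

    def test_infeasible_pair_comparison_frequency_matches_pf(self):
        # Over many rankings of infeasible pairs, the fraction compared by
        # fitness converges to P_f within Monte-Carlo error.
        p_f = 0.45
        rng = np.random.default_rng(11)
        counter = {}
        for _ in range(4000):
            pop = make_pop([1.0, 2.0], penalties=[3.0, 4.0])
            es.stochastic_rank(pop, p_f=p_f, rng=rng,
                               comparison_counter=counter)
        total = counter["fitness"] + counter["penalty"]
        freq = counter["fitness"] / total
        se = np.sqrt(p_f * (1 - p_f) / total)
        assert abs(freq - p_f) < 3 * se

    def test_unevaluated_individual_raises(self, rng):
        pop = [es.Individual(theta=np.zeros(1), sigma=np.ones(1))]
        with pytest.raises(ValueError, match="evaluated"):
            es.stochastic_rank(pop, 0.45, rng)


class TestSelect:
    def test_takes_top_mu_in_order(self):
        pop = make_pop([1.0, 2.0, 3.0, 4.0, 5.0])
        chosen = es.select_mu(pop, 2)
        assert [c.fitness for c in chosen] == [1.0, 2.0]

    def test_mu_equal_lambda_is_identity(self):
        pop = make_pop([2.0, 1.0])
        assert es.select_mu(pop, 2) == pop

    def test_idempotent_on_selected_set(self):
        pop = make_pop([1.0, 2.0, 3.0])
        once = es.select_mu(pop, 2)
        assert es.select_mu(once, 2) == once


class TestRecombine:
    def test_published_bookkeeping_125_25(self):
        cfg = es.ESConfig(lambda_pop=125, mu=25)
        parents = make_pop(list(range(25)))
        out = es.recombine(parents, cfg)
        copies = [o for o in out if o.is_copy]
        recombinants = [o for o in out if not o.is_copy]
        assert len(out) == 125
        assert len(copies) == 100 and len(recombinants) == 25
        # four copies of each parent
        for p in parents:
            assert sum(np.array_equal(c.theta, p.theta) for c in copies) == 4

    def test_remainder_copies_go_to_fittest(self):
        cfg = es.ESConfig(lambda_pop=5, mu=2)
        parents = [es.Individual(theta=np.array([0.0]), sigma=np.ones(1),
                                 fitness=1.0, penalty_value=0.0),
                   es.Individual(theta=np.array([1.0]), sigma=np.ones(1),
                                 fitness=2.0, penalty_value=0.0)]
        out = es.recombine(parents, cfg)
        copies = [o for o in out if o.is_copy]
        assert len(copies) == 3
        n_best = sum(c.theta[0] == 0.0 for c in copies)
        assert n_best == 2  # fittest parent copied twice, other once

    def test_identical_parents_recombine_to_themselves(self):
        cfg = es.ESConfig(lambda_pop=10, mu=2, chi=0.85)
        v = np.array([1.5, -2.0, 0.25])
        parents = [es.Individual(theta=v.copy(), sigma=np.ones(3),
                                 fitness=1.0, penalty_value=0.0)
                   for _ in range(2)]
        out = es.recombine(parents, cfg)
        for o in out:
            np.testing.assert_allclose(o.theta, v)

    def test_single_parent_rejected(self):
        cfg = es.ESConfig(lambda_pop=4, mu=1)
        with pytest.raises(ValueError, match="two parents"):
            es.recombine(make_pop([1.0])[:1], cfg)

    def test_recombinant_is_stated_affine_combination(self):
        cfg = es.ESConfig(lambda_pop=4, mu=2, chi=0.85)
        a = es.Individual(theta=np.array([1.0]), sigma=np.ones(1),
                          fitness=1.0, penalty_value=0.0)
        b = es.Individual(theta=np.array([3.0]), sigma=np.ones(1),
                          fitness=2.0, penalty_value=0.0)
        out = es.recombine([a, b], cfg)
        recombinants = [o for o in out if not o.is_copy]
        # parent a with next=b, best=a; parent b with next wrapping to a, best=a
        np.testing.assert_allclose(recombinants[0].theta,
                                   0.85 * 1 + 0.075 * (3 + 1))
        np.testing.assert_allclose(recombinants[1].theta,
                                   0.85 * 3 + 0.075 * (1 + 1))


class TestMutate:
    def test_only_copies_may_be_mutated(self, rng):
        ind = es.Individual(theta=np.zeros(2), sigma=np.ones(2), is_copy=False)
        with pytest.raises(ValueError, match="copy"):
            es.mutate([ind], es.ESConfig(lambda_pop=10, mu=2), rng)

    def test_smoothing_fixed_point_without_perturbation(self):
        # If the lognormal perturbation is the identity (zero draws), the
        # smoothed step size equals the previous one.
        class ZeroNormalRng:
            def standard_normal(self, size=None):
                return 0.0 if size is None else np.zeros(size)

        ind = es.Individual(theta=np.array([1.0, 2.0]),
                            sigma=np.array([0.3, 0.5]), is_copy=True)
        es.mutate([ind], es.ESConfig(lambda_pop=10, mu=2, alpha=0.2),
                  ZeroNormalRng())
        np.testing.assert_allclose(ind.sigma, [0.3, 0.5])
        np.testing.assert_allclose(ind.theta, [1.0, 2.0])

    def test_empirical_variance_matches_lognormal_closed_form(self):
        # theta' - theta = sigma' N with sigma' = sigma exp(tau_g N0 + tau_c Nj):
        # Var = sigma^2 exp(2 (tau_g^2 + tau_c^2)), derived independently from
        # the lognormal moment E[e^{2X}] = e^{2 var(X)}.
        n = 4
        sigma0 = 0.7
        cfg = es.ESConfig(lambda_pop=10, mu=2, phi_star=1.0, alpha=0.2)
        tau_g, tau_c = es._tuning_factors(n, cfg.phi_star)
        expected_var = sigma0 ** 2 * np.exp(2 * (tau_g ** 2 + tau_c ** 2))
        rng = np.random.default_rng(5)
        trials = 25_000
        deltas = np.empty((trials, n))
        for t in range(trials):
            ind = es.Individual(theta=np.zeros(n), sigma=np.full(n, sigma0),
                                is_copy=True)
            es.mutate([ind], cfg, rng)
            deltas[t] = ind.theta
        emp = deltas.var()
        # MC standard error of a variance estimate: var * sqrt(2/(N-1)) with
        # heavy-tailed inflation from the lognormal mixing; use kurtosis form.
        flat = deltas.ravel()
        m4 = np.mean((flat - flat.mean()) ** 4)
        se = np.sqrt((m4 - emp ** 2) / flat.size)
        assert abs(emp - expected_var) < 3 * se

    def test_step_sizes_remain_strictly_positive(self, rng):
        cfg = es.ESConfig(lambda_pop=10, mu=2)
        ind = es.Individual(theta=np.zeros(3), sigma=np.full(3, 1e-8),
                            is_copy=True)
        for _ in range(200):
            ind.is_copy = True
            es.mutate([ind], cfg, rng)
            assert np.all(ind.sigma > 0)


class TestGenerationStep:
    def test_output_size_is_always_lambda(self, rng):
        obj = SphereObjective(n=3)
        cfg = es.ESConfig(lambda_pop=12, mu=3, seed=0)
        pop = es.init_population(cfg, obj, rng)
        for _ in range(3):
            pop, stats = es.generation_step(pop, cfg, obj, rng)
            assert len(pop) == 12
            assert stats.evaluations == 12

    def test_accepts_oversized_population_after_immigration(self, rng):
        obj = SphereObjective(n=3)
        cfg = es.ESConfig(lambda_pop=10, mu=2, seed=0)
        pop = es.init_population(cfg, obj, rng)
        pop.extend(pop[:3])  # immigrants
        new, _ = es.generation_step(pop, cfg, obj, rng)
        assert len(new) == 10

    def test_same_seed_same_population_gives_identical_step(self):
        obj = SphereObjective(n=3)
        cfg = es.ESConfig(lambda_pop=10, mu=2, seed=0)
        pop_a = es.init_population(cfg, obj, np.random.default_rng(1))
        pop_b = es.init_population(cfg, obj, np.random.default_rng(1))
        out_a, _ = es.generation_step(pop_a, cfg, obj, np.random.default_rng(2))
        out_b, _ = es.generation_step(pop_b, cfg, obj, np.random.default_rng(2))
        for x, y in zip(out_a, out_b):
            np.testing.assert_array_equal(x.theta, y.theta)

    def test_descends_on_quadratic_toy_and_beats_random_sampling(self):
        obj = SphereObjective(n=2)
        cfg = es.ESConfig(lambda_pop=10, mu=2, seed=0)
        finals, randoms = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pop = es.init_population(cfg, obj, rng)
            first = min(i.fitness for i in pop)
            for _ in range(50):
                pop, stats = es.generation_step(pop, cfg, obj, rng)
            finals.append(min(i.fitness for i in pop) / first)
            rr = np.random.default_rng(100 + seed)
            best_rand = min(obj(obj.sample_theta(rr))[0] for _ in range(510))
            randoms.append(best_rand / first)
        assert np.median(finals) < 1.0
        assert np.median(finals) < np.median(randoms)
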
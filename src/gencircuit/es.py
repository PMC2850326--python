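"""One island of the (mu, lambda)-Evolution Strategy.

Each generation: the population is ordered by *stochastic ranking* (a
randomised bubble sort trading objective value against penalty with
probability ``P_f``), the top ``mu`` become parents, ``lambda - mu``
offspring are direct copies of parents and ``mu`` more are recombinants;
only the copies are then mutated, with non-isotropic self-adaptive step
sizes (lognormal step-size perturbation, Gaussian parameter perturbation,
exponential smoothing of the kept step sizes).  Parents do not survive —
selection is comma, not plus.

All randomness flows through an explicit ``numpy.random.Generator``; the
evolution of an island is a pure function of (seed, config, objective).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Individual",
    "ESConfig",
    "GenerationStats",
    "init_population",
    "stochastic_rank",
    "select_mu",
    "recombine",
    "mutate",
    "generation_step",
]

Objective = Callable[[np.ndarray], tuple[float, float]]


@dataclass
class Individual:
    """A parameter vector with per-parameter mutation step sizes and caches."""

    theta: np.ndarray
    sigma: np.ndarray
    fitness: float | None = None  # cached objective value E
    penalty_value: float | None = None  # cached penalty value
    is_copy: bool = False  # tag set by recombine: copy vs recombinant

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.theta.shape != self.sigma.shape:
            raise ValueError("theta and sigma must have the same length")
        if np.any(self.sigma <= 0):
            raise ValueError("step sizes must be strictly positive")

    @property
    def evaluated(self) -> bool:
        return self.fitness is not None


@dataclass(frozen=True)
class ESConfig:
    """Strategy constants of one island.

    Defaults are the published operating point for the gap-gene problem:
    population 125 with mu = lambda/5 = 25 parents, recombination factor
    0.85, ranking probability 0.45, mutation tuning phi* = 1, step-size
    smoothing 0.2, migration every 200 generations, logging every 20, and
    a 40000-generation run length.
    """

    lambda_pop: int = 125
    mu: int = 25
    chi: float = 0.85
    p_f: float = 0.45
    phi_star: float = 1.0
    alpha: float = 0.2
    migration_interval: int = 200
    log_interval: int = 20
    max_generations: int = 40000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.mu < self.lambda_pop:
            raise ValueError("need 0 < mu < lambda")
        if not 0.0 <= self.p_f <= 1.0:
            raise ValueError("P_f must lie in [0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        for name in ("migration_interval", "log_interval", "max_generations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GenerationStats:
    best_fitness: float
    best_penalty: float
    evaluations: int


def _evaluate(ind: Individual, objective: Objective) -> None:
    fit, pen = objective(ind.theta)
    ind.fitness = float(fit)
    ind.penalty_value = float(pen)


def init_population(config: ESConfig, objective, rng: np.random.Generator
                    ) -> list[Individual]:
    """Create and evaluate ``lambda`` individuals.

    ``objective`` must expose ``sample_theta(rng)`` and ``initial_sigma()``
    (kinetic rates uniform inside their open hard bounds, regulatory
    weights uniform in a penalty-feasible box, step sizes 10% of each
    parameter's range) in addition to being callable.
    """
    sigma0 = objective.initial_sigma()
    pop = []
    for _ in range(config.lambda_pop):
        ind = Individual(theta=objective.sample_theta(rng), sigma=sigma0.copy())
        _evaluate(ind, objective)
        pop.append(ind)
    return pop


def _feasible(pen: float) -> bool:
    return pen <= 0.0


def stochastic_rank(pop: Sequence[Individual], p_f: float,
                    rng: np.random.Generator,
                    comparison_counter: dict | None = None) -> list[int]:
    """Stochastic-ranking permutation of ``pop`` indices, best first.

    Bubble-sort-like: ``len(pop)`` sweeps over adjacent pairs from the top.
    A pair with both penalty values <= 0 is ordered by fitness.  Otherwise
    the pair is ordered by fitness with probability ``P_f`` and by penalty
    value with probability ``1 - P_f``.  Sweeping stops early when an
    entire sweep swaps nothing.  Uniform draws are consumed lazily (only
    for pairs that are not both feasible), so fully feasible populations
    rank deterministically.  ``comparison_counter``, when given, tallies how
    often not-both-feasible pairs were compared by fitness vs penalty.
    """
    for k, ind in enumerate(pop):
        if not ind.evaluated:
            raise ValueError(f"individual {k} has not been evaluated")
    order = list(range(len(pop)))
    n = len(order)
    for _sweep in range(n):
        swapped = False
        for j in range(n - 1):
            top, bot = pop[order[j]], pop[order[j + 1]]
            if _feasible(top.penalty_value) and _feasible(bot.penalty_value):
                by_fitness = True
            else:
                by_fitness = rng.random() < p_f
                if comparison_counter is not None:
                    key = "fitness" if by_fitness else "penalty"
                    comparison_counter[key] = comparison_counter.get(key, 0) + 1
            if by_fitness:
                swap = bot.fitness < top.fitness
            else:
                swap = bot.penalty_value < top.penalty_value
            if swap:
                order[j], order[j + 1] = order[j + 1], order[j]
                swapped = True
        if not swapped:
            break
    return order


def select_mu(ranked: Sequence[Individual], mu: int) -> list[Individual]:
    """Top ``mu`` individuals of an already-ranked population."""
    if mu > len(ranked):
        raise ValueError("mu cannot exceed the population size")
    return list(ranked[:mu])


def recombine(parents: Sequence[Individual], config: ESConfig) -> list[Individual]:
    """Produce ``lambda`` offspring from ``mu`` ranked parents.

    ``lambda - mu`` offspring are direct (asexual) copies — each parent
    copied ``(lambda-mu) // mu`` times, the fittest ``(lambda-mu) % mu``
    parents once more — tagged ``is_copy=True`` for the mutation stage.
    The remaining ``mu`` are recombinants: parent k combined with the
    next-fittest parent (wrapping to the fittest after the worst) and the
    fittest parent,

        x' = chi * x_k + (1 - chi)/2 * (x_next + x_best),

    an affine combination so identical parents recombine to themselves.
    Recombinants inherit the step sizes of their primary parent.
    """
    mu = len(parents)
    if mu != config.mu:
        raise ValueError(f"expected {config.mu} parents, got {mu}")
    if mu < 2:
        raise ValueError("recombination needs at least two parents")
    lam = config.lambda_pop
    n_copies = lam - mu
    base, extra = divmod(n_copies, mu)
    offspring: list[Individual] = []
    for k, parent in enumerate(parents):
        reps = base + (1 if k < extra else 0)
        for _ in range(reps):
            offspring.append(Individual(theta=parent.theta.copy(),
                                        sigma=parent.sigma.copy(),
                                        is_copy=True))
    chi = config.chi
    best = parents[0].theta
    for k, parent in enumerate(parents):
        nxt = parents[(k + 1) % mu].theta
        theta = chi * parent.theta + (1.0 - chi) / 2.0 * (nxt + best)
        offspring.append(Individual(theta=theta, sigma=parent.sigma.copy(),
                                    is_copy=False))
    return offspring


def _tuning_factors(n: int, phi_star: float) -> tuple[float, float]:
    """Global and per-coordinate lognormal learning rates (Schwefel's rates
    scaled by phi*)."""
    tau_global = phi_star / np.sqrt(2.0 * n)
    tau_coord = phi_star / np.sqrt(2.0 * np.sqrt(n))
    return tau_global, tau_coord


def mutate(copies: Sequence[Individual], config: ESConfig,
           rng: np.random.Generator) -> None:
    """Self-adaptive mutation, in place, of the tagged copy individuals.

    Per individual: (1) step sizes perturbed multiplicatively,
    ``sigma' = sigma * exp(tau_g N + tau_c N_j)`` with one shared normal
    draw N and fresh per-parameter draws N_j; (2) parameters perturbed
    additively, ``theta' = theta + sigma' N'_j``; (3) the kept step size is
    the exponentially smoothed ``alpha sigma' + (1 - alpha) sigma``.
    Step sizes remain strictly positive by construction.
    """
    for ind in copies:
        if not ind.is_copy:
            raise ValueError("mutate applies only to copy-tagged individuals")
        n = ind.theta.size
        tau_g, tau_c = _tuning_factors(n, config.phi_star)
        sigma_prime = ind.sigma * np.exp(tau_g * rng.standard_normal()
                                         + tau_c * rng.standard_normal(n))
        ind.theta = ind.theta + sigma_prime * rng.standard_normal(n)
        ind.sigma = config.alpha * sigma_prime + (1.0 - config.alpha) * ind.sigma
        ind.fitness = None
        ind.penalty_value = None


def generation_step(pop: Sequence[Individual], config: ESConfig,
                    objective: Objective, rng: np.random.Generator
                    ) -> tuple[list[Individual], GenerationStats]:
    """One full generation: rank, select, recombine, mutate, evaluate.

    Accepts a population of size >= lambda (post-immigration transients)
    and always returns exactly lambda evaluated individuals.
    """
    if len(pop) < config.lambda_pop:
        raise ValueError("population smaller than lambda")
    order = stochastic_rank(pop, config.p_f, rng)
    ranked = [pop[i] for i in order]
    parents = select_mu(ranked, config.mu)
    offspring = recombine(parents, config)
    mutate([o for o in offspring if o.is_copy], config, rng)
    n_evals = 0
    for o in offspring:
        _evaluate(o, objective)
        n_evals += 1
    best = min(offspring, key=lambda o: (o.fitness, o.penalty_value))
    return offspring, GenerationStats(best_fitness=best.fitness,
                                      best_penalty=best.penalty_value,
                                      evaluations=n_evals)
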
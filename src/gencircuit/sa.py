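"""Simplified parallel simulated-annealing baseline.

Implements the elements of the parallel Lam SA comparison algorithm that
are fully specified here: an energy given by objective plus penalty,
Metropolis acceptance, Boltzmann redistribution (mixing) of chain states
every ``m`` iterations, an initial burn at constant temperature, and the
freeze stopping condition.  Two pieces of the published algorithm are
deliberate stand-ins, clearly labelled as such:

* the Lam adaptive temperature schedule (defined in earlier annealing
  literature, not restated here) is replaced by a pluggable cooling
  schedule, geometric by default;
* the adaptive move-generation strategy is replaced by per-parameter
  Gaussian proposals whose scale adapts toward a target acceptance ratio.

"Parallelism" is emulated as K chains advancing in lockstep rounds with
shared-temperature mixing, matching the virtual scheduler used by the
island module.  Uphill moves are accepted with probability exp(-dE/T)
(standard Metropolis; the source description's printed sign would give
probabilities above one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .islands import RunLog, RunResult
from .es import Individual

__all__ = [
    "AnnealState",
    "SAConfig",
    "metropolis_step",
    "mix_states",
    "geometric_schedule",
    "run_sa",
]


@dataclass
class AnnealState:
    """One chain's current parameter vector, cached energy and temperature."""

    theta: np.ndarray
    energy: float
    temperature: float

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class SAConfig:
    """Chain count, temperatures, mixing/logging cadence and freeze rule.

    The freeze condition halts the run when the best energy changes by less
    than ``freeze_fraction`` (relatively) over ``freeze_window`` consecutive
    statistics checks.
    """

    K: int = 4
    T0: float = 1000.0
    n_init: int = 100
    mix_interval: int = 100
    stat_interval: int = 10000
    freeze_fraction: float = 1e-4
    freeze_window: int = 3
    cooling_rate: float = 0.999
    proposal_scale: float = 0.1
    target_acceptance: float = 0.44
    max_iterations: int = 200000
    seed: int = 0

    def __post_init__(self):
        for name in ("K", "T0", "n_init", "mix_interval", "stat_interval",
                     "freeze_window", "max_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.cooling_rate <= 1:
            raise ValueError("cooling_rate must lie in (0, 1]")


def geometric_schedule(T0: float, rate: float) -> Callable[[int], float]:
    """Stand-in cooling schedule: T(k) = T0 * rate^k after the burn."""
    return lambda k: T0 * rate ** k


def _energy(objective, theta: np.ndarray) -> float:
    E, pen = objective(theta)
    return E + pen


def metropolis_step(state: AnnealState, objective, rng: np.random.Generator,
                    proposal_scale: float | np.ndarray = 0.1) -> tuple[AnnealState, bool]:
    """One Metropolis move: Gaussian perturbation of a single parameter.

    Downhill moves (dE < 0) are always accepted; uphill moves with
    probability exp(-dE/T).  Moves into hard-bound-violating territory
    carry infinite energy and are rejected outright.  Returns the new state
    and whether the move was accepted.
    """
    if state.temperature <= 0:
        raise ValueError("temperature must be positive")
    theta = state.theta.copy()
    j = int(rng.integers(theta.size))
    scale = proposal_scale[j] if np.ndim(proposal_scale) else proposal_scale
    theta[j] += scale * rng.standard_normal()
    e_new = _energy(objective, theta)
    dE = e_new - state.energy
    if dE < 0:
        accept = True
    elif not np.isfinite(e_new):
        accept = False
    else:
        accept = rng.random() < np.exp(-dE / state.temperature)
    if accept:
        return AnnealState(theta=theta, energy=e_new,
                           temperature=state.temperature), True
    return state, False


def mix_states(states: Sequence[AnnealState], T: float,
               rng: np.random.Generator) -> list[AnnealState]:
    """Boltzmann redistribution of chain states across processes.

    Each process is independently assigned the state of chain ``i`` with
    probability exp(-E_i/T) / sum_j exp(-E_j/T) — assignment of existing
    states, never averaging, so good states propagate while higher-energy
    states stay reachable.
    """
    if not states:
        raise ValueError("need at least one state")
    energies = np.array([s.energy for s in states])
    finite = np.isfinite(energies)
    if not finite.any():
        raise ValueError("all chain energies are infinite")
    # Shift for numerical stability; -inf weight for infinite energies.
    logw = np.where(finite, -(energies - energies[finite].min()) / T, -np.inf)
    w = np.exp(logw)
    p = w / w.sum()
    picks = rng.choice(len(states), size=len(states), p=p)
    return [AnnealState(theta=states[i].theta.copy(), energy=states[i].energy,
                        temperature=T) for i in picks]


def run_sa(objective, config: SAConfig,
           termination_energy: float | None = None,
           clock: Callable[[], float] | None = None) -> RunResult:
    """Run the K-chain annealing baseline to freeze or the iteration cap.

    Chains burn ``n_init`` iterations at constant T0, then cool under the
    configured schedule with state mixing every ``mix_interval`` and
    statistics/logging every ``stat_interval`` iterations.  Proposal scales
    adapt toward the target acceptance ratio between checks (stand-in for
    the published adaptive move generation).
    """
    import time as _time

    if clock is None:
        start = _time.perf_counter()
        clock = lambda: _time.perf_counter() - start  # noqa: E731
    rngs = [np.random.default_rng(config.seed + k) for k in range(config.K)]
    schedule = geometric_schedule(config.T0, config.cooling_rate)
    states = []
    scales = []
    for k in range(config.K):
        theta = objective.sample_theta(rngs[k])
        states.append(AnnealState(theta=theta,
                                  energy=_energy(objective, theta),
                                  temperature=config.T0))
        scales.append(config.proposal_scale * objective.initial_sigma())
    best = min(states, key=lambda s: s.energy)
    best = AnnealState(best.theta.copy(), best.energy, best.temperature)
    log = RunLog(interval=config.stat_interval)
    accepted = np.zeros(config.K)
    proposed = np.zeros(config.K)
    frozen_checks = 0
    last_check_energy = np.inf
    halted = False
    for it in range(1, config.max_iterations + 1):
        T = config.T0 if it <= config.n_init else schedule(it - config.n_init)
        for k in range(config.K):
            states[k].temperature = T
            states[k], acc = metropolis_step(states[k], objective, rngs[k],
                                             scales[k])
            accepted[k] += acc
            proposed[k] += 1
            if states[k].energy < best.energy:
                best = AnnealState(states[k].theta.copy(), states[k].energy, T)
        if config.K > 1 and it % config.mix_interval == 0:
            states = mix_states(states, T, rngs[0])
        if it % config.stat_interval == 0:
            current = min(s.energy for s in states)
            log.append(it, clock(), current)
            # Acceptance-targeted scale adaptation (move-generation stand-in).
            for k in range(config.K):
                if proposed[k]:
                    ratio = accepted[k] / proposed[k]
                    scales[k] = scales[k] * np.exp(
                        0.5 * (ratio - config.target_acceptance))
                accepted[k] = proposed[k] = 0
            if termination_energy is not None and best.energy <= termination_energy:
                halted = True
            rel_change = abs(last_check_energy - best.energy) / max(
                abs(best.energy), 1e-300)
            if np.isfinite(last_check_energy) and rel_change < config.freeze_fraction:
                frozen_checks += 1
                if frozen_checks >= config.freeze_window:
                    halted = True  # freeze condition
            else:
                frozen_checks = 0
            last_check_energy = best.energy
            if halted:
                break
    best_ind = Individual(theta=best.theta,
                          sigma=np.full(best.theta.size, 1e-12) + 1.0,
                          fitness=best.energy, penalty_value=0.0)
    return RunResult(best=best_ind, log=log,
                     n_evaluations=int(config.K * min(it, config.max_iterations)),
                     mode="sa", n_islands=config.K)
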
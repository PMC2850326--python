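"""Multi-island execution: serial, synchronous-parallel and asynchronous modes.

Islands are independent (mu, lambda)-ES populations coupled only by
migration: every ``m`` generations each island's best individual is copied
into another island chosen uniformly at random, replacing that island's
worst individuals.  The synchronous parallel mode performs the same
exchange under barrier semantics and is bit-identical to the serial mode
for the same seeds — the determinism guarantee this module's tests pin
down.  The asynchronous mode exchanges migrants and statistics through
bounded per-sender buffers with no barriers; deposits to a full buffer are
deferred, never dropped.  True process-based concurrency is available for
integration testing; unit tests use a deterministic virtual-time scheduler
(round-robin with configurable per-island lag in generations), since the
asynchronous semantics live in the buffers, not the wall clock.

RNG discipline: island ``i`` draws from ``default_rng(seed + i)``;
migration schedules come from a dedicated master stream so that island
streams are identical between serial and synchronous modes.
"""

from __future__ import annotations

import time
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .es import ESConfig, Individual, generation_step, init_population

__all__ = [
    "MigrationSchedule",
    "MessageBuffer",
    "RunLog",
    "TerminationSpec",
    "RunResult",
    "serial_migrate",
    "sync_migrate",
    "async_step",
    "check_termination",
    "run",
]

MASTER_SEED_OFFSET = 999_983  # dedicated master-stream offset (prime)
MIGRANT_BUFFER_CAP = 10  # max migrants from one sender in one island buffer
MASTER_BUFFER_CAP = 50  # max messages from one sender in the master buffer


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MigrationSchedule:
    """sender -> receiver island mapping; no island sends to itself."""

    assignments: dict[int, int]

    def __post_init__(self):
        for s, r in self.assignments.items():
            if s == r:
                raise ValueError(f"island {s} may not migrate to itself")


@dataclass
class MessageBuffer:
    """Bounded per-sender FIFO message store (deferral, not loss, when full)."""

    capacity: int
    pending: dict[int, deque] = field(default_factory=dict)

    def can_accept(self, sender: int) -> bool:
        return len(self.pending.get(sender, ())) < self.capacity

    def put(self, sender: int, message) -> bool:
        """Deposit a message; returns False (caller must defer) when full."""
        q = self.pending.setdefault(sender, deque())
        if len(q) >= self.capacity:
            return False
        q.append(message)
        return True

    def drain(self) -> list:
        """Remove and return all pending messages, oldest first per sender."""
        out = []
        for sender in sorted(self.pending):
            out.extend(self.pending[sender])
        self.pending.clear()
        return out

    def __len__(self) -> int:
        return sum(len(q) for q in self.pending.values())


@dataclass
class RunLog:
    """Best-objective records at fixed generation intervals.

    ``records`` rows are (generation, elapsed_seconds, best_objective); the
    best is the current fittest across islands (it may fluctuate upward
    under comma selection — use :meth:`best_so_far` for descent analysis).
    """

    interval: int
    records: list[tuple[int, float, float]] = field(default_factory=list)

    def append(self, generation: int, elapsed: float, best: float) -> None:
        if generation % self.interval != 0:
            raise ValueError(
                f"generation {generation} is not a multiple of {self.interval}"
            )
        self.records.append((int(generation), float(elapsed), float(best)))

    @property
    def generations(self) -> np.ndarray:
        return np.array([r[0] for r in self.records], dtype=int)

    @property
    def elapsed(self) -> np.ndarray:
        return np.array([r[1] for r in self.records])

    @property
    def best(self) -> np.ndarray:
        return np.array([r[2] for r in self.records])

    def best_so_far(self) -> np.ndarray:
        if not self.records:
            return np.array([])
        return np.minimum.accumulate(self.best)

    def to_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("generation\telapsed_seconds\tbest_objective\n")
            for g, t, b in self.records:
                fh.write(f"{g}\t{t:.17g}\t{b:.17g}\n")

    @classmethod
    def from_tsv(cls, path) -> "RunLog":
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("generation"):
                    continue
                g, t, b = line.split("\t")
                records.append((int(g), float(t), float(b)))
        gens = [r[0] for r in records]
        interval = int(np.gcd.reduce(gens)) if gens else 1
        return cls(interval=max(interval, 1), records=records)


@dataclass(frozen=True)
class TerminationSpec:
    """Either a fixed generation count or a threshold-hold rule.

    ``threshold_hold`` halts once the currently lowest objective value has
    stayed at or below ``threshold`` for ``hold`` consecutive log checks
    (i.e. hold x log_interval generations).
    """

    mode: str = "fixed_generations"
    max_generations: int = 40000
    threshold: float | None = None
    hold: int = 1

    def __post_init__(self):
        if self.mode not in ("fixed_generations", "threshold_hold"):
            raise ValueError(f"unknown termination mode {self.mode!r}")
        if self.mode == "threshold_hold" and self.threshold is None:
            raise ValueError("threshold_hold requires a threshold")


@dataclass
class RunResult:
    best: Individual
    log: RunLog
    n_evaluations: int
    mode: str
    n_islands: int


# ---------------------------------------------------------------------------
# Migration
# ---------------------------------------------------------------------------


def _rank_key(ind: Individual):
    # Deterministic feasibility-then-fitness ordering used for picking
    # migrants and victims; avoids consuming RNG draws so serial and
    # synchronous island streams stay aligned.
    infeasible = 0 if (ind.penalty_value is not None and ind.penalty_value <= 0) else 1
    return (infeasible, ind.fitness, ind.penalty_value)


def _best_of(pop: Sequence[Individual]) -> Individual:
    return min(pop, key=_rank_key)


def _clone(ind: Individual) -> Individual:
    return Individual(theta=ind.theta.copy(), sigma=ind.sigma.copy(),
                      fitness=ind.fitness, penalty_value=ind.penalty_value,
                      is_copy=ind.is_copy)


def draw_schedule(n_islands: int, rng: np.random.Generator) -> MigrationSchedule:
    """Uniformly assign each island a receiver among the other islands."""
    assignments = {}
    for i in range(n_islands):
        r = int(rng.integers(n_islands - 1))
        assignments[i] = r if r < i else r + 1
    return MigrationSchedule(assignments=assignments)


def _apply_schedule(islands: list[list[Individual]],
                    schedule: MigrationSchedule) -> None:
    """Copy each sender's best to its receiver, replacing the receiver's worst.

    An island designated receiver by k senders has its k worst replaced.
    Migrants are taken from the pre-migration populations (copy semantics:
    senders keep their best).
    """
    migrants = {i: _clone(_best_of(pop)) for i, pop in enumerate(islands)}
    incoming: dict[int, list[Individual]] = {}
    for sender in sorted(schedule.assignments):
        incoming.setdefault(schedule.assignments[sender], []).append(
            migrants[sender])
    for receiver, arrivals in incoming.items():
        pop = islands[receiver]
        worst = sorted(range(len(pop)), key=lambda j: _rank_key(pop[j]),
                       reverse=True)[:len(arrivals)]
        for j, migrant in zip(worst, arrivals):
            pop[j] = migrant


def serial_migrate(islands: list[list[Individual]],
                   rng: np.random.Generator) -> MigrationSchedule | None:
    """Serial-mode migration; single island is a no-op."""
    if len(islands) < 2:
        return None
    schedule = draw_schedule(len(islands), rng)
    _apply_schedule(islands, schedule)
    return schedule


def sync_migrate(islands: list[list[Individual]],
                 master_rng: np.random.Generator) -> MigrationSchedule | None:
    """Synchronous-parallel migration under barrier semantics.

    The master draws the schedule and (conceptually) broadcasts it; islands
    then exchange point-to-point.  The rule and RNG stream are identical to
    :func:`serial_migrate`, which is what makes the synchronous mode
    bit-identical to the serial one.
    """
    return serial_migrate(islands, master_rng)


# ---------------------------------------------------------------------------
# Async (buffered) exchange
# ---------------------------------------------------------------------------


@dataclass
class _AsyncIsland:
    index: int
    pop: list[Individual]
    rng: np.random.Generator
    config: ESConfig
    generation: int = 0
    buffer: MessageBuffer = field(
        default_factory=lambda: MessageBuffer(capacity=MIGRANT_BUFFER_CAP))
    pending_deposit: list[tuple[int, Individual]] = field(default_factory=list)
    pending_master: list[tuple[int, float]] = field(default_factory=list)
    evaluations: int = 0
    halted: bool = False

    def choose_receiver(self, n_islands: int) -> int:
        others = [j for j in range(n_islands) if j != self.index]
        if len(others) == 1:
            return others[0]  # forced choice consumes no randomness
        return others[int(self.rng.integers(len(others)))]


def async_step(island: _AsyncIsland, islands: Sequence[_AsyncIsland]) -> None:
    """One buffered migration event for ``island`` (deposit, then absorb).

    Deposits the island's best into the buffer of a uniformly chosen other
    island; a deposit refused by a full buffer is retried at later events
    rather than dropped.  All migrants pending in the island's own buffer
    are then absorbed into its population (a transient size above lambda,
    restored at the next selection) and the buffer is cleared.
    """
    still_pending = []
    for receiver, migrant in island.pending_deposit:
        if not islands[receiver].buffer.put(island.index, migrant):
            still_pending.append((receiver, migrant))
    island.pending_deposit = still_pending

    receiver = island.choose_receiver(len(islands))
    migrant = _clone(_best_of(island.pop))
    if not islands[receiver].buffer.put(island.index, migrant):
        island.pending_deposit.append((receiver, migrant))

    island.pop.extend(island.buffer.drain())


def check_termination(log: RunLog, spec: TerminationSpec) -> bool:
    """Whether the run should halt given the log so far."""
    if not log.records:
        return False
    if spec.mode == "fixed_generations":
        return log.records[-1][0] >= spec.max_generations
    best = log.best
    trailing = 0
    for value in best[::-1]:
        if value <= spec.threshold:
            trailing += 1
        else:
            break
    return trailing >= spec.hold


# ---------------------------------------------------------------------------
# Run drivers
# ---------------------------------------------------------------------------


def _log_and_check(log: RunLog, gen: int, clock, pops, spec) -> bool:
    best = min((_best_of(pop) for pop in pops), key=_rank_key)
    log.append(gen, clock(), best.fitness)
    return check_termination(log, spec)


def _overall_best(pops) -> Individual:
    return _clone(min((_best_of(pop) for pop in pops), key=_rank_key))


def _run_lockstep(objective, config: ESConfig, n_islands: int, mode: str,
                  termination: TerminationSpec, clock) -> RunResult:
    """Serial and synchronous modes share this driver; they differ only in
    which migration operation is invoked (same rule, same master stream)."""
    rngs = [np.random.default_rng(config.seed + i) for i in range(n_islands)]
    master = np.random.default_rng(config.seed + MASTER_SEED_OFFSET)
    pops = [init_population(config, objective, rngs[i]) for i in range(n_islands)]
    n_evals = config.lambda_pop * n_islands
    log = RunLog(interval=config.log_interval)
    migrate = serial_migrate if mode == "serial" else sync_migrate
    gen = 0
    while gen < termination.max_generations:
        gen += 1
        for i in range(n_islands):
            pops[i], stats = generation_step(pops[i], config, objective, rngs[i])
            n_evals += stats.evaluations
        if n_islands > 1 and gen % config.migration_interval == 0:
            migrate(pops, master)
        if gen % config.log_interval == 0:
            if _log_and_check(log, gen, clock, pops, termination):
                break
    return RunResult(best=_overall_best(pops), log=log, n_evaluations=n_evals,
                     mode=mode, n_islands=n_islands)


def _run_async_virtual(objective, config: ESConfig, n_islands: int,
                       termination: TerminationSpec, clock,
                       lags: Sequence[int] | None) -> RunResult:
    """Deterministic virtual-time scheduler for the asynchronous algorithm.

    Rounds advance every island by one generation (island order), offset by
    per-island lags; migration events (deposit, then absorb) fire when an
    island's own generation count reaches a multiple of the migration
    interval, and statistics flow to the master through a bounded buffer.
    With zero lags the exchange pattern coincides with the synchronous one.
    """
    lags = list(lags) if lags is not None else [0] * n_islands
    if len(lags) != n_islands:
        raise ValueError("need one lag per island")
    islands = []
    for i in range(n_islands):
        rng = np.random.default_rng(config.seed + i)
        pop = init_population(config, objective, rng)
        islands.append(_AsyncIsland(index=i, pop=pop, rng=rng, config=config,
                                    evaluations=config.lambda_pop))
    master_buffer = MessageBuffer(capacity=MASTER_BUFFER_CAP)
    master_reports: dict[int, dict[int, float]] = {}
    log = RunLog(interval=config.log_interval)
    terminate = False
    rounds = 0
    max_rounds = termination.max_generations + max(lags) + 1
    while rounds <= max_rounds:
        rounds += 1
        active = False
        # Phase A: each running island advances one generation.
        for isl in islands:
            if isl.halted or terminate:
                continue
            if rounds <= lags[isl.index]:
                active = True
                continue
            if isl.generation >= termination.max_generations:
                isl.halted = True
                continue
            isl.pop, stats = generation_step(isl.pop, config, objective, isl.rng)
            isl.generation += 1
            isl.evaluations += stats.evaluations
            active = True
        # Phase B/C: buffered migration (all deposits, then all absorptions).
        if n_islands > 1:
            movers = [isl for isl in islands
                      if not isl.halted and isl.generation > 0
                      and isl.generation % config.migration_interval == 0]
            for isl in movers:
                still = []
                for receiver, migrant in isl.pending_deposit:
                    if not islands[receiver].buffer.put(isl.index, migrant):
                        still.append((receiver, migrant))
                isl.pending_deposit = still
                receiver = isl.choose_receiver(n_islands)
                migrant = _clone(_best_of(isl.pop))
                if not islands[receiver].buffer.put(isl.index, migrant):
                    isl.pending_deposit.append((receiver, migrant))
            for isl in movers:
                isl.pop.extend(isl.buffer.drain())
        # Phase D: statistics to the master buffer (deferred when full).
        for isl in islands:
            if isl.halted:
                continue
            if isl.generation > 0 and isl.generation % config.log_interval == 0:
                isl.pending_master.append(
                    (isl.generation, _best_of(isl.pop).fitness))
            still = []
            for msg in isl.pending_master:
                if not master_buffer.put(isl.index, (isl.index, *msg)):
                    still.append(msg)
            isl.pending_master = still
        # Phase E: master drains, logs complete generations, checks halt.
        for sender, gen, fit in master_buffer.drain():
            master_reports.setdefault(gen, {})[sender] = fit
        for gen in sorted(g for g, rep in master_reports.items()
                          if len(rep) == n_islands):
            rep = master_reports.pop(gen)
            log.append(gen, clock(), min(rep.values()))
            if check_termination(log, termination):
                terminate = True  # master's terminate signal
        if terminate or not active or all(isl.halted for isl in islands):
            break
    # Flush deferred deposits so nothing is silently dropped.
    for isl in islands:
        for receiver, migrant in isl.pending_deposit:
            islands[receiver].buffer.pending.setdefault(
                isl.index, deque()).append(migrant)
        isl.pending_deposit = []
    result = RunResult(best=_overall_best([isl.pop for isl in islands]),
                       log=log,
                       n_evaluations=sum(isl.evaluations for isl in islands),
                       mode="async", n_islands=n_islands)
    return result


def run(objective, config: ESConfig, n_islands: int = 1, mode: str = "serial",
        termination: TerminationSpec | None = None,
        clock: Callable[[], float] | None = None,
        lags: Sequence[int] | None = None) -> RunResult:
    """Run the island ES end to end in the requested execution mode.

    ``mode`` is one of ``serial``, ``sync`` (bit-identical to serial for
    the same seeds), ``async`` (virtual-time buffered scheduler; ``lags``
    staggers islands) or ``async-process`` (true process concurrency, see
    :func:`run_async_processes`).
    """
    if n_islands < 1:
        raise ValueError("need at least one island")
    if termination is None:
        termination = TerminationSpec(max_generations=config.max_generations)
    if clock is None:
        start = time.perf_counter()
        clock = lambda: time.perf_counter() - start  # noqa: E731
    if mode in ("serial", "sync"):
        if lags is not None:
            raise ValueError("lags apply to async mode only")
        return _run_lockstep(objective, config, n_islands, mode, termination,
                             clock)
    if mode == "async":
        return _run_async_virtual(objective, config, n_islands, termination,
                                  clock, lags)
    if mode == "async-process":
        from ._procasync import run_async_processes

        return run_async_processes(objective, config, n_islands, termination)
    raise ValueError(f"unknown mode {mode!r}")
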
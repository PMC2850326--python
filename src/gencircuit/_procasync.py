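"""True process-based asynchronous island execution.

One OS process per island, migrants and statistics exchanged through
queues, no barriers anywhere: each island deposits its best into the queue
of a randomly chosen island and absorbs whatever is waiting in its own,
deferring deposits when a queue is full.  This transport is exercised by
integration tests; the deterministic virtual-time scheduler in
:mod:`gencircuit.islands` covers the buffered semantics in unit tests.
"""

from __future__ import annotations

import multiprocessing as mp
import queue as queue_mod
import time

import numpy as np

from .es import ESConfig, generation_step, init_population
from .islands import (MASTER_BUFFER_CAP, MIGRANT_BUFFER_CAP, RunLog,
                      RunResult, TerminationSpec, check_termination,
                      _best_of, _rank_key)
from .es import Individual

__all__ = ["run_async_processes"]


def _worker(index: int, objective, config: ESConfig, n_islands: int,
            termination: TerminationSpec, migrant_queues, master_queue,
            stop_event):
    rng = np.random.default_rng(config.seed + index)
    pop = init_population(config, objective, rng)
    n_evals = config.lambda_pop
    pending = []
    others = [j for j in range(n_islands) if j != index]
    gen = 0
    while gen < termination.max_generations and not stop_event.is_set():
        gen += 1
        pop, stats = generation_step(pop, config, objective, rng)
        n_evals += stats.evaluations
        if n_islands > 1 and gen % config.migration_interval == 0:
            retry = []
            for receiver, payload in pending:
                try:
                    migrant_queues[receiver].put_nowait(payload)
                except queue_mod.Full:
                    retry.append((receiver, payload))
            pending = retry
            receiver = others[0] if len(others) == 1 else \
                others[int(rng.integers(len(others)))]
            best = _best_of(pop)
            payload = (best.theta.copy(), best.sigma.copy(), best.fitness,
                       best.penalty_value)
            try:
                migrant_queues[receiver].put_nowait(payload)
            except queue_mod.Full:
                pending.append((receiver, payload))
            while True:
                try:
                    th, sg, fit, pen = migrant_queues[index].get_nowait()
                except queue_mod.Empty:
                    break
                pop.append(Individual(theta=th, sigma=sg, fitness=fit,
                                      penalty_value=pen))
        if gen % config.log_interval == 0:
            best = _best_of(pop)
            master_queue.put(("stat", index, gen, best.fitness))
    best = _best_of(pop)
    master_queue.put(("done", index, gen, best.theta.copy(),
                      best.sigma.copy(), best.fitness, best.penalty_value,
                      n_evals))


def run_async_processes(objective, config: ESConfig, n_islands: int,
                        termination: TerminationSpec) -> RunResult:
    """Run the asynchronous island ES with one process per island."""
    ctx = mp.get_context("fork" if "fork" in mp.get_all_start_methods()
                         else "spawn")
    migrant_queues = [ctx.Queue(maxsize=MIGRANT_BUFFER_CAP * n_islands)
                      for _ in range(n_islands)]
    master_queue = ctx.Queue(maxsize=MASTER_BUFFER_CAP * n_islands)
    stop_event = ctx.Event()
    workers = [ctx.Process(target=_worker,
                           args=(i, objective, config, n_islands, termination,
                                 migrant_queues, master_queue, stop_event))
               for i in range(n_islands)]
    start = time.perf_counter()
    for w in workers:
        w.start()
    log = RunLog(interval=config.log_interval)
    reports: dict[int, dict[int, float]] = {}
    finals = {}
    n_evals = 0
    try:
        while len(finals) < n_islands:
            for w in workers:
                if w.exitcode not in (None, 0):
                    raise RuntimeError(
                        f"island process {w.pid} crashed with exit code "
                        f"{w.exitcode}")
            try:
                msg = master_queue.get(timeout=0.5)
            except queue_mod.Empty:
                continue
            if msg[0] == "stat":
                _, idx, gen, fit = msg
                reports.setdefault(gen, {})[idx] = fit
                rep = reports[gen]
                if len(rep) == n_islands:
                    log.append(gen, time.perf_counter() - start,
                               min(rep.values()))
                    del reports[gen]
                    if check_termination(log, termination):
                        stop_event.set()
            else:
                _, idx, gen, th, sg, fit, pen, evals = msg
                finals[idx] = Individual(theta=th, sigma=sg, fitness=fit,
                                         penalty_value=pen)
                n_evals += evals
    finally:
        stop_event.set()
        for q in migrant_queues:
            q.cancel_join_thread()
        for w in workers:
            w.join(timeout=30)
            if w.is_alive():
                w.terminate()
    best = min(finals.values(), key=_rank_key)
    return RunResult(best=best, log=log, n_evaluations=n_evals, mode="async-process",
                     n_islands=n_islands)
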
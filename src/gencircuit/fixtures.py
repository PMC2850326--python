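"""Synthetic ground-truth circuits and noisy expression datasets.

Real gap-gene expression data comes from quantified confocal images of
immunostained embryos; these fixtures emulate only what the inference
machinery needs — concentrations on a 1-D row of nuclei over a mitotic
schedule, generated from a known circuit, with additive truncated-Gaussian
noise — so every optimiser and metric is testable offline, including
parameter-recovery experiments against the known truth.

The canonical toy is a 2-gene mutual-repression circuit on 4 nuclei with
three time classes and one division: small enough for minute-scale ES runs,
rich enough to exercise production, decay, diffusion and the division rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model as M
from .es import ESConfig
from .islands import TerminationSpec, run
from .objective import (CircuitObjective, ExpressionDataSet, SearchSpace,
                        SimConfig)

__all__ = [
    "GroundTruth",
    "two_cycle_schedule",
    "mutual_repression_circuit",
    "make_toy_circuit",
    "simulate_dataset",
    "toy_problem",
    "random_search",
    "recovery_experiment",
    "SphereObjective",
]


@dataclass(frozen=True)
class GroundTruth:
    """A known circuit plus everything needed to synthesise data from it."""

    params: M.GeneCircuitParams
    schedule: M.MitoticSchedule
    bcd_by_epoch: dict[int, np.ndarray]
    space: SearchSpace
    noise_sd: float
    seed: int

    @property
    def n_nuclei(self) -> int:
        return len(self.bcd_by_epoch[0])


def two_cycle_schedule() -> M.MitoticSchedule:
    """Small two-cycle schedule: interphase, mitosis, division, interphase."""
    return M.MitoticSchedule(phases=(
        M.Phase(M.INTERPHASE, 0.0, 16.0),
        M.Phase(M.MITOSIS, 16.0, 20.0),
        M.Phase(M.DIVISION, 20.0, 20.0),
        M.Phase(M.INTERPHASE, 20.0, 36.0),
    ))


def _exponential_bcd(n_nuclei: int, peak: float = 80.0) -> np.ndarray:
    """Anterior-high exponential Bcd gradient along the nuclear row."""
    x = np.linspace(0.0, 1.0, n_nuclei)
    return peak * np.exp(-2.0 * x)


def _bcd_epochs(bcd0: np.ndarray, n_divisions: int) -> dict[int, np.ndarray]:
    out = {0: bcd0}
    for n in range(1, n_divisions + 1):
        out[n] = np.repeat(out[n - 1], 2)
    return out


def _toy_space() -> SearchSpace:
    # Both toy genes have their threshold frozen, like the trunk gap genes.
    return SearchSpace(h_fixed=-2.5, h_fixed_mask=None)


def mutual_repression_circuit() -> M.GeneCircuitParams:
    """Canonical 2-gene toy: each gene represses the other, Bcd activates both."""
    return M.GeneCircuitParams(
        W=np.array([[0.0, -0.02], [-0.02, 0.0]]),
        m=np.array([0.05, 0.03]),
        h=np.array([-2.5, -2.5]),
        R=np.array([15.0, 25.0]),
        D_base=np.array([0.10, 0.15]),
        decay=np.log(2.0) / np.array([10.0, 12.0]),
        genes=("gA", "gB"))


def make_toy_circuit(n_genes: int = 2, n_nuclei: int = 4, seed: int = 0,
                     noise_sd: float = 0.0,
                     space: SearchSpace | None = None) -> GroundTruth:
    """Random ground-truth circuit with hard bounds satisfied and zero penalty.

    Kinetic rates are uniform inside the open hard-bound intervals;
    regulatory weights are drawn small enough that the total regulatory
    input stays far inside the penalty bound at physiological
    concentrations (steady states are of order R/decay).
    """
    if n_genes < 1 or n_nuclei < 1:
        raise ValueError("need at least one gene and one nucleus")
    rng = np.random.default_rng(seed)
    space = space or _toy_space()
    hl = rng.uniform(*space.halflife_range, n_genes)
    conc_scale = space.R_range[1] / (np.log(2.0) / space.halflife_range[1])
    w_scale = 3.0 / (conc_scale * (n_genes + 1))
    h = (np.full(n_genes, space.h_fixed) if space.h_fixed is not None
         else rng.uniform(-5.0, 0.0, n_genes))
    params = M.GeneCircuitParams(
        W=rng.uniform(-w_scale, w_scale, (n_genes, n_genes)),
        m=rng.uniform(0.0, w_scale, n_genes),
        h=h,
        R=rng.uniform(*space.R_range, n_genes),
        D_base=rng.uniform(0.05, space.D_range[1] - 0.05, n_genes),
        decay=np.log(2.0) / hl,
        genes=tuple(f"g{chr(ord('A') + i)}" for i in range(n_genes)))
    schedule = two_cycle_schedule()
    bcd0 = _exponential_bcd(n_nuclei)
    return GroundTruth(params=params, schedule=schedule,
                       bcd_by_epoch=_bcd_epochs(bcd0, schedule.n_divisions),
                       space=space, noise_sd=noise_sd, seed=seed)


def simulate_dataset(truth: GroundTruth,
                     time_classes: tuple[float, ...] = (10.0, 28.0, 36.0),
                     noise_sd: float | None = None,
                     seed: int | None = None) -> ExpressionDataSet:
    """Synthesise a FlyEx-style dataset from a ground-truth circuit.

    The schedule start supplies the (noise-free) initial state; the given
    time classes are observed with independent Gaussian noise truncated at
    zero.  Per-gene maxima are taken from the noisy table, as they would be
    from real data.
    """
    noise_sd = truth.noise_sd if noise_sd is None else noise_sd
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    params = truth.params
    n0 = truth.n_nuclei
    init = M.EmbryoState(conc=np.zeros((n0, params.n_genes)),
                         bcd=truth.bcd_by_epoch[0], n_div=0,
                         time=truth.schedule.start)
    times = sorted(set([truth.schedule.start, *time_classes]))
    traj = M.simulate(params, init, truth.schedule, times,
                      tol=1e-6, atol=1e-9, bcd_by_epoch=truth.bcd_by_epoch)
    genes = params.gene_names()
    rows = []
    for state in traj.states:
        conc = state.conc.copy()
        if noise_sd > 0 and state.time != truth.schedule.start:
            conc = np.maximum(0.0, conc + rng.normal(0.0, noise_sd, conc.shape))
        ap = np.linspace(35.0, 92.0, state.n_nuclei)
        for i in range(state.n_nuclei):
            row = {"time_class": state.time, "nucleus_index": i,
                   "ap_position_percent": ap[i], "bcd": state.bcd[i]}
            row.update({g: conc[i, j] for j, g in enumerate(genes)})
            rows.append(row)
    return ExpressionDataSet(table=pd.DataFrame(rows), genes=genes,
                             bcd_by_epoch=truth.bcd_by_epoch)


def toy_problem(seed: int = 0, noise_sd: float = 0.0,
                tol: float = 1e-3) -> tuple[GroundTruth, ExpressionDataSet, CircuitObjective]:
    """The canonical 2-gene / 4-nucleus fitting problem, ready to optimise."""
    space = _toy_space()
    truth = GroundTruth(params=mutual_repression_circuit(),
                        schedule=two_cycle_schedule(),
                        bcd_by_epoch=_bcd_epochs(_exponential_bcd(4), 1),
                        space=space, noise_sd=noise_sd, seed=seed)
    data = simulate_dataset(truth, noise_sd=noise_sd, seed=seed)
    objective = CircuitObjective(data, SimConfig(schedule=truth.schedule,
                                                 tol=tol), space)
    return truth, data, objective


def toy_recovery_config(seed: int = 0) -> ESConfig:
    """ES operating point for minute-scale recovery runs on the canonical toy.

    Two islands of 20 individuals with migration every 100 generations keep
    the search from losing its best solutions under comma selection while
    staying small enough for a run to finish in under a minute.
    """
    return ESConfig(lambda_pop=20, mu=4, seed=seed, max_generations=2000,
                    log_interval=20, migration_interval=100)


def random_search(objective, n_evals: int, rng: np.random.Generator) -> float:
    """Equal-budget uniform random search baseline; returns the best E found."""
    best = np.inf
    for _ in range(n_evals):
        E, pen = objective(objective.sample_theta(rng))
        if pen <= 0 and E < best:
            best = E
    return float(best)


def recovery_experiment(truth: GroundTruth, data: ExpressionDataSet,
                        objective: CircuitObjective, config: ESConfig,
                        n_runs: int = 10, base_seed: int = 0,
                        n_islands: int = 2,
                        noise_floor_factor: float = 1e-3,
                        w_floor: float = 0.005) -> pd.DataFrame:
    """Repeatedly fit the noisy dataset and compare against the known truth.

    One row per run: final objective value, whether it fell below
    ``noise_floor_factor`` times the data sum of squares, and the fraction
    of ground-truth W entries with magnitude above ``w_floor`` whose sign
    the recovered circuit reproduces.
    """
    layout = objective.layout
    w_true = truth.params.W
    strong = np.abs(w_true) > w_floor
    threshold = noise_floor_factor * data.sum_of_squares()
    rows = []
    for j in range(n_runs):
        cfg = ESConfig(**{**config.__dict__, "seed": base_seed + j})
        result = run(objective, cfg, n_islands=n_islands, mode="serial",
                     termination=TerminationSpec(
                         max_generations=cfg.max_generations))
        fitted = layout.unpack(result.best.theta)
        agree = (np.sign(fitted.W[strong]) == np.sign(w_true[strong])).mean() \
            if strong.any() else np.nan
        sofar = result.log.best_so_far()
        best_E = min(result.best.fitness,
                     float(sofar[-1]) if sofar.size else np.inf)
        rows.append({"run": j, "seed": cfg.seed, "final_E": best_E,
                     "reached_floor": best_E <= threshold,
                     "w_sign_agreement": float(agree),
                     "n_evaluations": result.n_evaluations})
    return pd.DataFrame(rows)


class SphereObjective:
    """Unconstrained quadratic toy objective for optimiser plumbing tests.

    E(theta) = sum((theta - centre)^2), penalty always zero.  Picklable, so
    it also serves the process-based integration tests.
    """

    def __init__(self, n: int = 3, centre: float = 1.0, box: float = 5.0):
        self.n = n
        self.centre = np.full(n, float(centre))
        self.box = float(box)
        self.n_evaluations = 0

    def __call__(self, theta: np.ndarray) -> tuple[float, float]:
        self.n_evaluations += 1
        d = np.asarray(theta) - self.centre
        return float(d @ d), 0.0

    def sample_theta(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-self.box, self.box, self.n)

    def initial_sigma(self) -> np.ndarray:
        return np.full(self.n, 0.2 * self.box)
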
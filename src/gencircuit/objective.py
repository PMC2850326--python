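"""Scoring of circuit parameters against expression data, and search-space rules.

The objective is the unweighted sum of squared differences between model
output and observed per-nucleus concentrations, over every (time class,
gene, nucleus) cell with data.  Two kinds of constraints bound the search:

* **hard limits** on the kinetic rates — ``10 < R < 30``, ``0 < D < 0.3``
  and a half-life between 5 and 20 minutes (all strict); any value outside
  is unacceptable and rejected,
* a **penalty function** on the regulatory parameters (W, m, h) controlled
  by ``Lambda``: it is exactly zero while the largest achievable total
  regulatory input (taking each regulator at its maximum observed
  concentration) stays within ``1/Lambda`` in magnitude, and rises steeply
  outside.  Individual weights may grow large as long as the total input
  stays bounded.

Parameter vectors are flat with a fixed layout (W rows, m, free h, R,
D_base, decay).  Thresholds ``h`` can be frozen per gene; freezing reduces
the vector length by one per frozen gene (the canonical 6-gene gap circuit
frees cad and tll, giving 66 -> 62).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _fastsim
from . import model as M

__all__ = [
    "SearchSpace",
    "ParameterLayout",
    "ParameterVector",
    "ExpressionDataSet",
    "SimConfig",
    "pack_parameters",
    "unpack_parameters",
    "penalty",
    "check_hard_bounds",
    "objective_E",
    "CircuitObjective",
    "gap_gene_space",
    "GAP_GENES",
]

#: Canonical 6-gene gap circuit: maternal/terminal genes keep a free
#: threshold, the four trunk gap genes have it frozen at -2.5.
GAP_GENES = ("cad", "hb", "Kr", "kni", "gt", "tll")
_GAP_H_FIXED = ("hb", "Kr", "kni", "gt")


@dataclass(frozen=True)
class SearchSpace:
    """Hard bounds, penalty control and threshold-freezing policy.

    ``h_fixed`` is the frozen threshold value (None = all thresholds free);
    ``h_fixed_mask`` selects which genes are frozen (None = all of them).
    """

    Lambda: float = 1e-4
    R_range: tuple[float, float] = (10.0, 30.0)
    D_range: tuple[float, float] = (0.0, 0.3)
    halflife_range: tuple[float, float] = (5.0, 20.0)
    h_fixed: float | None = -2.5
    h_fixed_mask: tuple[bool, ...] | None = None

    def __post_init__(self):
        if self.Lambda <= 0:
            raise ValueError("Lambda must be positive")
        for name in ("R_range", "D_range", "halflife_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a non-empty interval")

    @property
    def decay_range(self) -> tuple[float, float]:
        """Decay-rate interval implied by the half-life bounds."""
        lo, hi = self.halflife_range
        return (np.log(2.0) / hi, np.log(2.0) / lo)

    def h_free_mask(self, n_genes: int) -> np.ndarray:
        """Boolean mask of genes whose threshold is a free parameter."""
        if self.h_fixed is None:
            return np.ones(n_genes, dtype=bool)
        if self.h_fixed_mask is None:
            return np.zeros(n_genes, dtype=bool)
        mask = np.asarray(self.h_fixed_mask, dtype=bool)
        if mask.shape != (n_genes,):
            raise ValueError(
                f"h_fixed_mask must have length {n_genes}, got {mask.shape}"
            )
        return ~mask


def gap_gene_space(**overrides) -> SearchSpace:
    """The canonical 6-gene gap-gene search space (62 free parameters)."""
    mask = tuple(g in _GAP_H_FIXED for g in GAP_GENES)
    kwargs = dict(h_fixed=-2.5, h_fixed_mask=mask)
    kwargs.update(overrides)
    return SearchSpace(**kwargs)


@dataclass(frozen=True)
class ParameterLayout:
    """Fixed flat ordering of the free parameters of one circuit.

    Order: W row-major (N_g^2), m (N_g), free h entries, R, D_base, decay.
    Length is ``N_g (N_g + 5) - n_frozen_thresholds``.
    """

    n_genes: int
    h_free: tuple[bool, ...]
    h_fixed_value: float | None
    genes: tuple[str, ...] | None = None

    @classmethod
    def from_space(cls, n_genes: int, space: SearchSpace,
                   genes: Sequence[str] | None = None) -> "ParameterLayout":
        free = space.h_free_mask(n_genes)
        return cls(n_genes=n_genes, h_free=tuple(bool(x) for x in free),
                   h_fixed_value=space.h_fixed,
                   genes=tuple(genes) if genes else None)

    @property
    def n_h_free(self) -> int:
        return sum(self.h_free)

    @property
    def n(self) -> int:
        ng = self.n_genes
        return ng * (ng + 5) - (ng - self.n_h_free)

    def slices(self) -> dict[str, slice]:
        ng = self.n_genes
        out = {}
        i = 0
        for name, width in (("W", ng * ng), ("m", ng), ("h", self.n_h_free),
                            ("R", ng), ("D_base", ng), ("decay", ng)):
            out[name] = slice(i, i + width)
            i += width
        return out

    def pack(self, params: M.GeneCircuitParams) -> np.ndarray:
        if params.n_genes != self.n_genes:
            raise ValueError("parameter/layout gene-count mismatch")
        mask = np.array(self.h_free)
        return np.concatenate([
            params.W.ravel(), params.m, params.h[mask],
            params.R, params.D_base, params.decay,
        ])

    def unpack(self, values: np.ndarray) -> M.GeneCircuitParams:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n,):
            raise ValueError(
                f"expected parameter vector of length {self.n}, got {values.shape}"
            )
        s = self.slices()
        ng = self.n_genes
        mask = np.array(self.h_free)
        h = np.full(ng, self.h_fixed_value if self.h_fixed_value is not None
                    else 0.0)
        h[mask] = values[s["h"]]
        return M.GeneCircuitParams(
            W=values[s["W"]].reshape(ng, ng), m=values[s["m"]], h=h,
            R=values[s["R"]], D_base=values[s["D_base"]],
            decay=values[s["decay"]], genes=self.genes)

    def param_names(self) -> list[str]:
        g = list(self.genes) if self.genes else [f"g{i}" for i in range(self.n_genes)]
        names = [f"W.{a}.{b}" for a in g for b in g]
        names += [f"m.{a}" for a in g]
        names += [f"h.{a}" for a, free in zip(g, self.h_free) if free]
        names += [f"R.{a}" for a in g]
        names += [f"D.{a}" for a in g]
        names += [f"decay.{a}" for a in g]
        return names


@dataclass(frozen=True)
class ParameterVector:
    """A flat parameter vector paired with its layout."""

    values: np.ndarray
    layout: ParameterLayout

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.layout.n,):
            raise ValueError(
                f"values must have length {self.layout.n}, got {values.shape}"
            )
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.layout.n


def pack_parameters(params: M.GeneCircuitParams, space: SearchSpace) -> ParameterVector:
    """Flatten a circuit into the estimation vector (frozen h excluded)."""
    layout = ParameterLayout.from_space(params.n_genes, space, params.genes)
    return ParameterVector(values=layout.pack(params), layout=layout)


def unpack_parameters(theta: ParameterVector) -> M.GeneCircuitParams:
    return theta.layout.unpack(theta.values)


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------


class ExpressionDataSet:
    """Observed per-nucleus, per-time-class protein concentrations.

    ``table`` is wide: one row per (time_class, nucleus_index) with columns
    ``time_class, nucleus_index, ap_position_percent, bcd`` plus one column
    per gene (NaN marks a cell without data).  The earliest time class
    supplies the initial state for simulation; later classes are the fitted
    observations.  ``bcd_by_epoch`` maps each division count to the Bcd
    profile used during that epoch.
    """

    def __init__(self, table: pd.DataFrame, genes: Sequence[str],
                 bcd_by_epoch: Mapping[int, np.ndarray],
                 initial_n_div: int = 0):
        genes = tuple(genes)
        required = ["time_class", "nucleus_index", "ap_position_percent", "bcd"]
        missing = [c for c in required + list(genes) if c not in table.columns]
        if missing:
            raise ValueError(f"table is missing columns: {missing}")
        table = table.sort_values(["time_class", "nucleus_index"]).reset_index(drop=True)
        if table.duplicated(["time_class", "nucleus_index"]).any():
            dup = table[table.duplicated(["time_class", "nucleus_index"])].iloc[0]
            raise ValueError(
                "duplicate (time_class, nucleus_index) key: "
                f"({dup['time_class']}, {dup['nucleus_index']})"
            )
        conc = table[list(genes)].to_numpy()
        if np.any(conc[~np.isnan(conc)] < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(table["bcd"].to_numpy() < 0):
            raise ValueError("bcd must be non-negative")
        self.table = table
        self.genes = genes
        self.bcd_by_epoch = {int(k): np.asarray(v, dtype=float)
                             for k, v in bcd_by_epoch.items()}
        self.initial_n_div = int(initial_n_div)

    @property
    def time_classes(self) -> np.ndarray:
        return np.unique(self.table["time_class"].to_numpy())

    @property
    def observation_classes(self) -> np.ndarray:
        """Time classes entering the objective (all but the earliest)."""
        return self.time_classes[1:]

    @property
    def gene_maxima(self) -> pd.Series:
        return self.table[list(self.genes)].max()

    @property
    def bcd_max(self) -> float:
        return float(self.table["bcd"].max())

    @property
    def n_observations(self) -> int:
        obs = self.table[self.table["time_class"].isin(self.observation_classes)]
        return int(obs[list(self.genes)].notna().to_numpy().sum())

    def sum_of_squares(self) -> float:
        """Sum of squared observed concentrations (scale of the objective)."""
        obs = self.table[self.table["time_class"].isin(self.observation_classes)]
        return float(np.nansum(obs[list(self.genes)].to_numpy() ** 2))

    def initial_state(self) -> M.EmbryoState:
        t0 = self.time_classes[0]
        rows = self.table[self.table["time_class"] == t0]
        conc = rows[list(self.genes)].to_numpy()
        if np.isnan(conc).any():
            raise ValueError("initial time class must have complete data")
        return M.EmbryoState(conc=conc, bcd=rows["bcd"].to_numpy(),
                             n_div=self.initial_n_div, time=float(t0))

    def class_frame(self, time_class: float) -> pd.DataFrame:
        return self.table[self.table["time_class"] == time_class]

    def observation_tensor(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, data) with data shaped (n_classes, max_nn, n_genes), NaN-padded."""
        times = self.observation_classes
        max_nn = int(self.table.groupby("time_class")["nucleus_index"].count().max())
        data = np.full((len(times), max_nn, len(self.genes)), np.nan)
        for k, t in enumerate(times):
            rows = self.class_frame(t)
            idx = rows["nucleus_index"].to_numpy().astype(int)
            data[k, idx] = rows[list(self.genes)].to_numpy()
        return np.asarray(times, dtype=float), data


# ---------------------------------------------------------------------------
# Objective, penalty, hard bounds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """How the circuit is solved when scoring parameters."""

    schedule: M.MitoticSchedule
    tol: float = 1e-3
    atol: float = 1e-6
    method: str = "bulirsch-stoer"
    use_fast: bool = True


def penalty(params: M.GeneCircuitParams, gene_maxima: np.ndarray,
            bcd_max: float, Lambda: float = 1e-4) -> float:
    """Search-space penalty on the regulatory parameters (W, m, h).

    For each target gene the extreme total regulatory inputs achievable
    with every regulator at its maximum observed concentration are

        u_hi^a = sum_b max(W_ab, 0) v_max^b + max(m_a, 0) bcd_max + h_a
        u_lo^a = sum_b min(W_ab, 0) v_max^b + min(m_a, 0) bcd_max + h_a

    The penalty is exactly zero while ``u_lo^a >= -1/Lambda`` and
    ``u_hi^a <= 1/Lambda`` for every gene, and grows quadratically in the
    exceedance outside; R, D and decay never enter.
    """
    vmax = np.asarray(gene_maxima, dtype=float)
    if np.any(vmax <= 0):
        raise ValueError("gene maxima must be positive")
    bound = 1.0 / Lambda
    u_hi = np.clip(params.W, 0, None) @ vmax + np.clip(params.m, 0, None) * bcd_max + params.h
    u_lo = np.clip(params.W, None, 0) @ vmax + np.clip(params.m, None, 0) * bcd_max + params.h
    over = np.maximum(0.0, u_hi - bound)
    under = np.maximum(0.0, -bound - u_lo)
    return float(Lambda * np.sum(over ** 2 + under ** 2))


def check_hard_bounds(params: M.GeneCircuitParams,
                      space: SearchSpace) -> tuple[bool, list[str]]:
    """Strict interval check on R, D and half-life; names each violation."""
    genes = params.gene_names()
    violations = []
    hl = params.half_life()
    for a in range(params.n_genes):
        if not space.R_range[0] < params.R[a] < space.R_range[1]:
            violations.append(f"R[{genes[a]}]={params.R[a]:g} outside "
                              f"({space.R_range[0]:g}, {space.R_range[1]:g})")
        if not space.D_range[0] < params.D_base[a] < space.D_range[1]:
            violations.append(f"D[{genes[a]}]={params.D_base[a]:g} outside "
                              f"({space.D_range[0]:g}, {space.D_range[1]:g})")
        if not space.halflife_range[0] < hl[a] < space.halflife_range[1]:
            violations.append(
                f"half-life[{genes[a]}]={hl[a]:g} outside "
                f"({space.halflife_range[0]:g}, {space.halflife_range[1]:g})")
    return (not violations, violations)


def _model_tensor(params: M.GeneCircuitParams, data: ExpressionDataSet,
                  sim: SimConfig, times: np.ndarray,
                  max_nn: int) -> np.ndarray | None:
    """Model concentrations at the observation classes; None on solver failure."""
    init = data.initial_state()
    if sim.use_fast and sim.method == "bulirsch-stoer":
        kinds, t0s, t1s, prods, rec_t, rec_nd = _fastsim.build_plan(
            _schedule_from(init.time, sim.schedule), times)
        n_epochs = max(data.bcd_by_epoch) + 1
        bcd_stack = np.zeros((n_epochs, max_nn))
        for nd, prof in data.bcd_by_epoch.items():
            bcd_stack[nd, :len(prof)] = prof
        out = np.full((len(rec_t), max_nn, params.n_genes), np.nan)
        ok = _fastsim.run_plan(params.W, params.m, params.h, params.R,
                               params.D_base, params.decay, init.conc,
                               bcd_stack, kinds, t0s, t1s, prods,
                               sim.tol, sim.atol, out)
        return out if ok else None
    try:
        traj = M.simulate(params, init, _schedule_from(init.time, sim.schedule),
                          times, tol=sim.tol, atol=sim.atol, method=sim.method,
                          bcd_by_epoch=data.bcd_by_epoch)
    except M.SolverError:
        return None
    out = np.full((len(times), max_nn, params.n_genes), np.nan)
    for k, s in enumerate(traj.states):
        out[k, :s.n_nuclei] = s.conc
    return out


def _schedule_from(t0: float, schedule: M.MitoticSchedule) -> M.MitoticSchedule:
    """Truncate a schedule to start at the dataset's initial time class."""
    if abs(t0 - schedule.start) <= 1e-9:
        return schedule
    phases = []
    for p in schedule.phases:
        if p.kind != M.DIVISION and p.end <= t0 + 1e-9:
            continue
        if p.kind == M.DIVISION and p.start < t0 - 1e-9:
            continue
        if p.kind != M.DIVISION and p.start < t0:
            phases.append(M.Phase(p.kind, t0, p.end))
        else:
            phases.append(p)
    return M.MitoticSchedule(phases=tuple(phases))


def objective_E(theta: ParameterVector | M.GeneCircuitParams,
                data: ExpressionDataSet, sim: SimConfig) -> float:
    """Sum of squared model-data differences over all observed cells.

    Solver failure yields ``inf`` so that global searches can discard
    pathological parameter sets without aborting.
    """
    params = unpack_parameters(theta) if isinstance(theta, ParameterVector) else theta
    times, obs = data.observation_tensor()
    if obs.size == 0:
        raise ValueError("dataset has no observations")
    model = _model_tensor(params, data, sim, times, obs.shape[1])
    if model is None:
        return float("inf")
    resid = model - obs
    resid[np.isnan(obs)] = 0.0
    if np.any(np.isnan(resid) & ~np.isnan(obs)):
        return float("inf")
    return float(np.nansum(resid ** 2))


class CircuitObjective:
    """Callable scoring bundle used by the optimisers.

    ``objective(values) -> (E, penalty)``; parameter sets outside the hard
    bounds score ``(inf, inf)`` without being simulated.  Keeps a running
    count of ODE solutions performed.
    """

    def __init__(self, data: ExpressionDataSet, sim: SimConfig,
                 space: SearchSpace, layout: ParameterLayout | None = None):
        self.data = data
        self.sim = sim
        self.space = space
        self.layout = layout or ParameterLayout.from_space(
            len(data.genes), space, data.genes)
        self.n_evaluations = 0
        self._gene_maxima = data.gene_maxima.to_numpy()
        self._bcd_max = data.bcd_max
        self._times, self._obs = data.observation_tensor()
        self._nan_mask = np.isnan(self._obs)
        self._fast = sim.use_fast and sim.method == "bulirsch-stoer"
        if self._fast:
            init = data.initial_state()
            self._init_conc = init.conc
            plan = _fastsim.build_plan(_schedule_from(init.time, sim.schedule),
                                       self._times)
            self._plan = plan[:4]
            max_nn = self._obs.shape[1]
            n_epochs = max(data.bcd_by_epoch) + 1
            self._bcd_stack = np.zeros((n_epochs, max_nn))
            for nd, prof in data.bcd_by_epoch.items():
                self._bcd_stack[nd, :len(prof)] = prof

    def __call__(self, values: np.ndarray) -> tuple[float, float]:
        try:
            params = self.layout.unpack(values)
        except M.CircuitError:
            # Negative rates etc.: outside the model's domain, hence outside
            # the hard bounds a fortiori.
            return float("inf"), float("inf")
        ok, _ = check_hard_bounds(params, self.space)
        if not ok:
            return float("inf"), float("inf")
        pen = penalty(params, self._gene_maxima, self._bcd_max,
                      self.space.Lambda)
        self.n_evaluations += 1
        if self._fast:
            model = np.full_like(self._obs, np.nan)
            ok = _fastsim.run_plan(params.W, params.m, params.h, params.R,
                                   params.D_base, params.decay,
                                   self._init_conc, self._bcd_stack,
                                   *self._plan, self.sim.tol, self.sim.atol,
                                   model)
            if not ok:
                return float("inf"), pen
        else:
            model = _model_tensor(params, self.data, self.sim, self._times,
                                  self._obs.shape[1])
            if model is None:
                return float("inf"), pen
        resid = model - self._obs
        resid[self._nan_mask] = 0.0
        if np.any(np.isnan(resid)):
            return float("inf"), pen
        return float(np.sum(resid ** 2)), pen

    # -- sampling helpers used by the optimisers -------------------------

    def regulatory_limit(self, u_scale: float = 3.0, safety: float = 0.5) -> float:
        """Half-width of the initial sampling box for W and m entries.

        Weights are initialised so that the total regulatory input spans the
        responsive range of the sigmoid (|u| of order ``u_scale``) rather
        than its saturated arms, with every regulator at its maximum
        observed concentration; capped by the zero-penalty bound (shrunk by
        ``safety``), so initial populations are always penalty-feasible.
        """
        bound = 1.0 / self.space.Lambda
        h_mag = abs(self.space.h_fixed) if self.space.h_fixed is not None else 0.0
        denom = float(np.sum(self._gene_maxima) + self._bcd_max)
        return min(u_scale, safety * (bound - h_mag)) / denom

    def sample_theta(self, rng: np.random.Generator) -> np.ndarray:
        """Uniform draw: kinetics inside hard bounds, weights penalty-feasible."""
        s = self.layout.slices()
        L = self.regulatory_limit()
        out = np.empty(self.layout.n)
        out[s["W"]] = rng.uniform(-L, L, s["W"].stop - s["W"].start)
        out[s["m"]] = rng.uniform(-L, L, s["m"].stop - s["m"].start)
        out[s["h"]] = rng.uniform(-5.0, 0.0, s["h"].stop - s["h"].start)
        out[s["R"]] = rng.uniform(*self.space.R_range, self.layout.n_genes)
        out[s["D_base"]] = rng.uniform(*self.space.D_range, self.layout.n_genes)
        hl = rng.uniform(*self.space.halflife_range, self.layout.n_genes)
        out[s["decay"]] = np.log(2.0) / hl
        return out

    def initial_sigma(self) -> np.ndarray:
        """Initial mutation step sizes: 10% of each parameter's range."""
        s = self.layout.slices()
        L = self.regulatory_limit()
        dlo, dhi = self.space.decay_range
        out = np.empty(self.layout.n)
        out[s["W"]] = 0.1 * 2 * L
        out[s["m"]] = 0.1 * 2 * L
        out[s["h"]] = 0.1 * 5.0
        out[s["R"]] = 0.1 * (self.space.R_range[1] - self.space.R_range[0])
        out[s["D_base"]] = 0.1 * (self.space.D_range[1] - self.space.D_range[0])
        out[s["decay"]] = 0.1 * (dhi - dlo)
        return out
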
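"""Connectionist gene-circuit model of the Drosophila gap-gene system.

The state of the system is the concentration of each of ``N_g`` gene
products in each of ``N_nuc`` nuclei arranged in a row along the
antero-posterior axis.  Each concentration obeys an ODE with three terms:

* **production** — a fraction of the maximal rate ``R^a``, given by a
  sigmoid of the total regulatory input
  ``u_i^a = sum_b W[a,b] * g_i^b + m[a] * bcd_i + h[a]``,
* **decay** — first-order with rate ``lambda^a`` (half-life ``ln2/lambda``),
* **diffusion** — Fickian exchange with the two neighbouring nuclei, with
  zero-flux boundaries at the ends of the row.

Nuclear divisions are discrete events: every nucleus splits in two, the
daughters inherit the mother's concentrations, and because internuclear
distance halves the effective diffusion rate quadruples,
``D(n) = 4 * D(n-1)`` where ``n`` counts divisions.  During mitosis the
production term is switched off; during interphase the full equation holds.

The reference integrator is a Bulirsch-Stoer scheme (Gragg modified
midpoint with polynomial extrapolation and adaptive step size); any
``scipy.integrate.solve_ivp`` method can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "GeneCircuitParams",
    "MitoticSchedule",
    "Phase",
    "EmbryoState",
    "Trajectory",
    "CircuitError",
    "SolverError",
    "sigmoid",
    "regulatory_input",
    "circuit_rhs",
    "apply_division",
    "integrate_interval",
    "simulate",
    "bulirsch_stoer",
]

INTERPHASE = "interphase"
MITOSIS = "mitosis"
DIVISION = "division"


class CircuitError(ValueError):
    """Structured error for malformed circuit inputs."""


class SolverError(RuntimeError):
    """ODE solver failure; carries the time at which it occurred."""

    def __init__(self, message: str, time: float):
        super().__init__(f"{message} (at t={time:g} min)")
        self.time = time


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneCircuitParams:
    """All regulatory and kinetic parameters of one circuit.

    Attributes
    ----------
    W : (N_g, N_g) array
        Regulatory weight of gene ``b`` (column) on gene ``a`` (row);
        positive = activation, negative = repression, ~0 = no interaction.
    m : (N_g,) array
        Regulatory weight of the external Bcd input on each gene.
    h : (N_g,) array
        Threshold of the sigmoid, the influence of ubiquitous maternal
        factors.
    R : (N_g,) array
        Maximal production rate, strictly positive.
    D_base : (N_g,) array
        Diffusion rate at division count ``n = 0``, non-negative.
    decay : (N_g,) array
        First-order decay rate per minute, strictly positive.
    genes : tuple of str, optional
        Gene names, for file output.
    """

    W: np.ndarray
    m: np.ndarray
    h: np.ndarray
    R: np.ndarray
    D_base: np.ndarray
    decay: np.ndarray
    genes: tuple[str, ...] | None = None

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        n = W.shape[0]
        if W.ndim != 2 or W.shape != (n, n):
            raise CircuitError(f"W must be square, got shape {W.shape}")
        for name in ("m", "h", "R", "D_base", "decay"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise CircuitError(
                    f"{name} must have length N_g={n}, got shape {v.shape}"
                )
            object.__setattr__(self, name, v)
        if np.any(self.R <= 0):
            raise CircuitError("R must be strictly positive")
        if np.any(self.decay <= 0):
            raise CircuitError("decay must be strictly positive")
        if np.any(self.D_base < 0):
            raise CircuitError("D_base must be non-negative")
        if self.genes is not None:
            genes = tuple(self.genes)
            if len(genes) != n:
                raise CircuitError("genes must have length N_g")
            object.__setattr__(self, "genes", genes)

    @property
    def n_genes(self) -> int:
        return self.W.shape[0]

    def gene_names(self) -> tuple[str, ...]:
        if self.genes is not None:
            return self.genes
        return tuple(f"g{i}" for i in range(self.n_genes))

    def half_life(self) -> np.ndarray:
        """Protein half-lives ln2/decay, in minutes."""
        return np.log(2.0) / self.decay


@dataclass(frozen=True)
class Phase:
    kind: str
    start: float
    end: float

    def __post_init__(self):
        if self.kind not in (INTERPHASE, MITOSIS, DIVISION):
            raise CircuitError(f"unknown phase kind {self.kind!r}")
        if self.kind == DIVISION:
            if self.end != self.start:
                raise CircuitError("division events must have zero duration")
        elif self.end <= self.start:
            raise CircuitError("continuous phases must have positive duration")


@dataclass(frozen=True)
class MitoticSchedule:
    """Ordered, contiguous sequence of interphase / mitosis / division phases."""

    phases: tuple[Phase, ...]

    def __post_init__(self):
        phases = tuple(
            p if isinstance(p, Phase) else Phase(*p) for p in self.phases
        )
        if not phases:
            raise CircuitError("schedule must contain at least one phase")
        for prev, cur in zip(phases, phases[1:]):
            if cur.start != prev.end:
                raise CircuitError(
                    f"phases must be contiguous: {prev.end} != {cur.start}"
                )
        object.__setattr__(self, "phases", phases)

    @property
    def start(self) -> float:
        return self.phases[0].start

    @property
    def end(self) -> float:
        return self.phases[-1].end

    @property
    def n_divisions(self) -> int:
        return sum(1 for p in self.phases if p.kind == DIVISION)

    def division_times(self) -> tuple[float, ...]:
        return tuple(p.start for p in self.phases if p.kind == DIVISION)

    def division_count_at(self, t: float) -> int:
        """Number of divisions applied at time ``t`` (post-division at the instant)."""
        return sum(1 for p in self.phases if p.kind == DIVISION and p.start <= t)


@dataclass(frozen=True)
class EmbryoState:
    """Concentrations of all gene products in all nuclei at one instant."""

    conc: np.ndarray  # (N_nuc, N_g)
    bcd: np.ndarray  # (N_nuc,)
    n_div: int = 0
    time: float = 0.0

    def __post_init__(self):
        conc = np.atleast_2d(np.asarray(self.conc, dtype=float))
        bcd = np.asarray(self.bcd, dtype=float)
        if bcd.shape != (conc.shape[0],):
            raise CircuitError(
                f"bcd rows ({bcd.shape}) must match conc rows ({conc.shape[0]})"
            )
        if conc.size == 0:
            raise CircuitError("state must contain at least one nucleus")
        if np.any(bcd < 0):
            raise CircuitError("bcd must be non-negative")
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "bcd", bcd)

    @property
    def n_nuclei(self) -> int:
        return self.conc.shape[0]

    @property
    def n_genes(self) -> int:
        return self.conc.shape[1]


@dataclass(frozen=True)
class Trajectory:
    """States recorded at requested output times (sorted ascending)."""

    states: tuple[EmbryoState, ...]

    def __post_init__(self):
        states = tuple(self.states)
        times = [s.time for s in states]
        if any(b < a for a, b in zip(times, times[1:])):
            raise CircuitError("trajectory output times must be sorted")
        object.__setattr__(self, "states", states)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    def to_frame(self, genes: Sequence[str] | None = None,
                 ap_range: tuple[float, float] = (35.0, 92.0)):
        """Long-format table: time, nucleus_index, ap_position_percent, genes."""
        import pandas as pd

        rows = []
        for s in self.states:
            ap = _ap_positions(s.n_nuclei, ap_range)
            names = genes or [f"g{i}" for i in range(s.n_genes)]
            for i in range(s.n_nuclei):
                row = {"time": s.time, "nucleus_index": i,
                       "ap_position_percent": ap[i]}
                row.update({g: s.conc[i, j] for j, g in enumerate(names)})
                rows.append(row)
        return pd.DataFrame(rows)


def _ap_positions(n_nuclei: int, ap_range: tuple[float, float] = (35.0, 92.0)) -> np.ndarray:
    """Nominal antero-posterior positions (percent egg length) of a nuclear row."""
    return np.linspace(ap_range[0], ap_range[1], n_nuclei)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------


def sigmoid(u):
    """Regulation-expression function g(u) = (u/sqrt(u^2+1) + 1)/2.

    Strictly increasing, bounded in (0, 1), with g(0) = 1/2.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise CircuitError("regulatory input must be finite")
    out = 0.5 * (u / np.sqrt(u * u + 1.0) + 1.0)
    return out if out.ndim else float(out)


def regulatory_input(params: GeneCircuitParams, conc_i: np.ndarray, bcd_i: float) -> np.ndarray:
    """Total regulatory input u^a = sum_b W[a,b] conc^b + m^a bcd + h^a."""
    conc_i = np.asarray(conc_i, dtype=float)
    if conc_i.shape != (params.n_genes,):
        raise CircuitError(
            f"conc_i must have length N_g={params.n_genes}, got {conc_i.shape}"
        )
    return params.W @ conc_i + params.m * float(bcd_i) + params.h


def _rhs_matrix(conc: np.ndarray, bcd: np.ndarray, params: GeneCircuitParams,
                n_div: int, production_on: bool,
                sigmoid_fn: Callable = sigmoid) -> np.ndarray:
    """dG/dt for the full (N_nuc, N_g) concentration matrix."""
    out = -params.decay * conc
    if production_on:
        u = conc @ params.W.T + np.outer(bcd, params.m) + params.h
        out = out + params.R * sigmoid_fn(u)
    if conc.shape[0] > 1:
        d_eff = (4.0 ** n_div) * params.D_base
        lap = np.empty_like(conc)
        lap[1:-1] = conc[:-2] + conc[2:] - 2.0 * conc[1:-1]
        lap[0] = conc[1] - conc[0]
        lap[-1] = conc[-2] - conc[-1]
        out = out + d_eff * lap
    return out


def circuit_rhs(state: EmbryoState, params: GeneCircuitParams, phase: str,
                sigmoid_fn: Callable = sigmoid,
                neg_tol: float = 1e-6) -> np.ndarray:
    """Time derivative of all concentrations under one continuous rule.

    ``phase`` selects the rule: during interphase the full equation holds;
    during mitosis the production term is set to zero.
    """
    if phase not in (INTERPHASE, MITOSIS):
        raise CircuitError(f"phase must be a continuous rule, got {phase!r}")
    if state.n_genes != params.n_genes:
        raise CircuitError(
            f"state has {state.n_genes} genes but params has {params.n_genes}"
        )
    if np.any(state.conc < -neg_tol):
        raise CircuitError("negative concentrations beyond tolerance")
    return _rhs_matrix(state.conc, state.bcd, params, state.n_div,
                       production_on=(phase == INTERPHASE),
                       sigmoid_fn=sigmoid_fn)


def apply_division(state: EmbryoState, bcd_new: np.ndarray | None = None) -> EmbryoState:
    """Discrete division rule: every nucleus splits into two.

    Daughters inherit the mother's concentrations unchanged and the
    division counter is incremented (so effective diffusion quadruples).
    The Bcd profile for the new epoch may be supplied; by default each
    daughter inherits its mother's Bcd value.
    """
    conc = np.repeat(state.conc, 2, axis=0)
    if bcd_new is None:
        bcd_new = np.repeat(state.bcd, 2)
    else:
        bcd_new = np.asarray(bcd_new, dtype=float)
        if bcd_new.shape != (conc.shape[0],):
            raise CircuitError(
                f"bcd_new must have length {conc.shape[0]}, got {bcd_new.shape}"
            )
    return EmbryoState(conc=conc, bcd=bcd_new, n_div=state.n_div + 1,
                       time=state.time)


# ---------------------------------------------------------------------------
# Bulirsch-Stoer integrator
# ---------------------------------------------------------------------------

_BS_SEQ = (2, 4, 6, 8, 10, 12, 14, 16)


def _modified_midpoint(f, t0: float, y0: np.ndarray, H: float, n: int) -> np.ndarray:
    """Gragg's modified midpoint rule over one macro step of size H."""
    h = H / n
    y_prev = y0
    y_cur = y0 + h * f(t0, y0)
    for i in range(1, n):
        y_prev, y_cur = y_cur, y_prev + 2.0 * h * f(t0 + i * h, y_cur)
    return 0.5 * (y_cur + y_prev + h * f(t0 + H, y_cur))


def bulirsch_stoer(f, y0: np.ndarray, t0: float, t1: float,
                   rtol: float = 1e-3, atol: float = 1e-6,
                   max_steps: int = 10_000) -> np.ndarray:
    """Integrate ``dy/dt = f(t, y)`` from t0 to t1 with adaptive macro steps.

    Each macro step extrapolates Gragg modified-midpoint results over the
    even step-number sequence 2, 4, ..., 16 in powers of h^2 (Neville
    tableau); the step is accepted when the last two tableau diagonals
    agree within the mixed tolerance ``atol + rtol*|y|``.
    """
    y = np.asarray(y0, dtype=float).copy()
    t = float(t0)
    H = t1 - t0
    steps = 0
    kmax = len(_BS_SEQ)
    while t < t1 - 1e-12 * max(1.0, abs(t1)):
        steps += 1
        if steps > max_steps:
            raise SolverError("Bulirsch-Stoer exceeded the step budget", t)
        H = min(H, t1 - t)
        accepted = False
        f0 = f(t, y)
        for _attempt in range(40):
            if H <= 1e-14 * max(1.0, abs(t)):
                raise SolverError("Bulirsch-Stoer step-size underflow", t)
            # Error scale from the step's start state (|y| + |H f|), so a
            # diverging extrapolant cannot inflate its own tolerance.
            scale = atol + rtol * (np.abs(y) + np.abs(H * f0))
            # Extrapolation tableau: rows[k][j] is the j-th extrapolation of
            # the modified-midpoint result with _BS_SEQ[k] substeps.
            rows: list[list[np.ndarray]] = []
            err = np.inf
            k_used = kmax - 1
            result = None
            prev_ok = False
            for k in range(kmax):
                row = [_modified_midpoint(f, t, y, H, _BS_SEQ[k])]
                for j in range(1, k + 1):
                    ratio = (_BS_SEQ[k] / _BS_SEQ[k - j]) ** 2
                    row.append(row[j - 1] + (row[j - 1] - rows[k - 1][j - 1])
                               / (ratio - 1.0))
                rows.append(row)
                if k > 1:
                    # Guard against false convergence of a diverging tableau
                    # (midpoint instability at large steps): both the last
                    # sub-diagonal pair and the last two diagonal entries
                    # must agree, at two consecutive orders, before the step
                    # is accepted — outside the asymptotic h^2 regime the
                    # entries can agree coincidentally at a single order.
                    err_sub = float(np.max(np.abs(row[k] - row[k - 1]) / scale))
                    err_diag = float(np.max(
                        np.abs(row[k] - rows[k - 1][k - 1]) / scale))
                    this_ok = (max(err_sub, err_diag) < 1.0
                               and np.all(np.isfinite(row[k])))
                    if this_ok and prev_ok:
                        err = max(err_sub, err_diag)
                        k_used, result = k, row[k]
                        break
                    prev_ok = this_ok
                    err = max(err_sub, err_diag)
            if result is not None:
                y = result
                t += H
                fac = 0.9 * err ** (-1.0 / (2 * k_used + 1)) if err > 0 else 4.0
                H *= min(4.0, max(0.3, fac))
                accepted = True
                break
            if not np.isfinite(err):
                H *= 0.1
            else:
                H *= max(0.1, 0.7 * err ** (-1.0 / (2 * kmax - 1)))
        if not accepted:
            raise SolverError("Bulirsch-Stoer failed to converge", t)
        if not np.all(np.isfinite(y)):
            raise SolverError("non-finite solution", t)
    return y


def _solve_segment(f, y0, t0, t1, rtol, atol, method: str):
    if method == "bulirsch-stoer":
        return bulirsch_stoer(f, y0, t0, t1, rtol=rtol, atol=atol)
    from scipy.integrate import solve_ivp

    sol = solve_ivp(f, (t0, t1), y0, method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise SolverError(f"solve_ivp({method}) failed: {sol.message}", t1)
    return sol.y[:, -1]


def integrate_interval(state: EmbryoState, params: GeneCircuitParams,
                       phase: str, t0: float, t1: float,
                       tol: float = 1e-3, atol: float = 1e-6,
                       method: str = "bulirsch-stoer",
                       sigmoid_fn: Callable = sigmoid) -> EmbryoState:
    """Advance the state through one continuous phase from t0 to t1.

    ``tol`` is the relative local-error tolerance; ``method`` selects the
    solver scheme ("bulirsch-stoer" or any ``solve_ivp`` method name).
    """
    if t1 <= t0:
        raise CircuitError(f"t1 ({t1}) must exceed t0 ({t0})")
    if phase not in (INTERPHASE, MITOSIS):
        raise CircuitError(f"phase must be a continuous rule, got {phase!r}")
    shape = state.conc.shape
    production_on = phase == INTERPHASE
    bcd = state.bcd
    n_div = state.n_div

    def f(t, y):
        return _rhs_matrix(y.reshape(shape), bcd, params, n_div,
                           production_on, sigmoid_fn).ravel()

    y1 = _solve_segment(f, state.conc.ravel(), t0, t1, tol, atol, method)
    return EmbryoState(conc=y1.reshape(shape), bcd=bcd, n_div=n_div, time=t1)


def simulate(params: GeneCircuitParams, initial: EmbryoState,
             schedule: MitoticSchedule, output_times: Iterable[float],
             tol: float = 1e-3, atol: float = 1e-6,
             method: str = "bulirsch-stoer",
             bcd_by_epoch: dict[int, np.ndarray] | None = None,
             sigmoid_fn: Callable = sigmoid) -> Trajectory:
    """Run the circuit over the mitotic schedule, recording requested times.

    Alternates the interphase / mitosis continuous rules with the discrete
    division rule.  An output time falling exactly on a division instant
    yields the post-division state.  ``bcd_by_epoch`` optionally maps each
    division count to the Bcd profile for that epoch.
    """
    output_times = sorted(float(t) for t in output_times)
    if output_times and (output_times[0] < schedule.start - 1e-9
                         or output_times[-1] > schedule.end + 1e-9):
        raise CircuitError("output_times must lie within the schedule span")
    if abs(initial.time - schedule.start) > 1e-9:
        raise CircuitError("initial.time must equal the schedule start")

    state = initial
    recorded: list[EmbryoState] = []
    pending = list(output_times)

    def record_up_to(t_end: float, phase_kind: str):
        nonlocal state, pending
        while pending and pending[0] <= t_end + 1e-12:
            t_out = pending.pop(0)
            if t_out > state.time + 1e-12:
                state = integrate_interval(state, params, phase_kind,
                                           state.time, t_out, tol=tol,
                                           atol=atol, method=method,
                                           sigmoid_fn=sigmoid_fn)
            recorded.append(replace(state, time=t_out))
        if t_end > state.time + 1e-12:
            state = integrate_interval(state, params, phase_kind, state.time,
                                       t_end, tol=tol, atol=atol,
                                       method=method, sigmoid_fn=sigmoid_fn)

    for phase in schedule.phases:
        if phase.kind == DIVISION:
            # Output exactly at the division instant reports the
            # post-division state, so drop any record made just before it.
            while recorded and abs(recorded[-1].time - phase.start) <= 1e-12:
                recorded.pop()
                pending.insert(0, phase.start)
            bcd_new = None
            if bcd_by_epoch is not None:
                bcd_new = bcd_by_epoch.get(state.n_div + 1)
            state = apply_division(state, bcd_new=bcd_new)
            while pending and abs(pending[0] - phase.start) <= 1e-12:
                pending.pop(0)
                recorded.append(replace(state, time=phase.start))
        else:
            record_up_to(phase.end, phase.kind)
    return Trajectory(states=tuple(recorded))
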
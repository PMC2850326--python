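"""Compiled fast path for repeated circuit simulation inside the optimisers.

Global optimisation evaluates the model ODEs millions of times, so the
inner Bulirsch-Stoer loop is implemented here on plain arrays and compiled
with numba when available (falling back to pure Python otherwise).  The
algorithm is identical to :mod:`gencircuit.model` — Gragg modified midpoint
with polynomial extrapolation and adaptive macro steps — restricted to the
default sigmoid.  Agreement between the two paths is asserted in the test
suite; anything needing a custom sigmoid or per-state introspection should
use :func:`gencircuit.model.simulate`.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


EV_INTEGRATE = 0
EV_RECORD = 1
EV_DIVIDE = 2

_KMAX = 8  # substep sequence 2, 4, ..., 16


@njit(cache=True)
def _rhs(conc, bcd, W, m, h, R, Deff, decay, prod, out):
    nn, ng = conc.shape
    for i in range(nn):
        for a in range(ng):
            val = -decay[a] * conc[i, a]
            if prod:
                u = h[a] + m[a] * bcd[i]
                for b in range(ng):
                    u += W[a, b] * conc[i, b]
                val += R[a] * 0.5 * (u / np.sqrt(u * u + 1.0) + 1.0)
            if nn > 1:
                if i == 0:
                    lap = conc[1, a] - conc[0, a]
                elif i == nn - 1:
                    lap = conc[nn - 2, a] - conc[nn - 1, a]
                else:
                    lap = conc[i - 1, a] + conc[i + 1, a] - 2.0 * conc[i, a]
                val += Deff[a] * lap
            out[i, a] = val


@njit(cache=True)
def _midpoint(y0, bcd, W, m, h, R, Deff, decay, prod, H, n, out):
    """Gragg modified midpoint with n substeps over a macro step H."""
    hs = H / n
    k = np.empty_like(y0)
    _rhs(y0, bcd, W, m, h, R, Deff, decay, prod, k)
    y_prev = y0.copy()
    y_cur = y0 + hs * k
    for _ in range(1, n):
        _rhs(y_cur, bcd, W, m, h, R, Deff, decay, prod, k)
        y_next = y_prev + 2.0 * hs * k
        y_prev = y_cur
        y_cur = y_next
    _rhs(y_cur, bcd, W, m, h, R, Deff, decay, prod, k)
    out[:, :] = 0.5 * (y_cur + y_prev + hs * k)


@njit(cache=True)
def _integrate(conc, bcd, W, m, h, R, Deff, decay, prod, t0, t1, rtol, atol):
    """Adaptive Bulirsch-Stoer over [t0, t1]; returns 1 on success."""
    nn, ng = conc.shape
    seq = np.array([2, 4, 6, 8, 10, 12, 14, 16])
    T = np.empty((_KMAX, _KMAX, nn, ng))
    f0 = np.empty((nn, ng))
    t = t0
    H = t1 - t0
    span = t1 - t0
    for _step in range(10000):
        if t >= t1 - 1e-12 * max(1.0, abs(t1)):
            return 1
        if H > t1 - t:
            H = t1 - t
        accepted = False
        _rhs(conc, bcd, W, m, h, R, Deff, decay, prod, f0)
        for _attempt in range(40):
            if H <= 1e-14 * max(1.0, abs(t)) or H <= 1e-14 * span:
                return 0
            err = 1e300
            done = False
            prev_ok = False
            for k in range(_KMAX):
                _midpoint(conc, bcd, W, m, h, R, Deff, decay, prod,
                          H, seq[k], T[k, 0])
                for j in range(1, k + 1):
                    ratio = (seq[k] / seq[k - j]) ** 2
                    T[k, j] = T[k, j - 1] + (T[k, j - 1] - T[k - 1, j - 1]) \
                        / (ratio - 1.0)
                if k > 1:
                    # Accept only when both the sub-diagonal pair and the
                    # last two diagonal entries agree at two consecutive
                    # orders (guards against coincidental agreement of a
                    # diverging tableau); error scale from the step's start
                    # state, never the extrapolant itself.
                    err = 0.0
                    ok = True
                    for i in range(nn):
                        for a in range(ng):
                            v = T[k, k, i, a]
                            if not np.isfinite(v):
                                ok = False
                            scale = atol + rtol * (abs(conc[i, a])
                                                   + abs(H * f0[i, a]))
                            e = abs(v - T[k, k - 1, i, a]) / scale
                            e2 = abs(v - T[k - 1, k - 1, i, a]) / scale
                            if e2 > e:
                                e = e2
                            if e > err:
                                err = e
                    this_ok = ok and err < 1.0
                    if this_ok and prev_ok:
                        conc[:, :] = T[k, k]
                        t += H
                        if err > 0.0:
                            fac = 0.9 * err ** (-1.0 / (2 * k + 1))
                        else:
                            fac = 4.0
                        if fac > 4.0:
                            fac = 4.0
                        if fac < 0.3:
                            fac = 0.3
                        H *= fac
                        done = True
                        break
                    prev_ok = this_ok
            if done:
                accepted = True
                break
            if np.isfinite(err) and err < 1e300:
                fac = 0.7 * err ** (-1.0 / (2 * _KMAX - 1))
                if fac < 0.1:
                    fac = 0.1
                H *= fac
            else:
                H *= 0.1
        if not accepted:
            return 0
    return 0


@njit(cache=True)
def run_plan(W, m, h, R, D_base, decay, conc0, bcd_stack,
             ev_kind, ev_t0, ev_t1, ev_prod,
             rtol, atol, out_concs):
    """Walk an event plan (integrate / record / divide); returns 1 on success.

    ``bcd_stack[n]`` is the Bcd profile for division epoch ``n`` (padded to
    the final nucleus count).  ``out_concs`` is (n_records, max_nn, ng),
    filled in record order; unused rows keep their initial value.
    """
    nn0, ng = conc0.shape
    max_nn = out_concs.shape[1]
    conc = np.zeros((max_nn, ng))
    conc[:nn0] = conc0
    nn = nn0
    nd = 0
    rec = 0
    for e in range(ev_kind.shape[0]):
        kind = ev_kind[e]
        if kind == EV_INTEGRATE:
            Deff = D_base * 4.0 ** nd
            ok = _integrate(conc[:nn], bcd_stack[nd, :nn], W, m, h, R, Deff,
                            decay, ev_prod[e] == 1, ev_t0[e], ev_t1[e],
                            rtol, atol)
            if ok == 0:
                return 0
        elif kind == EV_RECORD:
            out_concs[rec, :nn] = conc[:nn]
            rec += 1
        else:  # EV_DIVIDE
            for i in range(nn - 1, -1, -1):
                conc[2 * i + 1] = conc[i]
                conc[2 * i] = conc[i]
            nn *= 2
            nd += 1
    return 1


def build_plan(schedule, output_times):
    """Compile a mitotic schedule plus output times into flat event arrays.

    Returns (kinds, t0s, t1s, prods, record_times, record_ndiv).  An output
    time coinciding with a division instant records the post-division state.
    """
    from . import model as M

    pending = sorted(float(t) for t in output_times)
    kinds, t0s, t1s, prods = [], [], [], []
    rec_times, rec_ndiv = [], []
    t_cur = schedule.start
    nd = 0

    def push_integrate(t_end, prod):
        nonlocal t_cur
        if t_end > t_cur + 1e-12:
            kinds.append(EV_INTEGRATE)
            t0s.append(t_cur)
            t1s.append(t_end)
            prods.append(1 if prod else 0)
            t_cur = t_end

    for phase in schedule.phases:
        if phase.kind == M.DIVISION:
            at_div = [t for t in pending if abs(t - phase.start) <= 1e-12]
            pending = [t for t in pending if abs(t - phase.start) > 1e-12]
            kinds.append(EV_DIVIDE)
            t0s.append(phase.start)
            t1s.append(phase.start)
            prods.append(0)
            nd += 1
            for t in at_div:
                kinds.append(EV_RECORD)
                t0s.append(t)
                t1s.append(t)
                prods.append(0)
                rec_times.append(t)
                rec_ndiv.append(nd)
        else:
            prod = phase.kind == M.INTERPHASE
            while pending and pending[0] <= phase.end + 1e-12:
                t = pending.pop(0)
                push_integrate(t, prod)
                kinds.append(EV_RECORD)
                t0s.append(t)
                t1s.append(t)
                prods.append(0)
                rec_times.append(t)
                rec_ndiv.append(nd)
            push_integrate(phase.end, prod)
    return (np.array(kinds, dtype=np.int64),
            np.array(t0s, dtype=float),
            np.array(t1s, dtype=float),
            np.array(prods, dtype=np.int64),
            np.array(rec_times, dtype=float),
            np.array(rec_ndiv, dtype=np.int64))
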
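# Methods

## The model

`gencircuit` simulates and fits *gene circuits*: phenomenological ODE models
of transcriptional regulation on a one-dimensional row of embryonic nuclei,
of the kind used to reverse-engineer the Drosophila gap-gene network. The
state variables are protein concentrations `g_i^a` (nucleus `i`, gene `a`).
Each concentration obeys

    dg_i^a/dt = R^a Φ(u_i^a)  +  D^a(n) [(g_{i-1}^a − g_i^a) + (g_{i+1}^a − g_i^a)]  −  λ^a g_i^a

with total regulatory input

    u_i^a = Σ_b W^{ab} g_i^b + m^a bcd_i + h^a .

* `W` is the interconnectivity matrix — positive entries are activation,
  negative repression, near-zero no interaction. `m` weights the external
  Bicoid gradient (an input, never a state variable), and `h` is a
  threshold summarising ubiquitous maternal factors.
* `Φ(u) = ½(u/√(u²+1) + 1)` is the regulation-expression sigmoid, strictly
  increasing from 0 to 1 with `Φ(0) = ½`. A different sigmoid can be
  injected through the `sigmoid_fn` hook of the reference simulator.
* Diffusion is Fickian between adjacent nuclei with zero-flux boundaries at
  the ends of the row (the standard choice in this model family; with
  production off and no decay, total per-gene mass is conserved to solver
  tolerance, which is a unit test).
* Decay is first order; the half-life of product `a` is `ln 2 / λ^a`.

Development is driven by a *mitotic schedule* of three rules: during
interphase the full equation holds; during mitosis the production term is
set to zero; at a division instant every nucleus splits in two, daughters
copy the mother's concentrations, and — because internuclear distance
halves — the effective diffusion rate quadruples, `D(n) = 4 D(n−1)` where
`n` counts divisions. The schedule is fully user-specified
(`MitoticSchedule`); the shipped fixtures use a small two-cycle schedule
(interphase 0–16 min, mitosis 16–20, division at 20, interphase 20–36).
An output time that coincides with a division instant reports the
post-division state, since the discrete rule applies before integration
resumes. The Bcd profile of each division epoch is supplied by the dataset
(`bcd_by_epoch`); by default daughters inherit their mother's value.

## Numerics

The reference integrator is a Bulirsch–Stoer scheme: Gragg's modified
midpoint rule over the even substep sequence 2, 4, …, 16, Richardson
extrapolation in powers of h², and adaptive macro steps. Any
`scipy.integrate.solve_ivp` method name can be passed instead
(`method="DOP853"` etc.), and agreement between the two is a unit test.
Two robustness details matter and are themselves regression-tested:

* the local error is measured against a scale built from the step's
  **start** state, `atol + rtol(|y| + |H·f(y)|)` — scaling by the
  extrapolant itself lets a diverging tableau justify its own acceptance;
* a step is accepted only when both the final sub-diagonal pair and the
  last two *diagonal* tableau entries agree, at **two consecutive
  orders**. Outside the asymptotic h² regime (large `H·λ`) the midpoint
  instability makes tableau entries agree coincidentally at a single
  order — we observed an accepted value of 35.8 against a true value of
  0.9 on a plain decay problem before these guards were added.

With both guards, 2400 random decay-only circuits (12 seeds, tolerances
1e-3 and 1e-5) integrate with zero violations of the configured tolerance,
worst scaled error 0.04. The default
relative tolerance is 1e-3 (the accuracy actually needed during global
search); data synthesis in the fixtures uses 1e-6.

Because a global search evaluates the ODEs millions of times, the objective
uses a numba-compiled implementation of the same algorithm
(`gencircuit._fastsim`, ~40× faster than the numpy path, ~0.3 ms per
evaluation of the canonical toy). The compiled and reference paths are
compared in the test suite; the package degrades to pure Python if numba is
absent.

## Objective and constraints

Fitting minimises `E(θ) = Σ (model − data)²` over every observed (time
class, gene, nucleus) cell, unweighted. The earliest time class of a
dataset supplies the initial state; later classes are the fitted
observations. A solver failure during scoring yields `E = ∞` rather than an
exception — global searches routinely visit pathological parameter sets.

The search space is constrained twice:

* **hard bounds** (strict): `10 < R^a < 30`, `0 < D^a < 0.3`,
  `5 < ln2/λ^a < 20` min. Vectors outside score `(∞, ∞)` and are ranked
  worst; they are kept rather than resampled so step-size self-adaptation
  is not biased.
* a **penalty** `Π` on the regulatory parameters only (W, m, h), controlled
  by `Λ = 1e-4`. Per target gene we form the extreme total inputs
  reachable with every regulator at its maximum observed concentration,
  `u_hi^a = Σ_b max(W^{ab},0) v_max^b + max(m^a,0) bcd_max + h^a` (and
  `u_lo^a` with minima), and penalise quadratic exceedance beyond
  `±1/Λ`: `Π = Λ Σ_a [max(0, u_hi^a − 1/Λ)² + max(0, −1/Λ − u_lo^a)²]`.
  `Π` is exactly zero while total input stays inside the bound, continuous,
  and strictly increasing as any regulatory parameter scales beyond it —
  individual weights may grow large as long as total input stays bounded.
  `Π` never depends on R, D or λ (a unit test).

Parameter vectors are flat with layout `W` (row-major), `m`, free `h`, `R`,
`D_base`, `decay`. Thresholds can be frozen per gene at −2.5; in the
canonical 6-gene gap circuit (cad, hb, Kr, kni, gt, tll) the four trunk gap
genes are frozen and cad/tll stay free, so the vector length drops from
`N_g(N_g+5) = 66` to 62. Generically
`n = N_g(N_g+5) − (#frozen thresholds)`.

## The island (μ, λ)-Evolution Strategy

Defaults (`ESConfig`): λ = 125 individuals per island, μ = λ/5 = 25
parents, recombination factor χ = 0.85, ranking probability P_f = 0.45,
mutation tuning φ\* = 1, step-size smoothing α = 0.2, migration every
m = 200 generations, logging every τ = 20, 40000 generations. One RNG
stream per island (`base_seed + island_index`), a dedicated master stream
for migration schedules.

Per generation, per island:

1. **Stochastic ranking** — λ sweeps of adjacent-pair bubble sort; a pair
   with both penalties ≤ 0 is ordered by fitness, otherwise by fitness with
   probability P_f and by penalty value with probability 1 − P_f; early
   exit on a swap-free sweep. Uniform draws are consumed lazily (none for
   feasible pairs), which makes fully feasible populations rank as an
   exact fitness sort — tested against a comparison sort — and keeps RNG
   streams aligned across execution modes.
2. **Selection** — the top μ survive as parents (comma selection: parents
   die).
3. **Recombination** — λ − μ direct copies of the parents (each copied
   (λ−μ)//μ times, the fittest (λ−μ) mod μ once more) plus μ recombinants:
   parent k combined with the next-fittest parent (wrapping to the fittest
   after the worst) and the fittest parent as
   `x' = χ x_k + (1−χ)/2 (x_next + x_best)`. The combination is affine, so
   identical parents recombine to themselves; recombinants inherit their
   primary parent's step sizes.
4. **Mutation** — applied only to the copies. Step sizes are perturbed
   log-normally, `σ' = σ exp(τ_g N + τ_c N_j)` with a shared draw N and
   per-coordinate draws N_j, using Schwefel's rates scaled by φ\*
   (`τ_g = φ*/√(2n)`, `τ_c = φ*/√(2√n)`); parameters move by
   `θ' = θ + σ' N'_j`; the retained step size is the exponentially
   smoothed `α σ' + (1−α) σ`, strictly positive by construction.

Initial kinetic rates are uniform inside their open hard-bound intervals
(half-life sampled uniformly, then converted to a decay rate). Initial
regulatory weights are uniform in ±L with
`L = u_scale / (Σ v_max + bcd_max)`, `u_scale = 3`: the total regulatory
input then spans the responsive range of the sigmoid instead of its
saturated arms. This is the one genuinely open initialisation choice; the
penalty bound alone would allow |W| two orders of magnitude larger, which
parks the entire population on sigmoid plateaus with correspondingly huge
initial step sizes and stalls adaptation. L is additionally capped so the
penalty is zero at initialisation. Initial step sizes are 10% of each
parameter's range (self-adaptation corrects the constant).

### Execution modes

* **serial** — islands advance round-robin; every m generations each
  island's best is copied into a uniformly chosen other island, replacing
  the receiver's worst (a receiver of k migrants replaces its k worst).
* **sync** — the same exchange under barrier semantics, with the schedule
  drawn by a master stream and conceptually broadcast. Because the rule
  and the streams are identical, sync is *bit-identical* to serial for the
  same seeds — the determinism guarantee, pinned by a parametrised test
  over island counts and seeds. Migrant/victim choice uses a
  deterministic feasibility-then-fitness ordering, never an RNG draw, so
  the island streams cannot diverge between modes.
* **async** — no barriers; every m generations an island deposits its best
  into the buffer of a randomly chosen island (deposit, then absorb), and
  absorbs everything waiting in its own buffer (population transiently
  λ + k until the next selection). Buffers are bounded — at most 10
  migrants per sender per island buffer, 50 messages per sender in the
  master buffer — and a refused deposit is deferred and retried, never
  dropped. Statistics flow to a master every τ generations; the master
  logs the minimum across islands and emits the terminate signal.

  Unit tests drive asynchrony through a deterministic virtual-time
  scheduler (round-robin rounds with configurable per-island lag in
  generations): the asynchronous semantics live in the buffers, not the
  wall clock. With zero lag the exchange pattern coincides with the
  synchronous one — on an always-feasible objective the runs agree
  bit-for-bit, which is the scheduler-equivalence test. True process-based
  concurrency (one process per island, queue transport) exists as
  `mode="async-process"` and is exercised by an integration test.

Termination is either a fixed generation count (default 40000) or a
threshold-hold rule: stop once the current best objective has stayed at or
below a threshold for ρ consecutive τ-checks. Logs record (generation,
elapsed seconds, current best) every τ generations; the current best can
rise under comma selection, so descent analyses use the running minimum.
Wall-clock stamps come from an injectable clock.

## Simulated-annealing baseline

The comparison baseline anneals `E + Π` with K chains. Implemented
faithfully: Metropolis acceptance (downhill always, uphill with probability
`exp(−ΔE/T)`; the source description's printed sign would give
probabilities above one), Boltzmann mixing every m iterations (each chain
is independently reassigned chain i's state with probability
`exp(−E_i/T)/Σ_j exp(−E_j/T)` — assignment, never averaging), an initial
burn of `n_init` iterations at constant T₀, and the freeze stopping rule
(halt when the best energy changes by less than a set fraction over a set
window of checks). Two components are deliberate stand-ins, since the
original adaptive machinery is defined in the annealing literature rather
than restated here: the temperature schedule is pluggable (geometric by
default) and move generation is per-parameter Gaussian with
acceptance-ratio-targeted scale adaptation. The baseline is for
qualitative comparison; no quantitative annealing timings are claimed.

## Performance metrics

`metrics` computes, from run logs alone (pure functions, bit-reproducible):

* **descent curves** — per-interval mean, standard error and empirical
  2.5–97.5% envelope of best-so-far values across runs;
* **time-to-target** — first crossing of a target objective per run; the
  mean is over runs that reached the target, with SE = σ/√N_attempts
  (the benchmark convention), and the success rate carries an exact
  Clopper–Pearson binomial 95% interval;
* **speed-ups** — relative (serial with K islands ÷ parallel on K nodes)
  and absolute (best serial configuration, K\* = 1 island, ÷ parallel),
  with **Fieller** confidence intervals for the ratio of independent
  Gaussian means (zero covariance; the interval is flagged unbounded when
  the denominator is not significantly nonzero). Fieller coverage is
  verified by Monte-Carlo at ≈95%. Printed benchmark durations are
  parsed as hours:minutes, with ± read as a 95% CI half-width.

## Synthetic fixtures and what they do (not) show

`fixtures` generates ground-truth circuits whose kinetic rates are uniform
inside the hard bounds and whose weights are small enough for zero penalty,
plus FlyEx-style datasets: simulate the truth at high accuracy, observe at
the time classes, add independent Gaussian noise truncated at zero, and
take per-gene maxima from the noisy table as real data would. The
canonical toy is a 2-gene mutual-repression circuit (Bcd activates both) on
4 nuclei, 3 time classes, 1 division — 12 free parameters with thresholds
frozen.

The recovery experiment re-fits the noisy dataset n times and reports final
E, whether it fell below 10⁻³ of the data sum of squares, and the sign
agreement of recovered W entries above a magnitude floor. The frozen
operating point for the toy (2 islands, λ = 20, μ = 4, migration every
100, 2000 generations, ≈80 000 evaluations, <30 s per run) reaches the
floor in 10/10 runs and beats an equal-budget uniform random search by two
orders of magnitude in median final E.

These fixtures exercise the least-squares machinery, the mitotic schedule
and the constraint handling; they do **not** emulate real gap-gene
expression shapes, image-processing artefacts, registration error or
non-Gaussian noise. Passing tests therefore demonstrate the correctness
and determinism of the machinery and its ability to recover a known
circuit at toy scale — not biological fidelity at the 6-gene,
58-nucleus scale, whose wall-clock benchmarks on 10–50 cluster nodes are
out of scope here.

## Known limitations

* 1-D nuclear row only; no 2-D/3-D geometry, no stochastic expression.
* The exact published gap-gene mitotic timetable is not reproduced;
  schedules are user-supplied.
* The annealing baseline's schedule/move generation are stand-ins (above),
  so its timings are not comparable to published annealing results.
* The compiled fast path supports the default sigmoid only; custom
  sigmoids fall back to the slower reference simulator.
* `async-process` mode trades bit-reproducibility for true concurrency;
  deterministic analyses should use the virtual scheduler.
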
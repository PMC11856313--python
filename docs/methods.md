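# Methods

This note records the models the package implements, the assumptions
and defaults behind them, and the numerical choices made where the
design was genuinely open.

## Benchmark functions

The registry covers twenty classical continuous minimization problems
(`f1`–`f20`): Sphere, Beale, Rosenbrock, Griewank, Rastrigin, Ackley,
the Schwefel max-component and abs-sum-plus-product variants, a step
function, a noisy quadratic, non-continuous Rastrigin, two penalized
functions, five rotated counterparts, a "pathological" sum, and
weighted sum-of-squares.  Search boxes are not intrinsic to the
formulas, so the registry documents the standard literature defaults
(Sphere/Step/SumSquares/Schwefel family `[-100, 100]`; Rosenbrock
`[-30, 30]`; Rastrigin variants `[-5.12, 5.12]`; Griewank
`[-600, 600]`; Ackley `[-32, 32]`; Beale `[-4.5, 4.5]`; penalized
`[-50, 50]`; noisy quadratic `[-1.28, 1.28]`; pathological
`[-100, 100]`), all overridable per call.

Two deliberate readings, flagged in the code as well:

* **step (f9)** is implemented in the *continuous* paired-term form
  `Σ_{i<d} (x_i+0.5)² + (x_{i+1}+0.5)²` (interior coordinates counted
  twice, minimum 0 at `x = -0.5`), not the floor-based step function.
* **pathological (f19)** is `Σ -x_i² sin(x_i)`; its global minimum has
  no closed form and is recorded as unknown, so convergence statistics
  are not defined for it.
* **penalized1 (f12)** and **penalized2 (f13)** use the standard
  literature forms (with `y_i = 1 + (x_i+1)/4` and the `u(x, a, k, m)`
  boundary penalty).

Rotated variants apply `z = Mx` with `M` the Q factor of a seeded
standard-normal matrix (diagonal sign fixed), which is deterministic
per seed and uniform over the orthogonal group; orthogonality is
enforced to 1e-10.  The noisy quadratic adds a `U(0,1)` draw from a
caller-supplied stream, so noise is reproducible and can be silenced
in tests.  Beale is inherently two-dimensional; the experiment harness
runs it at its native dimension whatever dimension the suite requests.

## Canonical colony

Minimization with `SN` food sources; the onlooker count equals the
employed count.  Defaults `SN = 20`, `Limit = 30`, evaluation budget
5×10⁴, generation cap 2500.  The budget and the cap are both honored,
budget first (at `SN = 20` a generation costs ≈ 40 evaluations, so the
budget binds long before 2500 generations).  Every objective call —
initialization, employed/onlooker candidates, scout re-draws — counts
one evaluation, and candidate generation stops mid-phase the moment
the budget is exhausted.

Numerical/tie choices:

* **Greedy replacement requires strict improvement.**  Equal
  objectives keep the incumbent and increment the trial counter, so
  neutral drift cannot reset the `Limit` mechanism.
* **Onlooker probabilities are computed once per phase** from the
  fitnesses at the end of the employed phase (the standard
  implementation layout); sources updated mid-phase keep their
  selection weight until the next generation.
* **Boundary repair is the midpoint rule** (midpoint of the parent
  coordinate and the violated bound) in both the canonical and guided
  loops, so the two differ only in the guidance term.
* **Selection variants.**  Rank selection is linear ranking
  `P_i = (2-SP)/n + 2·rank_i·(SP-1)/(n(n-1))` with selective pressure
  `SP = 1.5` (ties get averaged ranks); disruptive selection weights
  by `|fit_i - mean fit|` with a uniform fallback when all deviations
  vanish; tournament selection uses size `t = 2` by default and its
  probability vector is the exact win law of one tournament with
  distinct uniformly drawn contestants and uniform tie-breaking.
* **RNG layout.**  One seeded `numpy` generator per run; per-phase
  draws are batched (arrays of `j`, `k`, `φ`) for speed.  Batch
  experiments derive run `r`'s seed as `base_seed + r`, so batches are
  order-invariant and individually reproducible.

## Guided colony (GABC)

The guided proposal adds `φ_b (x*_j − x_ij)` toward the incumbent best
with `φ_b = min(α + β·iter/MaxIter, C)`: `α ~ U(0,1)` fresh per
candidate, `β = 0.5`, capped at `C = 1.5` (the cap reconciles the
declared `[0, C]` range with the adaptive formula, which can reach
1.5).  `iter/MaxIter` uses the generation count against the generation
cap even when the evaluation budget stops the run earlier, so the
schedule does not depend on the budget.  Both employed and onlooker
phases use the guided proposal.

The belief space holds per dimension `(l_i, u_i)` and bound qualities
`(L_i, U_i)`, initialized to the full box with `+inf` qualities (an
unset sentinel the first update always beats).  The update rule: the
lower bound moves to `x_i` when `x_i ≤ l_i` (expansion) *or*
`f(x) < L_i` (shrink toward a better solution), symmetrically for the
upper bound; bounds re-order if they crossed and are clamped to the
box.  Each generation the belief space ingests every accepted
improvement plus the incumbent best (switchable to best-only).  How
the belief space "guides the search region" is operationalized
minimally: **scouts re-draw inside `[l, u]`** instead of the global
box (per-dimension fallback to the box when the interval is degenerate
below width 1e-12); this is a config switch, so global-box scouting
remains available.

With the guidance term disabled the proposal reduces exactly to the
canonical one, and the guided loop consumes the identical RNG stream —
`run_gabc(gbest_term=False, scout_in_belief=False)` reproduces
`run_abc` bit-for-bit under a shared seed.  This limit-case identity
is asserted in the test suite against the *independently written*
canonical loop.

## Experiment harness

`run_batch` aggregates final objectives into Best/Mean/Median/Worst
and the sample standard deviation (`n−1` denominator), the convergence
probability (fraction of runs with `|final − f*| < ε`), and the mean
first recorded evaluation count at which the best-so-far trajectory
reaches a target accuracy.  Trajectories are sampled at generation
boundaries (not every evaluation) to bound memory, and no
interpolation is performed, so FEs-to-accuracy is the first *recorded*
qualifying point.  Runs that never reach the accuracy are censored and
counted separately rather than averaged in.  The convergence tolerance
defaults to 5×10⁻⁷; the headline suite uses 1e-6.  Per-function target
accuracies for evaluation-count comparisons are a required parameter
(there is no principled universal choice), so absolute FEs-to-accuracy
values are reported but not treated as reference statistics.

## Supply-allocation case

**Demand model.**  Daily mask demand is `cases × 10`.  The infection
rate is estimated by a normal–normal conjugate update: precisions add
and the posterior mean is the precision-weighted average of the prior
(e.g. the other-area observation series) and the local sample
observation; each day's posterior is the next day's prior.  This is
the minimal model consistent with making the allocation decision each
morning on the previous day's posterior mean.  The mapping from a
continuous rate to an integer daily case count is area-specific and is
not modeled; the built-in case carries demand in units directly.

**Allocation model.**  Sources are a central reserve (10,000 masks
pooled *across* periods), donations (uncertain; a capacity interval
with point value 0 in the fixture), and three city manufacturers with
per-period capacities (1500/2000/2000, 1800/2800/4000,
1200/1200/1500).  The objective is acquisition cost plus a linear
shortage penalty (default 100/unit) — shortage is a *meaningful
output*, not an infeasibility, because emergency demand can exceed
total capacity (it does in the bundled case: 30,800 demanded vs 28,000
available).  Unit costs are not part of the recorded case data and are
required configuration with documented defaults (reserve 1.0,
donations 2.0, cities 3.0/3.5/4.0); optimal *quantities* therefore
depend on the chosen cost model and are not reference values.

**Solvers.**  The exact oracle is a linear program (HiGHS via
`scipy.optimize.linprog`) over quantities plus shortage slacks.  The
colony solver runs GABC over the box of per-source-per-period
quantities with pooled-stock over-commitment penalized in the
objective; the result is projected to feasibility (clip to capacities,
scale pooled totals down proportionally) and then refined by a
deterministic merit-order polish.  The polish exists because the
penalized box formulation has an exchange degeneracy: at a coverage
kink (supply = demand) moving supply from an expensive source to a
cheaper one changes two coordinates at once, and single-coordinate
colony moves are strictly worse in either direction, so the colony
alone stalls a few percent above the optimum.  The polish performs
only strictly cost-reducing operations (fill shortages from cheapest
slack while the unit cost is below the penalty, trim over-supply from
the most expensive source, exchange expensive supply into cheaper
slack, with pooled stock tracked globally) and leaves the LP as the
independent correctness oracle; across 50 random desk-scale instances
the best-of-10-seeds pipeline lands within a small fraction of a
percent of the LP optimum.

## Problem sizes and what the tests show

The acceptance suite runs the full standard protocol (30 runs ×
5×10⁴ evaluations per function on f1–f6 at D=30) — these are the study
conditions themselves, not a scaled-down surrogate.  Unit tests use
smaller budgets (hundreds to a few thousand evaluations) chosen to
exercise contracts, not performance.  The random desk-scale allocation
instances (≤ 3 periods, ≤ 5 sources, capacities 10–100) emulate the
*structure* of the case study — mixed pooled/per-period constraints,
demand both below and above capacity — but not real epidemic dynamics:
demands are independent uniforms, not trajectories from an outbreak
model, so passing tests certify solver correctness on this problem
class rather than forecasting skill.

Two properties of the benchmark protocol deserve honesty notes.
First, the six-function pooled convergence percentage is dominated by
Rosenbrock: its curved narrow valley at D=30 is not solvable to 1e-6
within 5×10⁴ evaluations by colony-style single-coordinate search (no
published ABC-family variant does so), so the pooled figure sits near
76% rather than the mid-90s one would see if Rosenbrock converged like
the other five.  Second, Monte-Carlo oracle tests compare exact
selection laws with simulated frequencies; they assert on the median
deviation across three independent replicates so that a single
replicate's ~1-in-50 chance excursion beyond 3 standard errors cannot
fail a mathematically exact implementation, while any persistent bias
still would.

## Known limitations

* The optimizer is a reference implementation in pure numpy; it is
  deliberately not vectorized across runs or JIT-compiled.
* No constraint handling beyond box bounds and the allocation model's
  penalties; no shifted-optimum or composition benchmark variants.
* The disruptive/rank/tournament colonies share the canonical proposal
  and differ only in onlooker selection, which is the documented
  reading of those variants.
* Donations are modeled as a deterministic capacity (default 0);
  stochastic donation scenarios and inventory carry-over between
  periods are out of scope.
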
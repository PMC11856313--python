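"""Canonical artificial bee colony (ABC) machinery.

The colony maintains ``SN`` food sources (candidate solutions).  Each
generation runs three phases:

* employed phase — every source proposes a one-coordinate neighborhood
  move ``v_j = x_ij + phi (x_ij - x_kj)`` with ``phi ~ U[-1, 1]`` and a
  random partner ``k != i``, kept only on strict improvement;
* onlooker phase — ``SN`` onlookers pick sources by a fitness-based
  selection scheme (proportional roulette by default; rank, disruptive
  and tournament variants are available) and search near them;
* scout phase — any source whose trial counter exceeds ``Limit`` is
  abandoned and re-drawn uniformly in the search box.

Minimization throughout.  The fitness transform maps an objective value
``f`` to a positive selection weight: ``1/(1+f)`` for ``f >= 0`` and
``1+|f|`` otherwise.

Function-evaluation (FE) accounting counts every objective call —
initialization, employed and onlooker candidates, and scout re-draws —
and the run stops as soon as the FE budget is exhausted or the
generation cap is reached, whichever comes first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .benchmarks import ObjectiveFunction

__all__ = [
    "ColonyConfig",
    "FoodSource",
    "ColonyState",
    "RunResult",
    "fitness_transform",
    "initialize_colony",
    "neighborhood_candidate",
    "greedy_replace",
    "selection_probabilities",
    "sample_selection",
    "scout_phase",
    "run_abc",
]

SELECTION_SCHEMES = ("proportional", "rank", "disruptive", "tournament")


@dataclass
class ColonyConfig:
    """Run configuration for ABC-family optimizers.

    ``sn`` is the employed-bee count (the onlooker count equals it),
    ``limit`` the trial threshold for scout conversion, ``max_fes`` the
    primary evaluation budget and ``max_iter`` a secondary generation
    cap.  ``selection`` picks the onlooker scheme; ``selection_params``
    carries scheme knobs (``sp`` selective pressure for rank,
    ``tournament_size`` for tournament).
    """

    sn: int = 20
    limit: int = 30
    max_iter: int = 2500
    max_fes: int = 50_000
    selection: str = "proportional"
    selection_params: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sn < 2:
            raise ValueError("sn must be >= 2")
        if self.limit < 1:
            raise ValueError("limit must be >= 1")
        if self.max_fes < self.sn:
            raise ValueError("max_fes must allow at least one evaluation per source")
        if self.selection not in SELECTION_SCHEMES:
            raise ValueError(f"unknown selection scheme {self.selection!r}")


@dataclass
class FoodSource:
    """One candidate solution: position, objective, fitness, trial counter."""

    position: np.ndarray
    objective: float
    fitness: float
    trial: int = 0


@dataclass
class ColonyState:
    """Population plus incumbent best and evaluation bookkeeping."""

    positions: np.ndarray  # (sn, dim)
    objectives: np.ndarray  # (sn,)
    fitness: np.ndarray  # (sn,)
    trials: np.ndarray  # (sn,) int
    best_position: np.ndarray
    best_objective: float
    fe_count: int
    iter: int = 0
    lower: np.ndarray = None
    upper: np.ndarray = None

    @property
    def sn(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def sources(self) -> list[FoodSource]:
        """Snapshot of the population as :class:`FoodSource` records."""
        return [
            FoodSource(self.positions[i].copy(), float(self.objectives[i]),
                       float(self.fitness[i]), int(self.trials[i]))
            for i in range(self.sn)
        ]


@dataclass
class RunResult:
    """Outcome of one optimizer run.

    ``trajectory_fe`` / ``trajectory_best`` sample the best-so-far
    objective at initialization and at every generation boundary.
    """

    best_position: np.ndarray
    best_objective: float
    fes_used: int
    n_iter: int
    trajectory_fe: np.ndarray
    trajectory_best: np.ndarray

    def to_dict(self) -> dict:
        return {
            "best_objective": self.best_objective,
            "best_position": self.best_position.tolist(),
            "fes_used": int(self.fes_used),
            "n_iter": int(self.n_iter),
        }


# ---------------------------------------------------------------------------
# primitives


def fitness_transform(f: float) -> float:
    """Objective-to-fitness map: ``1/(1+f)`` if ``f >= 0`` else ``1+|f|``.

    Positive, strictly decreasing in ``f``, and continuous at 0.
    """
    f = float(f)
    if not math.isfinite(f):
        raise ValueError("objective value must be finite")
    return 1.0 / (1.0 + f) if f >= 0.0 else 1.0 + abs(f)


def _fitness_array(objectives: np.ndarray) -> np.ndarray:
    obj = np.asarray(objectives, dtype=float)
    if not np.all(np.isfinite(obj)):
        raise ValueError("objective values must be finite")
    with np.errstate(divide="ignore"):  # discarded branch may hit f == -1
        return np.where(obj >= 0.0, 1.0 / (1.0 + obj), 1.0 + np.abs(obj))


def _evaluate(fn, x, noise_stream):
    return fn(x, noise_stream=noise_stream) if fn.needs_noise else fn(x)


def initialize_colony(
    config: ColonyConfig, fn: ObjectiveFunction, rng: np.random.Generator
) -> ColonyState:
    """Draw ``sn`` sources uniformly in the search box and evaluate them."""
    sn, dim = config.sn, fn.dim
    positions = rng.uniform(fn.lower, fn.upper, size=(sn, dim))
    objectives = np.array([_evaluate(fn, positions[i], rng) for i in range(sn)])
    fitness = _fitness_array(objectives)
    best = int(np.argmin(objectives))
    return ColonyState(
        positions=positions,
        objectives=objectives,
        fitness=fitness,
        trials=np.zeros(sn, dtype=np.int64),
        best_position=positions[best].copy(),
        best_objective=float(objectives[best]),
        fe_count=sn,
        iter=0,
        lower=fn.lower,
        upper=fn.upper,
    )


def _repair_midpoint(v: np.ndarray, x: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Midpoint boundary repair: an out-of-box coordinate is replaced by
    the midpoint of the parent coordinate and the violated bound."""
    over = v > upper
    under = v < lower
    if over.any():
        v = np.where(over, (x + upper) / 2.0, v)
    if under.any():
        v = np.where(under, (x + lower) / 2.0, v)
    return v


def neighborhood_candidate(
    state: ColonyState, i: int, rng: np.random.Generator
) -> np.ndarray:
    """One-coordinate neighborhood move for source ``i`` (the classic
    ABC proposal), repaired to the search box."""
    sn = state.sn
    if sn < 2:
        raise ValueError("need at least two sources for a neighborhood move")
    j = int(rng.integers(state.dim))
    k = int(rng.integers(sn - 1))
    if k >= i:
        k += 1
    phi = rng.uniform(-1.0, 1.0)
    v = state.positions[i].copy()
    v[j] = v[j] + phi * (v[j] - state.positions[k, j])
    return _repair_midpoint(v, state.positions[i], state.lower, state.upper)


def greedy_replace(source: FoodSource, candidate_position: np.ndarray, candidate_objective: float) -> FoodSource:
    """Strict-improvement greedy selection: adopt the candidate only if
    its objective is strictly better; otherwise keep the incumbent and
    increment its trial counter (equal objectives keep the incumbent, so
    neutral drift cannot reset the Limit counter)."""
    if candidate_objective < source.objective:
        return FoodSource(
            position=np.asarray(candidate_position, dtype=float).copy(),
            objective=float(candidate_objective),
            fitness=fitness_transform(candidate_objective),
            trial=0,
        )
    return FoodSource(
        position=source.position,
        objective=source.objective,
        fitness=source.fitness,
        trial=source.trial + 1,
    )


# ---------------------------------------------------------------------------
# selection schemes


def selection_probabilities(
    objectives: np.ndarray, scheme: str = "proportional", params: Optional[dict] = None
) -> np.ndarray:
    """Per-source selection probabilities for the onlooker phase.

    ``proportional`` is the classic roulette on transformed fitness,
    ``rank`` is linear ranking with selective pressure ``sp`` (default
    1.5), ``disruptive`` weights by absolute deviation of fitness from
    the population mean (uniform fallback when all deviations vanish),
    and ``tournament`` returns the exact win probability of a single
    size-``t`` tournament with distinct uniformly drawn contestants
    (ties broken uniformly).
    """
    params = params or {}
    obj = np.asarray(objectives, dtype=float)
    if obj.size == 0:
        raise ValueError("need at least one source")
    fit = _fitness_array(obj)
    n = fit.size

    if scheme == "proportional":
        return fit / fit.sum()

    if scheme == "disruptive":
        dev = np.abs(fit - fit.mean())
        total = dev.sum()
        if total == 0.0:
            return np.full(n, 1.0 / n)
        return dev / total

    if scheme == "rank":
        sp = float(params.get("sp", 1.5))
        if not 1.0 <= sp <= 2.0:
            raise ValueError("selective pressure sp must lie in [1, 2]")
        # rank 0 = worst ... n-1 = best; average ranks over ties
        order = np.argsort(fit, kind="stable")
        ranks = np.empty(n)
        ranks[order] = np.arange(n, dtype=float)
        for v in np.unique(fit):
            mask = fit == v
            if mask.sum() > 1:
                ranks[mask] = ranks[mask].mean()
        if n == 1:
            return np.ones(1)
        return (2.0 - sp) / n + 2.0 * ranks * (sp - 1.0) / (n * (n - 1.0))

    if scheme == "tournament":
        t = int(params.get("tournament_size", 2))
        if not 1 <= t <= n:
            raise ValueError("tournament size must lie in [1, n]")
        return _tournament_probabilities(fit, t)

    raise ValueError(f"unknown selection scheme {scheme!r}")


def _tournament_probabilities(fit: np.ndarray, t: int) -> np.ndarray:
    """Exact win probability of one size-``t`` tournament (distinct
    contestants drawn uniformly; the max-fitness contestant wins, ties
    broken uniformly)."""
    n = fit.size
    denom = math.comb(n, t)
    probs = np.zeros(n)
    for i in range(n):
        worse = int(np.sum(fit < fit[i]))
        equal = int(np.sum(fit == fit[i])) - 1
        p = 0.0
        for a in range(0, min(equal, t - 1) + 1):
            if t - 1 - a > worse:
                continue
            p += math.comb(equal, a) * math.comb(worse, t - 1 - a) / ((a + 1) * denom)
        probs[i] = p
    return probs


def sample_selection(
    objectives: np.ndarray,
    scheme: str,
    params: Optional[dict],
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``size`` source indices according to a selection scheme.

    For proportional/rank/disruptive this is a roulette over the
    scheme's probability vector; for tournament it simulates actual
    size-``t`` tournaments (the probability vector is its exact law).
    """
    params = params or {}
    if scheme == "tournament":
        fit = _fitness_array(objectives)
        n = fit.size
        t = int(params.get("tournament_size", 2))
        out = np.empty(size, dtype=np.int64)
        for s in range(size):
            contestants = rng.choice(n, size=t, replace=False)
            f = fit[contestants]
            winners = contestants[f == f.max()]
            out[s] = winners[0] if winners.size == 1 else rng.choice(winners)
        return out
    probs = selection_probabilities(objectives, scheme, params)
    return rng.choice(len(probs), size=size, p=probs)


# ---------------------------------------------------------------------------
# phases


def scout_phase(
    state: ColonyState,
    config: ColonyConfig,
    fn: ObjectiveFunction,
    rng: np.random.Generator,
    reinit_box: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> ColonyState:
    """Re-draw every source whose trial counter exceeds ``limit``
    uniformly inside ``reinit_box`` (default: the global search box).
    The incumbent best memory is never touched."""
    lower, upper = reinit_box if reinit_box is not None else (state.lower, state.upper)
    for i in range(state.sn):
        if state.trials[i] > config.limit:
            if state.fe_count >= config.max_fes:
                break
            x = rng.uniform(lower, upper)
            f = _evaluate(fn, x, rng)
            state.positions[i] = x
            state.objectives[i] = f
            state.fitness[i] = fitness_transform(f)
            state.trials[i] = 0
            state.fe_count += 1
            if f < state.best_objective:
                state.best_objective = float(f)
                state.best_position = x.copy()
    return state


def _working_phase(
    state: ColonyState,
    config: ColonyConfig,
    fn: ObjectiveFunction,
    rng: np.random.Generator,
    chosen: np.ndarray,
) -> None:
    """Shared employed/onlooker body: for each index in ``chosen``,
    propose a one-coordinate move, evaluate, greedily replace.  RNG
    draws are batched per phase (one array each of j, k, phi)."""
    sn, dim = state.sn, state.dim
    m = chosen.size
    js = rng.integers(0, dim, size=m)
    ks = rng.integers(0, sn - 1, size=m)
    phis = rng.uniform(-1.0, 1.0, size=m)
    for idx in range(m):
        if state.fe_count >= config.max_fes:
            return
        i = int(chosen[idx])
        j = int(js[idx])
        k = int(ks[idx])
        if k >= i:
            k += 1
        v = state.positions[i].copy()
        vj = v[j] + phis[idx] * (v[j] - state.positions[k, j])
        # midpoint repair, single coordinate
        if vj > state.upper[j]:
            vj = (state.positions[i, j] + state.upper[j]) / 2.0
        elif vj < state.lower[j]:
            vj = (state.positions[i, j] + state.lower[j]) / 2.0
        v[j] = vj
        f = _evaluate(fn, v, rng)
        state.fe_count += 1
        if f < state.best_objective:
            state.best_objective = float(f)
            state.best_position = v.copy()
        if f < state.objectives[i]:
            state.positions[i] = v
            state.objectives[i] = f
            state.fitness[i] = fitness_transform(f)
            state.trials[i] = 0
        else:
            state.trials[i] += 1


def run_abc(
    config: ColonyConfig,
    fn: ObjectiveFunction,
    rng: Optional[np.random.Generator] = None,
) -> RunResult:
    """Run canonical ABC (employed -> onlooker -> scout per generation)
    until the FE budget or the generation cap is exhausted."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = initialize_colony(config, fn, rng)
    traj_fe = [state.fe_count]
    traj_best = [state.best_objective]

    while state.fe_count < config.max_fes and state.iter < config.max_iter:
        # employed phase: one candidate per source
        _working_phase(state, config, fn, rng, np.arange(state.sn))
        # onlooker phase: SN picks by the configured selection scheme
        if state.fe_count < config.max_fes:
            chosen = sample_selection(
                state.objectives, config.selection, config.selection_params, state.sn, rng
            )
            _working_phase(state, config, fn, rng, chosen)
        # scout phase
        if state.fe_count < config.max_fes:
            scout_phase(state, config, fn, rng)
        state.iter += 1
        traj_fe.append(state.fe_count)
        traj_best.append(state.best_objective)

    return RunResult(
        best_position=state.best_position.copy(),
        best_objective=float(state.best_objective),
        fes_used=int(state.fe_count),
        n_iter=int(state.iter),
        trajectory_fe=np.asarray(traj_fe, dtype=np.int64),
        trajectory_best=np.asarray(traj_best, dtype=float),
    )
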
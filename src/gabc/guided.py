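"""Belief-space guided ABC (GABC).

Extends the canonical colony with two ideas borrowed from cultural
algorithms and particle swarm optimization:

* **Normative knowledge** — a per-dimension promising interval
  ``(l_i, u_i)`` with the objective quality ``(L_i, U_i)`` observed at
  each bound, maintained in a belief space alongside the population.
  The interval expands when a solution falls outside it and shrinks
  toward solutions whose objective beats the bound quality.  Scouts
  re-initialize inside the current interval instead of the global box,
  which is how the belief space "guides the search region".
* **Global-best guidance** — employed and onlooker candidates add a
  pull toward the incumbent best:
  ``v_j = x_ij + phi_ik (x_ij - x_kj) + phi_b (x*_j - x_ij)`` with
  ``phi_ik ~ U[-1, 1]`` and an iteration-adaptive weight
  ``phi_b = min(alpha + beta * iter / max_iter, C)``, ``alpha ~ U(0,1)``.
  Early in the run the weight is small on average (exploration); it
  grows linearly with the generation count (exploitation).

Out-of-box candidates are repaired by the midpoint rule (midpoint of
the parent coordinate and the violated bound).

With the guidance term disabled (``gbest_term=False``, which also skips
the alpha draws) and belief-space scouting off, the generator reduces
exactly to the canonical proposal, and :func:`run_gabc` reproduces
:func:`gabc.colony.run_abc` bit-for-bit under a shared seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .benchmarks import ObjectiveFunction
from .colony import (
    ColonyConfig,
    ColonyState,
    RunResult,
    _evaluate,
    fitness_transform,
    initialize_colony,
    _repair_midpoint,
    sample_selection,
)

__all__ = [
    "GuidanceParams",
    "NormativeKnowledge",
    "init_normative",
    "update_normative",
    "adaptive_phi",
    "guided_candidate",
    "repair_bounds",
    "run_gabc",
]

#: interval width below which scout re-draws fall back to the global box
DEGENERATE_WIDTH = 1e-12


@dataclass
class GuidanceParams:
    """Tunables of the guided search.

    ``c`` caps the guidance weight (default 1.5); ``beta`` is the slope
    of the iteration-adaptive term (default 0.5).  ``scout_in_belief``
    re-draws scouts inside the normative interval; ``gbest_term=False``
    switches the global-best pull off entirely (no alpha draws), which
    recovers the canonical proposal.  ``feed`` selects what the belief
    space ingests each generation: accepted improvements plus the
    incumbent best (``"accepted_and_best"``, default) or the incumbent
    best only (``"best_only"``).
    """

    c: float = 1.5
    beta: float = 0.5
    scout_in_belief: bool = True
    gbest_term: bool = True
    feed: str = "accepted_and_best"

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be nonnegative")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.feed not in ("accepted_and_best", "best_only"):
            raise ValueError(f"unknown feed mode {self.feed!r}")


@dataclass
class NormativeKnowledge:
    """Per-dimension belief interval with bound-quality objectives.

    ``l_obj``/``u_obj`` start at ``+inf`` (an unset sentinel treated as
    worse than any finite objective), so the first update always
    succeeds.
    """

    lower: np.ndarray
    upper: np.ndarray
    l_obj: np.ndarray
    u_obj: np.ndarray
    box_lower: np.ndarray
    box_upper: np.ndarray

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def init_normative(box: tuple[np.ndarray, np.ndarray]) -> NormativeKnowledge:
    """Start the belief interval at the full search box with unset
    bound qualities."""
    lo = np.asarray(box[0], dtype=float)
    hi = np.asarray(box[1], dtype=float)
    if lo.shape != hi.shape or np.any(lo > hi):
        raise ValueError("invalid search box")
    return NormativeKnowledge(
        lower=lo.copy(),
        upper=hi.copy(),
        l_obj=np.full(lo.shape, np.inf),
        u_obj=np.full(lo.shape, np.inf),
        box_lower=lo.copy(),
        box_upper=hi.copy(),
    )


def update_normative(nk: NormativeKnowledge, x: np.ndarray, f_x: float) -> NormativeKnowledge:
    """Cultural-algorithm normative update.

    Per dimension: the lower bound moves to ``x_i`` when ``x_i`` falls
    at or below it (expansion) *or* when ``f_x`` beats the lower bound
    quality (shrink toward a better solution); symmetrically for the
    upper bound.  Bounds are then re-ordered if they crossed and
    clamped to the global box.  Idempotent for a repeated ``(x, f_x)``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != nk.lower.shape:
        raise ValueError("dimension mismatch between update point and belief space")
    f_x = float(f_x)

    low_fire = (x <= nk.lower) | (f_x < nk.l_obj)
    nk.lower = np.where(low_fire, x, nk.lower)
    nk.l_obj = np.where(low_fire, f_x, nk.l_obj)

    up_fire = (x >= nk.upper) | (f_x < nk.u_obj)
    nk.upper = np.where(up_fire, x, nk.upper)
    nk.u_obj = np.where(up_fire, f_x, nk.u_obj)

    crossed = nk.lower > nk.upper
    if crossed.any():
        lo = np.where(crossed, nk.upper, nk.lower)
        hi = np.where(crossed, nk.lower, nk.upper)
        lo_q = np.where(crossed, nk.u_obj, nk.l_obj)
        hi_q = np.where(crossed, nk.l_obj, nk.u_obj)
        nk.lower, nk.upper, nk.l_obj, nk.u_obj = lo, hi, lo_q, hi_q

    np.clip(nk.lower, nk.box_lower, nk.box_upper, out=nk.lower)
    np.clip(nk.upper, nk.box_lower, nk.box_upper, out=nk.upper)
    return nk


def adaptive_phi(iter: int, max_iter: int, alpha: float, params: GuidanceParams) -> float:
    """Iteration-adaptive guidance weight
    ``min(alpha + beta * iter / max_iter, C)``."""
    if max_iter <= 0:
        raise ValueError("max_iter must be positive")
    if not 0 <= iter <= max_iter:
        raise ValueError("iter must lie in [0, max_iter]")
    return min(alpha + params.beta * iter / max_iter, params.c)


def repair_bounds(
    v: np.ndarray, x: np.ndarray, box: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Midpoint boundary repair: replace each out-of-box coordinate of
    ``v`` with the midpoint of the parent coordinate ``x`` and the
    violated bound."""
    lower = np.asarray(box[0], dtype=float)
    upper = np.asarray(box[1], dtype=float)
    return _repair_midpoint(np.asarray(v, dtype=float).copy(), np.asarray(x, dtype=float), lower, upper)


def guided_candidate(
    state: ColonyState, i: int, phi_bi: float, rng: np.random.Generator
) -> np.ndarray:
    """Global-best-guided one-coordinate move for source ``i``,
    repaired to the search box."""
    sn = state.sn
    if sn < 2:
        raise ValueError("need at least two sources for a guided move")
    j = int(rng.integers(state.dim))
    k = int(rng.integers(sn - 1))
    if k >= i:
        k += 1
    phi_ik = rng.uniform(-1.0, 1.0)
    v = state.positions[i].copy()
    v[j] = (
        v[j]
        + phi_ik * (v[j] - state.positions[k, j])
        + phi_bi * (state.best_position[j] - v[j])
    )
    return _repair_midpoint(v, state.positions[i], state.lower, state.upper)


# ---------------------------------------------------------------------------
# run loop


def _guided_phase(
    state: ColonyState,
    config: ColonyConfig,
    params: GuidanceParams,
    fn: ObjectiveFunction,
    rng: np.random.Generator,
    chosen: np.ndarray,
    phi_base: float,
    accepted: list,
) -> None:
    """Employed/onlooker body with the guidance term.  RNG draws are
    batched per phase in the same order as the canonical loop (j, k,
    phi_ik, then — only when guidance is on — alpha)."""
    sn, dim = state.sn, state.dim
    m = chosen.size
    js = rng.integers(0, dim, size=m)
    ks = rng.integers(0, sn - 1, size=m)
    phis = rng.uniform(-1.0, 1.0, size=m)
    if params.gbest_term:
        alphas = rng.uniform(0.0, 1.0, size=m)
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
        if params.gbest_term:
            phi_b = min(alphas[idx] + phi_base, params.c)
            vj += phi_b * (state.best_position[j] - v[j])
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
            accepted.append((v, f))
        else:
            state.trials[i] += 1


def _scout_in_belief(
    state: ColonyState,
    config: ColonyConfig,
    params: GuidanceParams,
    nk: NormativeKnowledge,
    fn: ObjectiveFunction,
    rng: np.random.Generator,
) -> None:
    if params.scout_in_belief:
        ok = nk.width >= DEGENERATE_WIDTH
        lower = np.where(ok, nk.lower, state.lower)
        upper = np.where(ok, nk.upper, state.upper)
    else:
        lower, upper = state.lower, state.upper
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


def run_gabc(
    config: ColonyConfig,
    params: GuidanceParams,
    fn: ObjectiveFunction,
    rng: Optional[np.random.Generator] = None,
) -> RunResult:
    """Run the belief-space guided colony.

    As :func:`gabc.colony.run_abc`, but candidates carry the
    global-best pull with the iteration-adaptive weight, accepted
    improvements and the incumbent best feed the normative interval
    each generation, and scouts re-draw inside that interval.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = initialize_colony(config, fn, rng)
    nk = init_normative((fn.lower, fn.upper))
    traj_fe = [state.fe_count]
    traj_best = [state.best_objective]

    while state.fe_count < config.max_fes and state.iter < config.max_iter:
        phi_base = params.beta * state.iter / config.max_iter
        accepted: list = []
        _guided_phase(state, config, params, fn, rng, np.arange(state.sn), phi_base, accepted)
        if state.fe_count < config.max_fes:
            chosen = sample_selection(
                state.objectives, config.selection, config.selection_params, state.sn, rng
            )
            _guided_phase(state, config, params, fn, rng, chosen, phi_base, accepted)
        if state.fe_count < config.max_fes:
            _scout_in_belief(state, config, params, nk, fn, rng)
        if params.feed == "accepted_and_best":
            for v, f in accepted:
                update_normative(nk, v, f)
        update_normative(nk, state.best_position, state.best_objective)
        state.iter += 1
        traj_fe.append(state.fe_count)
        traj_best.append(state.best_objective)

    result = RunResult(
        best_position=state.best_position.copy(),
        best_objective=float(state.best_objective),
        fes_used=int(state.fe_count),
        n_iter=int(state.iter),
        trajectory_fe=np.asarray(traj_fe, dtype=np.int64),
        trajectory_best=np.asarray(traj_best, dtype=float),
    )
    result.normative = nk  # belief interval at termination, for inspection
    return result
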
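"""Canonical colony machinery: fitness transform, phases, selection
schemes (with a Monte-Carlo frequency oracle), and full ABC runs."""

import numpy as np
import pytest

from gabc.benchmarks import ObjectiveFunction, get_function
from gabc.colony import (
    ColonyConfig,
    ColonyState,
    FoodSource,
    fitness_transform,
    greedy_replace,
    initialize_colony,
    neighborhood_candidate,
    run_abc,
    sample_selection,
    scout_phase,
    selection_probabilities,
)


def _zero_width_function(c, dim):
    return ObjectiveFunction(
        name="const-box", formula_id="test", dim=dim,
        lower=np.full(dim, c), upper=np.full(dim, c),
        f_star=None, x_star=None, _fn=lambda z: float(z @ z),
    )


def _make_state(positions, objectives, best=None):
    positions = np.asarray(positions, dtype=float)
    objectives = np.asarray(objectives, dtype=float)
    fitness = np.where(objectives >= 0, 1 / (1 + objectives), 1 + np.abs(objectives))
    b = int(np.argmin(objectives))
    return ColonyState(
        positions=positions, objectives=objectives, fitness=fitness,
        trials=np.zeros(len(objectives), dtype=np.int64),
        best_position=positions[b].copy() if best is None else np.asarray(best, float),
        best_objective=float(objectives[b]),
        fe_count=len(objectives),
        lower=np.full(positions.shape[1], -10.0),
        upper=np.full(positions.shape[1], 10.0),
    )


# ---------------------------------------------------------------------------
# fitness transform


@pytest.mark.parametrize(
    "f,expected", [(0.0, 1.0), (3.0, 0.25), (-0.5, 1.5), (-0.0, 1.0)]
)
def test_fitness_transform_values(f, expected):
    assert fitness_transform(f) == expected


def test_fitness_transform_monotone_and_positive(rng):
    fs = np.sort(rng.uniform(-50, 50, size=200))
    fits = [fitness_transform(f) for f in fs]
    assert all(v > 0 for v in fits)
    assert all(a >= b for a, b in zip(fits, fits[1:]))


def test_fitness_transform_rejects_nonfinite():
    with pytest.raises(ValueError):
        fitness_transform(float("inf"))
    with pytest.raises(ValueError):
        fitness_transform(float("nan"))


# ---------------------------------------------------------------------------
# initialization


def test_initialize_in_box_and_counts(rng):
    fn = get_function("f5", 4)
    cfg = ColonyConfig(sn=20)
    state = initialize_colony(cfg, fn, rng)
    assert state.positions.shape == (20, 4)
    assert state.fe_count == 20
    assert np.all(state.positions >= fn.lower) and np.all(state.positions <= fn.upper)
    assert state.best_objective == state.objectives.min()
    assert np.all(state.trials == 0)


def test_initialize_zero_width_box(rng):
    fn = _zero_width_function(2.5, 3)
    state = initialize_colony(ColonyConfig(sn=5, max_fes=5), fn, rng)
    assert np.all(state.positions == 2.5)


def test_initialize_deterministic():
    fn = get_function("f1", 3)
    cfg = ColonyConfig(sn=10)
    s1 = initialize_colony(cfg, fn, np.random.default_rng(5))
    s2 = initialize_colony(cfg, fn, np.random.default_rng(5))
    assert np.array_equal(s1.positions, s2.positions)
    assert np.array_equal(s1.objectives, s2.objectives)


def test_config_validation():
    with pytest.raises(ValueError):
        ColonyConfig(sn=1)
    with pytest.raises(ValueError):
        ColonyConfig(limit=0)
    with pytest.raises(ValueError):
        ColonyConfig(sn=20, max_fes=10)
    with pytest.raises(ValueError):
        ColonyConfig(selection="magic")


# ---------------------------------------------------------------------------
# neighborhood moves and greedy replacement


def test_neighborhood_changes_at_most_one_coordinate(rng):
    state = _make_state(rng.uniform(-5, 5, size=(6, 4)), rng.uniform(0, 10, size=6))
    for _ in range(1000):
        v = neighborhood_candidate(state, 2, rng)
        assert np.sum(v != state.positions[2]) <= 1
        assert np.all(v >= state.lower) and np.all(v <= state.upper)


def test_neighborhood_identical_population_is_fixed_point(rng):
    state = _make_state(np.ones((4, 3)), np.full(4, 2.0))
    for _ in range(50):
        assert np.array_equal(neighborhood_candidate(state, 1, rng), state.positions[1])


def test_neighborhood_zero_phi_identity(stub_rng_factory):
    state = _make_state([[1.0, 2.0], [3.0, 4.0]], [1.0, 2.0])
    v = neighborhood_candidate(state, 0, stub_rng_factory(integers_values=[1, 0], uniform_value=0.0))
    assert np.array_equal(v, state.positions[0])


def test_neighborhood_requires_partner(rng):
    state = _make_state([[0.0, 0.0]], [1.0])
    with pytest.raises(ValueError):
        neighborhood_candidate(state, 0, rng)


def test_greedy_replace_rules():
    src = FoodSource(np.array([1.0]), objective=10.0, fitness=fitness_transform(10.0), trial=3)
    adopted = greedy_replace(src, np.array([2.0]), 5.0)
    assert adopted.objective == 5.0 and adopted.trial == 0
    assert adopted.fitness == fitness_transform(5.0)

    src = FoodSource(np.array([1.0]), objective=5.0, fitness=fitness_transform(5.0), trial=3)
    kept = greedy_replace(src, np.array([2.0]), 10.0)
    assert kept.objective == 5.0 and kept.trial == 4

    tied = greedy_replace(kept, np.array([2.0]), 5.0)  # equal objective keeps incumbent
    assert tied.objective == 5.0 and tied.trial == 5


# ---------------------------------------------------------------------------
# selection schemes


def test_proportional_probabilities_closed_form():
    # objectives 0 and -2 have fitness 1 and 3
    p = selection_probabilities([0.0, -2.0], "proportional")
    assert np.allclose(p, [0.25, 0.75], atol=1e-15)


def test_disruptive_probabilities_closed_form():
    # fitness 1, 2, 3 -> deviations 1, 0, 1
    p = selection_probabilities([0.0, -1.0, -2.0], "disruptive")
    assert np.allclose(p, [0.5, 0.0, 0.5], atol=1e-15)


def test_disruptive_uniform_fallback():
    p = selection_probabilities([1.0, 1.0, 1.0], "disruptive")
    assert np.allclose(p, [1 / 3] * 3)


def test_tournament_probabilities_enumeration():
    # fitness 3, 2, 1: of the three possible pairs the top individual
    # wins {0,1} and {0,2}, the middle one wins {1,2}
    p = selection_probabilities([-2.0, -1.0, 0.0], "tournament", {"tournament_size": 2})
    assert np.allclose(p, [2 / 3, 1 / 3, 0.0], atol=1e-15)


def test_rank_probabilities_closed_form():
    # three sources ordered worst -> best with selective pressure 1.5
    p = selection_probabilities([3.0, 2.0, 1.0], "rank", {"sp": 1.5})
    assert np.allclose(p, [1 / 6, 1 / 3, 1 / 2], atol=1e-15)


@pytest.mark.parametrize("scheme,params", [
    ("proportional", None),
    ("rank", {"sp": 1.5}),
    ("disruptive", None),
    ("tournament", {"tournament_size": 2}),
    ("tournament", {"tournament_size": 4}),
])
def test_probabilities_normalized(scheme, params, rng):
    for _ in range(20):
        obj = rng.uniform(-5, 5, size=8)
        p = selection_probabilities(obj, scheme, params)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) <= 1e-12


def test_probabilities_empty_error():
    with pytest.raises(ValueError):
        selection_probabilities([], "proportional")


def test_sample_selection_matches_probabilities(rng):
    """sample_selection frequencies agree with the probability vector
    within 3 standard errors (10^5 draws per scheme here; the full
    10^6-draw check lives in the acceptance suite)."""
    obj = np.array([0.5, -1.0, 2.0, -0.3, 1.1, 0.0])
    n_draws = 100_000
    for scheme, params in [
        ("proportional", None),
        ("rank", {"sp": 1.5}),
        ("disruptive", None),
        ("tournament", {"tournament_size": 2}),
    ]:
        p = selection_probabilities(obj, scheme, params)
        draws = sample_selection(obj, scheme, params, n_draws, rng)
        freq = np.bincount(draws, minlength=len(obj)) / n_draws
        se = np.sqrt(p * (1 - p) / n_draws)
        assert np.all(np.abs(freq - p) <= 3 * se + 1e-12), (scheme, freq, p)


# ---------------------------------------------------------------------------
# scout phase


def test_scout_noop_below_limit(rng):
    fn = get_function("f1", 3)
    cfg = ColonyConfig(sn=4, limit=5, max_fes=1000)
    state = initialize_colony(cfg, fn, rng)
    before = state.positions.copy()
    scout_phase(state, cfg, fn, rng)
    assert np.array_equal(state.positions, before)


def test_scout_redraws_over_limit_and_keeps_best_memory(rng):
    fn = get_function("f1", 3)
    cfg = ColonyConfig(sn=4, limit=5, max_fes=1000)
    state = initialize_colony(cfg, fn, rng)
    # make source 0 the population best AND over-limit
    state.positions[0] = 0.0
    state.objectives[0] = 0.0
    state.trials[0] = cfg.limit + 1
    state.best_position = state.positions[0].copy()
    state.best_objective = 0.0
    old_fe = state.fe_count
    scout_phase(state, cfg, fn, rng)
    assert state.trials[0] == 0
    assert state.fe_count == old_fe + 1
    assert np.all(state.positions[0] >= fn.lower) and np.all(state.positions[0] <= fn.upper)
    assert state.best_objective == 0.0  # memory survives abandonment


# ---------------------------------------------------------------------------
# full runs


def test_run_abc_solves_low_dim_sphere():
    fn = get_function("f1", 2)
    result = run_abc(ColonyConfig(max_fes=50_000), fn, np.random.default_rng(0))
    assert result.best_objective <= 1e-10


def test_run_with_budget_equal_to_init_returns_best_draw():
    fn = get_function("f1", 3)
    cfg = ColonyConfig(sn=20, max_fes=20)
    rng = np.random.default_rng(9)
    result = run_abc(cfg, fn, rng)
    init = initialize_colony(cfg, fn, np.random.default_rng(9))
    assert result.best_objective == init.objectives.min()
    assert result.fes_used == 20


def test_run_abc_deterministic_and_bounded():
    fn = get_function("f5", 5)
    cfg = ColonyConfig(max_fes=3000)
    r1 = run_abc(cfg, fn, np.random.default_rng(3))
    r2 = run_abc(cfg, fn, np.random.default_rng(3))
    assert r1.best_objective == r2.best_objective
    assert np.array_equal(r1.best_position, r2.best_position)
    assert np.array_equal(r1.trajectory_best, r2.trajectory_best)
    assert r1.fes_used <= cfg.max_fes + cfg.sn


def test_trajectory_monotone_nonincreasing():
    fn = get_function("f4", 5)
    r = run_abc(ColonyConfig(max_fes=5000), fn, np.random.default_rng(4))
    assert np.all(np.diff(r.trajectory_best) <= 0)
    assert np.all(np.diff(r.trajectory_fe) >= 0)


@pytest.mark.parametrize("scheme", ["rank", "disruptive", "tournament"])
def test_selection_variants_run(scheme):
    fn = get_function("f1", 3)
    cfg = ColonyConfig(max_fes=2000, selection=scheme)
    r = run_abc(cfg, fn, np.random.default_rng(1))
    assert np.isfinite(r.best_objective)
    assert r.best_objective < 100.0  # improves well beyond a random draw


def test_noisy_function_run():
    fn = get_function("f10", 3)
    r = run_abc(ColonyConfig(max_fes=2000), fn, np.random.default_rng(2))
    assert np.isfinite(r.best_objective)
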
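"""Multi-run experiment harness.

Runs an ABC-family optimizer ``n_runs`` times with per-run seeds
``base_seed + run_index`` and aggregates the final objectives into the
standard batch statistics (Best / Mean / Median / Worst / Std, sample
standard deviation with the ``n-1`` denominator), the convergence
probability (fraction of runs ending within ``tolerance`` of the known
global minimum), and the mean number of function evaluations needed to
first reach a target accuracy (censored runs excluded and counted).

Results round-trip losslessly through a per-run CSV plus a JSON summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .benchmarks import get_function, native_dim
from .colony import ColonyConfig, RunResult, run_abc
from .guided import GuidanceParams, run_gabc

__all__ = [
    "ALGORITHMS",
    "ExperimentConfig",
    "ExperimentSummary",
    "run_single",
    "run_batch",
    "summarize",
    "convergence_probability",
    "fes_to_accuracy",
    "write_results",
    "read_results",
]

#: algorithm id -> onlooker selection scheme ("gabc" uses the guided engine)
ALGORITHMS = {
    "abc": "proportional",
    "rabc": "rank",
    "dabc": "disruptive",
    "tabc": "tournament",
    "gabc": "proportional",
}

_RUN_COLUMNS = ["run_id", "seed", "final_objective", "fes_used", "converged"]


@dataclass
class ExperimentConfig:
    """One experiment cell: an algorithm on a function at a dimension.

    ``tolerance`` is the convergence-counting epsilon (default 5e-7;
    the headline suite uses 1e-6).  ``accuracy`` is the FEs-to-accuracy
    target; when ``None`` it defaults to ``tolerance``.
    """

    algorithm: str
    function: str
    dim: int
    n_runs: int = 30
    base_seed: int = 0
    fe_budget: int = 50_000
    max_iter: int = 2500
    sn: int = 20
    limit: int = 30
    tolerance: float = 5e-7
    accuracy: Optional[float] = None
    guidance: GuidanceParams = field(default_factory=GuidanceParams)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; known: {sorted(ALGORITHMS)}"
            )
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class ExperimentSummary:
    """Aggregated outcome of a batch of independent runs."""

    algorithm: str
    function: str
    dim: int
    n_runs: int
    base_seed: int
    fe_budget: int
    tolerance: float
    best: float
    mean: float
    median: float
    worst: float
    std: float
    convergence_probability: Optional[float]
    mean_fes_to_accuracy: Optional[float]
    n_censored: Optional[int]
    runs: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "algorithm", "function", "dim", "n_runs", "base_seed", "fe_budget",
            "tolerance", "best", "mean", "median", "worst", "std",
            "convergence_probability", "mean_fes_to_accuracy", "n_censored",
        )}
        return d


def run_single(cfg: ExperimentConfig, seed: int) -> RunResult:
    """One seeded run of the configured algorithm/function cell."""
    dim = native_dim(cfg.function, cfg.dim)
    fn = get_function(cfg.function, dim)
    colony = ColonyConfig(
        sn=cfg.sn,
        limit=cfg.limit,
        max_iter=cfg.max_iter,
        max_fes=cfg.fe_budget,
        selection=ALGORITHMS[cfg.algorithm],
    )
    rng = np.random.default_rng(seed)
    if cfg.algorithm == "gabc":
        return run_gabc(colony, cfg.guidance, fn, rng)
    return run_abc(colony, fn, rng)


def run_batch(cfg: ExperimentConfig) -> ExperimentSummary:
    """Run ``n_runs`` independent seeded runs and aggregate them.

    Deterministic given ``base_seed``; run ``r`` uses seed
    ``base_seed + r``, so the batch is invariant to execution order.
    """
    dim = native_dim(cfg.function, cfg.dim)
    fn = get_function(cfg.function, dim)
    accuracy = cfg.accuracy if cfg.accuracy is not None else cfg.tolerance

    records = []
    fes_acc: list[float] = []
    n_censored = 0
    for r in range(cfg.n_runs):
        seed = cfg.base_seed + r
        result = run_single(cfg, seed)
        converged = (
            fn.f_star is not None
            and abs(result.best_objective - fn.f_star) < cfg.tolerance
        )
        records.append(
            {
                "run_id": r,
                "seed": seed,
                "final_objective": result.best_objective,
                "fes_used": result.fes_used,
                "converged": bool(converged),
            }
        )
        if fn.f_star is not None:
            hit = fes_to_accuracy(
                (result.trajectory_fe, result.trajectory_best), fn.f_star, accuracy
            )
            if hit is None:
                n_censored += 1
            else:
                fes_acc.append(hit)

    runs = pd.DataFrame.from_records(records, columns=_RUN_COLUMNS)
    finals = runs["final_objective"].to_numpy()
    best, mean, median, worst, std = summarize(finals)
    conv = (
        convergence_probability(finals, fn.f_star, cfg.tolerance)
        if fn.f_star is not None
        else None
    )
    return ExperimentSummary(
        algorithm=cfg.algorithm,
        function=cfg.function,
        dim=dim,
        n_runs=cfg.n_runs,
        base_seed=cfg.base_seed,
        fe_budget=cfg.fe_budget,
        tolerance=cfg.tolerance,
        best=best,
        mean=mean,
        median=median,
        worst=worst,
        std=std,
        convergence_probability=conv,
        mean_fes_to_accuracy=(float(np.mean(fes_acc)) if fes_acc else None),
        n_censored=(n_censored if fn.f_star is not None else None),
        runs=runs,
    )


def summarize(finals: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(best, mean, median, worst, std) of final objectives; sample
    standard deviation (``n-1`` denominator, 0 for a single run)."""
    x = np.asarray(finals, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one final objective")
    std = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return float(x.min()), float(x.mean()), float(np.median(x)), float(x.max()), std


def convergence_probability(finals: Sequence[float], f_star: float, epsilon: float) -> float:
    """Fraction of runs whose final objective lies within ``epsilon``
    of the known global minimum."""
    if f_star is None:
        raise ValueError("convergence probability requires a known global minimum")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    x = np.asarray(finals, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one final objective")
    return float(np.mean(np.abs(x - f_star) < epsilon))


def fes_to_accuracy(
    trajectory: tuple[Sequence[int], Sequence[float]], f_star: float, accuracy: float
) -> Optional[int]:
    """Smallest recorded FE count at which the best-so-far objective is
    within ``accuracy`` of ``f_star``; ``None`` when never reached
    (censored).  The trajectory is sampled at generation boundaries and
    no interpolation is performed."""
    fe = np.asarray(trajectory[0])
    best = np.asarray(trajectory[1], dtype=float)
    if fe.size != best.size:
        raise ValueError("trajectory arrays must have equal length")
    if np.any(np.diff(fe) < 0):
        raise ValueError("trajectory must be sorted by FE count")
    hits = np.nonzero(best - f_star <= accuracy)[0]
    return int(fe[hits[0]]) if hits.size else None


# ---------------------------------------------------------------------------
# persistence


def write_results(summary: ExperimentSummary, path: str | Path) -> None:
    """Write ``<path>.json`` (summary) and ``<path>_runs.csv`` (per-run
    records).  Numeric output uses 17 significant digits so a re-read
    is bit-exact."""
    if summary.runs.empty:
        raise ValueError("refusing to write an empty record set")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    summary.runs.to_csv(path.with_suffix(".csv"), index=False, float_format="%.17g")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)


def read_results(path: str | Path) -> ExperimentSummary:
    """Round-trip counterpart of :func:`write_results`."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    try:
        runs = pd.read_csv(csv_path)
    except Exception as exc:  # noqa: BLE001 - surfaced with file context
        raise ValueError(f"cannot parse {csv_path}: {exc}") from exc
    missing = [c for c in _RUN_COLUMNS if c not in runs.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing column(s) {missing}")
    with open(json_path) as fh:
        meta = json.load(fh)
    return ExperimentSummary(runs=runs, **meta)
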
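"""Aggregate 10 independent seeded runs into batch statistics.

The harness reports Best/Mean/Median/Worst/Std of the final objectives,
the convergence probability (fraction of runs ending within the
tolerance of the known minimum), and the mean number of function
evaluations needed to first reach that accuracy.
"""

from gabc import ExperimentConfig, run_batch

cfg = ExperimentConfig(
    algorithm="gabc",
    function="ackley",
    dim=10,
    n_runs=10,
    base_seed=42,
    fe_budget=20_000,
    tolerance=1e-6,
)
s = run_batch(cfg)

print(f"{cfg.algorithm} on {cfg.function} (D={s.dim}), {s.n_runs} runs, budget {s.fe_budget} FEs")
print(f"  best   {s.best:.3e}")
print(f"  mean   {s.mean:.3e}   (std {s.std:.3e})")
print(f"  median {s.median:.3e}")
print(f"  worst  {s.worst:.3e}")
print(f"  convergence probability at 1e-6: {s.convergence_probability:.0%}")
print(f"  mean FEs to reach 1e-6: {s.mean_fes_to_accuracy:.0f} ({s.n_censored} runs never did)")
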
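"""Benchmark objective functions for colony-based optimizers.

A registry of twenty classical continuous test functions (Sphere,
Rosenbrock, Rastrigin, Ackley, Griewank, the Schwefel max/abs-product
variants, penalized functions, and five rotated counterparts), each with
a documented default search box and, where known, the global minimum
value and location.  Functions are addressable by short id (``f1`` ...
``f20``) or by name.

Two functions deliberately deviate from their most common textbook
form (see ``docs/methods.md`` for the rationale):

* ``step`` (f9) is the *continuous* paired-term form
  ``sum_{i<d} (x_i+0.5)^2 + (x_{i+1}+0.5)^2`` (no floor), minimized at
  ``x = -0.5``;
* ``pathological`` (f19) is ``sum_i -x_i^2 sin(x_i)``, whose global
  minimum has no simple closed form and is recorded as unknown.

The penalized functions (f12, f13) use the standard literature forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "ObjectiveFunction",
    "RotationSpec",
    "make_rotation",
    "get_function",
    "default_box",
    "list_functions",
    "registry_json",
    "FORMULA_IDS",
]


# ---------------------------------------------------------------------------
# rotation


@dataclass(frozen=True)
class RotationSpec:
    """A seeded orthogonal matrix used for rotated benchmark variants."""

    seed: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("rotation matrix must be square")
        if not np.allclose(m @ m.T, np.eye(m.shape[0]), atol=1e-10):
            raise ValueError("rotation matrix is not orthogonal")


def make_rotation(seed: int, dim: int) -> RotationSpec:
    """Deterministic orthogonal matrix: QR of a seeded standard-normal
    matrix with the diagonal sign fixed (uniform over the orthogonal
    group for a given seed)."""
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((dim, dim))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return RotationSpec(seed=seed, matrix=q)


# ---------------------------------------------------------------------------
# raw formulas (operate on the, possibly rotated, coordinate vector z)


def _sphere(z: np.ndarray) -> float:
    return float(z @ z)


def _beale(z: np.ndarray) -> float:
    x1, x2 = z
    return float(
        (1.5 - x1 + x1 * x2) ** 2
        + (2.25 - x1 + x1 * x2**2) ** 2
        + (2.625 - x1 + x1 * x2**3) ** 2
    )


def _rosenbrock(z: np.ndarray) -> float:
    return float(np.sum(100.0 * (z[1:] - z[:-1] ** 2) ** 2 + (z[:-1] - 1.0) ** 2))


def _griewank(z: np.ndarray) -> float:
    i = np.arange(1, z.size + 1)
    return float(np.sum(z * z) / 4000.0 - np.prod(np.cos(z / np.sqrt(i))) + 1.0)


def _rastrigin(z: np.ndarray) -> float:
    return float(np.sum(z * z - 10.0 * np.cos(2.0 * np.pi * z)) + 10.0 * z.size)


def _ackley(z: np.ndarray) -> float:
    d = z.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(z * z) / d))
        - np.exp(np.sum(np.cos(2.0 * np.pi * z)) / d)
        + 20.0
        + np.e
    )


def _schwefel_max(z: np.ndarray) -> float:
    return float(np.max(np.abs(z)))


def _schwefel_abs_prod(z: np.ndarray) -> float:
    a = np.abs(z)
    return float(np.sum(a) + np.prod(a))


def _step_paired(z: np.ndarray) -> float:
    # Continuous paired-term step: sum_{i<d} (x_i+.5)^2 + (x_{i+1}+.5)^2.
    # Interior coordinates are counted twice; minimum 0 at x = -0.5.
    s = (z + 0.5) ** 2
    return float(np.sum(s[:-1]) + np.sum(s[1:]))


def _noise_quadratic(z: np.ndarray) -> float:
    i = np.arange(1, z.size + 1)
    return float(np.sum(i * z**4))


def _noncontinuous_rastrigin(z: np.ndarray) -> float:
    y = np.where(np.abs(z) < 0.5, z, np.round(2.0 * z) / 2.0)
    return _rastrigin(y)


def _u_penalty(z: np.ndarray, a: float, k: float, m: float) -> float:
    over = np.maximum(z - a, 0.0)
    under = np.maximum(-z - a, 0.0)
    return float(k * np.sum(over**m + under**m))


def _penalized1(z: np.ndarray) -> float:
    d = z.size
    y = 1.0 + (z + 1.0) / 4.0
    core = (
        10.0 * np.sin(np.pi * y[0]) ** 2
        + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[1:]) ** 2))
        + (y[-1] - 1.0) ** 2
    )
    return float(np.pi / d * core + _u_penalty(z, 10.0, 100.0, 4.0))


def _penalized2(z: np.ndarray) -> float:
    core = (
        np.sin(3.0 * np.pi * z[0]) ** 2
        + np.sum((z[:-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * z[1:]) ** 2))
        + (z[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * z[-1]) ** 2)
    )
    return float(0.1 * core + _u_penalty(z, 5.0, 100.0, 4.0))


def _pathological(z: np.ndarray) -> float:
    # Nonstandard form: sum_i -x_i^2 sin(x_i); global minimum unknown.
    return float(np.sum(-(z**2) * np.sin(z)))


def _sum_squares(z: np.ndarray) -> float:
    i = np.arange(1, z.size + 1)
    return float(np.sum(i * z * z))


# ---------------------------------------------------------------------------
# registry

_ORIGIN = "origin"
_UNKNOWN = "unknown"

# id -> (name, formula, box, x_star rule, fixed_dim, rotated, noisy)
# x_star rule: "origin" | constant c (vector of c) | "ones" | "unknown"
_REGISTRY: dict[str, dict] = {
    "f1": dict(name="sphere", fn=_sphere, box=(-100.0, 100.0), x_star=_ORIGIN),
    "f2": dict(name="beale", fn=_beale, box=(-4.5, 4.5), x_star=np.array([3.0, 0.5]), fixed_dim=2),
    "f3": dict(name="rosenbrock", fn=_rosenbrock, box=(-30.0, 30.0), x_star="ones"),
    "f4": dict(name="griewank", fn=_griewank, box=(-600.0, 600.0), x_star=_ORIGIN),
    "f5": dict(name="rastrigin", fn=_rastrigin, box=(-5.12, 5.12), x_star=_ORIGIN),
    "f6": dict(name="ackley", fn=_ackley, box=(-32.0, 32.0), x_star=_ORIGIN),
    "f7": dict(name="schwefel_max", fn=_schwefel_max, box=(-100.0, 100.0), x_star=_ORIGIN),
    "f8": dict(name="schwefel_abs_prod", fn=_schwefel_abs_prod, box=(-100.0, 100.0), x_star=_ORIGIN),
    "f9": dict(name="step", fn=_step_paired, box=(-100.0, 100.0), x_star=-0.5),
    "f10": dict(name="noise_quadratic", fn=_noise_quadratic, box=(-1.28, 1.28), x_star=_ORIGIN, noisy=True),
    "f11": dict(name="noncontinuous_rastrigin", fn=_noncontinuous_rastrigin, box=(-5.12, 5.12), x_star=_ORIGIN),
    "f12": dict(name="penalized1", fn=_penalized1, box=(-50.0, 50.0), x_star=-1.0),
    "f13": dict(name="penalized2", fn=_penalized2, box=(-50.0, 50.0), x_star="ones"),
    "f14": dict(name="rotated_sphere", fn=_sphere, box=(-100.0, 100.0), x_star=_ORIGIN, rotated=True),
    "f15": dict(name="rotated_rosenbrock", fn=_rosenbrock, box=(-30.0, 30.0), x_star="ones", rotated=True),
    "f16": dict(name="rotated_schwefel_max", fn=_schwefel_max, box=(-100.0, 100.0), x_star=_ORIGIN, rotated=True),
    "f17": dict(name="rotated_rastrigin", fn=_rastrigin, box=(-5.12, 5.12), x_star=_ORIGIN, rotated=True),
    "f18": dict(name="rotated_griewank", fn=_griewank, box=(-600.0, 600.0), x_star=_ORIGIN, rotated=True),
    "f19": dict(name="pathological", fn=_pathological, box=(-100.0, 100.0), x_star=_UNKNOWN),
    "f20": dict(name="sum_squares", fn=_sum_squares, box=(-100.0, 100.0), x_star=_ORIGIN),
}

FORMULA_IDS: tuple[str, ...] = tuple(_REGISTRY)
_NAME_TO_ID = {entry["name"]: fid for fid, entry in _REGISTRY.items()}


@dataclass(frozen=True)
class ObjectiveFunction:
    """A named, bounded, dimension-parameterized scalar test function.

    ``f_star``/``x_star`` are ``None`` when the global minimum is not
    known in closed form (only ``pathological``).  ``needs_noise`` marks
    the noisy quadratic, whose evaluation adds a uniform(0,1) draw from
    a caller-supplied stream.
    """

    name: str
    formula_id: str
    dim: int
    lower: np.ndarray
    upper: np.ndarray
    f_star: Optional[float]
    x_star: Optional[np.ndarray]
    rotation: Optional[RotationSpec] = None
    needs_noise: bool = False
    _fn: Callable[[np.ndarray], float] = field(default=None, repr=False, compare=False)

    def __call__(self, x: np.ndarray, noise_stream: Optional[np.random.Generator] = None) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dim,):
            raise ValueError(
                f"{self.formula_id} expects a vector of length {self.dim}, got shape {x.shape}"
            )
        if self.needs_noise and noise_stream is None:
            raise ValueError(f"{self.formula_id} is stochastic and requires a noise stream")
        z = self.rotation.matrix @ x if self.rotation is not None else x
        value = self._fn(z)
        if self.needs_noise:
            value += float(noise_stream.uniform(0.0, 1.0))
        return value


def evaluate(
    fn: ObjectiveFunction, x: np.ndarray, noise_stream: Optional[np.random.Generator] = None
) -> float:
    """Evaluate ``fn`` at ``x`` (functional alias of ``fn(x)``)."""
    return fn(x, noise_stream=noise_stream)


def default_box(formula_id: str) -> tuple[float, float]:
    """Documented default per-dimension search interval for a function id."""
    entry = _REGISTRY.get(_resolve_id(formula_id))
    return entry["box"]


def _resolve_id(key: str) -> str:
    if key in _REGISTRY:
        return key
    if key in _NAME_TO_ID:
        return _NAME_TO_ID[key]
    raise KeyError(f"unknown benchmark function {key!r}; known ids: f1..f20 or names")


def native_dim(formula_id: str, requested: int) -> int:
    """The dimension a function actually runs at: fixed-dimension
    functions (Beale) ignore the request."""
    entry = _REGISTRY[_resolve_id(formula_id)]
    return entry.get("fixed_dim", requested)


def get_function(
    key: str,
    dim: int,
    *,
    bounds: Optional[tuple[float, float]] = None,
    rotation_seed: int = 12345,
) -> ObjectiveFunction:
    """Build an :class:`ObjectiveFunction` from the registry.

    Parameters
    ----------
    key:
        Function id (``f1``...``f20``) or name (``sphere``, ...).
    dim:
        Requested dimension.  Fixed-dimension functions (Beale) must be
        requested at their native dimension.
    bounds:
        Optional ``(lower, upper)`` overriding the documented default box.
    rotation_seed:
        Seed of the orthogonal matrix for rotated variants; ignored
        otherwise.
    """
    fid = _resolve_id(key)
    entry = _REGISTRY[fid]
    fixed = entry.get("fixed_dim")
    if fixed is not None and dim != fixed:
        raise ValueError(f"{entry['name']} ({fid}) is defined only for dim={fixed}")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if fid in ("f3", "f9", "f13", "f15") and dim < 2:
        raise ValueError(f"{fid} needs dim >= 2")

    lo, hi = bounds if bounds is not None else entry["box"]
    if not lo < hi:
        raise ValueError("lower bound must be strictly below upper bound")
    lower = np.full(dim, float(lo))
    upper = np.full(dim, float(hi))

    rotation = make_rotation(rotation_seed, dim) if entry.get("rotated") else None

    xs = entry["x_star"]
    if isinstance(xs, str) and xs == _UNKNOWN:
        x_star, f_star = None, None
    else:
        if isinstance(xs, str) and xs == _ORIGIN:
            z_star = np.zeros(dim)
        elif isinstance(xs, str) and xs == "ones":
            z_star = np.ones(dim)
        elif isinstance(xs, np.ndarray):
            z_star = xs.copy()
        else:  # constant
            z_star = np.full(dim, float(xs))
        # the formula attains its minimum at z_star; in x-space that is M^T z_star
        x_star = rotation.matrix.T @ z_star if rotation is not None else z_star
        f_star = entry["fn"](z_star)

    return ObjectiveFunction(
        name=entry["name"],
        formula_id=fid,
        dim=dim,
        lower=lower,
        upper=upper,
        f_star=f_star,
        x_star=x_star,
        rotation=rotation,
        needs_noise=bool(entry.get("noisy")),
        _fn=entry["fn"],
    )


def list_functions() -> list[str]:
    """Registry ids in suite order."""
    return list(FORMULA_IDS)


def registry_json() -> list[dict]:
    """JSON-serializable registry summary (id, name, default box, f_star)."""
    out = []
    for fid, entry in _REGISTRY.items():
        xs = entry["x_star"]
        known = not (isinstance(xs, str) and xs == _UNKNOWN)
        out.append(
            {
                "id": fid,
                "name": entry["name"],
                "box": list(entry["box"]),
                "fixed_dim": entry.get("fixed_dim"),
                "rotated": bool(entry.get("rotated")),
                "noisy": bool(entry.get("noisy")),
                "f_star": 0.0 if known else None,
            }
        )
    return out
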
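"""Desirability-based multi-objective optimization of response surfaces.

Each population's count-scale prediction is mapped to a desirability
d in [0, 1] by the Derringer-Suich larger-is-better function (0 below a
lower bound L, 1 above a target T, a power ramp in between); the overall
desirability D is the weighted geometric mean of the per-population d's and
is maximized over the coded concentration box by basin-hopping (random
perturbation, derivative-free local minimization, Metropolis acceptance).

The optimization objectives change with developmental stage: early intervals
maximize progenitor populations (proT, CD4ISP, early DP), later intervals
the maturing ones (late DP, CD8SP); which populations count in which 7-day
interval is read from an ObjectiveSchedule.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import yaml

from .design import Factor
from .errors import (
    InvalidObjectiveError,
    NoObjectiveError,
    ScheduleModelMismatchError,
)
from .rsm import RSMModel

__all__ = [
    "DesirabilityObjective",
    "ObjectiveSchedule",
    "OptimizationResult",
    "desirability_score",
    "overall_desirability",
    "auto_target",
    "basin_hop_maximize",
    "optimize_all_intervals",
    "schedule_from_yaml",
]


@dataclass(frozen=True)
class DesirabilityObjective:
    """How one population enters the overall desirability for one interval."""

    population: str
    direction: str = "maximize"   # "maximize" | "exclude"
    L: float = 0.0                # count where d = 0
    T: float | str = "auto"       # count where d = 1; "auto" -> grid pre-pass
    s: float = 1.0                # ramp exponent
    weight: float = 1.0

    def __post_init__(self):
        if self.direction not in ("maximize", "exclude"):
            raise InvalidObjectiveError(f"unknown direction {self.direction!r}")
        if self.direction == "maximize":
            if self.s <= 0 or self.weight <= 0:
                raise InvalidObjectiveError("s and weight must be positive")
            if self.T != "auto" and self.L >= float(self.T):
                raise InvalidObjectiveError(
                    f"{self.population}: require L < T, got L={self.L}, T={self.T}")


def desirability_score(yhat: float, objective: DesirabilityObjective) -> float:
    """Derringer-Suich larger-is-better desirability of a count prediction."""
    if objective.direction != "maximize":
        raise InvalidObjectiveError("desirability defined only for maximize objectives")
    L, T, s = objective.L, float(objective.T), objective.s
    if L >= T:
        raise InvalidObjectiveError(f"require L < T, got L={L}, T={T}")
    if yhat <= L:
        return 0.0
    if yhat >= T:
        return 1.0
    return float(((yhat - L) / (T - L)) ** s)


def overall_desirability(ds, weights=None) -> float:
    """Weighted geometric mean of desirabilities: D = (prod d_i^w_i)^(1/sum w)."""
    ds = np.asarray(list(ds), dtype=float)
    if ds.size == 0:
        raise NoObjectiveError("no desirabilities to combine")
    if np.any((ds < 0) | (ds > 1)):
        raise ValueError("desirabilities must lie in [0, 1]")
    w = np.ones_like(ds) if weights is None else np.asarray(list(weights), dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.any(ds == 0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(ds)) / np.sum(w)))


def auto_target(model: RSMModel, bounds, n_grid: int = 9, polish: bool = True) -> float:
    """Estimate the attainable count maximum over the bounds box.

    Coarse pre-pass: an ``n_grid``-point sweep along each marginal axis
    (others at coded 0) plus the center, then (by default) a short
    derivative-free polish from the best grid point so the target sits at the
    surface's actual maximum rather than the best axis-aligned value.
    """
    lo, hi = _bounds_arrays(bounds, len(model.factors))
    key = (tuple(lo), tuple(hi), n_grid, polish)
    cache = getattr(model, "_auto_target_cache", None)
    if cache is not None and key in cache:
        return cache[key]
    k = len(model.factors)
    pts = [np.zeros(k)]
    for i in range(k):
        for v in np.linspace(lo[i], hi[i], n_grid):
            p = np.zeros(k)
            p[i] = v
            pts.append(p)
    pts = np.array(pts)
    counts = model.count_prediction(pts)
    best = float(counts.max())
    if polish:
        x0 = pts[int(np.argmax(counts))]
        res = scipy.optimize.minimize(
            lambda x: -model.count_at(np.clip(x, lo, hi)),
            x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        best = max(best, float(-res.fun))
    if cache is None:
        cache = model._auto_target_cache = {}
    cache[key] = best
    return best


def _bounds_arrays(bounds, k):
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim == 1:  # symmetric box (lo, hi) shared by all factors
        lo = np.full(k, bounds[0])
        hi = np.full(k, bounds[1])
    else:
        lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(lo < hi):
        raise ValueError("bounds must satisfy lo < hi")
    return lo, hi


def _resolve(models: dict, objectives, bounds):
    """Pair maximize objectives with their models, resolving T='auto'."""
    resolved = []
    for obj in objectives:
        if obj.direction == "exclude":
            continue
        if obj.population not in models:
            raise ScheduleModelMismatchError(
                f"no model for scheduled population {obj.population!r}")
        model = models[obj.population]
        T = auto_target(model, bounds) if obj.T == "auto" else float(obj.T)
        if obj.L >= T:
            raise InvalidObjectiveError(
                f"{obj.population}: resolved target T={T} <= L={obj.L}")
        resolved.append((model, obj.L, T, obj.s, obj.weight))
    if not resolved:
        raise NoObjectiveError("schedule has no maximize objective")
    return resolved


def _overall_d_fn(resolved):
    weights = np.array([w for *_, w in resolved])
    wsum = weights.sum()
    pre = [(model.quad_form(), L, T, s, w) for (model, L, T, s, w) in resolved]

    def D(x):
        logs = 0.0
        for ((beta0, b, Q), L, T, s, w) in pre:
            yhat_sqrt = beta0 + b @ x + x @ (Q @ x)
            yhat = max(yhat_sqrt, 0.0) ** 2
            if yhat <= L:
                return 0.0
            d = min((yhat - L) / (T - L), 1.0) ** s
            logs += w * np.log(d)
        return float(np.exp(logs / wsum))

    return D


class _ClippedUniformStep:
    """Uniform perturbation of magnitude <= stepsize, clipped to the box."""

    def __init__(self, rng, lo, hi, stepsize):
        self.rng = rng
        self.lo = lo
        self.hi = hi
        self.stepsize = stepsize

    def __call__(self, x):
        step = self.rng.uniform(-self.stepsize, self.stepsize, size=len(x))
        return np.clip(x + step, self.lo, self.hi)


@dataclass
class OptimizationResult:
    """Basin-hopping output for one 7-day interval."""

    interval: tuple[int, int]
    best_coded: np.ndarray
    best_natural: dict | None
    D: float
    top_k: list                  # [(coded point, D)] sorted non-increasing
    seed: int
    n_iterations: int
    n_local_minima: int
    settings: dict = field(default_factory=dict)
    top5_mean: np.ndarray | None = None
    top5_std: np.ndarray | None = None

    def deduplicated_top(self, min_linf: float = 0.05) -> list:
        """Top solutions with near-duplicates (L-inf distance <= min_linf) dropped."""
        kept = []
        for x, d in self.top_k:
            if all(np.max(np.abs(x - k0)) > min_linf for k0, _ in kept):
                kept.append((x, d))
        return kept


def basin_hop_maximize(
    models: dict,
    objectives,
    bounds,
    n_iter: int = 200,
    step_size: float = 0.5,
    temperature: float = 1.0,
    seed: int = 0,
    k_top: int = 5,
    factors: list[Factor] | None = None,
    interval: tuple[int, int] | None = None,
) -> OptimizationResult:
    """Maximize overall desirability over a coded box by basin-hopping.

    ``models`` maps population -> RSMModel for one interval; ``objectives``
    is that interval's list of DesirabilityObjective.  Maximization runs as
    scipy basin-hopping on -D with a bounded Nelder-Mead local minimizer,
    a clipped uniform take-step, and Metropolis acceptance at the given
    temperature.  Deterministic given ``seed``; the ``k_top`` best local
    minima are retained.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    some_model = next(iter(models.values()))
    k = len(some_model.factors)
    lo, hi = _bounds_arrays(bounds, k)
    resolved = _resolve(models, objectives, bounds)
    D = _overall_d_fn(resolved)

    def f(x):
        return -D(np.clip(x, lo, hi))

    rng = np.random.default_rng(seed)
    x0 = np.clip(np.zeros(k), lo, hi)
    records = []

    def callback(x, fval, accepted):
        records.append((np.clip(np.array(x, dtype=float), lo, hi), float(-fval)))

    minimizer_kwargs = {
        "method": "Nelder-Mead",
        "bounds": list(zip(lo, hi)),
        "options": {"xatol": 1e-7, "fatol": 1e-11, "maxiter": 200 * k},
    }
    res = scipy.optimize.basinhopping(
        f, x0, niter=n_iter, T=temperature, stepsize=step_size,
        minimizer_kwargs=minimizer_kwargs,
        take_step=_ClippedUniformStep(rng, lo, hi, step_size),
        callback=callback, rng=rng)
    records.append((np.clip(np.array(res.x, dtype=float), lo, hi), float(-res.fun)))

    if all(d == 0.0 for _, d in records):
        import warnings
        warnings.warn("flat objective: overall desirability is 0 everywhere "
                      "sampled; returning best-effort point")

    records.sort(key=lambda r: -r[1])
    top_k = records[:k_top]
    best_x, best_d = top_k[0]
    top_pts = np.array([x for x, _ in top_k])
    natural = None
    if factors is not None:
        by_name = {fc.name: fc for fc in factors}
        natural = {n: float(by_name[n].to_natural(v))
                   for n, v in zip(some_model.factors, best_x)}
    return OptimizationResult(
        interval=interval or some_model.interval,
        best_coded=best_x, best_natural=natural, D=best_d, top_k=top_k,
        seed=seed, n_iterations=n_iter, n_local_minima=len(records),
        settings={"step_size": step_size, "temperature": temperature,
                  "k_top": k_top, "bounds": [list(lo), list(hi)]},
        top5_mean=top_pts.mean(axis=0), top5_std=top_pts.std(axis=0))


@dataclass
class ObjectiveSchedule:
    """Per-interval desirability objectives for the 42-day campaign."""

    entries: dict  # (day_start, day_end) -> list[DesirabilityObjective]

    def intervals(self) -> list[tuple[int, int]]:
        return sorted(self.entries, key=lambda iv: iv[0])

    def maximized_populations(self, interval) -> list[str]:
        return [o.population for o in self.entries[tuple(interval)]
                if o.direction == "maximize"]


def optimize_all_intervals(
    models: dict,
    schedule: ObjectiveSchedule,
    bounds=(-2.0, 2.0),
    n_iter: int = 200,
    step_size: float = 0.5,
    temperature: float = 1.0,
    seed: int = 0,
    k_top: int = 5,
    factors: list[Factor] | None = None,
) -> list[OptimizationResult]:
    """Run basin-hopping for every scheduled 7-day interval, in temporal order.

    ``models`` maps (interval, population) -> RSMModel.  Each interval gets
    an independent seed derived from ``seed`` so results are reproducible yet
    decoupled.  Each result carries the mean and standard deviation of its
    top-5 points.
    """
    results = []
    for i, interval in enumerate(schedule.intervals()):
        objectives = schedule.entries[interval]
        interval_models = {}
        for obj in objectives:
            if obj.direction == "exclude":
                continue
            key = (interval, obj.population)
            if key not in models:
                raise ScheduleModelMismatchError(
                    f"no model for population {obj.population!r} in interval {interval}")
            interval_models[obj.population] = models[key]
        results.append(basin_hop_maximize(
            interval_models, objectives, bounds, n_iter=n_iter,
            step_size=step_size, temperature=temperature,
            seed=seed + 1009 * i, k_top=k_top, factors=factors,
            interval=interval))
    return results


def optimization_result_to_json(result: OptimizationResult, path) -> None:
    """Serialize an interval optimum with full seed/settings provenance."""
    payload = {
        "interval": list(result.interval),
        "best_coded": [float(v) for v in result.best_coded],
        "best_natural": result.best_natural,
        "overall_desirability": result.D,
        "top_k": [{"coded": [float(v) for v in x], "D": d}
                  for x, d in result.top_k],
        "seed": result.seed,
        "n_iterations": result.n_iterations,
        "n_local_minima": result.n_local_minima,
        "settings": result.settings,
        "top5_mean": [float(v) for v in result.top5_mean],
        "top5_std": [float(v) for v in result.top5_std],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def schedule_from_yaml(path) -> ObjectiveSchedule:
    """Load a schedule: {"intervals": [{day_start, day_end, objectives: [...]}]}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = {}
    for item in raw["intervals"]:
        iv = (int(item["day_start"]), int(item["day_end"]))
        objs = []
        for o in item["objectives"]:
            objs.append(DesirabilityObjective(
                population=o["population"],
                direction=o.get("direction", "maximize"),
                L=float(o.get("L", 0.0)),
                T=o.get("T", "auto"),
                s=float(o.get("s", 1.0)),
                weight=float(o.get("weight", 1.0))))
        entries[iv] = objs
    return ObjectiveSchedule(entries=entries)
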
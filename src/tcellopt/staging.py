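"""Collapse per-interval optima into a three-stage cytokine protocol.

The 42-day assay is split at boundaries (t1, t2), both multiples of 7 with
7 <= t1 < t2 <= 35, into stages [0,t1), [t1,t2), [t2,42].  Each stage's
cytokine concentrations are the arithmetic mean (in ng/ml) of the optimal
concentrations of the 7-day intervals it contains; the pair maximizing the
average overall desirability across the six intervals defines the protocol.
Weekly intervals are half-open and a week belongs to the stage containing
its start day.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .design import Factor
from .desirability import ObjectiveSchedule, _overall_d_fn, _resolve
from .errors import IncompleteOptimaError

__all__ = [
    "StagedProtocol",
    "enumerate_partitions",
    "evaluate_staged_protocol",
    "select_best_partition",
    "protocol_to_json",
]

BOUNDARY_CANDIDATES = (7, 14, 21, 28, 35)
ASSAY_END = 42


def enumerate_partitions() -> list[tuple[int, int]]:
    """All (t1, t2) with t1 < t2 from the weekly boundary candidates,
    in lexicographic order (10 pairs)."""
    return [(t1, t2) for i, t1 in enumerate(BOUNDARY_CANDIDATES)
            for t2 in BOUNDARY_CANDIDATES[i + 1:]]


@dataclass
class StagedProtocol:
    """Three-stage protocol: boundaries, per-stage ng/ml, and its desirability."""

    t1: int
    t2: int
    stage_concentrations: list[dict]   # 3 dicts of factor -> ng/ml
    average_D: float
    per_interval_D: list[float]
    factors: list[str] = field(default_factory=list)


def _stage_of(day_start: int, t1: int, t2: int) -> int:
    if day_start < t1:
        return 0
    if day_start < t2:
        return 1
    return 2


def _resolved_schedule(models: dict, schedule: ObjectiveSchedule, bounds) -> dict:
    """Resolve every interval's objectives (incl. T='auto') once, up front."""
    out = {}
    for iv in schedule.intervals():
        objectives = schedule.entries[iv]
        interval_models = {o.population: models[(iv, o.population)]
                           for o in objectives if o.direction == "maximize"}
        out[iv] = _resolve(interval_models, objectives, bounds)
    return out


def evaluate_staged_protocol(
    interval_optima,
    models: dict,
    schedule: ObjectiveSchedule,
    t1: int,
    t2: int,
    factors: list[Factor],
    bounds=(-2.0, 2.0),
    average_in: str = "natural",
    _resolved: dict | None = None,
) -> StagedProtocol:
    """Average interval optima into 3 stages and score each interval there.

    ``interval_optima`` is the list from optimize_all_intervals (one result
    per interval, in temporal order, with natural-unit best points).  Stage
    concentrations are arithmetic means in natural ng/ml (how media are
    formulated); ``average_in="coded"`` averages the coded optima instead
    and maps the means back, for sensitivity analysis.  The desirability of
    each interval is recomputed at its stage's concentration with that
    interval's own objectives.
    """
    if average_in not in ("natural", "coded"):
        raise ValueError(f"unknown averaging space {average_in!r}")
    if not (t1 in BOUNDARY_CANDIDATES and t2 in BOUNDARY_CANDIDATES and t1 < t2):
        raise ValueError(f"invalid boundaries ({t1}, {t2})")
    intervals = schedule.intervals()
    by_interval = {tuple(r.interval): r for r in interval_optima}
    missing = [iv for iv in intervals if iv not in by_interval]
    if missing:
        raise IncompleteOptimaError(missing)

    names = [f.name for f in factors]
    by_name = {f.name: f for f in factors}

    # mean concentration per stage (natural ng/ml or coded, per average_in)
    stage_concs = []
    for stage in range(3):
        pts = []
        for iv in intervals:
            if _stage_of(iv[0], t1, t2) == stage:
                opt = by_interval[iv]
                if average_in == "coded":
                    pts.append(np.asarray(opt.best_coded, dtype=float))
                    continue
                if opt.best_natural is None:
                    raise IncompleteOptimaError(
                        [iv], "interval optimum lacks natural-unit concentrations")
                pts.append([opt.best_natural[n] for n in names])
        if not pts:
            raise IncompleteOptimaError(
                [], f"stage {stage} of partition ({t1},{t2}) contains no interval")
        mean_pt = np.mean(pts, axis=0)
        if average_in == "coded":
            mean_pt = [by_name[n].to_natural(v) for n, v in zip(names, mean_pt)]
        stage_concs.append(dict(zip(names, mean_pt)))

    resolved_all = _resolved if _resolved is not None else _resolved_schedule(
        models, schedule, bounds)
    per_interval_D = []
    for iv in intervals:
        conc = stage_concs[_stage_of(iv[0], t1, t2)]
        D = _overall_d_fn(resolved_all[iv])
        x = np.array([by_name[n].to_coded(conc[n]) for n in names])
        per_interval_D.append(D(x))

    return StagedProtocol(t1=t1, t2=t2, stage_concentrations=stage_concs,
                          average_D=float(np.mean(per_interval_D)),
                          per_interval_D=per_interval_D, factors=names)


def select_best_partition(
    interval_optima,
    models: dict,
    schedule: ObjectiveSchedule,
    factors: list[Factor],
    bounds=(-2.0, 2.0),
    average_in: str = "natural",
) -> StagedProtocol:
    """Exhaustively evaluate all 10 (t1, t2) pairs and return the argmax of
    average overall desirability; ties go to the lexicographically earlier pair."""
    resolved = _resolved_schedule(models, schedule, bounds)
    best = None
    for (t1, t2) in enumerate_partitions():
        prot = evaluate_staged_protocol(interval_optima, models, schedule,
                                        t1, t2, factors, bounds,
                                        average_in=average_in,
                                        _resolved=resolved)
        if best is None or prot.average_D > best.average_D + 1e-12:
            best = prot
    return best


def protocol_to_json(protocol: StagedProtocol, path) -> None:
    payload = {
        "t1": protocol.t1,
        "t2": protocol.t2,
        "stages": [
            {"days": [0, protocol.t1], "concentrations_ngml": protocol.stage_concentrations[0]},
            {"days": [protocol.t1, protocol.t2], "concentrations_ngml": protocol.stage_concentrations[1]},
            {"days": [protocol.t2, ASSAY_END], "concentrations_ngml": protocol.stage_concentrations[2]},
        ],
        "average_overall_desirability": protocol.average_D,
        "per_interval_desirability": protocol.per_interval_D,
        "factors": protocol.factors,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
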
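"""Screening analysis: z-scores against the 4F control condition and
forward stepwise regression with the minimum-BIC stopping rule.

Counts from each screening run are standardized against the control wells of
the same donor, interval and population, so a z-score reads directly as
"this condition did better/worse than the baseline cocktail by so many
control standard deviations".  Influential cytokines are then picked by
forward selection over main/quadratic/interaction terms, adding at each step
the move that most decreases BIC = n*ln(RSS/n) + k*ln(n) and stopping when
no move decreases it.  Strong effect heredity is enforced: an interaction
may only be in the model with both parent main effects, a quadratic with its
main effect; a term whose parents are absent may still enter as a *bundle*
together with the missing parents when the bundle as a whole lowers BIC.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .errors import (
    DegenerateControlError,
    InsufficientControlError,
)

__all__ = [
    "compute_zscores",
    "stepwise_bic_fit",
    "ScreenModel",
    "candidate_terms",
    "term_column",
    "screen_model_to_json",
]

GROUP_KEYS = ["donor_id", "interval", "population"]


def _with_interval_key(obs: pd.DataFrame) -> pd.DataFrame:
    obs = obs.copy()
    if "interval" not in obs.columns:
        obs["interval"] = list(zip(obs["day_start"], obs["day_end"]))
    return obs


def compute_zscores(obs: pd.DataFrame) -> pd.DataFrame:
    """Standardize counts against control rows per (donor, interval, population).

    ``obs`` follows the ObservationTable schema (run_id, donor_id,
    day_start/day_end or interval, population, count, is_control).  Control
    statistics use the n-1 sample standard deviation.  Returns the table with
    a ``z`` column (control rows included; their mean z is 0 per group).
    """
    obs = _with_interval_key(obs)
    if not np.isfinite(obs["count"].to_numpy(dtype=float)).all():
        raise ValueError("counts must be finite")
    if (obs["count"] < 0).any():
        raise ValueError("counts must be non-negative")

    out = []
    for key, grp in obs.groupby(GROUP_KEYS, sort=False):
        ctrl = grp.loc[grp["is_control"].astype(bool), "count"].to_numpy(dtype=float)
        if len(ctrl) < 2:
            raise InsufficientControlError(
                f"group {key}: {len(ctrl)} control replicate(s); need >= 2")
        mu = ctrl.mean()
        sd = ctrl.std(ddof=1)
        if sd == 0:
            raise DegenerateControlError(f"group {key}: control sd is 0")
        g = grp.copy()
        g["z"] = (g["count"].to_numpy(dtype=float) - mu) / sd
        out.append(g)
    return pd.concat(out).loc[obs.index]


# ---------------------------------------------------------------------------
# stepwise minimum-BIC selection

# A term is a tuple of factor names: () intercept, (a,) main, (a, a)
# quadratic, (a, b) a<b interaction.


def term_column(term: tuple, coded: pd.DataFrame) -> np.ndarray:
    col = np.ones(len(coded))
    for name in term:
        col = col * coded[name].to_numpy(dtype=float)
    return col


def term_label(term: tuple) -> str:
    if not term:
        return "intercept"
    if len(term) == 2 and term[0] == term[1]:
        return f"{term[0]}^2"
    return "*".join(term)


def candidate_terms(names: list[str], candidate_set: str) -> list[tuple]:
    mains = [(n,) for n in names]
    quads = [(n, n) for n in names]
    inters = [tuple(sorted(p)) for p in itertools.combinations(names, 2)]
    if candidate_set == "main_only":
        return mains
    if candidate_set == "main_quadratic":
        return mains + quads
    if candidate_set == "full_quadratic":
        return mains + inters + quads
    raise ValueError(f"unknown candidate_set {candidate_set!r}")


def _parents(term: tuple) -> set:
    if len(term) == 2:
        if term[0] == term[1]:
            return {(term[0],)}
        return {(term[0],), (term[1],)}
    return set()


def _bic(rss: float, n: int, k: int, floor: float = 1e-300) -> float:
    # rss below `floor` is numerically zero: clamping stops the selection
    # from chasing float-noise improvements once a fit is exact
    return n * math.log(max(rss, floor) / n) + k * math.log(n)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _collinear(X: np.ndarray, col: np.ndarray, tol: float = 1e-10) -> bool:
    """True if ``col`` is numerically in the column span of X."""
    beta, *_ = np.linalg.lstsq(X, col, rcond=None)
    resid = col - X @ beta
    scale = float(col @ col) or 1.0
    return float(resid @ resid) / scale < tol


@dataclass
class ScreenModel:
    """Result of a stepwise minimum-BIC screen fit."""

    response: str
    terms: list[tuple]            # includes () intercept, in selection order
    coefficients: dict            # term label -> OLS coefficient
    bic_trace: list[float]        # BIC after each accepted move
    n: int
    rss: float
    aliased: list[tuple] = field(default_factory=list)

    @property
    def selected_labels(self) -> list[str]:
        return [term_label(t) for t in self.terms]


def stepwise_bic_fit(
    design: DesignMatrix,
    response: np.ndarray,
    candidate_set: str = "main_quadratic",
    response_label: str = "response",
) -> ScreenModel:
    """Forward stepwise OLS with strong heredity, stopping at minimum BIC.

    ``response`` must align with the design's runs (z-scores for initial
    screens; raw counts for follow-up screens).  Candidate moves at each step
    are single eligible terms, or bundles of a term plus its missing parent
    main effects; the move with the largest BIC decrease is accepted.
    Candidates collinear with the current model are set aside and reported in
    ``aliased``.
    """
    y = np.asarray(response, dtype=float)
    coded = design.coded
    n = len(coded)
    if len(y) != n:
        raise ValueError(f"response length {len(y)} != run count {n}")

    pool = candidate_terms(design.factor_names, candidate_set)
    cols = {t: term_column(t, coded) for t in pool}

    selected: list[tuple] = [()]
    X = np.ones((n, 1))
    rss = _rss(X, y)
    floor = max(1e-300, (1e-9 * float(np.linalg.norm(y))) ** 2)
    trace = [_bic(rss, n, 1, floor)]
    aliased: set = set()

    while True:
        remaining = [t for t in pool if t not in selected]
        best = None  # (bic, bundle, Xnew, rss)
        for t in remaining:
            missing = [p for p in _parents(t) if p not in selected and p in pool]
            bundle = missing + [t]
            add = [cols[b] for b in bundle]
            Xt = X
            ok = True
            for c in add:
                if _collinear(Xt, c):
                    ok = False
                    break
                Xt = np.column_stack([Xt, c])
            if not ok:
                if not missing:
                    aliased.add(t)
                continue
            r = _rss(Xt, y)
            b = _bic(r, n, Xt.shape[1], floor)
            if best is None or b < best[0]:
                best = (b, bundle, Xt, r)
        if best is None or best[0] >= trace[-1] - 1e-12:
            break
        trace.append(best[0])
        selected.extend(best[1])
        X, rss = best[2], best[3]

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coefs = {term_label(t): float(b) for t, b in zip(selected, beta)}
    return ScreenModel(response=response_label, terms=selected,
                       coefficients=coefs, bic_trace=trace, n=n, rss=rss,
                       aliased=sorted(aliased))


def effect_table(model: ScreenModel, design: DesignMatrix,
                 response: np.ndarray) -> pd.DataFrame:
    """Tidy {term, coefficient, p_value} table for a fitted screen model.

    p-values are two-sided t tests of the OLS coefficients in the selected
    model (the tabular analog of an effect-size circle/color map).
    """
    from scipy import stats

    y = np.asarray(response, dtype=float)
    X = np.column_stack([term_column(t, design.coded) for t in model.terms])
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    if dof <= 0:
        pvals = np.full(p, np.nan)
    else:
        sigma2 = float(resid @ resid) / dof
        se = np.sqrt(np.maximum(sigma2 * np.diag(np.linalg.inv(X.T @ X)), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, np.inf)
        pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    return pd.DataFrame({"term": [term_label(t) for t in model.terms],
                         "coefficient": beta, "p_value": pvals})


def screen_model_to_json(model: ScreenModel, path) -> None:
    payload = {
        "response": model.response,
        "terms": model.selected_labels,
        "coefficients": model.coefficients,
        "bic_trace": model.bic_trace,
        "n": model.n,
        "rss": model.rss,
        "aliased": [term_label(t) for t in model.aliased],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
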
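"""Full-quadratic response-surface models of square-root-transformed cell
counts, fitted per population per 7-day interval.

The square-root transform stabilizes the variance of flow-cytometry counts,
so ordinary least squares on sqrt(count) with a second-order polynomial in
coded cytokine concentrations is the working model.  Predictions are made on
the sqrt scale and back-transformed by clipping negative values to zero
before squaring (a negative sqrt-count has no physical meaning).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix, Factor
from .errors import AliasingError, ExtrapolationError, IncompleteDataError

__all__ = [
    "RSMModel",
    "fit_rsm",
    "predict_response",
    "dose_sweep",
    "quadratic_design_matrix",
    "rsm_model_to_json",
    "rsm_model_from_json",
]


def _term_order(names: list[str]):
    """Canonical term order: intercept, linear, interactions (i<j), quadratics."""
    k = len(names)
    inters = [(names[i], names[j]) for i in range(k) for j in range(i + 1, k)]
    quads = [(n, n) for n in names]
    return [()] + [(n,) for n in names] + inters + quads


def quadratic_design_matrix(coded: np.ndarray, names: list[str]) -> tuple[np.ndarray, list]:
    """Expand coded points (n x k) to the full quadratic model matrix."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    idx = {n: i for i, n in enumerate(names)}
    terms = _term_order(names)
    cols = []
    for t in terms:
        c = np.ones(len(coded))
        for nm in t:
            c = c * coded[:, idx[nm]]
        cols.append(c)
    return np.column_stack(cols), terms


@dataclass
class RSMModel:
    """Second-order model of sqrt(count) in coded units for one population
    and one 7-day interval."""

    population: str
    interval: tuple[int, int]
    factors: list[str]
    beta0: float
    linear: dict            # factor -> coefficient
    interaction: dict       # "a*b" (a<b in factor order) -> coefficient
    quadratic: dict         # factor -> coefficient
    diagnostics: dict = field(default_factory=dict)
    transform: str = "sqrt"
    coded_bound: float | None = None  # design hull half-width (alpha)

    def quad_form(self) -> tuple[float, np.ndarray, np.ndarray]:
        """(beta0, b, Q) with sqrt prediction = beta0 + b.x + x.Q.x
        (Q symmetric: pure quadratics on the diagonal, half interactions off).
        Cached; invalidated only by constructing a new model."""
        cached = getattr(self, "_qf", None)
        if cached is not None:
            return cached
        names = self.factors
        k = len(names)
        b = np.array([self.linear.get(n, 0.0) for n in names])
        Q = np.diag([self.quadratic.get(n, 0.0) for n in names]).astype(float)
        for i in range(k):
            for j in range(i + 1, k):
                v = self.interaction.get(f"{names[i]}*{names[j]}", 0.0) / 2.0
                Q[i, j] = Q[j, i] = v
        self._qf = (self.beta0, b, Q)
        return self._qf

    def sqrt_at(self, x: np.ndarray) -> float:
        """Fast single-point sqrt-scale prediction via the quadratic form."""
        beta0, b, Q = self.quad_form()
        return float(beta0 + b @ x + x @ (Q @ x))

    def count_at(self, x: np.ndarray) -> float:
        return max(self.sqrt_at(x), 0.0) ** 2

    def coefficient_vector(self) -> np.ndarray:
        """Coefficients in canonical term order (see quadratic_design_matrix)."""
        names = self.factors
        out = [self.beta0]
        out += [self.linear.get(n, 0.0) for n in names]
        k = len(names)
        for i in range(k):
            for j in range(i + 1, k):
                out.append(self.interaction.get(f"{names[i]}*{names[j]}", 0.0))
        out += [self.quadratic.get(n, 0.0) for n in names]
        return np.array(out, dtype=float)

    def sqrt_prediction(self, coded_points: np.ndarray) -> np.ndarray:
        X, _ = quadratic_design_matrix(coded_points, self.factors)
        return X @ self.coefficient_vector()

    def count_prediction(self, coded_points: np.ndarray) -> np.ndarray:
        return np.maximum(self.sqrt_prediction(coded_points), 0.0) ** 2


def fit_rsm(
    design: DesignMatrix,
    obs: pd.DataFrame,
    population: str,
    interval: tuple[int, int],
) -> RSMModel:
    """OLS of sqrt(count) on the full quadratic expansion in coded units.

    Observations for the requested population/interval are matched to design
    runs by ``run_id``; replicate rows (e.g. donors, center replicates) pool
    into the single fit.  Raises IncompleteDataError if any design run lacks
    an observation and AliasingError if the expansion is rank-deficient.
    """
    t = obs.copy()
    if "interval" not in t.columns:
        t["interval"] = list(zip(t["day_start"], t["day_end"]))
    sel = t[(t["population"] == population) & (t["interval"] == tuple(interval))]
    if "is_control" in sel.columns:
        sel = sel[~sel["is_control"].astype(bool)]
    present = set(sel["run_id"])
    missing = [r for r in design.coded.index if r not in present]
    if missing:
        raise IncompleteDataError(missing)

    coded = design.coded.loc[sel["run_id"]].to_numpy(dtype=float)
    y = np.sqrt(sel["count"].to_numpy(dtype=float))
    X, terms = quadratic_design_matrix(coded, design.factor_names)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns outside the span of the preceding ones
        aliased = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                aliased.append(terms[j])
        raise AliasingError(aliased)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    n, p = X.shape
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    adj = 0.0 if tss == 0 or n <= p else 1.0 - (rss / (n - p)) / (tss / (n - 1))
    diagnostics = {
        "r2": r2,
        "adj_r2": adj,
        "rmse": float(np.sqrt(rss / n)),
        "bic": n * float(np.log(max(rss, 1e-300) / n)) + p * float(np.log(n)),
        "n": n,
    }

    names = design.factor_names
    k = len(names)
    lin = {n_: float(b) for n_, b in zip(names, beta[1 : 1 + k])}
    inter = {}
    pos = 1 + k
    for i in range(k):
        for j in range(i + 1, k):
            inter[f"{names[i]}*{names[j]}"] = float(beta[pos])
            pos += 1
    quad = {n_: float(b) for n_, b in zip(names, beta[pos:])}
    return RSMModel(population=population, interval=tuple(interval),
                    factors=list(names), beta0=float(beta[0]), linear=lin,
                    interaction=inter, quadratic=quad, diagnostics=diagnostics,
                    coded_bound=design.alpha)


def predict_response(
    model: RSMModel,
    point,
    scale: str = "count",
    coded: bool = True,
    factors: list[Factor] | None = None,
    extrapolate: bool = False,
):
    """Evaluate the model at a point (dict or array in factor order).

    Natural-unit points require ``factors`` (with coding maps) and
    ``coded=False``.  Points outside the coded hull [-alpha, +alpha] raise
    ExtrapolationError unless ``extrapolate=True``.
    """
    if isinstance(point, dict):
        x = np.array([point[n] for n in model.factors], dtype=float)
    else:
        x = np.asarray(point, dtype=float)
    if not coded:
        if factors is None:
            raise ValueError("natural-unit points require the factor list")
        by_name = {f.name: f for f in factors}
        x = np.array([by_name[n].to_coded(v) for n, v in zip(model.factors, x)])
    bound = model.coded_bound
    if bound is not None and not extrapolate and np.any(np.abs(x) > bound + 1e-9):
        raise ExtrapolationError(
            f"point {x} outside coded hull ±{bound:.4g}; pass extrapolate=True")
    yhat = float(model.sqrt_prediction(x[None, :])[0])
    if scale == "sqrt":
        return yhat
    if scale == "count":
        return max(yhat, 0.0) ** 2
    raise ValueError(f"unknown scale {scale!r}")


def dose_sweep(model: RSMModel, factor: str, grid) -> pd.DataFrame:
    """Sweep one factor over ``grid`` (coded), others pinned at coded 0.

    Returns a DataFrame with columns ``coded`` and ``count`` in grid order.
    """
    if factor not in model.factors:
        raise KeyError(f"factor {factor!r} not in model factors {model.factors}")
    grid = np.asarray(grid, dtype=float)
    pts = np.zeros((len(grid), len(model.factors)))
    pts[:, model.factors.index(factor)] = grid
    counts = model.count_prediction(pts)
    return pd.DataFrame({"coded": grid, "count": counts})


# ---------------------------------------------------------------------------
# JSON serialization (also the import format for externally transcribed
# coefficient tables)

def rsm_model_to_json(model: RSMModel, path) -> None:
    payload = {
        "population": model.population,
        "interval": list(model.interval),
        "factors": model.factors,
        "beta0": model.beta0,
        "linear": model.linear,
        "interaction": model.interaction,
        "quadratic": model.quadratic,
        "diagnostics": model.diagnostics,
        "transform": model.transform,
        "coded_bound": model.coded_bound,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def rsm_model_from_json(path) -> RSMModel:
    with open(path) as fh:
        d = json.load(fh)
    return RSMModel(population=d["population"], interval=tuple(d["interval"]),
                    factors=list(d["factors"]), beta0=float(d["beta0"]),
                    linear=d.get("linear", {}), interaction=d.get("interaction", {}),
                    quadratic=d.get("quadratic", {}),
                    diagnostics=d.get("diagnostics", {}),
                    transform=d.get("transform", "sqrt"),
                    coded_bound=d.get("coded_bound"))
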
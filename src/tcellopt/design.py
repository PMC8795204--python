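"""Experimental designs: definitive screening designs (DSD) and central
composite designs (CCD), with coded <-> natural concentration mapping.

Coded units place the design center at 0 and the main factorial levels at
±1.  A DSD tests every factor at three levels {-1, 0, +1} in 2m+1 runs and
is used to screen many candidate cytokines cheaply; a CCD adds axial runs at
±alpha and center replicates so a full second-order (quadratic) model can be
fitted per factor at five levels.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._conference import AVAILABLE_ORDERS, conference_matrix
from .errors import (
    DegenerateDesignError,
    DomainError,
    InvalidFactorError,
    UnsupportedSizeError,
)

__all__ = [
    "Factor",
    "DesignMatrix",
    "generate_dsd",
    "generate_ccd",
    "map_units",
    "factors_from_yaml",
    "design_to_csv",
    "design_from_csv",
]

_CENTER_RTOL = 1e-9


@dataclass(frozen=True)
class Factor:
    """One cytokine with its concentration range in ng/ml.

    ``low``, ``center`` and ``high`` are the natural concentrations at coded
    -1, 0 and +1.  Under linear coding the center must be the arithmetic
    midpoint; under log10 coding it must be the geometric midpoint (and all
    levels strictly positive).
    """

    name: str
    low: float
    center: float
    high: float
    scale: str = "linear"  # "linear" | "log10"

    def __post_init__(self) -> None:
        if not (self.low < self.center < self.high):
            raise InvalidFactorError(
                f"{self.name}: require low < center < high, "
                f"got ({self.low}, {self.center}, {self.high})")
        if self.low < 0:
            raise InvalidFactorError(f"{self.name}: negative concentration")
        if self.scale not in ("linear", "log10"):
            raise InvalidFactorError(f"{self.name}: unknown scale {self.scale!r}")
        if self.scale == "log10":
            if self.low <= 0:
                raise InvalidFactorError(
                    f"{self.name}: log10 coding requires strictly positive levels")
            mid = math.sqrt(self.low * self.high)
            if not math.isclose(self.center, mid, rel_tol=_CENTER_RTOL):
                raise InvalidFactorError(
                    f"{self.name}: center {self.center} is not the geometric "
                    f"midpoint {mid} of (low, high)")
        else:
            mid = (self.low + self.high) / 2.0
            if not math.isclose(self.center, mid, rel_tol=_CENTER_RTOL, abs_tol=0.0):
                raise InvalidFactorError(
                    f"{self.name}: center {self.center} is not the midpoint "
                    f"{mid} of (low, high)")

    # half-range of the coding map on the (possibly log) working scale
    def _step(self) -> float:
        if self.scale == "log10":
            return (math.log10(self.high) - math.log10(self.low)) / 2.0
        return (self.high - self.low) / 2.0

    def to_natural(self, coded):
        coded = np.asarray(coded, dtype=float)
        if self.scale == "log10":
            out = 10.0 ** (math.log10(self.center) + coded * self._step())
        else:
            out = self.center + coded * self._step()
        return out if out.ndim else float(out)

    def to_coded(self, natural):
        natural = np.asarray(natural, dtype=float)
        if np.any(natural < 0):
            raise DomainError(f"{self.name}: negative natural concentration")
        if self.scale == "log10":
            if np.any(natural <= 0):
                raise DomainError(f"{self.name}: log10 coding undefined at 0")
            out = (np.log10(natural) - math.log10(self.center)) / self._step()
        else:
            out = (natural - self.center) / self._step()
        return out if out.ndim else float(out)


@dataclass
class DesignMatrix:
    """A coded run x factor table plus the natural-unit mapping.

    ``coded`` is a DataFrame with one column per factor (coded levels) and a
    ``run_id`` index.  ``alpha`` is the axial distance (CCD only).
    """

    kind: str  # "DSD" | "CCD"
    factors: list[Factor]
    coded: pd.DataFrame
    n_center: int
    alpha: float | None = None

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    def natural(self) -> pd.DataFrame:
        """Natural-unit (ng/ml) version of the coded table."""
        out = {}
        for f in self.factors:
            out[f.name] = f.to_natural(self.coded[f.name].to_numpy())
        return pd.DataFrame(out, index=self.coded.index)

    def is_center(self) -> np.ndarray:
        return (self.coded.to_numpy() == 0).all(axis=1)


def _validate_factors(factors: list[Factor]) -> None:
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise InvalidFactorError(f"duplicate factor names in {names}")


def generate_dsd(factors: list[Factor]) -> DesignMatrix:
    """Build a definitive screening design from a conference matrix.

    For m factors the design is [C; -C; 0] where C is the conference matrix
    of the smallest stored even order m' >= m (trailing columns dropped when
    m' > m), giving 2m' + 1 runs.  Every non-center run has a mirror
    (negated) partner and each retained column takes the three levels
    {-1, 0, +1}.
    """
    _validate_factors(factors)
    m = len(factors)
    if not (4 <= m <= 16):
        raise UnsupportedSizeError(
            f"DSD supports 4-16 factors, got {m}")
    order = next(o for o in AVAILABLE_ORDERS if o >= m)
    C = conference_matrix(order)[:, :m]  # drop trailing columns
    rows = np.vstack([C, -C, np.zeros((1, m), dtype=int)])
    coded = pd.DataFrame(rows.astype(float), columns=[f.name for f in factors])
    coded.index.name = "run_id"
    return DesignMatrix(kind="DSD", factors=list(factors), coded=coded, n_center=1)


def _factorial_core(k: int, fraction: str) -> np.ndarray:
    """Two-level factorial core: full, or a resolution-V+ half fraction."""
    if fraction == "full":
        return np.array(list(itertools.product([-1, 1], repeat=k)), dtype=float)
    if fraction == "half":
        base = np.array(list(itertools.product([-1, 1], repeat=k - 1)), dtype=float)
        gen = np.prod(base, axis=1)  # last factor = product of the others
        return np.column_stack([base, gen])
    raise ValueError(f"unknown fraction {fraction!r}")


def generate_ccd(
    factors: list[Factor],
    n_center: int = 8,
    alpha_mode: str = "orthogonal",
    fraction: str | None = None,
) -> DesignMatrix:
    """Build a central composite design (factorial core + axial + center runs).

    ``alpha_mode``:
      * ``orthogonal`` - alpha = [((sqrt(N) - sqrt(F))^2 * F) / 4]^(1/4) with
        F the factorial run count and N the total run count, which makes
        centered pure-quadratic columns orthogonal to the rest of the model;
      * ``rotatable``  - alpha = F^(1/4);
      * ``face``       - alpha = 1 (axial points on the faces; 3 levels only).

    The factorial core defaults to a full factorial for k <= 5 and a
    resolution-V half fraction for k = 6-8 (override with ``fraction``).
    """
    _validate_factors(factors)
    k = len(factors)
    if not (2 <= k <= 8):
        raise UnsupportedSizeError(f"CCD supports 2-8 factors, got {k}")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    if fraction is None:
        fraction = "full" if k <= 5 else "half"
    core = _factorial_core(k, fraction)
    F = len(core)
    N = F + 2 * k + n_center
    if alpha_mode == "orthogonal":
        alpha = (((math.sqrt(N) - math.sqrt(F)) ** 2 * F) / 4.0) ** 0.25
        if alpha <= 1.0:
            raise DegenerateDesignError(
                f"orthogonal alpha = {alpha:.4f} <= 1; add center runs or "
                f"enlarge the factorial core")
    elif alpha_mode == "rotatable":
        alpha = F ** 0.25
    elif alpha_mode == "face":
        alpha = 1.0
    else:
        raise ValueError(f"unknown alpha_mode {alpha_mode!r}")

    axial = np.zeros((2 * k, k))
    for i in range(k):
        axial[2 * i, i] = -alpha
        axial[2 * i + 1, i] = alpha
    center = np.zeros((n_center, k))
    rows = np.vstack([core, axial, center])
    coded = pd.DataFrame(rows, columns=[f.name for f in factors])
    coded.index.name = "run_id"
    return DesignMatrix(kind="CCD", factors=list(factors), coded=coded,
                        n_center=n_center, alpha=alpha)


def map_units(point, factors: list[Factor], direction: str):
    """Map a point (or table) between coded and natural units.

    ``point`` may be a dict, Series or DataFrame keyed by factor name, or an
    array whose columns follow ``factors`` order.  Returns the same shape.
    """
    if direction not in ("to_natural", "to_coded"):
        raise ValueError(f"unknown direction {direction!r}")
    by_name = {f.name: f for f in factors}

    def _map_one(name, values):
        f = by_name[name]
        return f.to_natural(values) if direction == "to_natural" else f.to_coded(values)

    if isinstance(point, pd.DataFrame):
        return pd.DataFrame({n: _map_one(n, point[n].to_numpy()) for n in point.columns},
                            index=point.index)
    if isinstance(point, pd.Series):
        return pd.Series({n: _map_one(n, point[n]) for n in point.index})
    if isinstance(point, dict):
        return {n: _map_one(n, v) for n, v in point.items()}
    arr = np.asarray(point, dtype=float)
    if arr.ndim == 1:
        if len(arr) != len(factors):
            raise ValueError("point length does not match factor count")
        return np.array([_map_one(f.name, arr[i]) for i, f in enumerate(factors)])
    return np.column_stack([_map_one(f.name, arr[:, i]) for i, f in enumerate(factors)])


# ---------------------------------------------------------------------------
# I/O

def factors_from_yaml(path) -> list[Factor]:
    """Read a factor list from YAML/JSON: list of {name, low, center, high, scale}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [Factor(name=d["name"], low=float(d["low"]), center=float(d["center"]),
                   high=float(d["high"]), scale=d.get("scale", "linear"))
            for d in raw]


def design_to_csv(design: DesignMatrix, path) -> None:
    """Write run_id, kind, per-factor ".coded"/".ngml" columns and is_center."""
    nat = design.natural()
    out = pd.DataFrame(index=design.coded.index)
    out["kind"] = design.kind
    for f in design.factors:
        out[f"{f.name}.coded"] = design.coded[f.name]
        out[f"{f.name}.ngml"] = nat[f.name]
    out["is_center"] = design.is_center()
    out.to_csv(path, index=True)


def design_from_csv(path, factors: list[Factor]) -> DesignMatrix:
    raw = pd.read_csv(path, index_col="run_id")
    kind = str(raw["kind"].iloc[0])
    coded = pd.DataFrame({f.name: raw[f"{f.name}.coded"] for f in factors})
    coded.index.name = "run_id"
    n_center = int((coded.to_numpy() == 0).all(axis=1).sum())
    alpha = float(np.abs(coded.to_numpy()).max()) if kind == "CCD" else None
    return DesignMatrix(kind=kind, factors=list(factors), coded=coded,
                        n_center=n_center, alpha=alpha)
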
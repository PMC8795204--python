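"""Ground-truth dose-response surfaces and simulated experiment tables.

The generator emulates the statistical structure the analysis assumes: per
population and per 7-day interval, a full-quadratic surface on the
square-root-count scale in coded cytokine units, plus Gaussian noise on the
sqrt scale (variance-stabilized counts) and optional additive donor offsets.
Counts are max(s, 0)^2 of the noisy sqrt-scale value.

The default ground truth encodes the study's qualitative regimes:

* days 0-7: strong positive SCF, IL-3 and TNFα effects with positive
  SCF×TNFα and IL-3×TNFα interactions; cells not yet responsive to IL-7;
* days 7-21: SCF and IL-7 drive expansion, IL-3 response gone, TNFα small
  and positive with a small negative TNFα×CXCL12 interaction;
* days 21-42: TNFα turns inhibitory (negative linear term), IL-3 inert,
  SCF and IL-7 dominate with a positive interaction;
* Flt3L is inert throughout.

Coefficient magnitudes are package defaults (recorded here), not measured
values.  The regimes are piecewise-constant with breaks exactly at days 7
and 21, so the staging search has a known correct answer — a fixture choice,
not a claim that real data switches sharply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioassay import DoseResponseCurve
from .design import DesignMatrix, Factor
from .desirability import DesirabilityObjective, ObjectiveSchedule
from .errors import ConfigError, DomainError
from .rsm import RSMModel

__all__ = [
    "GroundTruthSurface",
    "SimulationConfig",
    "default_factors",
    "default_ground_truth",
    "default_schedule",
    "ground_truth_from_yaml",
    "ground_truth_to_yaml",
    "simulate_dataset",
    "simulate_dose_response_curve",
    "INTERVALS",
    "POPULATIONS_BY_INTERVAL",
]

REQUIRED_FACTORS = ("SCF", "Flt3L", "IL3", "IL7", "TNFa", "CXCL12")

INTERVALS = ((0, 7), (7, 14), (14, 21), (21, 28), (28, 35), (35, 42))

# populations measured early (pre-CD3) vs from day 14 on
_EARLY_POPS = {"proT": 1.0, "CD4ISP": 0.7, "earlyDP": 0.4}
_LATE_POPS = {"CD4ISP": 0.9, "earlyDP": 1.0, "lateDP": 0.8, "CD8SP": 0.6}

POPULATIONS_BY_INTERVAL = {
    iv: (_EARLY_POPS if iv[0] < 14 else _LATE_POPS) for iv in INTERVALS
}

# sqrt-count-scale coefficient regimes; keys are factor names, interaction
# keys "a*b".  Every factor keeps a negative pure-quadratic term so the
# surfaces are strictly concave and each optimum is unique and interior.
_REGIMES = {
    "early": {  # [0, 7)
        "beta0": 25.0,
        "linear": {"SCF": 2.0, "IL3": 2.5, "TNFa": 2.0, "CXCL12": 0.5},
        "interaction": {"SCF*TNFa": 0.6, "IL3*TNFa": 0.8},
        "quadratic": {"SCF": -1.5, "Flt3L": -0.5, "IL3": -1.8, "IL7": -0.5,
                      "TNFa": -1.6, "CXCL12": -0.8},
    },
    "mid": {  # [7, 21)
        "beta0": 28.0,
        "linear": {"SCF": 2.2, "IL7": 2.4, "TNFa": 0.4, "CXCL12": 0.4},
        "interaction": {"TNFa*CXCL12": -0.3},
        "quadratic": {"SCF": -1.5, "Flt3L": -0.5, "IL3": -0.5, "IL7": -1.5,
                      "TNFa": -0.8, "CXCL12": -0.8},
    },
    "late": {  # [21, 42)
        "beta0": 30.0,
        "linear": {"SCF": 2.0, "IL7": 2.2, "TNFa": -1.5},
        "interaction": {"SCF*IL7": 0.4},
        "quadratic": {"SCF": -1.5, "Flt3L": -0.5, "IL3": -0.5, "IL7": -1.5,
                      "TNFa": -1.0, "CXCL12": -0.5},
    },
}


def _regime_of(interval) -> str:
    if interval[0] < 7:
        return "early"
    if interval[0] < 21:
        return "mid"
    return "late"


@dataclass
class GroundTruthSurface:
    """Generative counterpart of an RSMModel plus its sqrt-scale noise sd."""

    population: str
    interval: tuple[int, int]
    model: RSMModel
    noise_sd: float = 0.5

    def sqrt_value(self, coded_points) -> np.ndarray:
        return self.model.sqrt_prediction(np.atleast_2d(coded_points))

    def count_value(self, coded_points) -> np.ndarray:
        return self.model.count_prediction(np.atleast_2d(coded_points))


@dataclass
class SimulationConfig:
    """Reproducible simulation settings.

    ``donor_offsets`` maps donor id to an additive sqrt-scale shift
    (default: one donor, no offset).  ``control_point`` is the coded location
    of the control condition used to generate ``n_control`` replicate control
    rows per (donor, interval, population) for z-scoring.
    """

    seed: int = 0
    noise_sd: float | None = None      # override surface noise sd if set
    donor_offsets: dict = field(default_factory=lambda: {"donor1": 0.0})
    control_point: np.ndarray | None = None
    n_control: int = 4
    noise_model: str = "sqrt-gaussian"  # or "negative-binomial" (count scale)
    nb_dispersion: float = 10.0         # NB size parameter (larger = closer to Poisson)

    def __post_init__(self):
        if not self.donor_offsets:
            raise ConfigError("at least one donor required")
        if self.n_control < 0:
            raise ConfigError("n_control must be >= 0")
        if self.noise_model not in ("sqrt-gaussian", "negative-binomial"):
            raise ConfigError(f"unknown noise model {self.noise_model!r}")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")


def default_factors() -> list[Factor]:
    """Six cytokines with linear coding on plausible ng/ml ranges.

    Ranges are chosen so axial points of an orthogonal 6-factor CCD
    (alpha ~ 2.1) remain non-negative in natural units; IL-3 and TNFα center
    on the study's working concentrations (10 and 5 ng/ml).
    """
    return [
        Factor("SCF", 12.0, 20.0, 28.0),
        Factor("Flt3L", 12.0, 20.0, 28.0),
        Factor("IL3", 6.0, 10.0, 14.0),
        Factor("IL7", 12.0, 20.0, 28.0),
        Factor("TNFa", 3.0, 5.0, 7.0),
        Factor("CXCL12", 12.0, 20.0, 28.0),
    ]


def default_ground_truth(factors: list[Factor], noise_sd: float = 0.5) -> dict:
    """Surfaces keyed by (interval, population) encoding the default regimes.

    Within an interval all populations share the same surface shape scaled by
    a positive population multiplier, so they agree on where the optimum is
    (an ancestor-progeny consistency assumption).
    """
    names = [f.name for f in factors]
    missing = [n for n in REQUIRED_FACTORS if n not in names]
    if missing:
        raise ConfigError(f"default ground truth requires factors {missing}")
    surfaces = {}
    for interval in INTERVALS:
        reg = _REGIMES[_regime_of(interval)]
        for pop, mult in POPULATIONS_BY_INTERVAL[interval].items():
            model = RSMModel(
                population=pop, interval=interval, factors=list(names),
                beta0=mult * reg["beta0"],
                linear={n: mult * reg["linear"].get(n, 0.0) for n in names},
                interaction={k: mult * v for k, v in reg["interaction"].items()},
                quadratic={n: mult * reg["quadratic"].get(n, 0.0) for n in names},
            )
            surfaces[(interval, pop)] = GroundTruthSurface(
                population=pop, interval=interval, model=model, noise_sd=noise_sd)
    return surfaces


def default_schedule() -> ObjectiveSchedule:
    """Maximize every modeled population in its interval (T resolved by the
    auto pre-pass); the maximize/exclude pattern is configurable via YAML."""
    entries = {}
    for iv in INTERVALS:
        entries[iv] = [DesirabilityObjective(population=p)
                       for p in POPULATIONS_BY_INTERVAL[iv]]
    return ObjectiveSchedule(entries=entries)


def simulate_dataset(
    design: DesignMatrix,
    surfaces: dict,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate an ObservationTable for every surface over the design's runs.

    For each run x donor x (interval, population): count = max(s, 0)^2 with
    s = surface sqrt-value + donor offset + N(0, noise_sd).  Control rows are
    generated at ``config.control_point`` (coded center by default) with
    run ids "control<j>".  Deterministic given ``config.seed``; surfaces are
    visited in sorted order and donors in insertion order so the random
    stream is reproducible.
    """
    names = design.factor_names
    for (iv, pop), surf in surfaces.items():
        if surf.model.factors != names:
            raise ConfigError(
                f"surface {(iv, pop)} factor layout {surf.model.factors} "
                f"!= design factors {names}")
    rng = np.random.default_rng(config.seed)
    coded = design.coded.to_numpy(dtype=float)
    run_ids = list(design.coded.index)
    ctrl_point = (np.zeros(len(names)) if config.control_point is None
                  else np.asarray(config.control_point, dtype=float))

    def _draw_counts(sqrt_means, offset, sd, n=None):
        s = np.asarray(sqrt_means, dtype=float) + offset
        if n is not None:
            s = np.repeat(s, n)
        if config.noise_model == "negative-binomial":
            mu = np.maximum(s, 0.0) ** 2
            size = config.nb_dispersion
            p = size / (size + np.maximum(mu, 1e-12))
            return rng.negative_binomial(size, p).astype(float)
        noise = rng.normal(0.0, sd, size=len(s)) if sd > 0 else 0.0
        return np.maximum(s + noise, 0.0) ** 2

    rows = []
    for key in sorted(surfaces, key=lambda k: (k[0], k[1])):
        surf = surfaces[key]
        (day_start, day_end), pop = surf.interval, surf.population
        sd = config.noise_sd if config.noise_sd is not None else surf.noise_sd
        base = surf.sqrt_value(coded)
        ctrl_base = float(surf.sqrt_value(ctrl_point[None, :])[0])
        for donor, offset in config.donor_offsets.items():
            counts = _draw_counts(base, offset, sd)
            for rid, c in zip(run_ids, counts):
                rows.append((rid, donor, day_start, day_end, pop, float(c), False))
            if config.n_control:
                cs = _draw_counts([ctrl_base], offset, sd, n=config.n_control)
                for j, c in enumerate(cs):
                    rows.append((f"control{j}", donor, day_start, day_end,
                                 pop, float(c), True))
    obs = pd.DataFrame(rows, columns=["run_id", "donor_id", "day_start",
                                      "day_end", "population", "count",
                                      "is_control"])
    obs["interval"] = list(zip(obs["day_start"], obs["day_end"]))
    return obs


def ground_truth_to_yaml(surfaces: dict, path) -> None:
    """Write ground-truth surfaces (coefficients + noise sd) to YAML."""
    import yaml

    out = []
    for (iv, pop) in sorted(surfaces):
        s = surfaces[(iv, pop)]
        m = s.model
        out.append({"population": pop, "day_start": iv[0], "day_end": iv[1],
                    "factors": m.factors, "beta0": m.beta0, "linear": m.linear,
                    "interaction": m.interaction, "quadratic": m.quadratic,
                    "noise_sd": s.noise_sd})
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def ground_truth_from_yaml(path) -> dict:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    surfaces = {}
    for d in raw:
        iv = (int(d["day_start"]), int(d["day_end"]))
        model = RSMModel(population=d["population"], interval=iv,
                         factors=list(d["factors"]), beta0=float(d["beta0"]),
                         linear=d.get("linear", {}),
                         interaction=d.get("interaction", {}),
                         quadratic=d.get("quadratic", {}))
        surfaces[(iv, d["population"])] = GroundTruthSurface(
            population=d["population"], interval=iv, model=model,
            noise_sd=float(d.get("noise_sd", 0.5)))
    return surfaces


def simulate_dose_response_curve(
    ed50_true: float,
    hill: float,
    doses,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> DoseResponseCurve:
    """Logistic inhibitor decay 100 / (1 + (d / ED50)^hill) with optional
    seeded Gaussian noise, floored at 0.  The dose grid must start at 0."""
    doses = np.asarray(doses, dtype=float)
    if ed50_true <= 0:
        raise DomainError("ed50_true must be positive")
    if doses[0] != 0:
        raise ValueError("dose grid must include 0 (vehicle control) first")
    if not (doses.min() <= ed50_true <= doses.max()):
        raise DomainError("ed50_true must lie within the dose grid span")
    with np.errstate(divide="ignore"):
        resp = 100.0 / (1.0 + (doses / ed50_true) ** hill)
    resp[doses == 0] = 100.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, size=len(resp))
    resp = np.maximum(resp, 0.0)
    return DoseResponseCurve(doses=tuple(doses), responses=tuple(resp))
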
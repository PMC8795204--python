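"""Small assay computations around the optimization campaign: ED50 by linear
interpolation, cumulative fold expansion across weekly passages, coating
surface density, delta-Ct relative expression, group summaries, and the
normality-gated group comparison procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError

__all__ = [
    "DoseResponseCurve",
    "Ed50Estimate",
    "PassageRecord",
    "QpcrMeasurement",
    "ed50_interpolate",
    "cumulative_fold_expansion",
    "coating_density",
    "delta_ct_expression",
    "group_summary",
    "adaptive_group_test",
]


@dataclass(frozen=True)
class DoseResponseCurve:
    """Inhibitor dose-response: ascending doses (µM) starting at the vehicle
    control (dose 0) with aligned responses (frequency % or fold-change)."""

    doses: tuple
    responses: tuple

    def __post_init__(self):
        doses = np.asarray(self.doses, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if len(doses) != len(resp):
            raise ValueError("doses and responses must align")
        if len(doses) < 2:
            raise ValueError("need at least 2 doses")
        if doses[0] != 0:
            raise ValueError("first dose must be the 0 µM vehicle control")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly ascending")
        if np.any(resp < 0):
            raise ValueError("responses must be non-negative")


@dataclass(frozen=True)
class Ed50Estimate:
    """ED50 (µM) by linear interpolation; censored if the normalized response
    never falls below 50% of the vehicle control."""

    value: float
    censored: bool = False
    non_monotone: bool = False
    method: str = "linear-interpolation"


@dataclass(frozen=True)
class PassageRecord:
    """One weekly passage: cells counted at the end of the week and the
    fraction carried forward onto the next plate."""

    counted: float
    fraction_carried: float = 1.0

    def __post_init__(self):
        if self.counted <= 0:
            raise ValueError("counted cells must be positive")
        if not (0 < self.fraction_carried <= 1):
            raise ValueError("fraction carried must be in (0, 1]")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Cycle thresholds for a gene and the reference gene (β-actin)."""

    ct_gene: float
    ct_reference: float
    gene: str = ""
    reference: str = "ACTB"

    def __post_init__(self):
        for v in (self.ct_gene, self.ct_reference):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("cycle thresholds must be positive and finite")


def dose_response_from_csv(path, donor_id: str | None = None) -> DoseResponseCurve:
    """Load one donor's curve from a CSV with columns dose_uM, donor_id, response."""
    import pandas as pd

    t = pd.read_csv(path)
    if donor_id is not None:
        t = t[t["donor_id"] == donor_id]
    t = t.sort_values("dose_uM")
    return DoseResponseCurve(doses=tuple(t["dose_uM"].astype(float)),
                             responses=tuple(t["response"].astype(float)))


def passages_from_csv(path) -> list:
    """Load weekly passage records from a CSV with columns week, counted,
    fraction_carried (sorted by week)."""
    import pandas as pd

    t = pd.read_csv(path).sort_values("week")
    return [PassageRecord(counted=float(r.counted),
                          fraction_carried=float(r.fraction_carried))
            for r in t.itertuples()]


def ed50_interpolate(curve: DoseResponseCurve) -> Ed50Estimate:
    """ED50 from the first adjacent dose pair whose normalized responses
    bracket 50% of the dose-0 (vehicle) response.

    Responses are normalized so dose 0 reads 100%.  With a non-monotone
    curve the first crossing is used and flagged.  If the curve never drops
    below 50%, the estimate is censored at the maximum dose.
    """
    doses = np.asarray(curve.doses, dtype=float)
    resp = np.asarray(curve.responses, dtype=float)
    if resp[0] == 0:
        raise DomainError("response at dose 0 is 0; baseline undefined")
    norm = 100.0 * resp / resp[0]
    below = norm < 50.0
    crossings = [i for i in range(len(norm) - 1) if norm[i] >= 50.0 > norm[i + 1]]
    if not crossings:
        if below.any():  # starts below after rebound - cannot happen: norm[0]=100
            pass
        return Ed50Estimate(value=float(doses[-1]), censored=True)
    i = crossings[0]
    frac = (norm[i] - 50.0) / (norm[i] - norm[i + 1])
    value = float(doses[i] + frac * (doses[i + 1] - doses[i]))
    non_monotone = bool(np.any(np.diff(norm) > 0))
    return Ed50Estimate(value=value, non_monotone=non_monotone)


def cumulative_fold_expansion(records, initial_seed: float) -> float:
    """Split-adjusted per-cell fold expansion across weekly passages.

    Week w starts from ``seeded_w`` cells (the initial seed for week 1,
    afterwards the previous count times the carried fraction) and ends with
    ``counted_w``; the cumulative fold is the product of per-week ratios, so
    the passage split itself does not distort the result.
    """
    if not records:
        raise ValueError("need at least one passage record")
    if initial_seed <= 0:
        raise ZeroDivisionError("initial seed must be positive")
    fold = 1.0
    seeded = float(initial_seed)
    for rec in records:
        fold *= rec.counted / seeded
        seeded = rec.counted * rec.fraction_carried
    return fold


def coating_density(concentration_ug_ml: float, volume_ul: float, area_mm2: float) -> float:
    """Surface density (ng/mm²) of a plate-bound protein.

    mass [ng] = concentration [µg/ml] * volume [µl]  (µg/ml == ng/µl);
    density = mass / area.
    """
    if concentration_ug_ml <= 0 or volume_ul <= 0 or area_mm2 <= 0:
        raise DomainError("concentration, volume and area must be positive")
    return concentration_ug_ml * volume_ul / area_mm2


def delta_ct_expression(m: QpcrMeasurement) -> float:
    """Relative expression 2^(-ΔCt), ΔCt = Ct(gene) - Ct(reference)."""
    return float(2.0 ** (-(m.ct_gene - m.ct_reference)))


def group_summary(groups: dict, reference: str | None = None) -> dict:
    """Descriptive statistics per group plus median ratios vs a reference.

    Returns {group: {median, iqr, p5, p95, mean, sem, n, median_ratio}} where
    median_ratio = group median / reference median (when a reference is named).
    """
    if not groups:
        raise ValueError("no groups given")
    out = {}
    ref_median = None
    if reference is not None:
        if reference not in groups:
            raise KeyError(f"reference group {reference!r} not found")
        ref_vals = np.asarray(groups[reference], dtype=float)
        if ref_vals.size == 0:
            raise ValueError("empty reference group")
        ref_median = float(np.median(ref_vals))
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise ValueError(f"empty group {name!r}")
        q25, q75 = np.percentile(v, [25, 75])
        p5, p95 = np.percentile(v, [5, 95])
        stats = {
            "median": float(np.median(v)),
            "iqr": float(q75 - q25),
            "p5": float(p5),
            "p95": float(p95),
            "mean": float(v.mean()),
            "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0,
            "n": int(v.size),
        }
        if ref_median is not None:
            stats["median_ratio"] = float(np.median(v)) / ref_median
        out[name] = stats
    return out


def _dunn_posthoc(groups: dict) -> dict:
    """Dunn's pairwise z tests on pooled ranks with tie correction;
    two-sided p-values (unadjusted)."""
    names = list(groups)
    data = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(data)
    ranks = scipy.stats.rankdata(pooled)
    N = len(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0
    mean_ranks = {}
    pos = 0
    for n, d in zip(names, data):
        mean_ranks[n] = ranks[pos:pos + len(d)].mean()
        pos += len(d)
    pvals = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            na, nb = len(groups[a]), len(groups[b])
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            pvals[(a, b)] = 2.0 * scipy.stats.norm.sf(abs(z))
    return pvals


def adaptive_group_test(groups: dict) -> dict:
    """Compare >= 2 groups, choosing the test family by Shapiro-Wilk normality.

    If any group rejects normality (Shapiro-Wilk p < 0.05): Kruskal-Wallis
    with Dunn post hoc and Benjamini-Hochberg adjustment.  Otherwise one-way
    ANOVA with Tukey post hoc.  Groups that are all-constant make the
    normality test (and omnibus test) degenerate; the comparison is skipped
    with a warning.  Returns {test, statistic, p_value, shapiro_p,
    pairwise: {(a, b): adjusted p}}.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    data = [np.asarray(groups[n], dtype=float) for n in names]
    if any(len(d) < 3 for d in data):
        raise ValueError("each group needs at least 3 values")

    if all(np.ptp(d) == 0 for d in data):
        warnings.warn("all groups have zero variance; tests skipped")
        return {"test": "skipped-degenerate", "statistic": float("nan"),
                "p_value": float("nan"), "shapiro_p": {}, "pairwise": {}}

    shapiro_p = {}
    for n, d in zip(names, data):
        if np.ptp(d) == 0:
            shapiro_p[n] = 0.0  # constant group: trivially non-Gaussian
        else:
            shapiro_p[n] = float(scipy.stats.shapiro(d).pvalue)

    if any(p < 0.05 for p in shapiro_p.values()):
        stat, p = scipy.stats.kruskal(*data)
        raw = _dunn_posthoc(groups)
        keys = list(raw)
        adj = multipletests([raw[k] for k in keys], method="fdr_bh")[1]
        pairwise = {k: float(a) for k, a in zip(keys, adj)}
        return {"test": "kruskal-wallis+dunn+bh", "statistic": float(stat),
                "p_value": float(p), "shapiro_p": shapiro_p, "pairwise": pairwise}

    stat, p = scipy.stats.f_oneway(*data)
    tk = scipy.stats.tukey_hsd(*data)
    pairwise = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            pairwise[(a, names[j])] = float(tk.pvalue[i, j])
    return {"test": "anova+tukey", "statistic": float(stat), "p_value": float(p),
            "shapiro_p": shapiro_p, "pairwise": pairwise}
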
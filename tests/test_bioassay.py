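"""ED50 interpolation, fold expansion, coating density, ΔCt, summaries and
the normality-gated group comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcellopt import (
    DoseResponseCurve,
    PassageRecord,
    QpcrMeasurement,
    adaptive_group_test,
    coating_density,
    cumulative_fold_expansion,
    delta_ct_expression,
    ed50_interpolate,
    group_summary,
)
from tcellopt.errors import DomainError


class TestEd50:
    def test_linear_decay_midpoint(self):
        curve = DoseResponseCurve((0.0, 1.0), (100.0, 0.0))
        assert ed50_interpolate(curve).value == pytest.approx(0.5)

    def test_hand_interpolation(self):
        curve = DoseResponseCurve((0.0, 0.1, 0.5), (100.0, 80.0, 40.0))
        est = ed50_interpolate(curve)
        assert est.value == pytest.approx(0.4)
        assert not est.censored

    def test_flat_curve_censored_at_max(self):
        curve = DoseResponseCurve((0.0, 0.5, 1.0), (100.0, 100.0, 100.0))
        est = ed50_interpolate(curve)
        assert est.censored and est.value == 1.0

    def test_normalization_is_relative_to_vehicle(self):
        # same shape, different absolute scale -> same ED50
        c1 = DoseResponseCurve((0.0, 0.2, 0.8), (50.0, 30.0, 10.0))
        c2 = DoseResponseCurve((0.0, 0.2, 0.8), (5.0, 3.0, 1.0))
        assert ed50_interpolate(c1).value == pytest.approx(ed50_interpolate(c2).value)

    def test_first_crossing_rule_flagged(self):
        curve = DoseResponseCurve((0.0, 0.1, 0.2, 0.4), (100.0, 30.0, 70.0, 20.0))
        est = ed50_interpolate(curve)
        assert est.non_monotone
        # first bracketing pair is (0, 0.1): 100 -> 30
        assert est.value == pytest.approx(0.1 * 50.0 / 70.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(DomainError):
            ed50_interpolate(DoseResponseCurve((0.0, 1.0), (0.0, 0.0)))

    def test_matches_analytic_inverse_of_piecewise_linear(self):
        """Grid refinements of a known piecewise-linear curve always give the
        exact analytic 50% dose."""
        # response = 100 - 90*d for d in [0, 1]: 50% at d = 5/9
        for n in (3, 5, 9, 33):
            doses = np.linspace(0, 1, n)
            curve = DoseResponseCurve(tuple(doses), tuple(100 - 90 * doses))
            assert ed50_interpolate(curve).value == pytest.approx(5 / 9, abs=1e-12)

    def test_logistic_midpoint_within_grid_spacing(self):
        from tcellopt import simulate_dose_response_curve
        doses = (0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6)
        curve = simulate_dose_response_curve(0.3, hill=1.5, doses=doses)
        est = ed50_interpolate(curve)
        spacing = 0.4 - 0.2  # local grid spacing around the true midpoint
        assert abs(est.value - 0.3) <= spacing


class TestFoldExpansion:
    def test_two_weeks_tenfold(self):
        recs = [PassageRecord(1000.0, 1.0), PassageRecord(10000.0, 1.0)]
        assert cumulative_fold_expansion(recs, 100.0) == pytest.approx(100.0)

    def test_split_adjustment(self):
        # 10x per-cell growth, half the cells carried: still 100-fold overall
        recs = [PassageRecord(1000.0, 0.5), PassageRecord(5000.0, 0.5)]
        assert cumulative_fold_expansion(recs, 100.0) == pytest.approx(100.0)

    def test_single_week_identity(self):
        assert cumulative_fold_expansion([PassageRecord(500.0)], 500.0) == 1.0

    @given(st.lists(st.floats(0.1, 1.0), min_size=1, max_size=6),
           st.floats(1.1, 20.0))
    @settings(max_examples=100, deadline=None)
    def test_invariant_to_carried_fraction(self, fractions, growth):
        """Per-cell growth fixed: the cumulative fold must not depend on how
        much of each passage is carried forward."""
        seed = 1000.0
        def run(fracs):
            seeded, recs = seed, []
            for fr in fracs:
                counted = seeded * growth
                recs.append(PassageRecord(counted, fr))
                seeded = counted * fr
            return cumulative_fold_expansion(recs, seed)
        full = run([1.0] * len(fractions))
        split = run(fractions)
        assert split == pytest.approx(full, rel=1e-9)
        assert full == pytest.approx(growth ** len(fractions), rel=1e-9)

    def test_zero_seed_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cumulative_fold_expansion([PassageRecord(10.0)], 0.0)


class TestCoatingDensity:
    def test_vcam1_working_density(self):
        # 2.5 ug/ml in 50 ul over a 32 mm^2 well ~ 4 ng/mm^2
        assert round(coating_density(2.5, 50.0, 32.0)) == 4

    def test_dl4_working_density(self):
        assert round(coating_density(15.0, 50.0, 32.0)) == 23  # "~24 ng/mm2"

    def test_unit_identity(self):
        assert coating_density(1.0, 1000.0, 1000.0) == pytest.approx(1.0)

    def test_inverse_proportionality_to_area(self):
        assert coating_density(2.0, 100.0, 50.0) == pytest.approx(
            2 * coating_density(2.0, 100.0, 100.0))


class TestDeltaCt:
    @pytest.mark.parametrize("ct_gene,ct_ref,expected", [
        (20.0, 20.0, 1.0),
        (21.0, 20.0, 0.5),
        (18.0, 20.0, 4.0),
    ])
    def test_relative_expression(self, ct_gene, ct_ref, expected):
        m = QpcrMeasurement(ct_gene=ct_gene, ct_reference=ct_ref)
        assert delta_ct_expression(m) == pytest.approx(expected)

    def test_gene_equals_reference_exactly_one(self):
        for ct in (5.0, 17.3, 39.9):
            assert delta_ct_expression(QpcrMeasurement(ct, ct)) == 1.0

    def test_invalid_ct_rejected(self):
        with pytest.raises(ValueError):
            QpcrMeasurement(ct_gene=-1.0, ct_reference=20.0)


class TestGroupSummary:
    def test_reference_ratio_identity(self):
        out = group_summary({"a": [1, 2, 3], "b": [1, 2, 3]}, reference="b")
        assert out["a"]["median_ratio"] == pytest.approx(1.0)

    def test_optimum_vs_control_magnitude(self):
        """Median CD3+TCRab counts 1.02e6 vs 1680 land at about 600-fold."""
        out = group_summary({"optimum": [1.02e6], "control": [1680.0]},
                            reference="control")
        ratio = out["optimum"]["median_ratio"]
        assert ratio == pytest.approx(607.14, rel=1e-3)
        assert round(ratio, -2) == 600.0

    def test_degenerate_single_value(self):
        out = group_summary({"a": [5.0]})
        assert out["a"]["median"] == out["a"]["mean"] == 5.0
        assert out["a"]["iqr"] == 0.0 and out["a"]["sem"] == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_summary({"a": []})


class TestAdaptiveGroupTest:
    def test_gaussian_groups_take_anova_branch(self):
        rng = np.random.default_rng(14)
        groups = {"a": rng.normal(10, 1, 30), "b": rng.normal(10, 1, 30)}
        out = adaptive_group_test(groups)
        assert out["test"] == "anova+tukey"
        assert out["pairwise"][("a", "b")] > 0.05

    def test_skewed_groups_take_nonparametric_branch(self):
        rng = np.random.default_rng(8)
        groups = {"a": rng.lognormal(0, 1.5, 30), "b": rng.lognormal(0, 1.5, 30),
                  "c": rng.lognormal(1.0, 1.5, 30)}
        out = adaptive_group_test(groups)
        assert out["test"] == "kruskal-wallis+dunn+bh"
        assert len(out["pairwise"]) == 3
        assert all(0 <= p <= 1 for p in out["pairwise"].values())

    def test_shifted_gaussians_detected(self):
        rng = np.random.default_rng(5)
        groups = {"lo": rng.normal(0, 1, 25), "hi": rng.normal(3, 1, 25)}
        out = adaptive_group_test(groups)
        assert out["p_value"] < 0.01

    def test_constant_groups_skipped_with_warning(self):
        groups = {"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]}
        with pytest.warns(UserWarning):
            out = adaptive_group_test(groups)
        assert out["test"] == "skipped-degenerate"

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            adaptive_group_test({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})
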
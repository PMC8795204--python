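"""z-scoring against the control condition and stepwise min-BIC selection."""

import math

import numpy as np
import pandas as pd
import pytest

from tcellopt import Factor, compute_zscores, generate_ccd, generate_dsd, stepwise_bic_fit
from tcellopt.errors import DegenerateControlError, InsufficientControlError
from tcellopt.screening import term_column, term_label


def _obs(rows):
    return pd.DataFrame(rows, columns=["run_id", "donor_id", "day_start", "day_end",
                                       "population", "count", "is_control"])


def _factors(m):
    return [Factor(f"x{i}", 10.0, 20.0, 30.0) for i in range(m)]


class TestZScores:
    def test_hand_example(self):
        obs = _obs([
            ("c1", "d1", 0, 7, "proT", 8.0, True),
            ("c2", "d1", 0, 7, "proT", 10.0, True),
            ("c3", "d1", 0, 7, "proT", 12.0, True),
            ("r1", "d1", 0, 7, "proT", 14.0, False),
            ("r2", "d1", 0, 7, "proT", 10.0, False),
        ])
        z = compute_zscores(obs)
        assert z.loc[z.run_id == "r1", "z"].iloc[0] == pytest.approx(2.0)
        assert z.loc[z.run_id == "r2", "z"].iloc[0] == pytest.approx(0.0)

    def test_control_mean_zero_per_group(self):
        rng = np.random.default_rng(3)
        rows = []
        for donor in ["d1", "d2"]:
            for pop in ["proT", "CD4ISP"]:
                for j in range(4):
                    rows.append((f"c{j}", donor, 0, 7, pop, rng.uniform(50, 150), True))
                for j in range(6):
                    rows.append((f"r{j}", donor, 0, 7, pop, rng.uniform(50, 150), False))
        z = compute_zscores(_obs(rows))
        ctrl = z[z.is_control]
        for _, grp in ctrl.groupby(["donor_id", "interval", "population"]):
            assert abs(grp["z"].mean()) < 1e-10

    def test_insufficient_and_degenerate_controls(self):
        one_ctrl = _obs([("c1", "d1", 0, 7, "proT", 10.0, True),
                         ("r1", "d1", 0, 7, "proT", 12.0, False)])
        with pytest.raises(InsufficientControlError):
            compute_zscores(one_ctrl)
        flat = _obs([("c1", "d1", 0, 7, "proT", 10.0, True),
                     ("c2", "d1", 0, 7, "proT", 10.0, True),
                     ("r1", "d1", 0, 7, "proT", 12.0, False)])
        with pytest.raises(DegenerateControlError):
            compute_zscores(flat)


class TestStepwise:
    def test_noiseless_single_main_effect(self):
        design = generate_dsd(_factors(6))
        y = 3.0 * design.coded["x0"].to_numpy()
        model = stepwise_bic_fit(design, y, candidate_set="main_quadratic")
        assert model.selected_labels == ["intercept", "x0"]
        assert model.coefficients["x0"] == pytest.approx(3.0, abs=1e-10)
        assert model.coefficients["intercept"] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("make_design", [
        lambda: generate_dsd(_factors(6)),
        lambda: generate_ccd(_factors(6), n_center=8),
    ])
    def test_interaction_enters_with_its_parents(self, make_design):
        design = make_design()
        c = design.coded
        y = 2.0 * c["x0"].to_numpy() + 1.5 * (c["x0"] * c["x1"]).to_numpy()
        model = stepwise_bic_fit(design, y, candidate_set="full_quadratic")
        assert {"x0", "x1", "x0*x1"} <= set(model.selected_labels)
        assert model.coefficients["x0"] == pytest.approx(2.0, abs=1e-8)
        assert model.coefficients["x0*x1"] == pytest.approx(1.5, abs=1e-8)
        assert model.coefficients["x1"] == pytest.approx(0.0, abs=1e-8)

    def test_bic_trace_strictly_decreasing(self):
        design = generate_dsd(_factors(6))
        rng = np.random.default_rng(11)
        y = 3 * design.coded["x2"].to_numpy() + rng.normal(0, 1, design.n_runs)
        model = stepwise_bic_fit(design, y)
        assert all(b - a < -1e-12 for a, b in zip(model.bic_trace, model.bic_trace[1:]))

    def test_idempotent_on_own_predictions(self):
        design = generate_dsd(_factors(6))
        rng = np.random.default_rng(5)
        y = (2.5 * design.coded["x0"].to_numpy()
             - 2.0 * design.coded["x3"].to_numpy() + rng.normal(0, 0.5, design.n_runs))
        m1 = stepwise_bic_fit(design, y)
        yhat = sum(m1.coefficients[term_label(t)] * term_column(t, design.coded)
                   for t in m1.terms)
        m2 = stepwise_bic_fit(design, yhat)
        assert m2.selected_labels == m1.selected_labels

    def test_agrees_with_brute_force_forward_selection(self):
        """Dual route: package selection == an independent plain forward
        min-BIC loop, on main-effects-only candidates where the two
        procedures are definitionally identical."""
        design = generate_dsd(_factors(6))
        X = design.coded.to_numpy()
        n = design.n_runs

        def oracle(y):
            sel, Xc = [], np.ones((n, 1))
            def bic(Xm):
                b, *_ = np.linalg.lstsq(Xm, y, rcond=None)
                r = y - Xm @ b
                return n * math.log(max(float(r @ r), 1e-300) / n) + Xm.shape[1] * math.log(n)
            cur = bic(Xc)
            while True:
                cand = [(bic(np.column_stack([Xc, X[:, j]])), j)
                        for j in range(6) if j not in sel]
                if not cand:
                    return sel
                b, j = min(cand)
                if b >= cur - 1e-12:
                    return sel
                cur, Xc = b, np.column_stack([Xc, X[:, j]])
                sel.append(j)

        rng = np.random.default_rng(2024)
        for _ in range(25):
            beta = rng.choice([0.0, 0.0, 2.0, -3.0], size=6)
            y = X @ beta + rng.normal(0, 1, n)
            m = stepwise_bic_fit(design, y, candidate_set="main_only")
            got = [design.factor_names.index(lbl) for lbl in m.selected_labels[1:]]
            assert got == oracle(y)

    def test_power_and_false_inclusion_rates(self):
        """|beta| = 3*sigma active mains are always recovered; min-BIC at
        n=13 admits on average about one spurious term (simulation-calibrated
        bands)."""
        design = generate_dsd(_factors(6))
        X = design.coded.to_numpy()
        rng = np.random.default_rng(77)
        n_rep, all_active, fps = 100, 0, []
        for _ in range(n_rep):
            y = 3 * X[:, 0] + 3 * X[:, 1] + rng.normal(0, 1, design.n_runs)
            sel = set(stepwise_bic_fit(design, y, "main_only").selected_labels[1:])
            if {"x0", "x1"} <= sel:
                all_active += 1
            fps.append(len(sel - {"x0", "x1"}))
        assert all_active == n_rep
        assert np.mean(fps) < 2.0

    def test_noise_only_often_keeps_intercept_model(self):
        """Pure-noise responses: the intercept-only model is the single most
        common outcome (simulation-calibrated rate ~1/3 at n=13)."""
        design = generate_dsd(_factors(6))
        rng = np.random.default_rng(123)
        hits = sum(
            stepwise_bic_fit(design, rng.normal(0, 1, design.n_runs),
                             "main_only").selected_labels == ["intercept"]
            for _ in range(100))
        assert 20 <= hits <= 50


def test_screen_pipeline_recovers_active_cytokines():
    """End to end: simulate a DSD screen from the day-0-7 ground truth,
    z-score against the control wells, and check stepwise selection finds
    the cytokines that actually drive early expansion."""
    from tcellopt import SimulationConfig, default_factors, default_ground_truth, generate_dsd, simulate_dataset

    factors = default_factors()
    design = generate_dsd(factors)
    truth = {k: v for k, v in default_ground_truth(factors, noise_sd=0.3).items()
             if k[0] == (0, 7) and k[1] == "proT"}
    obs = simulate_dataset(design, truth, SimulationConfig(seed=9, n_control=4))
    z = compute_zscores(obs)
    test_rows = z[~z.is_control].set_index("run_id").loc[design.coded.index]
    model = stepwise_bic_fit(design, test_rows["z"].to_numpy(), "main_quadratic")
    sel = set(model.selected_labels)
    assert {"SCF", "IL3", "TNFa"} <= sel
    for c in ("SCF", "IL3", "TNFa"):
        assert model.coefficients[c] > 0
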
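"""Identifiability screen, eFAST, WSSR, PSO fitting, fit evaluation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from betacell.calibration import (
    CalibrationProblem,
    FitConfig,
    detect_correlated_velocity_pairs,
    efast_sensitivity,
    evaluate_predictions,
    fit_pso,
    reparameterize_equilibrium,
    wssr,
)
from betacell.datasets import FoldChangeDataset
from betacell.efast import efast_indices
from betacell.network import DefinitionError
from betacell.parameters import ParameterSet
from betacell.pso import pso_minimize
from betacell.simulate import StimulationProtocol, initial_state, simulate
from betacell.synthetic import generate_ground_truth, simulate_study


def _dataset(rows):
    return FoldChangeDataset(pd.DataFrame(rows), enforce_split=False)


def _obs(met, fc, sd=0.1, time=3.0, comparison="high_vs_low", source="spegel2013",
         role="train"):
    return dict(metabolite=met, time_min=time, comparison=comparison,
                fold_change=fc, sd=sd, source=source, role=role)


class TestWSSR:
    def test_perfect_predictions_zero(self):
        ds = _dataset([_obs("A", 1.5), _obs("B", 2.0)])
        preds = {("A", "spegel2013", 3.0, "high_vs_low"): 1.5,
                 ("B", "spegel2013", 3.0, "high_vs_low"): 2.0}
        assert wssr(preds, ds) == 0.0

    def test_single_point_contribution(self):
        # pred 2, obs 1, sd 1 -> ((2-1)/(1*1))^2 = 1
        ds = _dataset([_obs("A", 1.0, sd=1.0)])
        assert wssr({("A", "spegel2013", 3.0, "high_vs_low"): 2.0}, ds) == pytest.approx(1.0)

    def test_doubling_sd_quarters_wssr(self):
        rows = [_obs("A", 1.4, sd=0.2), _obs("B", 0.7, sd=0.1)]
        preds = {("A", "spegel2013", 3.0, "high_vs_low"): 1.9,
                 ("B", "spegel2013", 3.0, "high_vs_low"): 0.9}
        w1 = wssr(preds, _dataset(rows))
        rows2 = [dict(r, sd=2 * r["sd"]) for r in rows]
        assert wssr(preds, _dataset(rows2)) == pytest.approx(w1 / 4.0)

    def test_order_invariance(self):
        rows = [_obs("A", 1.4, sd=0.2), _obs("B", 0.7, sd=0.1), _obs("C", 2.2, sd=0.3)]
        preds = {("A", "spegel2013", 3.0, "high_vs_low"): 1.5,
                 ("B", "spegel2013", 3.0, "high_vs_low"): 0.8,
                 ("C", "spegel2013", 3.0, "high_vs_low"): 2.0}
        assert wssr(preds, _dataset(rows)) == pytest.approx(
            wssr(preds, _dataset(rows[::-1])))

    def test_zero_sd_uses_median_relative_sd(self):
        rows = [_obs("A", 2.0, sd=0.0), _obs("B", 1.0, sd=0.2)]
        preds = {("A", "spegel2013", 3.0, "high_vs_low"): 2.2,
                 ("B", "spegel2013", 3.0, "high_vs_low"): 1.0}
        # median relative sd = 0.2 -> effective sd for A = 0.4
        assert wssr(preds, _dataset(rows)) == pytest.approx((0.2 / (0.4 * 2.0)) ** 2)

    def test_missing_prediction_names_observation(self):
        ds = _dataset([_obs("A", 1.5)])
        with pytest.raises(KeyError, match="A"):
            wssr({}, ds)


class TestReparameterization:
    def test_equilibrium_constraint_reduces_free_vmax(self, full):
        from betacell.network import parameter_inventory

        # the shipped model already carries the 11 constrained pairs;
        # rebuilding from scratch and re-applying them must agree
        inv = parameter_inventory(full)
        assert inv.n_free_vmax == inv.n_velocities - 11

    def test_empty_pair_list_is_identity(self, reduced):
        out = reparameterize_equilibrium(reduced, [])
        assert sum(r.rate_law.constrained for r in out.reactions) == 0

    def test_missing_keq_raises_definition_error(self, reduced):
        # reduced fixture reversible reactions carry no Keq parameters
        with pytest.raises(DefinitionError, match="equilibrium constant"):
            reparameterize_equilibrium(reduced, ["gld"])

    def test_constrained_model_reproduces_rates_when_vr_matches(self, full):
        import copy

        from betacell.simulate import rhs

        uncon = copy.deepcopy(full)
        for r in uncon.reactions:
            r.rate_law.constrained = False
        # definition ships Vr = Vf / Keq for the constrained reactions, so
        # the unconstrained twin must produce identical derivatives
        state = initial_state(full)
        d1 = rhs(full, state, full.parameters)
        d2 = rhs(uncon, state, uncon.parameters)
        assert np.allclose(d1, d2, rtol=1e-6, atol=1e-8)


class TestIdentifiabilityScreen:
    def test_collinear_fixture_pair_flagged(self):
        # outputs depend on Vf and Vr only through a common direction:
        # a reversible reaction near equilibrium
        params = ParameterSet({"Vf_r": 10.0, "Vr_r": 5.0},
                              classes={"Vf_r": "velocity", "Vr_r": "velocity"})

        class FakeReaction:
            id = "r"
            reversible = True

            class rate_law:
                constrained = False

        class FakeModel:
            reactions = [FakeReaction()]

        def observable(p):
            # equilibrium ratio observable: depends only on Vf/Vr
            return np.array([p["Vf_r"] / p["Vr_r"], 2.0 * p["Vf_r"] / p["Vr_r"]])

        pairs = detect_correlated_velocity_pairs(FakeModel(), params,
                                                 observable_fn=observable)
        assert pairs == [("r", ("Vf_r", "Vr_r"))]

    def test_inert_reverse_velocity_not_flagged(self):
        params = ParameterSet({"Vf_r": 10.0, "Vr_r": 5.0},
                              classes={"Vf_r": "velocity", "Vr_r": "velocity"})

        class FakeReaction:
            id = "r"
            reversible = True

            class rate_law:
                constrained = False

        class FakeModel:
            reactions = [FakeReaction()]

        def observable(p):
            return np.array([p["Vf_r"], p["Vf_r"] ** 2])  # Vr has zero effect

        pairs = detect_correlated_velocity_pairs(FakeModel(), params,
                                                 observable_fn=observable)
        assert pairs == []


class TestEFAST:
    def test_single_active_factor_dominates(self):
        def func(X):
            return X[:, [0]]  # y = x1, x2 inert

        res = efast_indices(func, 2, n_samples=65, M=4, resamples=2, seed=0)
        st = res["total"][:, 0]
        assert st[0] == pytest.approx(1.0, abs=0.05)
        assert st[1] == pytest.approx(0.0, abs=0.05)

    def test_additive_model_matches_variance_fractions(self):
        a, b = 3.0, 1.0

        def func(X):
            return (a * X[:, 0] + b * X[:, 1])[:, None]

        res = efast_indices(func, 2, n_samples=129, M=4, resamples=4, seed=1)
        st = res["total"][:, 0]
        s1 = res["first"][:, 0]
        expect = np.array([a ** 2, b ** 2]) / (a ** 2 + b ** 2)
        assert np.allclose(st, expect, atol=0.05)
        assert np.allclose(s1, expect, atol=0.05)
        # additive model: first-order indices sum to ~1, total >= first
        assert s1.sum() == pytest.approx(1.0, abs=0.05)
        assert np.all(st >= s1 - 0.05)

    def test_sample_size_below_minimum_rejected(self):
        with pytest.raises(ValueError, match="minimum"):
            efast_indices(lambda X: X[:, [0]], 2, n_samples=10, M=4)

    def test_threshold_selection(self):
        params = ParameterSet({"p1": 1.0, "p2": 1.0},
                              classes={"p1": "velocity", "p2": "velocity"})

        def outputs(p):
            return np.array([p["p1"]])  # only p1 matters

        res = efast_sensitivity(None, params, ["p1", "p2"], output_fn=outputs,
                                n_samples=65, M=4, seed=0)
        assert res.selection == ["p1"]
        assert res.indices.shape == (2, 1)
        assert np.all(res.indices <= 1.0 + 0.05)


class TestPSO:
    def test_quadratic_bowl_recovered(self):
        target = np.array([0.3, -1.2])

        def f(x):
            return float(np.sum((x - target) ** 2))

        res = pso_minimize(f, np.array([-5.0, -5.0]), np.array([5.0, 5.0]),
                           n_particles=20, iterations=200, seed=4)
        assert np.allclose(res.best_x, target, atol=1e-3)

    def test_best_so_far_trace_monotone(self):
        def f(x):
            return float(np.sum(np.abs(x)) + np.sin(10 * x[0]))

        res = pso_minimize(f, np.array([-3.0]), np.array([3.0]),
                           n_particles=10, iterations=50, seed=0)
        assert np.all(np.diff(res.trace) <= 1e-12)

    def test_failures_penalized_not_fatal(self):
        calls = {"n": 0}

        def f(x):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("boom")
            return float(np.sum(x ** 2))

        res = pso_minimize(f, np.array([-1.0]), np.array([1.0]),
                           n_particles=8, iterations=30, seed=2)
        assert res.n_failures > 0
        assert res.best_f < 0.1


class TestFitEvaluation:
    def test_perfect_predictions_full_sign_agreement(self):
        ds = _dataset([_obs("A", 1.5, sd=0.1), _obs("B", 0.7, sd=0.1)])
        table = pd.DataFrame({0: [1.5, 0.7], 1: [1.5, 0.7], 2: [1.5, 0.7]})
        frame = evaluate_predictions([None] * 3, ds, prediction_table=table)
        s = frame.attrs["summary"]
        assert s["n_significant_mismatches"] == 0
        assert s["sign_agreement_fraction"] == 1.0

    def test_one_inverted_of_ten_gives_ninety_percent(self):
        rows = [_obs(f"M{i}", 1.5, sd=0.1) for i in range(10)]
        ds = _dataset(rows)
        preds = [1.5] * 9 + [0.6]  # last one predicted in the wrong direction
        table = pd.DataFrame({0: preds, 1: preds})
        frame = evaluate_predictions([None] * 2, ds, prediction_table=table)
        assert frame.attrs["summary"]["sign_agreement_fraction"] == pytest.approx(0.9)

    def test_welch_statistic_matches_textbook_formula(self, rng):
        rows = [_obs(f"M{i}", float(rng.uniform(0.5, 3.0)), sd=float(rng.uniform(0.05, 0.4)))
                for i in range(6)]
        ds = _dataset(rows)
        table = pd.DataFrame(rng.uniform(0.5, 3.0, size=(6, 8)))
        frame = evaluate_predictions([None] * 8, ds, prediction_table=table, replicates=3)
        for i, obs in enumerate(ds.observations):
            preds = table.iloc[i].to_numpy()
            m1, s1, n1 = preds.mean(), preds.std(ddof=1), 8
            m2, s2, n2 = obs.fold_change, obs.sd, 3
            t_manual = (m1 - m2) / np.sqrt(s1 ** 2 / n1 + s2 ** 2 / n2)
            assert frame.t_stat.iloc[i] == pytest.approx(t_manual)
            t_scipy, p_scipy = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                                          equal_var=False)
            assert frame.p_value.iloc[i] == pytest.approx(p_scipy)

    def test_single_fit_skips_ttest_keeps_signs(self):
        ds = _dataset([_obs("A", 1.5, sd=0.1)])
        table = pd.DataFrame({0: [1.4]})
        frame = evaluate_predictions([None], ds, prediction_table=table)
        assert np.isnan(frame.t_stat.iloc[0])
        assert frame.sign_agreement.iloc[0]


class TestFitPSO:
    """Small-budget fitting sanity; the full recovery experiment lives in
    the acceptance suite."""

    def test_best_wssr_not_worse_than_initial_guess(self, reduced):
        truth = generate_ground_truth(reduced, 0.3, seed=5, names=["Vf_hk", "Vf_gld"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            study = simulate_study(reduced, truth, noise_cv=0.0, seed=5,
                                   rtol=1e-5, atol=1e-8)
            ds = study.dataset()
            cfg = FitConfig(free_parameters=["Vf_hk", "Vf_gld"], iterations=15,
                            runs=2, keep_best=2, swarm_size=8, seed=1)
            problem = CalibrationProblem(reduced, ds.train, rtol=cfg.rtol, atol=cfg.atol)
            initial = wssr(problem.predictions(reduced.parameters), ds.train)
            fr = fit_pso(reduced, ds, cfg)
        assert fr.wssr_values[0] <= initial
        assert fr.wssr_values == sorted(fr.wssr_values)
        assert np.all(np.diff(fr.traces[0]) <= 1e-12)


class TestInitialConditionSelection:
    def test_recipe_prefers_truthful_initial_conditions(self, reduced):
        """Candidate initial-condition sets are ranked by fit quality; the
        winner must carry a finite score and the scores one per candidate."""
        from betacell.calibration import select_initial_conditions

        truth = generate_ground_truth(reduced, 0.3, seed=3, names=["Vf_hk"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            study = simulate_study(reduced, truth, noise_cv=0.0, seed=3,
                                   rtol=1e-5, atol=1e-8)
            cfg = FitConfig(free_parameters=["Vf_hk"], iterations=8, runs=1,
                            keep_best=1, swarm_size=6, seed=2)
            winner, scores = select_initial_conditions(
                reduced, study.dataset(), {"CIT_m": (0.05, 1.0)}, cfg,
                n_sets=3, fits_per_set=1, seed=5)
        assert len(scores) == 3
        assert np.isfinite(scores).all()
        assert set(winner) == {"CIT_m"}
        assert scores[int(np.argmin(scores))] == min(scores)
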
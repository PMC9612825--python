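"""ODE integration, conservation, steady states, fold changes, flux utilities."""

import warnings

import numpy as np
import pytest

from betacell.network import build_network, conserved_moieties
from betacell.simulate import (
    StimulationProtocol,
    fold_change,
    initial_state,
    lhs_initial_conditions,
    normalize_fluxes_to_glut,
    pooled_fold_change,
    rhs,
    simulate,
    steady_state,
    time_averaged_fluxes,
)


def _two_species_chain(k=0.25):
    """A -> B with mass-action rate k (closed-form solution available)."""
    return build_network({
        "name": "chain",
        "compartments": [{"id": "c", "name": "cytosol", "relative_volume": 1.0}],
        "species": [
            {"id": "A", "name": "A", "compartment": "c", "init": 2.0},
            {"id": "B", "name": "B", "compartment": "c", "init": 0.0},
        ],
        "reactions": [{"id": "r", "template": "mass_action",
                       "substrates": {"A": 1}, "products": {"B": 1},
                       "params": {"kf": "k"}}],
        "parameters": {"k": {"value": k, "class": "velocity"}},
    })


class TestRhs:
    def test_zero_vmax_zero_derivative(self, reduced):
        params = reduced.parameters.copy()
        for n in params.names_of_class("velocity"):
            params.values[n] = 0.0
        d = rhs(reduced, initial_state(reduced), params)
        assert np.allclose(d, 0.0)

    def test_state_length_checked(self, reduced):
        with pytest.raises(ValueError, match="dynamic species"):
            rhs(reduced, np.ones(3), reduced.parameters)


class TestSimulate:
    def test_initial_point_equals_init(self, reduced):
        init = initial_state(reduced)
        traj = simulate(reduced, reduced.parameters, init, StimulationProtocol(
            phases=[(10.0, {"GLC_e": 2.8})], output_grid=np.array([0.0, 5.0])))
        assert np.allclose(traj.state_at(0.0), init)

    def test_mass_action_chain_matches_analytic_exponential(self):
        model = _two_species_chain(k=0.25)
        t = np.linspace(0.0, 20.0, 21)
        traj = simulate(model, model.parameters, initial_state(model),
                        StimulationProtocol(phases=[(20.0, {})], output_grid=t))
        expect_A = 2.0 * np.exp(-0.25 * t)
        assert np.allclose(traj.species("A"), expect_A, atol=1e-6)
        assert np.allclose(traj.species("B"), 2.0 - expect_A, atol=1e-6)

    def test_conserved_totals_constant_along_trajectory(self, reduced):
        init = initial_state(reduced)
        traj = simulate(reduced, reduced.parameters, init, StimulationProtocol(
            phases=[(120.0, {"GLC_e": 2.8}), (60.0, {"GLC_e": 16.7})],
            output_grid=np.arange(0.0, 181.0, 5.0)))
        vols = reduced.species_volumes()
        for rel in conserved_moieties(reduced):
            totals = traj.concentrations @ (rel.coefficients * vols)
            assert np.max(np.abs(totals / totals[0] - 1)) < 1e-6

    def test_glucose_step_protocol_raises_glycolytic_intermediates(self, reduced):
        init = initial_state(reduced)
        traj = simulate(reduced, reduced.parameters, init, StimulationProtocol(
            phases=[(120.0, {"GLC_e": 2.8}), (15.0, {"GLC_e": 16.7})],
            output_grid=np.array([120.0, 135.0])))
        pre, post = traj.state_at(120.0), traj.state_at(135.0)
        i = traj.species_ids.index("G6P_c")
        assert post[i] > pre[i] * 1.2

    def test_tolerance_refinement_changes_little(self, reduced):
        init = initial_state(reduced)
        proto = StimulationProtocol(phases=[(60.0, {"GLC_e": 16.7})],
                                    output_grid=np.array([0.0, 30.0, 60.0]))
        a = simulate(reduced, reduced.parameters, init, proto, rtol=1e-8, atol=1e-10)
        b = simulate(reduced, reduced.parameters, init, proto, rtol=1e-10, atol=1e-12)
        rel = np.abs(a.concentrations[-1] - b.concentrations[-1]) / np.maximum(
            b.concentrations[-1], 1e-9)
        assert rel.max() < 1e-3

    def test_nonnegative_concentrations(self, reduced):
        init = initial_state(reduced)
        traj = simulate(reduced, reduced.parameters, init, StimulationProtocol(
            phases=[(200.0, {"GLC_e": 16.7})], output_grid=np.arange(0.0, 201.0, 10.0)))
        assert traj.concentrations.min() >= 0.0


class TestSteadyState:
    def test_linear_reversible_pair_matches_keq_ratio(self):
        model = build_network({
            "name": "eq",
            "compartments": [{"id": "c", "name": "cytosol", "relative_volume": 1.0}],
            "species": [
                {"id": "A", "name": "A", "compartment": "c", "init": 3.0},
                {"id": "B", "name": "B", "compartment": "c", "init": 0.0},
            ],
            "reactions": [{"id": "r", "template": "mass_action",
                           "substrates": {"A": 1}, "products": {"B": 1},
                           "params": {"kf": "kf", "kr": "kr"}}],
            "parameters": {"kf": {"value": 1.0, "class": "velocity"},
                           "kr": {"value": 0.5, "class": "velocity"}},
        })
        ss = steady_state(model, model.parameters, initial_state(model), {}, horizon=200.0)
        assert ss.converged
        d = ss.state_dict()
        assert d["B"] / d["A"] == pytest.approx(2.0, rel=1e-5)

    def test_reduced_fixture_certifies_and_balances(self, reduced_high_ss):
        assert reduced_high_ss.converged
        assert reduced_high_ss.sv_inf_norm < 1e-6

    def test_steady_state_independent_of_initial_condition(self, reduced, reduced_high_ss):
        init2 = initial_state(reduced) * 1.7 + 0.05
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ss2 = steady_state(reduced, reduced.parameters, init2, {"GLC_e": 16.7},
                               horizon=3000.0)
        # conserved pools differ between starts; compare a non-conserved species
        i = reduced_high_ss.species_ids.index("GLC_c")
        assert ss2.state[i] == pytest.approx(reduced_high_ss.state[i], rel=5e-3)


class TestFoldChanges:
    def test_identical_trajectories_unity(self, reduced):
        init = initial_state(reduced)
        proto = StimulationProtocol(phases=[(5.0, {"GLC_e": 2.8})],
                                    output_grid=np.array([0.0, 5.0]))
        t1 = simulate(reduced, reduced.parameters, init, proto)
        fc = fold_change(t1, t1, 5.0, "high_vs_low")
        assert all(v == pytest.approx(1.0) for v in fc.values.values())

    def test_elementwise_ratio_matches_brute_force(self, reduced, rng):
        init = initial_state(reduced)
        proto = StimulationProtocol(phases=[(5.0, {"GLC_e": 2.8})],
                                    output_grid=np.array([0.0, 5.0]))
        t1 = simulate(reduced, reduced.parameters, init, proto)
        t2 = simulate(reduced, reduced.parameters, init * rng.uniform(0.5, 2.0, init.size),
                      proto)
        fc = fold_change(t2, t1, 5.0, "high_vs_low")
        a, b = t2.state_at(5.0), t1.state_at(5.0)
        for i, sid in enumerate(t1.species_ids):
            if b[i] >= 1e-9:
                assert fc.values[sid] == pytest.approx(a[i] / b[i])

    def test_vs_t0_uses_own_initial_state(self, reduced):
        init = initial_state(reduced)
        proto = StimulationProtocol(phases=[(5.0, {"GLC_e": 16.7})],
                                    output_grid=np.array([0.0, 5.0]))
        t1 = simulate(reduced, reduced.parameters, init, proto)
        fc = fold_change(t1, None, 5.0, "vs_t0")
        i = t1.species_ids.index("GLC_c")
        assert fc.values["GLC_c"] == pytest.approx(t1.state_at(5.0)[i] / init[i])

    def test_undefined_reference_flagged_not_raised(self, reduced):
        init = initial_state(reduced)
        zeroed = init.copy()
        zeroed[reduced.dynamic_index["LAC_c"]] = 0.0
        proto = StimulationProtocol(phases=[(1e-6, {"GLC_e": 2.8})],
                                    output_grid=np.array([0.0]))
        t0 = simulate(reduced, reduced.parameters, zeroed, proto)
        fc = fold_change(t0, None, 0.0, "vs_t0")
        assert "LAC_c" in fc.undefined


class TestPooling:
    def test_three_to_one_weighting(self, reduced):
        num = initial_state(reduced).copy()
        den = initial_state(reduced).copy()
        ic, im = reduced.dynamic_index["MAL_c"], reduced.dynamic_index["MAL_m"]
        den[ic], den[im] = 2.0, 1.0
        num[ic], num[im] = 4.0, 1.0
        fc = pooled_fold_change(reduced, num, den)
        assert fc.values["MAL"] == pytest.approx(13.0 / 7.0)

    def test_both_compartments_doubling_gives_two(self, reduced):
        den = initial_state(reduced)
        fc = pooled_fold_change(reduced, 2.0 * den, den)
        assert fc.values["MAL"] == pytest.approx(2.0)

    def test_single_compartment_metabolite_passthrough(self, reduced):
        den = initial_state(reduced)
        num = den.copy()
        i = reduced.dynamic_index["G6P_c"]
        num[i] = den[i] * 3.3
        fc = pooled_fold_change(reduced, num, den)
        assert fc.values["G6P"] == pytest.approx(3.3)


class TestFluxUtilities:
    def _traj(self, times, fluxes):
        from betacell.simulate import Trajectory

        return Trajectory(times=np.asarray(times, float),
                          concentrations=np.zeros((len(times), 1)),
                          fluxes=np.asarray(fluxes, float),
                          species_ids=["x"], reaction_ids=["r"])

    def test_constant_flux_average_is_itself(self):
        t = self._traj([0, 1, 2, 3], [[2.0]] * 4)
        assert time_averaged_fluxes(t, (0, 3))[0] == pytest.approx(2.0)

    def test_linear_ramp_averages_to_half(self):
        times = np.linspace(0, 10, 11)
        t = self._traj(times, [[x] for x in times])
        assert time_averaged_fluxes(t, (0, 10))[0] == pytest.approx(5.0)

    def test_trapezoid_close_to_fine_riemann(self, rng):
        times = np.arange(0.0, 61.0, 1.0)
        vals = np.interp(times, [0, 10, 30, 60], [0.1, 0.9, 0.4, 0.6])
        t = self._traj(times, vals[:, None])
        fine = np.linspace(0, 60, 60001)
        riemann = np.trapezoid(np.interp(fine, times, vals), fine) / 60.0
        assert time_averaged_fluxes(t, (0, 60))[0] == pytest.approx(riemann, rel=5e-3)

    def test_empty_window_raises(self):
        t = self._traj([0, 1, 2], [[1.0]] * 3)
        with pytest.raises(ValueError):
            time_averaged_fluxes(t, (5.0, 6.0))

    def test_normalization_assigns_glut_100(self, reduced_high_ss):
        pct = normalize_fluxes_to_glut(reduced_high_ss.fluxes,
                                       reduced_high_ss.reaction_ids)
        assert pct[reduced_high_ss.reaction_ids.index("glut")] == pytest.approx(100.0)

    def test_normalization_preserves_sign_and_ratio(self):
        pct = normalize_fluxes_to_glut(np.array([2.0, 1.0, -0.5]), ["glut", "a", "b"])
        assert pct.tolist() == [100.0, 50.0, -25.0]

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            normalize_fluxes_to_glut(np.array([0.0, 1.0]), ["glut", "a"])


class TestLHS:
    RANGES = {"a": (0.1, 1.0), "b": (1.0, 10.0), "c": (0.01, 0.02)}

    def test_samples_within_ranges_and_count(self):
        sets = lhs_initial_conditions(self.RANGES, 50, seed=7)
        assert len(sets) == 50
        for s in sets:
            for k, (lo, hi) in self.RANGES.items():
                assert lo <= s[k] <= hi

    def test_per_dimension_stratification(self):
        n = 20
        sets = lhs_initial_conditions(self.RANGES, n, seed=3)
        for k, (lo, hi) in self.RANGES.items():
            strata = np.floor((np.array([s[k] for s in sets]) - lo) / (hi - lo) * n)
            assert sorted(strata) == list(range(n))

    def test_deterministic_under_seed(self):
        a = lhs_initial_conditions(self.RANGES, 10, seed=11)
        b = lhs_initial_conditions(self.RANGES, 10, seed=11)
        assert a == b

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            lhs_initial_conditions({"a": (1.0, 0.5)}, 5, seed=0)
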
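import numpy as np
import pytest

from deltafba import core, model_io
from deltafba.core import (InfeasibleProblem, build_milp, minimize_norm,
                           net_delta, solve_consistency, solve_two_step)
from deltafba.regulation import RegulationInput, default_thresholds

from _oracle import oracle_phi_star
from conftest import make_network


def chain_spec(chain_network, eps=0.1, r_up=None, r_down=None, **kwargs):
    split = model_io.split_reversible(chain_network)
    bounds = model_io.delta_bounds(split)
    n = split.n_split
    reg = RegulationInput(
        r_up=dict(r_up or {}), r_down=dict(r_down or {}),
        mu=np.full(n, eps), eta=np.full(n, eps))
    return split, build_milp(split, bounds, reg, **kwargs)


class TestBuild:
    def test_chain_dimensions(self, chain_network):
        split, spec = chain_spec(chain_network, r_up={1: 1.0})
        assert spec.n == 3
        A, lo, hi = spec.constraint_system()
        assert A.shape[1] == 4 * spec.n   # dv + three binary families
        l, u = spec.variable_bounds()
        assert np.all(l[3:] == 0) and np.all(u[3:] == 1)

    def test_empty_regulation_zero_objective(self, chain_network):
        _, spec = chain_spec(chain_network)
        c_u, c_d = spec.objective_z()
        assert not c_u.any() and not c_d.any()
        assert spec.phi_upper_bound == 0.0

    def test_explicit_small_M_rejected(self, chain_network):
        with pytest.raises(ValueError, match="big-M"):
            chain_spec(chain_network, r_up={1: 1.0}, M=5.0)

    def test_default_M_auto_raised_with_warning(self, chain_network):
        chain_network.ub_C[:] = chain_network.ub_P[:] = 2e5
        with pytest.warns(UserWarning, match="raised"):
            _, spec = chain_spec(chain_network, r_up={1: 1.0}, bound_cap=3e5)
        assert spec.M > 4e5

    def test_infinite_bounds_capped(self, chain_network):
        chain_network.ub_P[1] = np.inf
        _, spec = chain_spec(chain_network, r_up={1: 1.0})
        assert spec.dv_max[1] == core.DEFAULT_BOUND_CAP

    def test_reaction_in_both_sets_rejected(self, chain_network):
        split = model_io.split_reversible(chain_network)
        bounds = model_io.delta_bounds(split)
        reg = RegulationInput(r_up={1: 1.0}, r_down={1: 1.0})
        reg.mu, reg.eta = default_thresholds(split)
        with pytest.raises(ValueError, match="both"):
            build_milp(split, bounds, reg)


class TestConsistencyStep:
    def test_chain_upregulated_middle(self, chain_network):
        """Flux balance ties all three reactions; one upregulation is satisfiable."""
        split, spec = chain_spec(chain_network, r_up={1: 1.0})
        phi, inc = solve_consistency(spec)
        assert phi == 1.0
        assert phi == oracle_phi_star(
            np.asarray(split.S_split.todense()), spec.dv_min, spec.dv_max,
            spec.mu, spec.eta, spec.r_up, spec.r_down, split.pair_map)
        assert inc.z_up[1] == 1
        assert inc.dv_split[1] >= spec.mu[1] - 1e-9

    def test_empty_regulation_phi_zero(self, chain_network):
        _, spec = chain_spec(chain_network)
        phi, _ = solve_consistency(spec)
        assert phi == 0.0

    def test_stoichiometrically_conflicting_pair(self):
        """Two producers of one metabolite must have opposite flux changes;
        with both upregulated only one can comply."""
        net = make_network(
            [("R1", {"A": 1.0}), ("R2", {"A": 1.0}), ("SINK", {"A": -1.0})],
            ["A"], [(-10, 10), (-10, 10), (0, 0)])
        split = model_io.split_reversible(net)
        bounds = model_io.delta_bounds(split)
        n = split.n_split
        r_up = {int(split.forward_of[0]): 1.0, int(split.forward_of[1]): 1.0}
        reg = RegulationInput(r_up=r_up, mu=np.full(n, 0.1), eta=np.full(n, 0.1))
        spec = build_milp(split, bounds, reg)
        phi, _ = solve_consistency(spec)
        assert phi == 1.0
        assert phi == oracle_phi_star(
            np.asarray(split.S_split.todense()), spec.dv_min, spec.dv_max,
            spec.mu, spec.eta, spec.r_up, spec.r_down, split.pair_map)

    def test_forced_zero_blocks_chain(self, chain_network):
        split = model_io.split_reversible(chain_network)
        bounds = model_io.delta_bounds(split)
        reg = RegulationInput(r_up={1: 1.0}, forced_zero={0},
                              mu=np.full(3, 0.1), eta=np.full(3, 0.1))
        spec = build_milp(split, bounds, reg)
        phi, inc = solve_consistency(spec)
        assert phi == 0.0          # dv must vanish along the whole chain
        assert abs(inc.dv_split[1]) <= 1e-9

    def test_contradictory_overrides_report_infeasible(self, chain_network):
        split = model_io.split_reversible(chain_network)
        bounds = model_io.delta_bounds(
            split, overrides={"EX_A": (2.0, 2.0), "EX_B": (-2.0, -2.0)})
        reg = RegulationInput(mu=np.full(3, 0.1), eta=np.full(3, 0.1))
        spec = build_milp(split, bounds, reg)
        with pytest.raises(InfeasibleProblem, match="override"):
            solve_consistency(spec)


class TestNormStep:
    @pytest.mark.parametrize("norm,binaries", [
        ("L2", "free"), ("L2", "fixed"), ("L1", "free"), ("L1", "fixed")])
    def test_chain_pins_at_threshold(self, chain_network, norm, binaries):
        """Balance forces equal dv on the chain; minimality pins it at eps."""
        _, spec = chain_spec(chain_network, eps=0.1, r_up={1: 1.0})
        phi, inc = solve_consistency(spec)
        sol = minimize_norm(spec, phi, inc, norm=norm, binaries=binaries)
        np.testing.assert_allclose(sol.dv_split, [0.1, 0.1, 0.1], atol=1e-6)
        expected = 3 * 0.1 if norm == "L1" else 3 * 0.01
        assert sol.step2_norm == pytest.approx(expected, abs=1e-6)
        assert sol.phi_star == phi

    def test_empty_regulation_gives_zero_vector(self, chain_network):
        _, spec = chain_spec(chain_network)
        sol = solve_two_step(spec)
        np.testing.assert_allclose(sol.dv_split, 0.0, atol=1e-9)
        assert sol.step2_norm == pytest.approx(0.0, abs=1e-12)

    def test_step2_norm_never_exceeds_incumbent(self, chain_network):
        _, spec = chain_spec(chain_network, r_up={1: 1.0}, r_down={2: 1.0})
        phi, inc = solve_consistency(spec)
        inc_norm = float(inc.dv_split @ inc.dv_split)
        for binaries in ("free", "fixed"):
            sol = minimize_norm(spec, phi, inc, norm="L2", binaries=binaries)
            assert sol.step2_norm <= inc_norm + 1e-9

    def test_fixed_binaries_resolve_is_deterministic(self, chain_network):
        _, spec = chain_spec(chain_network, r_up={1: 1.0})
        phi, inc = solve_consistency(spec)
        a = minimize_norm(spec, phi, inc, norm="L2", binaries="fixed")
        b = minimize_norm(spec, phi, inc, norm="L2", binaries="fixed")
        np.testing.assert_allclose(a.dv_split, b.dv_split, atol=1e-6)

    def test_l1_equals_l2_phi(self, chain_network):
        _, spec = chain_spec(chain_network, r_up={1: 1.0})
        s1 = solve_two_step(spec, norm="L1")
        s2 = solve_two_step(spec, norm="L2")
        assert s1.phi_star == s2.phi_star

    def test_unknown_norm_rejected(self, chain_network):
        _, spec = chain_spec(chain_network, r_up={1: 1.0})
        phi, inc = solve_consistency(spec)
        with pytest.raises(ValueError, match="norm"):
            minimize_norm(spec, phi, inc, norm="L7")


class TestSolutionContracts:
    def scenarios(self):
        from deltafba import synthetic
        for seed in range(4):
            net = synthetic.make_toy_network(5, 2, 0.4, seed=seed)
            yield synthetic.simulate_condition_pair(
                net, ["R1"], 1.0, 0.2, 0.2, seed=seed)

    @pytest.mark.parametrize("norm", ["L1", "L2"])
    def test_balance_and_indicator_soundness(self, norm):
        from deltafba.pipeline import run_scenario

        for scen in self.scenarios():
            out = run_scenario(scen, norm=norm, binaries="free")
            sol, spec = out["solution"], out["spec"]
            scale = max(1.0, float(np.max(np.abs(sol.dv_split))))
            assert sol.balance_residual <= 1e-6 * scale
            up = sol.z_up.astype(bool)
            down = sol.z_down.astype(bool)
            zero = sol.z_zero.astype(bool)
            assert np.all(sol.z_up + sol.z_down <= 1)
            assert np.all(sol.dv_split[up] >= spec.mu[up] - 1e-6)
            assert np.all(sol.dv_split[down] <= -spec.eta[down] + 1e-6)
            assert np.all(np.abs(sol.dv_split[zero]) <= 1e-6)
            # zU=0 implies dv <= mu, zD=0 implies dv >= -eta
            assert np.all(sol.dv_split[~up] <= spec.mu[~up] + 1e-6)
            assert np.all(sol.dv_split[~down] >= -spec.eta[~down] - 1e-6)

    def test_phi_bounded_by_total_weight(self):
        from deltafba.pipeline import run_scenario

        for scen in self.scenarios():
            out = run_scenario(scen)
            assert out["phi_star"] <= out["spec"].phi_upper_bound + 1e-12


class TestZeroModeAndCoupling:
    def reversible_case(self, pair_coupling="symmetric", z0_mode="free"):
        net = make_network(
            [("SRC", {"A": 1.0}), ("R", {"A": -1.0, "B": 1.0}),
             ("ALT", {"A": -1.0, "B": 1.0}), ("SNK", {"B": -1.0})],
            ["A", "B"], [(0, 10), (-10, 10), (-10, 10), (0, 10)])
        split = model_io.split_reversible(net)
        bounds = model_io.delta_bounds(split)
        n = split.n_split
        reg = RegulationInput(r_up={int(split.forward_of[1]): 1.0},
                              r_down={int(split.forward_of[2]): 1.0},
                              mu=np.full(n, 0.1), eta=np.full(n, 0.1))
        return split, build_milp(split, bounds, reg,
                                 pair_coupling=pair_coupling, z0_mode=z0_mode)

    @pytest.mark.parametrize("coupling", ["symmetric", "printed"])
    def test_phi_matches_oracle_under_both_couplings(self, coupling):
        split, spec = self.reversible_case(pair_coupling=coupling)
        phi, _ = solve_consistency(spec)
        phi_o = oracle_phi_star(
            np.asarray(split.S_split.todense()), spec.dv_min, spec.dv_max,
            spec.mu, spec.eta, spec.r_up, spec.r_down, split.pair_map,
            pair_coupling=coupling)
        assert phi == phi_o

    def test_strict_z0_never_beats_free(self):
        _, spec_free = self.reversible_case(z0_mode="free")
        _, spec_strict = self.reversible_case(z0_mode="strict")
        phi_free, _ = solve_consistency(spec_free)
        phi_strict, _ = solve_consistency(spec_strict)
        assert phi_strict <= phi_free

    def test_symmetric_coupling_prevents_pair_cancellation(self):
        """With symmetric coupling an upregulated reversible reaction cannot
        hide its change in a sub-threshold backward leak."""
        split, spec = self.reversible_case(pair_coupling="symmetric")
        sol = solve_two_step(spec, norm="L2", binaries="free")
        j = split.net.reaction_index("R")
        assert sol.dv_net[j] >= spec.mu[split.forward_of[j]] - 1e-9


class TestNetDelta:
    def test_forward_backward_combination(self, chain_network):
        net = make_network(
            [("R1", {"A": 1.0}), ("R2", {"A": -1.0})], ["A"],
            [(-10, 10), (0, 10)])
        split = model_io.split_reversible(net)
        sol = core.DeltaSolution(
            dv_split=np.array([2.0, 0.0, 1.5]), dv_net=None,
            z_up=np.zeros(3, int), z_down=np.zeros(3, int),
            z_zero=np.zeros(3, int), phi_star=0.0, step2_norm=None,
            solver_status="n/a", gap=0.0)
        np.testing.assert_allclose(net_delta(sol, split), [2.0, 1.5])
        sol.dv_split = np.array([0.0, 3.0, 1.5])
        np.testing.assert_allclose(net_delta(sol, split), [-3.0, 1.5])
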
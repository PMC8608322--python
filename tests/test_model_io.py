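import numpy as np
import pytest
import scipy.sparse as sp

from deltafba import model_io
from deltafba.gpr import parse_gpr

from conftest import make_network

from pathlib import Path

FIXTURE = Path(__file__).parent / "data" / "mini_ecoli.json"


class TestLoadModel:
    def test_json_fixture_counts_and_rules(self):
        net = model_io.load_model(FIXTURE, format="json")
        assert net.n_reactions == 10
        assert net.S.shape[0] == len(net.metabolite_ids)
        # every GPR string parses without error
        for rule in net.gpr_rules:
            parse_gpr(rule)
        assert "b2388" in net.gene_ids
        assert net.subsystems[net.reaction_index("PGI")] == "Glycolysis/Gluconeogenesis"
        # both conditions initialized to the model bounds
        np.testing.assert_array_equal(net.lb_C, net.lb_P)
        np.testing.assert_array_equal(net.ub_C, net.ub_P)

    def test_sbml_round_trip(self, tmp_path, chain_network):
        import cobra

        model = cobra.Model("chain")
        a = cobra.Metabolite("A", compartment="c")
        b = cobra.Metabolite("B", compartment="c")
        model.add_metabolites([a, b])
        r1 = cobra.Reaction("EX_A", lower_bound=0, upper_bound=10)
        r2 = cobra.Reaction("R_AB", lower_bound=0, upper_bound=10)
        r3 = cobra.Reaction("EX_B", lower_bound=0, upper_bound=10)
        model.add_reactions([r1, r2, r3])
        r1.add_metabolites({a: 1})
        r2.add_metabolites({a: -1, b: 1})
        r3.add_metabolites({b: -1})
        r2.gene_reaction_rule = "g1"
        path = tmp_path / "chain.xml"
        cobra.io.write_sbml_model(model, str(path))

        net = model_io.load_model(path, format="sbml")
        assert net.reaction_ids == ["EX_A", "R_AB", "EX_B"]
        assert net.n_metabolites == 2
        np.testing.assert_array_equal(
            np.asarray(net.S.todense()), np.asarray(chain_network.S.todense()))

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            model_io.load_model("no/such/model.json")

    def test_unknown_format(self):
        with pytest.raises(ValueError, match="unknown model format"):
            model_io.load_model(FIXTURE, format="mat")

    def test_empty_network_rejected(self, tmp_path):
        import cobra
        import cobra.io

        path = tmp_path / "empty.json"
        cobra.io.save_json_model(cobra.Model("empty"), str(path))
        with pytest.raises(ValueError, match="empty network"):
            model_io.load_model(path)

    def test_undeclared_rule_genes_registered_with_warning(self):
        with pytest.warns(UserWarning, match="auto-registering"):
            net = make_network(
                reactions=[("R1", {"A": 1.0}), ("R2", {"A": -1.0})],
                metabolites=["A"],
                bounds=[(0, 10), (0, 10)],
                rules=["gX and gY", ""],
            )
        assert {"gX", "gY"} <= set(net.gene_ids)


class TestSplitReversible:
    @pytest.mark.parametrize(
        "bounds, expect",
        [
            # (forward lb, ub), (backward lb, ub) or None if unsplit
            ((-10, 10), ((0, 10), (0, 10))),
            ((0, 10), ((0, 10), None)),
            ((-10, -2), ((0, 0), (2, 10))),
        ],
    )
    def test_bound_transfer(self, bounds, expect):
        lo, hi = bounds
        net = make_network(
            reactions=[("SRC", {"A": 1.0}), ("R", {"A": -1.0})],
            metabolites=["A"],
            bounds=[(0, 10), (lo, hi)],
        )
        split = model_io.split_reversible(net)
        j = split.forward_of[1]
        fwd_expect, bwd_expect = expect
        assert (split.lb_C[j], split.ub_C[j]) == fwd_expect
        if bwd_expect is None:
            assert split.backward_of[1] == -1
        else:
            k = split.backward_of[1]
            assert (split.lb_C[k], split.ub_C[k]) == bwd_expect
            assert (1 if lo < 0 else 0) and (j, k) in split.pair_map

    def test_pair_columns_are_exact_negatives(self):
        net = make_network(
            reactions=[("R1", {"A": 1.0, "B": -2.0}), ("R2", {"B": 1.0})],
            metabolites=["A", "B"],
            bounds=[(-5, 5), (-3, 9)],
        )
        split = model_io.split_reversible(net)
        S = np.asarray(split.S_split.todense())
        for k, kp in split.pair_map:
            np.testing.assert_array_equal(S[:, kp], -S[:, k])

    def test_net_round_trip_forward_only_vector(self):
        net = make_network(
            reactions=[("R1", {"A": 1.0}), ("R2", {"A": -1.0, "B": 1.0}),
                       ("R3", {"B": -1.0})],
            metabolites=["A", "B"],
            bounds=[(0, 10), (-10, 10), (-2, 10)],
        )
        split = model_io.split_reversible(net)
        x = np.zeros(split.n_split)
        x[split.forward_of] = [1.0, 2.0, 3.0]
        np.testing.assert_allclose(split.net_vector(x), [1.0, 2.0, 3.0])

    def test_one_condition_reversibility_still_splits(self):
        net = make_network(
            reactions=[("R", {"A": 1.0}), ("X", {"A": -1.0})],
            metabolites=["A"], bounds=[(0, 10), (0, 10)],
        )
        net.lb_P[0] = -4.0  # reversible only in the perturbed condition
        split = model_io.split_reversible(net)
        k = split.backward_of[0]
        assert k >= 0
        assert (split.lb_C[k], split.ub_C[k]) == (0.0, 0.0)   # disallowed in C
        assert (split.lb_P[k], split.ub_P[k]) == (0.0, 4.0)


class TestDeltaBounds:
    def test_basic_interval(self):
        net = make_network([("SRC", {"A": 1.0}), ("R", {"A": -1.0})], ["A"],
                           [(0, 10), (0, 10)])
        split = model_io.split_reversible(net)
        db = model_io.delta_bounds(split)
        np.testing.assert_allclose(db.dv_min, [-10, -10])
        np.testing.assert_allclose(db.dv_max, [10, 10])

    def test_fixed_bounds_give_point_interval(self):
        net = make_network([("SRC", {"A": 1.0}), ("R", {"A": -1.0})], ["A"],
                           [(0, 10), (0, 10)])
        net.lb_P[1] = net.ub_P[1] = 2.0
        net.lb_C[1] = net.ub_C[1] = 5.0
        split = model_io.split_reversible(net)
        db = model_io.delta_bounds(split)
        j = split.forward_of[1]
        assert (db.dv_min[j], db.dv_max[j]) == (-3.0, -3.0)

    def test_reversible_in_p_only_forward_interval(self):
        # v_P in [-5, 8] (forward half [0, 8]); v_C forward [0, 10]
        net = make_network([("SRC", {"A": 1.0}), ("R", {"A": -1.0})], ["A"],
                           [(0, 20), (0, 10)])
        net.lb_P[1], net.ub_P[1] = -5.0, 8.0
        split = model_io.split_reversible(net)
        db = model_io.delta_bounds(split)
        j = split.forward_of[1]
        assert (db.dv_min[j], db.dv_max[j]) == (-10.0, 8.0)

    def test_override_irreversible_replaces_interval(self):
        net = make_network([("SRC", {"A": 1.0}), ("R", {"A": -1.0})], ["A"],
                           [(0, 10), (0, 10)])
        split = model_io.split_reversible(net)
        db = model_io.delta_bounds(split, overrides={"R": (-1.5, -1.5)})
        j = split.forward_of[1]
        assert (db.dv_min[j], db.dv_max[j]) == (-1.5, -1.5)
        assert not db.net_overrides

    def test_override_reversible_becomes_net_constraint(self):
        net = make_network([("SRC", {"A": 1.0}), ("R", {"A": -1.0})], ["A"],
                           [(0, 10), (-10, 10)])
        split = model_io.split_reversible(net)
        db = model_io.delta_bounds(split, overrides={"R": (0.5, 2.0)})
        assert db.net_overrides == {1: (0.5, 2.0)}

    def test_override_inverted_interval_rejected(self):
        net = make_network([("R", {"A": 1.0}), ("X", {"A": -1.0})], ["A"],
                           [(0, 10), (0, 10)])
        split = model_io.split_reversible(net)
        with pytest.raises(ValueError, match="dv_min"):
            model_io.delta_bounds(split, overrides={"R": (3.0, 1.0)})

    def test_widening_bounds_never_narrows_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            ub = rng.uniform(1, 20)
            net = make_network([("SRC", {"A": 1.0}), ("R", {"A": -1.0})], ["A"],
                               [(0, 10), (0, ub)])
            split = model_io.split_reversible(net)
            db = model_io.delta_bounds(split)
            net.ub_P[1] = ub + rng.uniform(0, 5)   # widen P
            net.lb_C[1] = -rng.uniform(0, 5)       # widen C
            split2 = model_io.split_reversible(net)
            db2 = model_io.delta_bounds(split2)
            j, j2 = split.forward_of[1], split2.forward_of[1]
            assert db2.dv_min[j2] <= db.dv_min[j] + 1e-12
            assert db2.dv_max[j2] >= db.dv_max[j] - 1e-12
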
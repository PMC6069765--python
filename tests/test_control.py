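import numpy as np
import pytest

from netcontrol import (
    ControlConfig,
    ControlPath,
    ControlSolution,
    DirectedNetwork,
    brute_force_minimum_driven,
    build_realization,
    find_driven_nodes,
    is_target_controllable_generic,
    kalman_rank_check,
    single_run,
    verify_path_family,
)
from netcontrol.fixtures import fig3_network, random_digraph

CFG = ControlConfig(runs=50, rng_seed=7)


class TestHeuristic:
    def test_chain_single_driven_node(self, chain):
        sol = find_driven_nodes(chain, {"b", "c"}, CFG)
        assert sol.driven == {"a"}
        assert sol.paths["b"].node_sequence == ("a", "b")
        assert sol.paths["c"].node_sequence == ("a", "b", "c")

    def test_star_needs_two_driven_nodes(self, star):
        sol = find_driven_nodes(star, {"t1", "t2"}, CFG)
        assert len(sol.driven) == 2
        assert sol.driven != {"h"}
        assert verify_path_family(star, sol, {"t1", "t2"}).ok

    def test_isolated_target_drives_itself(self):
        net = DirectedNetwork(nodes=["t"])
        sol = single_run(net, {"t"}, CFG, np.random.default_rng(0))
        assert sol.driven == {"t"}
        assert sol.paths["t"].node_sequence == ("t",)

    def test_unknown_target_named_in_error(self, chain):
        with pytest.raises(ValueError, match="zzz"):
            find_driven_nodes(chain, {"zzz"}, CFG)

    def test_deterministic_for_fixed_seed(self, fig3):
        cfg = ControlConfig(runs=30, rng_seed=11, preferred=fig3.drug_targets)
        a = find_driven_nodes(fig3.network, fig3.targets, cfg)
        b = find_driven_nodes(fig3.network, fig3.targets, cfg)
        assert a.driven == b.driven
        assert {t: p.node_sequence for t, p in a.paths.items()} == {
            t: p.node_sequence for t, p in b.paths.items()
        }

    def test_restart_monotonicity(self):
        net = random_digraph(12, 0.25, rng_seed=3)
        targets = {"n0", "n3", "n7"}
        prev = None
        for runs in (1, 10, 100):
            cfg = ControlConfig(runs=runs, rng_seed=5)
            key = find_driven_nodes(net, targets, cfg).objective(frozenset())
            if prev is not None:
                assert key <= prev
            prev = key

    def test_driven_never_exceeds_targets(self):
        for seed in range(10):
            net = random_digraph(15, 0.2, rng_seed=seed)
            targets = {f"n{i}" for i in (0, 4, 9)}
            sol = find_driven_nodes(net, targets, ControlConfig(runs=10, rng_seed=seed))
            assert len(sol.driven) <= len(targets)
            assert sum(sol.targets_controlled.values()) == len(targets)

    def test_fig3_with_drug_preference(self, fig3):
        cfg = ControlConfig(runs=1000, rng_seed=42, preferred=fig3.drug_targets)
        sol = find_driven_nodes(fig3.network, fig3.targets, cfg)
        assert sol.driven == {"AKT1", "NRG1"}
        assert sol.paths["MTOR"].start == "AKT1"
        assert sol.paths["ERBB3"].start == "NRG1"

    def test_fig3_without_preference_single_driver(self, fig3):
        cfg = ControlConfig(runs=1000, rng_seed=42)
        sol = find_driven_nodes(fig3.network, fig3.targets, cfg)
        assert sol.driven == {"NRG1"}
        assert verify_path_family(fig3.network, sol, fig3.targets).ok


class TestVerifier:
    def test_valid_fig3_solution_passes(self, fig3):
        sol = ControlSolution(
            driven=frozenset({"AKT1", "NRG1"}),
            paths={
                "MTOR": ControlPath(("AKT1", "MTOR")),
                "ERBB3": ControlPath(("NRG1", "ERBB3")),
            },
        )
        assert verify_path_family(fig3.network, sol, {"MTOR", "ERBB3"}).ok

    def test_layer_collision_detected(self, star):
        sol = ControlSolution(
            driven=frozenset({"h"}),
            paths={"t1": ControlPath(("h", "t1")), "t2": ControlPath(("h", "t2"))},
        )
        report = verify_path_family(star, sol, {"t1", "t2"})
        assert not report.ok
        assert any(v[0] == "layer" and v[1] == 1 and v[2] == "h" for v in report.violations)

    def test_missing_path_detected(self, chain):
        sol = ControlSolution(driven=frozenset(), paths={})
        assert not verify_path_family(chain, sol, {"c"}).ok

    def test_non_edge_step_detected(self, chain):
        sol = ControlSolution(
            driven=frozenset({"c"}), paths={"a": ControlPath(("c", "a"))}
        )
        report = verify_path_family(chain, sol, {"a"})
        assert any(v[0] == "edge" for v in report.violations)


class TestRealization:
    def test_structure_forced_two_node(self):
        net = DirectedNetwork(edges=[("a", "b")])
        real = build_realization(net, {"a"}, {"b"}, np.random.default_rng(1))
        ia, ib = real.node_index["a"], real.node_index["b"]
        assert real.A[ib, ia] != 0
        assert np.count_nonzero(real.A) == 1
        assert np.count_nonzero(real.B) == 1 and real.B[ia, 0] != 0
        assert real.C.tolist() == [[0.0, 1.0]] if ib == 1 else [[1.0, 0.0]]

    def test_same_seed_identical(self, fig3):
        r1 = build_realization(fig3.network, {"NRG1"}, fig3.targets, np.random.default_rng(9))
        r2 = build_realization(fig3.network, {"NRG1"}, fig3.targets, np.random.default_rng(9))
        assert np.array_equal(r1.A, r2.A) and np.array_equal(r1.B, r2.B)

    def test_fig3_nonzero_count(self, fig3):
        real = build_realization(fig3.network, {"NRG1"}, fig3.targets, np.random.default_rng(0))
        assert np.count_nonzero(real.A) == 42

    def test_empty_driven_rejected(self, chain):
        with pytest.raises(ValueError):
            build_realization(chain, set(), {"c"}, np.random.default_rng(0))


class TestRankOracle:
    def test_chain_rank_two(self, chain):
        real = build_realization(chain, {"a"}, {"b", "c"}, np.random.default_rng(2))
        assert kalman_rank_check(real) == 2

    def test_star_rank_one_from_hub(self, star):
        real = build_realization(star, {"h"}, {"t1", "t2"}, np.random.default_rng(2))
        assert kalman_rank_check(real) == 1

    def test_driven_equal_targets_full_rank(self):
        net = random_digraph(8, 0.3, rng_seed=1)
        targets = {"n1", "n4", "n6"}
        real = build_realization(net, targets, targets, np.random.default_rng(3))
        assert kalman_rank_check(real) == 3

    def test_cayley_hamilton_truncation(self):
        # extending beyond n blocks never increases the rank
        net = random_digraph(7, 0.3, rng_seed=4)
        real = build_realization(net, {"n0"}, {"n2", "n5"}, np.random.default_rng(4))
        rank_n = kalman_rank_check(real)
        blocks = []
        M = real.B.copy()
        for _ in range(real.n + 5):
            blocks.append(real.C @ M)
            M = real.A @ M
            norms = np.linalg.norm(M, axis=0)
            norms[norms == 0] = 1.0
            M /= norms
        rank_ext = np.linalg.matrix_rank(np.hstack(blocks))
        assert rank_n == rank_ext

    def test_oracle_cap_enforced(self):
        big = np.zeros((201, 201))
        from netcontrol.control import LinearSystemRealization

        real = LinearSystemRealization(big, np.zeros((201, 1)), np.zeros((1, 201)), {})
        with pytest.raises(ValueError, match="cap"):
            kalman_rank_check(real)


class TestGenericControllability:
    def test_star_hub_alone_insufficient(self, star):
        assert not is_target_controllable_generic(star, {"h"}, {"t1", "t2"})

    def test_targets_subset_of_driven(self, chain):
        assert is_target_controllable_generic(chain, {"b", "c"}, {"b", "c"})

    def test_heuristic_solutions_always_generic(self):
        for seed in range(15):
            net = random_digraph(10, 0.25, rng_seed=seed)
            targets = {"n1", "n5"}
            sol = find_driven_nodes(net, targets, ControlConfig(runs=5, rng_seed=seed))
            assert verify_path_family(net, sol, targets).ok
            assert is_target_controllable_generic(net, sol.driven, targets)


class TestBruteForce:
    def test_chain_minimum_is_one(self, chain):
        assert brute_force_minimum_driven(chain, {"b", "c"}) == {"a"}

    def test_star_minimum_is_two(self, star):
        best = brute_force_minimum_driven(star, {"t1", "t2"})
        assert best is not None and len(best) == 2

    def test_single_target_with_parent(self, chain):
        best = brute_force_minimum_driven(chain, {"b"})
        assert best is not None and len(best) == 1

    def test_size_cap(self):
        net = random_digraph(16, 0.1, rng_seed=0)
        with pytest.raises(ValueError, match="15"):
            brute_force_minimum_driven(net, {"n0"})

    def test_heuristic_never_beats_brute_force(self):
        for seed in range(8):
            net = random_digraph(9, 0.25, rng_seed=100 + seed)
            targets = {"n0", "n3", "n6"}
            sol = find_driven_nodes(net, targets, ControlConfig(runs=100, rng_seed=seed))
            best = brute_force_minimum_driven(net, targets)
            assert best is not None
            assert len(sol.driven) >= len(best)


def test_config_validation():
    with pytest.raises(ValueError):
        ControlConfig(runs=0)
    with pytest.raises(ValueError):
        ControlConfig(termination_prob=1.5)
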
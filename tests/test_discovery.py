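"""Tabu search: neighborhood correctness, stopping rules, optimality."""
import numpy as np
import pytest

from bowtiepm.discovery import (
    SearchParams,
    discover_bowtie,
    enumerate_moves,
    initial_model,
    neighborhood,
    tabu_search,
)
from bowtiepm.model import (
    ProcessModel,
    SizeConstraints,
    Support,
    SuccessionUniverse,
    succession_universe,
    within_constraints,
)

from conftest import exhaustive_optimum, make_log, oracle_score


def tiny_universe():
    return SuccessionUniverse(
        nodes={"A": Support(3, 3), "B": Support(2, 2)},
        edges={("A", "B"): Support(2, 2)},
    )


class TestInitialModel:
    def test_single_node_universe_is_forced(self):
        uni = SuccessionUniverse(nodes={"A": Support(1, 1)}, edges={})
        for seed in range(5):
            m = initial_model(uni, SizeConstraints(5, 5), seed)
            assert m == ProcessModel(frozenset({"A"}), frozenset())

    def test_same_seed_same_model(self):
        uni = tiny_universe()
        assert initial_model(uni, SizeConstraints(2, 1), 42) == initial_model(
            uni, SizeConstraints(2, 1), 42
        )

    def test_equal_supports_give_uniform_slot_frequencies(self):
        uni = SuccessionUniverse(
            nodes={c: Support(5, 5) for c in "ABC"}, edges={}
        )
        rng = np.random.default_rng(0)
        hits = {c: 0 for c in "ABC"}
        slots = 0
        for _ in range(1000):
            m = initial_model(uni, SizeConstraints(3, 0), rng)
            for c in m.nodes:
                hits[c] += 1
            slots += m.n_nodes
        for c in "ABC":
            assert abs(hits[c] / slots - 1 / 3) <= 0.05

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            initial_model(SuccessionUniverse(nodes={}, edges={}), SizeConstraints(2, 2), 0)


class TestNeighborhood:
    def test_empty_model_grows_single_node_models(self):
        nbs = neighborhood(ProcessModel.empty(), tiny_universe(), SizeConstraints(2, 1))
        sigs = {nb.signature() for nb in nbs}
        assert ProcessModel(frozenset("A"), frozenset()).signature() in sigs
        assert ProcessModel(frozenset("B"), frozenset()).signature() in sigs

    def test_no_add_node_at_node_cap(self):
        current = ProcessModel(frozenset({"A"}), frozenset())
        nbs = neighborhood(current, tiny_universe(), SizeConstraints(1, 1))
        assert all(nb.n_nodes <= 1 for nb in nbs)

    def test_full_neighbor_set_matches_hand_enumeration(self):
        # {A,B} with edge (A,B) over the tiny universe: the only legal
        # single edits are dropping a node (with its edges) or the edge.
        current = ProcessModel(frozenset({"A", "B"}), frozenset({("A", "B")}))
        nbs = neighborhood(current, tiny_universe(), SizeConstraints(2, 1))
        expected = {
            ProcessModel(frozenset({"A"}), frozenset()).signature(),
            ProcessModel(frozenset({"B"}), frozenset()).signature(),
            ProcessModel(frozenset({"A", "B"}), frozenset()).signature(),
        }
        assert {nb.signature() for nb in nbs} == expected

    def test_all_neighbors_feasible(self, demo_log):
        uni = succession_universe(demo_log, "pre")
        constraints = SizeConstraints(6, 8)
        current = initial_model(uni, constraints, 1)
        for _ in range(3):
            nbs = neighborhood(current, uni, constraints)
            assert nbs, "expected a non-empty neighborhood"
            assert all(within_constraints(nb, constraints) for nb in nbs)
            current = nbs[0]

    def test_moves_cover_five_kinds(self, demo_log):
        uni = succession_universe(demo_log, "pre")
        constraints = SizeConstraints(6, 8)
        m = initial_model(uni, constraints, 3)
        kinds = {mv[0] for mv in enumerate_moves(m, uni, constraints)}
        assert kinds <= {"add_node", "remove_node", "add_edge", "remove_edge", "swap_node"}
        assert {"remove_node", "swap_node"} <= kinds


class TestTabuSearch:
    def test_reaches_perfect_score_when_full_graph_feasible(self):
        log = make_log(pre={"p1": ["A", "B", "C"], "p2": ["A", "C"], "p3": ["B", "C"]})
        res = tabu_search(log, "pre", None, SizeConstraints(5, 10), SearchParams(seed=0))
        assert res.best_score == 1.0
        assert res.iterations_run <= 500

    def test_plateau_stop_accumulates_exactly_patience(self):
        log = make_log(pre={"p1": ["A", "B"], "p2": ["A", "B"]})
        res = tabu_search(log, "pre", None, SizeConstraints(3, 3), SearchParams(seed=1))
        assert res.stop_reason == "plateau"
        assert res.plateau_length_at_stop == 25

    def test_budget_stop_at_max_iterations(self, demo_log):
        params = SearchParams(max_iterations=5, patience=100, seed=2)
        res = tabu_search(demo_log, "pre", None, SizeConstraints(25, 40), params)
        assert res.stop_reason == "budget"
        assert res.iterations_run == 5

    def test_empty_side_returns_empty_model(self):
        log = make_log(pre={"p1": ["A"]})
        res = tabu_search(log, "post", None, SizeConstraints(5, 5), SearchParams(seed=0))
        assert res.best_model == ProcessModel.empty()
        assert res.best_score == 0.0
        assert res.iterations_run == 0 and res.stop_reason == "budget"

    def test_identical_params_identical_results(self, demo_log):
        params = SearchParams(max_iterations=40, seed=9)
        a = tabu_search(demo_log, "pre", None, SizeConstraints(10, 15), params)
        b = tabu_search(demo_log, "pre", None, SizeConstraints(10, 15), params)
        assert a.best_model == b.best_model
        assert a.score_history == b.score_history

    def test_global_score_history_is_monotone(self, demo_log):
        res = tabu_search(demo_log, "pre", None, SizeConstraints(25, 40), SearchParams(seed=4))
        best_seq = [b for _, b in res.score_history]
        assert all(x <= y + 1e-12 for x, y in zip(best_seq, best_seq[1:]))
        assert res.best_score == best_seq[-1]

    def test_hill_climb_mode_never_degrades_current(self, demo_log):
        params = SearchParams(seed=5, hill_climb=True, max_iterations=60)
        res = tabu_search(demo_log, "pre", None, SizeConstraints(15, 25), params)
        cur_seq = [c for c, _ in res.score_history]
        assert all(x <= y + 1e-12 for x, y in zip(cur_seq, cur_seq[1:]))

    @pytest.mark.parametrize(
        "pre,constraints",
        [
            ({"p1": ["A", "B"], "p2": ["B", "A"], "p3": ["A", "B", "A"]}, (2, 1)),
            ({"p1": ["A", "B", "C"], "p2": ["C", "A"], "p3": ["B"]}, (2, 2)),
            ({"p1": ["A", "A", "B"], "p2": ["A", "B"]}, (1, 1)),
        ],
    )
    def test_attains_exhaustive_optimum_on_tiny_instances(self, pre, constraints):
        log = make_log(pre=pre)
        opt, _ = exhaustive_optimum(log, "pre", *constraints)
        res = tabu_search(
            log, "pre", None, SizeConstraints(*constraints), SearchParams(seed=0)
        )
        assert res.best_score <= opt + 1e-12
        assert res.best_score == pytest.approx(opt)
        # the reported score is reproducible from the reported model
        assert oracle_score(log, "pre", res.best_model.nodes, res.best_model.edges) == (
            pytest.approx(res.best_score)
        )


class TestDiscoverBowtie:
    def test_halves_respect_their_constraints(self, demo_log):
        res = discover_bowtie(demo_log, params=SearchParams(seed=0))
        assert res.pre.best_model.n_nodes <= 25 and res.pre.best_model.n_edges <= 40
        assert res.post.best_model.n_nodes <= 15 and res.post.best_model.n_edges <= 25
        assert res.index_class == "Septicemia"
        assert res.index_class not in res.pre.best_model.nodes
        assert res.index_class not in res.post.best_model.nodes

    def test_join_edges_restricted_to_discovered_nodes(self):
        log = make_log(
            pre={"p1": ["A", "B"], "p2": ["B"], "p3": ["C"]},
            post={"p1": ["D"], "p2": [], "p3": ["D", "E"]},
            index_class="X",
        )
        res = discover_bowtie(log, (3, 4), (2, 2), SearchParams(seed=1))
        for (a, b), n in res.join_edges.items():
            assert n >= 1
            if b == "X":
                assert a in res.pre.best_model.nodes
            else:
                assert a == "X" and b in res.post.best_model.nodes
        # every patient whose last pre event was discovered contributes once
        total_entry = sum(n for (a, b), n in res.join_edges.items() if b == "X")
        assert total_entry <= 3

    def test_log_without_post_events_gives_empty_post_model(self):
        log = make_log(pre={"p1": ["A", "B"]})
        res = discover_bowtie(log, (3, 3), (3, 3), SearchParams(seed=0))
        assert res.post.best_model == ProcessModel.empty()

    def test_result_json_round_trip(self, demo_log):
        from bowtiepm.discovery import BowTieResult

        res = discover_bowtie(demo_log, params=SearchParams(seed=2, max_iterations=30))
        back = BowTieResult.from_dict(res.to_dict())
        assert back.pre.best_model == res.pre.best_model
        assert back.join_edges == res.join_edges
        assert back.pre.score_history == res.pre.score_history
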
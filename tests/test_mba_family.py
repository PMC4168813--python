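import numpy as np
import pandas as pd
import pytest

from ctxcut import (
    ConsistencyError,
    CoreSpec,
    binarize_expression,
    check_model_consistency_fastcore,
    check_model_consistency_mba,
    extract_submodel,
    fastcore,
    find_blocked_fva,
    find_sparse_mode,
    mba,
    mba_single,
    mcadre,
    mcadre_scores,
)
from ctxcut.synthetic import make_random_model

from conftest import build_model


def _two_path_symmetric():
    """up -> A; p1, p2: A -> B (symmetric alternatives); B -> out."""
    return build_model(
        [
            ("up", {"A": 1}, 0, 10),
            ("p1", {"A": -1, "B": 1}, 0, 10),
            ("p2", {"A": -1, "B": 1}, 0, 10),
            ("ex", {"B": -1}, 0, 10),
        ]
    )


class TestConsistencyCheckers:
    def test_dead_end_found(self, chain_deadend):
        assert check_model_consistency_mba(chain_deadend) == {"r4"}
        assert check_model_consistency_fastcore(chain_deadend) == {"r4"}

    def test_consistent_chain_clean(self, chain):
        assert check_model_consistency_mba(chain) == set()
        assert check_model_consistency_fastcore(chain) == set()

    @pytest.mark.parametrize("seed", range(25))
    def test_equivalence_with_fva_reference(self, seed):
        model = make_random_model(12, seed=seed, reversible_fraction=0.4)
        ref = find_blocked_fva(model)
        assert check_model_consistency_mba(model, seed=seed) == ref
        assert check_model_consistency_fastcore(model) == ref


class TestMbaSingle:
    def test_parallel_path_any_order(self, parallel_path):
        core = CoreSpec({"r4"}, {"r2"}, k=0.5)
        for order in (["r1", "r3"], ["r3", "r1"]):
            assert mba_single(parallel_path, core, order) == {"r1", "r2", "r4"}

    def test_empty_non_core_returns_everything(self, parallel_path):
        core = CoreSpec({"r4"}, {"r1", "r2", "r3"})
        assert mba_single(parallel_path, core, []) == set(parallel_path.reaction_ids)

    def test_order_dependence_on_symmetric_paths(self):
        model = _two_path_symmetric()
        core = CoreSpec({"ex"}, set(), k=0.5)
        first = mba_single(model, core, ["p1", "p2", "up"])
        second = mba_single(model, core, ["p2", "p1", "up"])
        assert first != second
        assert {"p1", "p2"} & first and {"p1", "p2"} & second

    def test_blocked_high_core_is_error(self, chain_deadend):
        core = CoreSpec({"r4"}, set())
        with pytest.raises(ConsistencyError):
            mba_single(chain_deadend, core, ["r1", "r2", "r3"])


class TestMba:
    def test_single_iteration_equals_seeded_single_pass(self, parallel_path):
        core = CoreSpec({"r4"}, {"r2"}, k=0.5)
        rng = np.random.default_rng(7)
        n_c = sorted(set(parallel_path.reaction_ids) - core.core)
        perm = [n_c[i] for i in rng.permutation(len(n_c))]
        single = mba_single(parallel_path, core, perm)
        r_p, _ = mba(parallel_path, core, n_iter=1, seed=7)
        # consolidation keeps exactly the reactions occurring in the population
        assert r_p <= single

    def test_same_seed_reproduces_everything(self, parallel_path):
        core = CoreSpec({"r4"}, {"r2"}, k=0.5)
        a = mba(parallel_path, core, n_iter=20, seed=3)
        b = mba(parallel_path, core, n_iter=20, seed=3)
        assert a == b

    def test_symmetric_paths_split_the_population(self):
        model = _two_path_symmetric()
        core = CoreSpec({"ex"}, set(), k=0.5)
        r_p, ranking = mba(model, core, n_iter=50, seed=11)
        freq = dict(ranking)
        # each path should occur in roughly half the population
        # (binomial(50, .5): within [0.22, 0.78] except with prob < 1e-4)
        assert 0.22 <= freq["p1"] <= 0.78
        assert 0.22 <= freq["p2"] <= 0.78
        assert freq["up"] == 1.0
        assert not find_blocked_fva(extract_submodel(model, r_p))

    def test_output_contains_high_core_and_is_consistent(self, parallel_path):
        core = CoreSpec({"r4"}, {"r2"}, k=0.5)
        r_p, _ = mba(parallel_path, core, n_iter=10, seed=0)
        assert core.c_h <= r_p
        assert not find_blocked_fva(extract_submodel(parallel_path, r_p))

    def test_moderate_core_retention_grows_with_k(self):
        # p2 in C_M; removing p1 blocks nothing, removing p2's support is
        # protected more as k rises
        model = build_model(
            [
                ("up", {"A": 1}, 0, 10),
                ("p1", {"A": -1, "B": 1}, 0, 10),
                ("m1", {"A": -1, "C": 1}, 0, 10),
                ("m2", {"C": -1, "B": 1}, 0, 10),
                ("ex", {"B": -1}, 0, 10),
            ]
        )
        core_low = CoreSpec({"ex"}, {"m1", "m2"}, k=0.0)
        core_high = CoreSpec({"ex"}, {"m1", "m2"}, k=10.0)
        kept_low, _ = mba(model, core_low, n_iter=10, seed=2)
        kept_high, _ = mba(model, core_high, n_iter=10, seed=2)
        assert len(kept_low & {"m1", "m2"}) <= len(kept_high & {"m1", "m2"})


class TestMcadreScores:
    def _model(self):
        return build_model(
            [("r1", {"A": 1}, 0, 10), ("r2", {"A": -1, "B": 1}, 0, 10),
             ("r3", {"B": -1}, 0, 10)],
            gpr={"r1": "g1", "r2": "g2", "r3": "g3"},
        )

    def test_expression_frequency(self):
        profiles = pd.DataFrame(
            {"g1": [1, 1, 1, 0], "g2": [1, 1, 1, 1], "g3": [0, 0, 0, 0]}
        )
        scores = mcadre_scores(self._model(), profiles)
        assert scores.expression["r1"] == pytest.approx(0.75)
        assert scores.expression["r2"] == 1.0
        assert scores.expression["r3"] == 0.0
        assert scores.has_evidence == {"r1", "r2", "r3"}

    def test_connectivity_neighbor_means(self):
        profiles = pd.DataFrame({"g1": [1], "g2": [0], "g3": [1]})
        scores = mcadre_scores(self._model(), profiles)
        # r1-A-r2, r2-B-r3 adjacency
        assert scores.connectivity["r1"] == pytest.approx(0.0)  # only neighbor r2
        assert scores.connectivity["r2"] == pytest.approx(1.0)  # neighbors r1, r3
        assert scores.connectivity["r3"] == pytest.approx(0.0)

    def test_isolated_reaction_gets_zero_connectivity(self):
        model = build_model(
            [("r1", {"A": 1}, 0, 1), ("r2", {"A": -1}, 0, 1), ("iso", {"Z": 1}, 0, 1)],
            gpr={"iso": "gz"},
        )
        scores = mcadre_scores(model, pd.DataFrame({"gz": [1]}))
        assert scores.connectivity["iso"] == 0.0

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binariz"):
            mcadre_scores(self._model(), pd.DataFrame({"g1": [0.7]}))

    def test_binarize_helper(self):
        raw = pd.DataFrame({"g1": [6.0, 2.0]})
        assert binarize_expression(raw, 5.0)["g1"].tolist() == [1, 0]

    def test_gpr_mapped_per_sample(self):
        model = build_model(
            [("r1", {"A": 1}, 0, 1), ("r2", {"A": -1}, 0, 1)],
            gpr={"r1": "ga and gb"},
        )
        profiles = pd.DataFrame({"ga": [1, 1], "gb": [0, 1]})
        scores = mcadre_scores(model, profiles)
        assert scores.expression["r1"] == pytest.approx(0.5)


class TestMcadre:
    def _scores(self, model, expr, evidence=None):
        from ctxcut.mba_family import McadreScores

        conn = {r: 0.0 for r in model.reaction_ids}
        conf = {r: 0.0 for r in model.reaction_ids}
        return McadreScores(dict(expr), conn, conf, evidence or set(expr))

    def test_lowest_scored_path_removed(self, parallel_path):
        expr = {"r1": 1.0, "r2": 0.9, "r3": 0.1, "r4": 1.0}
        scores = self._scores(parallel_path, expr)
        r_p = mcadre(parallel_path, scores, core_threshold=0.5)
        assert r_p == {"r1", "r2", "r4"}

    def test_key_metabolite_producer_protected(self, parallel_path):
        # r2 and r3 produce B; removing both would kill production, and each
        # is each other's only alternative once one is gone
        expr = {"r1": 1.0, "r2": 0.1, "r3": 0.05, "r4": 1.0}
        scores = self._scores(parallel_path, expr)
        r_p = mcadre(parallel_path, scores, core_threshold=0.5, key_metabolites=["B"])
        from ctxcut.mba_family import _can_produce

        sub = extract_submodel(parallel_path, r_p)
        assert "B" in sub.metabolite_ids and _can_produce(sub, "B", 1e-4)

    def test_negative_branch_arithmetic(self):
        # negative-evidence reaction x whose removal blocks one core reaction
        # (c1, reachable only through x) and three non-core reactions
        model = build_model(
            [
                ("up", {"A": 1}, 0, 10),
                ("keep", {"A": -1, "B": 1}, 0, 10),
                ("ex", {"B": -1}, 0, 10),
                ("x", {"A": -1, "C": 1}, 0, 10),
                ("c1", {"C": -1, "D": 1}, 0, 10),
                ("n1", {"D": -1, "E": 1}, 0, 10),
                ("n2", {"E": -1, "F": 1}, 0, 10),
                ("n3", {"F": -1}, 0, 10),
            ],
            gpr={"x": "gx"},
        )
        expr = {"up": 1.0, "keep": 1.0, "ex": 1.0, "c1": 0.9,
                "x": 0.0, "n1": 0.2, "n2": 0.2, "n3": 0.2}
        # removal of x blocks c1 (1 core) and n1..n3 (3 non-core):
        # committed iff 1 < k*3
        scores = self._scores(model, expr)
        kept_small_k = mcadre(model, scores, core_threshold=0.5, k=0.2)
        assert "x" in kept_small_k  # 1 < 0.6 is false -> retained
        scores = self._scores(model, expr)
        kept_big_k = mcadre(model, scores, core_threshold=0.5, k=0.5)
        assert "x" not in kept_big_k  # 1 < 1.5 -> removed, with c1 sacrificed
        assert "c1" not in kept_big_k

    def test_non_negative_reaction_cannot_sacrifice_core(self):
        model = build_model(
            [
                ("up", {"A": 1}, 0, 10),
                ("x", {"A": -1, "C": 1}, 0, 10),
                ("c1", {"C": -1}, 0, 10),
                ("ex", {"A": -1}, 0, 10),
            ],
            gpr={"x": "gx"},
        )
        expr = {"up": 1.0, "x": 0.3, "c1": 0.9, "ex": 1.0}
        scores = self._scores(model, expr)
        r_p = mcadre(model, scores, core_threshold=0.5)
        assert "x" in r_p and "c1" in r_p

    def test_result_always_consistent(self, parallel_path):
        expr = {"r1": 0.4, "r2": 0.3, "r3": 0.2, "r4": 0.6}
        scores = self._scores(parallel_path, expr)
        r_p = mcadre(parallel_path, scores, core_threshold=0.5)
        assert not find_blocked_fva(extract_submodel(parallel_path, r_p))


class TestFindSparseMode:
    def test_activates_core_and_avoids_penalized_alternative(self, parallel_path):
        support = find_sparse_mode(parallel_path, ["r2"], ["r1", "r3", "r4"])
        assert support == {"r1", "r2", "r4"}

    def test_empty_j_gives_empty_support(self, parallel_path):
        assert find_sparse_mode(parallel_path, [], ["r1"]) == set()

    def test_blocked_j_gives_empty_support(self, chain_deadend):
        assert find_sparse_mode(chain_deadend, ["r4"], ["r1", "r2", "r3"]) == set()

    def test_overlapping_sets_rejected(self, chain):
        with pytest.raises(ValueError):
            find_sparse_mode(chain, ["r1"], ["r1", "r2"])


class TestFastcore:
    def test_minimal_superset_on_parallel_paths(self, parallel_path):
        r_p = fastcore(parallel_path, {"r4"})
        assert "r4" in r_p and len(r_p) == 3
        assert len({"r2", "r3"} & r_p) == 1

    def test_full_unblocked_core_returns_itself(self, chain_deadend):
        core = {"r1", "r2", "r3"}
        assert fastcore(chain_deadend, core) == core

    def test_blocked_core_reaction_is_error(self, chain_deadend):
        with pytest.raises(ConsistencyError, match="r4"):
            fastcore(chain_deadend, {"r4"})

    def test_reversible_core_activated_by_flipping(self):
        # rv is only usable in its reverse sense (B -> A)
        model = build_model(
            [
                ("up", {"B": 1}, 0, 10),
                ("rv", {"A": 1, "B": -1}, -10, 10),
                ("ex", {"A": -1}, 0, 10),
            ]
        )
        r_p = fastcore(model, {"rv"})
        assert r_p == {"up", "rv", "ex"}

    @pytest.mark.parametrize("seed", range(6))
    def test_result_consistent_and_contains_core(self, seed):
        model = make_random_model(12, seed=seed, reversible_fraction=0.3)
        unblocked = sorted(set(model.reaction_ids) - find_blocked_fva(model))
        rng = np.random.default_rng(seed)
        core = {unblocked[i] for i in rng.choice(len(unblocked), size=2, replace=False)}
        r_p = fastcore(model, core)
        assert core <= r_p
        assert not find_blocked_fva(extract_submodel(model, r_p))
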
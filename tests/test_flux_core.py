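import json

import numpy as np
import pytest

from ctxcut import (
    FormatError,
    MetabolicModel,
    ValidationError,
    extract_submodel,
    fba,
    find_blocked_fva,
    flip_reaction,
    fva,
    load_model,
    save_model,
    split_reversible,
)
from ctxcut._solver import InfeasibleError, UnboundedError
from ctxcut.synthetic import make_random_model

from conftest import build_model


class TestModelIO:
    def test_json_chain_fixture(self, tmp_path):
        doc = {
            "metabolites": ["A", "B"],
            "reactions": [
                {"id": "r1", "stoich": {"A": 1}, "lb": 0, "ub": 10},
                {"id": "r2", "stoich": {"A": -1, "B": 1}, "lb": 0, "ub": 10, "gpr": "g2"},
                {"id": "r3", "stoich": {"B": -1}, "lb": 0, "ub": 10},
            ],
        }
        path = tmp_path / "chain.json"
        path.write_text(json.dumps(doc))
        model = load_model(path)
        assert model.n_reactions == 3
        assert model.reversible == set()
        assert model.gpr == {"r2": "g2"}

    def test_default_bounds_when_absent(self, tmp_path):
        doc = {
            "metabolites": ["A"],
            "reactions": [{"id": "r1", "stoich": {"A": 1}}],
        }
        path = tmp_path / "m.json"
        path.write_text(json.dumps(doc))
        model = load_model(path)
        assert (model.lb[0], model.ub[0]) == (-1000.0, 1000.0)

    def test_duplicate_reaction_is_validation_error(self, tmp_path):
        doc = {
            "metabolites": ["A"],
            "reactions": [
                {"id": "r1", "stoich": {"A": 1}, "lb": 0, "ub": 1},
                {"id": "r1", "stoich": {"A": -1}, "lb": 0, "ub": 1},
            ],
        }
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError, match="r1"):
            load_model(path)

    def test_unparsable_json_is_format_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(FormatError):
            load_model(path)

    @pytest.mark.parametrize("fmt,suffix", [("json", "json"), ("sbml", "xml")])
    def test_round_trip_preserves_structure(self, tmp_path, fmt, suffix, parallel_path):
        model = parallel_path
        model.gpr = {"r2": "g1 and (g2 or g3)", "r3": "g4"}
        path = tmp_path / f"m.{suffix}"
        save_model(model, path, fmt)
        back = load_model(path, fmt)
        assert back.reaction_ids == model.reaction_ids
        assert back.metabolite_ids == model.metabolite_ids
        assert np.array_equal(back.S, model.S)
        assert np.array_equal(back.lb, model.lb)
        assert np.array_equal(back.ub, model.ub)
        assert back.gpr == model.gpr


class TestFba:
    def test_bound_limited_chain(self, chain):
        assert fba(chain, "r3").objective_value == pytest.approx(10.0)

    def test_bottleneck(self, chain):
        chain.ub[1] = 4.0
        assert fba(chain, "r3").objective_value == pytest.approx(4.0)

    def test_dead_end_forces_zero(self):
        model = build_model(
            [("r1", {"A": 1}, 0, 10), ("r2", {"A": -1, "B": 1}, 0, 10)]
        )
        assert fba(model, "r2").objective_value == pytest.approx(0.0)

    def test_steady_state_invariant(self, parallel_path):
        sol = fba(parallel_path, "r4")
        assert np.allclose(parallel_path.S @ sol.values, 0.0, atol=1e-6)

    def test_infeasible_and_unbounded_are_distinguished(self, chain):
        with pytest.raises(InfeasibleError):
            fba(chain, "r3", extra_constraints=[({"r3": 1.0}, 20.0, 20.0)])
        free = build_model([("r1", {"A": 1}, -np.inf, np.inf),
                            ("r2", {"A": -1}, -np.inf, np.inf)])
        with pytest.raises(UnboundedError):
            fba(free, "r1")

    def test_agrees_with_cobrapy(self, parallel_path):
        """Independent cross-check of the LP route against cobrapy's solver."""
        from ctxcut.flux_core import to_cobra

        cmodel = to_cobra(parallel_path)
        cmodel.objective = cmodel.reactions.get_by_id("r4")
        expected = cmodel.optimize().objective_value
        assert fba(parallel_path, "r4").objective_value == pytest.approx(expected)


class TestFva:
    def test_fully_coupled_chain(self, chain):
        assert fva(chain, ["r2"])["r2"] == pytest.approx((0.0, 10.0))

    def test_dead_end_is_pinned_to_zero(self, chain_deadend):
        assert fva(chain_deadend, ["r4"])["r4"] == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_parallel_paths_each_span_full_range(self, parallel_path):
        res = fva(parallel_path, ["r2", "r3"])
        assert res["r2"] == pytest.approx((0.0, 10.0))
        assert res["r3"] == pytest.approx((0.0, 10.0))

    def test_brackets_fba_optimum(self, parallel_path):
        sol = fba(parallel_path, "r4")
        lo, hi = fva(parallel_path, ["r4"])["r4"]
        assert lo - 1e-9 <= sol["r4"] <= hi + 1e-9


class TestBlockedDetection:
    def test_consistent_chain_has_none(self, chain):
        assert find_blocked_fva(chain) == set()

    def test_dead_end_detected(self, chain_deadend):
        assert find_blocked_fva(chain_deadend) == {"r4"}

    def test_empty_model(self):
        model = MetabolicModel([], [], np.zeros((0, 0)), np.zeros(0), np.zeros(0))
        assert find_blocked_fva(model) == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_per_reaction_lp(self, seed):
        """Reference detector equals per-reaction min/max LP enumeration."""
        model = make_random_model(12, seed=seed, reversible_fraction=0.4)
        blocked = set()
        for rid in model.reaction_ids:
            lo, hi = fva(model, [rid])[rid]
            if abs(lo) <= 1e-6 and abs(hi) <= 1e-6:
                blocked.add(rid)
        assert find_blocked_fva(model) == blocked


class TestSplitReversible:
    def test_irreversible_model_unchanged(self, chain):
        split, mapping = split_reversible(chain)
        assert split.reaction_ids == chain.reaction_ids
        assert mapping.reverse == {}

    def test_bounds_of_split_pair(self):
        model = build_model([("r1", {"A": 1}, -5, 10), ("r2", {"A": -1}, 0, 10)])
        split, mapping = split_reversible(model)
        i_f = split.reaction_ids.index(mapping.forward["r1"])
        i_r = split.reaction_ids.index(mapping.reverse["r1"])
        assert (split.lb[i_f], split.ub[i_f]) == (0.0, 10.0)
        assert (split.lb[i_r], split.ub[i_r]) == (0.0, 5.0)
        assert np.array_equal(split.S[:, i_r], -split.S[:, i_f])

    @pytest.mark.parametrize("seed", range(8))
    def test_fba_optimum_invariant(self, seed):
        model = make_random_model(10, seed=seed, reversible_fraction=0.5)
        c = {"ex": 1.0}
        direct = fba(model, c).objective_value
        split, mapping = split_reversible(model)
        c_split = {mapping.forward["ex"]: 1.0}
        if "ex" in mapping.reverse:
            c_split[mapping.reverse["ex"]] = -1.0
        assert fba(split, c_split).objective_value == pytest.approx(direct, abs=1e-6)


class TestFlipReaction:
    def test_involution(self, chain):
        flipped_twice = flip_reaction(flip_reaction(chain, "r2"), "r2")
        assert np.array_equal(flipped_twice.S, chain.S)
        assert np.array_equal(flipped_twice.lb, chain.lb)
        assert np.array_equal(flipped_twice.ub, chain.ub)

    def test_bounds_negate(self, chain):
        flipped = flip_reaction(chain, "r2")
        i = chain.index("r2")
        assert (flipped.lb[i], flipped.ub[i]) == (-10.0, 0.0)

    def test_unknown_reaction(self, chain):
        with pytest.raises(KeyError):
            flip_reaction(chain, "nope")

    @pytest.mark.parametrize("seed", range(8))
    def test_blocked_set_invariant(self, seed):
        model = make_random_model(10, seed=seed, reversible_fraction=0.4)
        ref = find_blocked_fva(model)
        rid = model.reaction_ids[seed % model.n_reactions]
        assert find_blocked_fva(flip_reaction(model, rid)) == ref


class TestExtractSubmodel:
    def test_full_keep_is_identity(self, parallel_path):
        sub = extract_submodel(parallel_path, parallel_path.reaction_ids)
        assert sub.reaction_ids == parallel_path.reaction_ids
        assert np.array_equal(sub.S, parallel_path.S)

    def test_orphaned_metabolites_dropped(self, chain):
        sub = extract_submodel(chain, ["r1", "r2"])
        assert sub.reaction_ids == ["r1", "r2"]
        assert set(sub.metabolite_ids) == {"A", "B"}
        sub2 = extract_submodel(chain, ["r1"])
        assert sub2.metabolite_ids == ["A"]

    def test_empty_keep(self, chain):
        sub = extract_submodel(chain, [])
        assert sub.n_reactions == 0 and sub.n_metabolites == 0

    def test_unknown_ids_listed(self, chain):
        with pytest.raises(KeyError, match="rX"):
            extract_submodel(chain, ["r1", "rX"])


class TestValidation:
    def test_lb_above_ub_rejected(self):
        with pytest.raises(ValidationError):
            build_model([("r1", {"A": 1}, 5, 1)])

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValidationError):
            MetabolicModel(
                ["r1"], ["A"], np.zeros((1, 1)), np.zeros(1), np.ones(1)
            )

    def test_reversible_set_definition(self):
        model = build_model(
            [("a", {"A": 1}, -1, 1), ("b", {"A": -1}, 0, 1), ("c", {"A": -1}, -1, 0)]
        )
        assert model.reversible == {"a"}
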
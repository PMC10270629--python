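import numpy as np
import pytest

from conftest import EX, IN, TR, build_model
from fluxcohort.io import model_to_dict, read_model, write_model
from fluxcohort.model import (
    EXTRACELLULAR,
    MetabolicTask,
    ModelError,
    Reaction,
    check_tasks,
    find_dead_end_metabolites,
    model_stats,
    remove_dead_ends,
)
from fluxcohort.fva import fba


def models_equal(a, b):
    return model_to_dict(a) == model_to_dict(b)


class TestInvariants:
    def test_lower_bound_above_upper_rejected(self):
        with pytest.raises(ModelError, match="lower_bound"):
            Reaction("bad", {"a_c": -1}, 5, 1)

    def test_exchange_kind_must_match_structure(self, chain_model):
        rxn = chain_model.reaction("R1")
        rxn.kind = EX  # internal conversion mislabeled as exchange
        with pytest.raises(ModelError, match="exchange"):
            chain_model.validate()

    def test_multi_compartment_internal_rejected(self):
        with pytest.raises(ModelError, match="transport"):
            build_model(
                "bad",
                {"a_c": "c", "a_m": "m"},
                [("X", {"a_c": -1, "a_m": 1}, 0, 10, "", "", IN)],
            )

    def test_genes_are_union_of_gpr_leaves(self, mini_model):
        leaves = set()
        for r in mini_model.reactions:
            leaves |= r.gpr.genes()
        assert mini_model.genes == leaves


class TestDeadEnds:
    def stray_model(self):
        return build_model(
            "stray",
            {"a_s": EXTRACELLULAR, "a_c": "c", "b_s": EXTRACELLULAR, "x_c": "c"},
            [
                ("EX_a", {"a_s": -1}, -10, 10, "", "", EX),
                ("At", {"a_s": -1, "a_c": 1}, 0, 10, "", "", TR),
                ("AB", {"a_c": -1, "b_s": 1}, 0, 10, "", "", TR),
                ("EX_b", {"b_s": -1}, 0, 10, "", "", EX),
                ("AX", {"a_c": -1, "x_c": 1}, 0, 10, "", "", IN),
            ],
        )

    def test_single_dead_end_removed(self):
        pruned = remove_dead_ends(self.stray_model())
        assert not pruned.has_reaction("AX")
        assert "x_c" not in {m.id for m in pruned.metabolites}
        assert {r.id for r in pruned.reactions} == {"EX_a", "At", "AB", "EX_b"}

    def test_balanced_model_is_fixed_point(self, chain_model):
        assert models_equal(remove_dead_ends(chain_model), chain_model)

    def test_two_step_cascade_removed(self):
        # A -> X -> Y with Y never consumed: both reactions must go,
        # which takes two sweeps of the fixed-point iteration
        model = build_model(
            "cascade",
            {"a_s": EXTRACELLULAR, "a_c": "c", "x_c": "c", "y_c": "c"},
            [
                ("EX_a", {"a_s": -1}, -10, 10, "", "", EX),
                ("At", {"a_s": -1, "a_c": 1}, 0, 10, "", "", TR),
                ("AX", {"a_c": -1, "x_c": 1}, 0, 10, "", "", IN),
                ("XY", {"x_c": -1, "y_c": 1}, 0, 10, "", "", IN),
            ],
        )
        pruned = remove_dead_ends(model)
        assert {r.id for r in pruned.reactions} == {"EX_a"}

    def test_idempotent(self, mini_model, core_model):
        for model in (self.stray_model(), mini_model, core_model):
            once = remove_dead_ends(model)
            assert models_equal(remove_dead_ends(once), once)

    def test_no_dead_ends_after_pruning(self):
        assert find_dead_end_metabolites(remove_dead_ends(self.stray_model())) == set()

    def test_biomass_removal_raises(self):
        model = build_model(
            "frag",
            {"a_s": EXTRACELLULAR, "a_c": "c", "x_c": "c"},
            [
                ("EX_a", {"a_s": -1}, -10, 10, "", "", EX),
                ("At", {"a_s": -1, "a_c": 1}, 0, 10, "", "", TR),
                ("BIO", {"a_c": -1, "x_c": 1}, 0, 10, "", "", IN),
            ],
            biomass_id="BIO",
        )
        with pytest.raises(ModelError, match="biomass"):
            remove_dead_ends(model)

    def test_empty_model_raises(self):
        model = build_model(
            "one",
            {"a_s": EXTRACELLULAR},
            [("EX_a", {"a_s": -1}, -10, 10, "", "", EX)],
        )
        model.reactions.clear()
        with pytest.raises(ModelError, match="empty"):
            remove_dead_ends(model)

    def test_every_reaction_flux_consistent_after_pruning(self, mini_model):
        """With all exchanges open, each surviving reaction can carry flux."""
        model = remove_dead_ends(mini_model)
        for ex in model.exchanges():
            ex.lower_bound = -10
        for r in model.reactions:
            hi = fba(model, r.id, sense="max")
            lo = fba(model, r.id, sense="min")
            best = max(abs(hi.objective_value), abs(lo.objective_value))
            assert best > 1e-6, f"{r.id} is flux-blocked"


class TestStats:
    def test_counts_on_constructed_model(self, chain_model):
        assert model_stats(chain_model) == {
            "reactions": 5,
            "metabolites": 4,
            "genes": 0,
        }

    def test_counts_match_generator_declaration(self, mini_model):
        from fluxcohort.synthetic import template_layout

        assert model_stats(mini_model) == template_layout("mini").declared_sizes

    def test_pruning_never_increases_counts(self):
        model = TestDeadEnds().stray_model()
        before = model_stats(model)
        after = model_stats(remove_dead_ends(model))
        assert all(after[k] <= before[k] for k in before)


class TestTasks:
    def test_respiration_task_passes(self, mini_model):
        task = MetabolicTask(
            id="co2_from_glc",
            allowed_inputs={"glc_s": 10, "ala_s": 10, "o2_s": 10},
            required_outputs={"co2_s": 1.0},
        )
        result = check_tasks(mini_model, [task])
        assert result["co2_from_glc"].passed

    def test_task_fails_with_inputs_closed(self, mini_model):
        task = MetabolicTask(
            id="no_source", allowed_inputs={}, required_outputs={"co2_s": 1.0}
        )
        assert not check_tasks(mini_model, [task])["no_source"].passed

    def test_unknown_output_metabolite_raises(self, mini_model):
        task = MetabolicTask(
            id="ghost", allowed_inputs={"glc_s": 10},
            required_outputs={"unobtainium_s": 1.0},
        )
        with pytest.raises(ModelError):
            check_tasks(mini_model, [task])

    def test_bounds_restored_after_check(self, mini_model):
        before = model_to_dict(mini_model)
        task = MetabolicTask(
            id="t", allowed_inputs={"glc_s": 5}, required_outputs={"co2_s": 0.1}
        )
        check_tasks(mini_model, [task])
        assert model_to_dict(mini_model) == before


class TestIO:
    def test_json_round_trip(self, tmp_path, mini_model):
        path = tmp_path / "model.json"
        write_model(mini_model, path)
        assert models_equal(read_model(path), mini_model)

    def test_sbml_round_trip(self, tmp_path, core_model):
        path = tmp_path / "model.xml"
        write_model(core_model, path, format="sbml")
        back = read_model(path, format="sbml")
        assert models_equal(back, core_model)

    def test_sbml_without_gpr_gives_empty_trees(self, tmp_path, chain_model):
        path = tmp_path / "chain.xml"
        write_model(chain_model, path, format="sbml")
        back = read_model(path)
        assert all(r.gpr.is_empty for r in back.reactions)

    def test_json_with_inverted_bounds_rejected(self, tmp_path, mini_model):
        import json

        from fluxcohort.io import FormatError

        data = model_to_dict(mini_model)
        data["reactions"][0]["lower_bound"] = 99
        data["reactions"][0]["upper_bound"] = -99
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(data))
        with pytest.raises(FormatError):
            read_model(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_model(tmp_path / "nope.json")
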
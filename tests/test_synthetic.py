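import numpy as np
import pandas as pd
import pytest

from fluxcohort.gpr import BoolOp
from fluxcohort.io import model_to_dict
from fluxcohort.model import ReactionKind, find_dead_end_metabolites
from fluxcohort.synthetic import (
    SyntheticSpec,
    default_media,
    make_cohort,
    make_external_cohort,
    make_model,
    template_layout,
)


class TestSpec:
    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(seed=1, template="mega")

    def test_group_size_floor(self):
        with pytest.raises(ValueError):
            SyntheticSpec(seed=1, n_healthy=1)

    def test_effect_size_range(self):
        with pytest.raises(ValueError):
            SyntheticSpec(seed=1, effect_size=0.0)
        with pytest.raises(ValueError):
            SyntheticSpec(seed=1, effect_size=1.5)


class TestModelTemplates:
    @pytest.mark.parametrize("template", ["mini", "core"])
    def test_structural_postconditions(self, template):
        spec = SyntheticSpec(seed=1, template=template, perturbed_pathways=())
        model = make_model(spec)
        model.validate()
        assert len(model.subsystems()) >= 2
        assert len(model.exchanges()) >= 5
        kinds = {r.kind for r in model.reactions}
        assert ReactionKind.TRANSPORT in kinds
        biomass = model.reaction(model.biomass_id)
        assert len(biomass.substrates()) >= 3
        objective = model.reaction(model.objective_id)
        assert {model.metabolite(m).compartment
                for m in objective.stoichiometry} == {"m"}
        ops = set()
        for r in model.reactions:
            if isinstance(r.gpr.root, BoolOp):
                ops.add(r.gpr.root.op)
                for child in r.gpr.root.children:
                    if isinstance(child, BoolOp):
                        ops.add(child.op)
        assert {"and", "or"} <= ops
        assert find_dead_end_metabolites(model) == set()

    @pytest.mark.parametrize("template", ["mini", "core"])
    def test_deterministic_and_seed_free(self, template):
        a = make_model(SyntheticSpec(seed=1, template=template, perturbed_pathways=()))
        b = make_model(SyntheticSpec(seed=2, template=template, perturbed_pathways=()))
        assert model_to_dict(a) == model_to_dict(b)

    @pytest.mark.parametrize("template", ["mini", "core"])
    def test_counts_match_declared_sizes(self, template):
        from fluxcohort.model import model_stats

        model = make_model(SyntheticSpec(seed=1, template=template,
                                         perturbed_pathways=()))
        assert model_stats(model) == template_layout(template).declared_sizes

    def test_mini_feasible_under_default_media(self, mini_model):
        from fluxcohort.eflux import apply_media
        from fluxcohort.fva import fba

        constrained = apply_media(mini_model, default_media(mini_model))
        sol = fba(constrained, "ATPM")
        assert sol.status == "optimal" and sol.objective_value > 0

    def test_media_metabolites_are_nutrients_only(self, core_model):
        media = default_media(core_model)
        assert "co2" not in media.uptake
        assert "glc" in media.uptake and "o2" in media.uptake


class TestCohort:
    def test_same_seed_identical_counts(self, core_spec, core_model):
        a, _ = make_cohort(core_model, core_spec)
        b, _ = make_cohort(core_model, core_spec)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_different_seed_differs(self, core_model, core_spec):
        other = SyntheticSpec(seed=core_spec.seed + 1, template="core")
        a, _ = make_cohort(core_model, core_spec)
        b, _ = make_cohort(core_model, other)
        assert not a.values.equals(b.values)

    def test_knockdown_halves_planted_gene_means(self, core_model):
        spec = SyntheticSpec(seed=5, template="core", effect_size=0.5,
                             n_healthy=60, n_disease=60)
        expr, truth = make_cohort(core_model, spec)
        h = expr.values[expr.group_samples("healthy")].mean(axis=1)
        d = expr.values[expr.group_samples("disease")].mean(axis=1)
        planted = sorted(truth.perturbed_genes)
        ratios = (d[planted] / h[planted]).to_numpy()
        assert np.all(ratios < 0.7)
        assert np.median(ratios) == pytest.approx(0.5, abs=0.08)
        null_genes = [g for g in core_model.genes if g not in truth.perturbed_genes]
        null_ratio = (d[null_genes] / h[null_genes]).to_numpy()
        assert np.median(null_ratio) == pytest.approx(1.0, abs=0.1)

    def test_unknown_pathway_rejected(self, core_model):
        spec = SyntheticSpec(seed=1, template="core",
                             perturbed_pathways=("astrology",))
        with pytest.raises(ValueError, match="astrology"):
            make_cohort(core_model, spec)

    def test_ground_truth_covers_downstream_scoring(self, core_model, core_spec):
        _, truth = make_cohort(core_model, core_spec)
        assert truth.perturbed_pathways == core_spec.perturbed_pathways
        rxn_ids = {r.id for r in core_model.reactions}
        assert truth.perturbed_reactions <= rxn_ids
        assert truth.coupled_reactions <= rxn_ids
        subsystems = {core_model.reaction(r).subsystem
                      for r in truth.perturbed_reactions}
        assert subsystems == set(core_spec.perturbed_pathways)

    def test_low_genes_planted_below_filter(self, core_model, core_spec):
        expr, _ = make_cohort(core_model, core_spec)
        low = [g for g in expr.genes if g.startswith("gene_low_")]
        assert len(low) == core_spec.n_low_genes
        assert (expr.values.loc[low] < 5).mean(axis=1).min() > 0.75


class TestExternalCohort:
    def test_fraction_bounds(self, core_model, core_spec):
        with pytest.raises(ValueError):
            make_external_cohort(core_model, core_spec, shift_labels=1.5)

    def test_no_shift_means_no_confounders(self, core_model, core_spec):
        expr, sub, _ = make_external_cohort(core_model, core_spec, 0.0)
        assert (sub == "core").all()
        assert (expr.sample_groups == "disease").sum() == core_spec.n_disease

    def test_half_shift_relabels_half_the_disease_samples(self, core_model, core_spec):
        expr, sub, _ = make_external_cohort(core_model, core_spec, 0.5)
        n_conf = (sub == "confounder").sum()
        assert n_conf == core_spec.n_disease // 2
        assert (expr.sample_groups[sub == "confounder"] == "healthy").all()

    def test_fresh_cohort_differs_from_primary(self, core_model, core_spec):
        primary, _ = make_cohort(core_model, core_spec)
        external, _, _ = make_external_cohort(core_model, core_spec, 0.0)
        assert not np.array_equal(primary.values.values, external.values.values)
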
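import numpy as np
import pandas as pd
import pytest

from conftest import EX, IN, TR, build_model
from fluxcohort.eflux import (
    EfluxError,
    MediaSpec,
    ReactionActivity,
    apply_eflux,
    apply_media,
    compute_activities,
    gpr_activity,
    personalize,
)
from fluxcohort.gpr import parse_gpr
from fluxcohort.io import model_to_dict
from fluxcohort.model import EXTRACELLULAR
from fluxcohort.preprocess import ExpressionMatrix


class TestGprActivity:
    def test_and_is_min_or_is_sum(self):
        gpr = parse_gpr("(g1 and g2) or g3")
        assert gpr_activity(gpr, {"g1": 2, "g2": 4, "g3": 5}) == 7

    def test_leaf_passthrough(self):
        assert gpr_activity(parse_gpr("g1"), {"g1": 0}) == 0
        assert gpr_activity(parse_gpr("g1"), {"g1": 3.5}) == 3.5

    def test_missing_gene_dropped_from_parent(self):
        assert gpr_activity(parse_gpr("g1 or g2"), {"g2": 3}) == 3
        assert gpr_activity(parse_gpr("g1 and g2"), {"g2": 3}) == 3

    def test_all_missing_node_is_missing(self):
        assert gpr_activity(parse_gpr("g1 or g2"), {}) is None
        assert gpr_activity(parse_gpr(""), {"g1": 1}) is None

    def test_negative_expression_rejected(self):
        with pytest.raises(EfluxError, match="negative"):
            gpr_activity(parse_gpr("g1"), {"g1": -1})

    def test_monotone_in_every_gene(self):
        rng = np.random.default_rng(3)
        gpr = parse_gpr("(g1 and g2) or (g3 and g4) or g5")
        genes = [f"g{i}" for i in range(1, 6)]
        for _ in range(100):
            expr = {g: float(rng.uniform(0, 10)) for g in genes}
            base = gpr_activity(gpr, expr)
            bumped = dict(expr)
            g = genes[rng.integers(5)]
            bumped[g] = expr[g] + rng.uniform(0, 5)
            assert gpr_activity(gpr, bumped) >= base


@pytest.fixture
def two_enzyme_model():
    return build_model(
        "two",
        {"a_s": EXTRACELLULAR, "a_c": "c", "b_c": "c", "c_c": "c"},
        [
            ("EX_a", {"a_s": -1}, -10, 1000, "", "", EX),
            ("At", {"a_s": -1, "a_c": 1}, 0, 1000, "", "", TR),
            ("R1", {"a_c": -1, "b_c": 1}, -1000, 1000, "g1", "p1", IN),
            ("R2", {"b_c": -1, "c_c": 1}, 0, 1000, "g2", "p2", IN),
            ("SINK", {"c_c": -1}, 0, 1000, "", "", IN),
        ],
    )


class TestApplyEflux:
    def test_proportional_symmetric_scaling(self, two_enzyme_model):
        acts = ReactionActivity({"R1": 7.0, "R2": 10.0})
        out = apply_eflux(two_enzyme_model, acts)
        r1 = out.reaction("R1")
        assert (r1.lower_bound, r1.upper_bound) == (-700.0, 700.0)

    def test_max_activity_keeps_bounds(self, two_enzyme_model):
        out = apply_eflux(two_enzyme_model, ReactionActivity({"R1": 3.0, "R2": 3.0}))
        r2 = out.reaction("R2")
        assert (r2.lower_bound, r2.upper_bound) == (0.0, 1000.0)

    def test_zero_activity_blocks_reaction(self, two_enzyme_model):
        out = apply_eflux(two_enzyme_model, ReactionActivity({"R1": 0.0, "R2": 5.0}))
        r1 = out.reaction("R1")
        assert (r1.lower_bound, r1.upper_bound) == (0.0, 0.0)

    def test_unconstrained_and_exchange_exempt(self, two_enzyme_model):
        acts = compute_activities(two_enzyme_model, {"g1": 1.0, "g2": 4.0})
        out = apply_eflux(two_enzyme_model, acts)
        for rid in ("EX_a", "At", "SINK"):
            assert out.reaction(rid).upper_bound == 1000.0

    def test_degenerate_expression_rejected(self, two_enzyme_model):
        with pytest.raises(EfluxError, match="degenerate"):
            apply_eflux(two_enzyme_model, ReactionActivity({"R1": 0.0, "R2": 0.0}))

    def test_scale_invariance_of_activities(self, two_enzyme_model):
        a = ReactionActivity({"R1": 2.0, "R2": 8.0})
        b = ReactionActivity({"R1": 2.0 * 13, "R2": 8.0 * 13})
        assert model_to_dict(apply_eflux(two_enzyme_model, a)) == model_to_dict(
            apply_eflux(two_enzyme_model, b)
        )

    def test_stoichiometry_untouched(self, two_enzyme_model):
        out = apply_eflux(two_enzyme_model, ReactionActivity({"R1": 1.0, "R2": 2.0}))
        for r_out, r_in in zip(out.reactions, two_enzyme_model.reactions):
            assert r_out.stoichiometry == r_in.stoichiometry


class TestMedia:
    def test_uptake_set_only_for_media_metabolites(self, mini_model):
        media = MediaSpec(uptake=frozenset({"glc"}), default_uptake=10)
        out = apply_media(mini_model, media)
        assert out.reaction("EX_glc").lower_bound == -10
        assert out.reaction("EX_ala").lower_bound == 0
        assert out.reaction("EX_glc").upper_bound == 1000  # secretion untouched

    def test_media_without_exchange_raises(self, mini_model):
        media = MediaSpec(uptake=frozenset({"unobtainium"}), default_uptake=10)
        with pytest.raises(EfluxError, match="unobtainium"):
            apply_media(mini_model, media)

    def test_idempotent(self, mini_model):
        media = MediaSpec(uptake=frozenset({"glc", "o2"}), default_uptake=5)
        once = apply_media(mini_model, media)
        assert model_to_dict(apply_media(once, media)) == model_to_dict(once)

    def test_empty_media_rejected(self):
        with pytest.raises(EfluxError):
            MediaSpec(uptake=frozenset())

    def test_yaml_round_trip(self, tmp_path):
        media = MediaSpec(uptake=frozenset({"glc", "ala"}), default_uptake=7.5)
        media.to_yaml(tmp_path / "media.yaml")
        assert MediaSpec.from_yaml(tmp_path / "media.yaml") == media


def normalized_matrix(values: dict, genes: list, groups: list) -> ExpressionMatrix:
    df = pd.DataFrame(values, index=genes, dtype=float)
    return ExpressionMatrix(
        values=df,
        gene_lengths=pd.Series(1000.0, index=df.index),
        sample_groups=pd.Series(groups, index=df.columns),
        stage="normalized",
    )


class TestPersonalize:
    @pytest.fixture
    def media(self):
        return MediaSpec(uptake=frozenset({"a"}), default_uptake=10)

    def test_identical_samples_identical_models(self, two_enzyme_model, media):
        expr = normalized_matrix(
            {"s1": [2, 8], "s2": [2, 8]}, ["g1", "g2"], ["healthy", "disease"]
        )
        m1 = personalize(two_enzyme_model, expr, media, sample="s1")
        m2 = personalize(two_enzyme_model, expr, media, sample="s2")
        assert model_to_dict(m1) == model_to_dict(m2)

    def test_single_sample_group_mean_equals_sample(self, two_enzyme_model, media):
        expr = normalized_matrix(
            {"s1": [2, 8], "s2": [3, 5]}, ["g1", "g2"], ["healthy", "disease"]
        )
        by_group = personalize(two_enzyme_model, expr, media, group="healthy")
        by_sample = personalize(two_enzyme_model, expr, media, sample="s1")
        assert model_to_dict(by_group) == model_to_dict(by_sample)

    def test_halved_activity_halves_bounds(self, two_enzyme_model, media):
        # g2 pins the per-sample maximum in both groups, so halving g1's
        # value in the disease group exactly halves R1's bounds
        expr = normalized_matrix(
            {"h": [4, 8], "d": [2, 8]}, ["g1", "g2"], ["healthy", "disease"]
        )
        mh = personalize(two_enzyme_model, expr, media, group="healthy")
        md = personalize(two_enzyme_model, expr, media, group="disease")
        assert md.reaction("R1").upper_bound == pytest.approx(
            mh.reaction("R1").upper_bound / 2
        )

    def test_unknown_sample_or_group(self, two_enzyme_model, media):
        expr = normalized_matrix(
            {"s1": [2, 8], "s2": [3, 5]}, ["g1", "g2"], ["healthy", "disease"]
        )
        with pytest.raises(EfluxError):
            personalize(two_enzyme_model, expr, media, sample="nope")
        with pytest.raises(EfluxError):
            personalize(two_enzyme_model, expr, media, group="nope")
        with pytest.raises(EfluxError):
            personalize(two_enzyme_model, expr, media)
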
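import numpy as np
import pandas as pd
import pytest

from fluxcohort.model import (
    EXTRACELLULAR,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKind,
)
from fluxcohort.synthetic import SyntheticSpec, make_cohort, make_model

EX = ReactionKind.EXCHANGE
TR = ReactionKind.TRANSPORT
IN = ReactionKind.INTERNAL


def build_model(id, mets, rxns, **kwargs):
    """Terse model builder: mets = {id: compartment}, rxns = tuples."""
    model = MetabolicModel(
        id=id,
        metabolites=[Metabolite(id=m, compartment=c) for m, c in mets.items()],
        reactions=[
            Reaction(rid, stoich, lb, ub, gpr, sub, kind)
            for rid, stoich, lb, ub, gpr, sub, kind in rxns
        ],
        **kwargs,
    )
    model.validate()
    return model


@pytest.fixture
def chain_model():
    """∅ -> A -> B -> ∅ with a 10-unit uptake bottleneck."""
    return build_model(
        "chain",
        {"a_s": EXTRACELLULAR, "a_c": "c", "b_c": "c", "b_s": EXTRACELLULAR},
        [
            ("EX_a", {"a_s": -1}, -10, 1000, "", "", EX),
            ("At", {"a_s": -1, "a_c": 1}, 0, 1000, "", "", TR),
            ("R1", {"a_c": -1, "b_c": 1}, 0, 1000, "", "core", IN),
            ("Bt", {"b_c": -1, "b_s": 1}, 0, 1000, "", "", TR),
            ("EX_b", {"b_s": -1}, 0, 1000, "", "", EX),
        ],
    )


@pytest.fixture
def branch_model():
    """Two routes from glucose to ATP with yields 2 vs 3."""
    return build_model(
        "branch",
        {"glc_s": EXTRACELLULAR, "glc_c": "c", "atp_c": "c"},
        [
            ("EX_glc", {"glc_s": -1}, -10, 1000, "", "", EX),
            ("Gt", {"glc_s": -1, "glc_c": 1}, 0, 1000, "", "", TR),
            ("LOW", {"glc_c": -1, "atp_c": 2}, 0, 1000, "", "", IN),
            ("HIGH", {"glc_c": -1, "atp_c": 3}, 0, 1000, "", "", IN),
            ("ATPM", {"atp_c": -1}, 0, 1000, "", "", IN),
        ],
        objective_id="ATPM",
    )


@pytest.fixture(scope="session")
def mini_spec():
    return SyntheticSpec(
        seed=11,
        template="mini",
        perturbed_pathways=("alanine metabolism",),
        n_healthy=6,
        n_disease=6,
    )


@pytest.fixture(scope="session")
def mini_model(mini_spec):
    return make_model(mini_spec)


@pytest.fixture(scope="session")
def mini_cohort(mini_spec, mini_model):
    return make_cohort(mini_model, mini_spec)


@pytest.fixture(scope="session")
def core_spec():
    return SyntheticSpec(seed=21, template="core")


@pytest.fixture(scope="session")
def core_model(core_spec):
    return make_model(core_spec)
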
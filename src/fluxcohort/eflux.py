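"""E-Flux: scale reaction flux bounds by transcriptional activity.

Each reaction's GPR is evaluated against a sample's normalized
expression (AND = min of the subunits, a complex is limited by its
scarcest part; OR = sum of the isozymes, parallel enzymes add capacity).
Activities are divided by the sample's maximum activity over
GPR-bearing reactions, giving per-reaction scale factors in [0, 1] that
multiply both flux bounds.  Reactions without a usable GPR and exchange
reactions (no enzyme) keep their original bounds; exchanges are governed
by the media specification instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .gpr import BoolOp, GeneRef, Gpr, GprNode
from .model import MetabolicModel, ModelError, ReactionKind
from .preprocess import ExpressionMatrix


class EfluxError(ValueError):
    pass


def _eval_node(node: GprNode, expr: Mapping[str, float]) -> Optional[float]:
    if isinstance(node, GeneRef):
        if node.gene not in expr:
            return None
        value = expr[node.gene]
        if value < 0:
            raise EfluxError(
                f"negative expression for {node.gene}: activities are "
                "evaluated on log2(x+1) values, which are non-negative"
            )
        return float(value)
    child_values = [
        v for v in (_eval_node(c, expr) for c in node.children) if v is not None
    ]
    if not child_values:
        return None
    return min(child_values) if node.op == "and" else sum(child_values)


def gpr_activity(gpr: Gpr, expr: Mapping[str, float]) -> Optional[float]:
    """Evaluate a GPR tree against gene expression values.

    Genes absent from ``expr`` are dropped from their parent node
    (annotation gaps should not block reactions); a node whose children
    are all missing is itself missing.  Returns ``None`` — the
    "unconstrained" sentinel — for the empty tree or an all-missing one.
    """
    if gpr.is_empty:
        return None
    return _eval_node(gpr.root, expr)


@dataclass(frozen=True)
class ReactionActivity:
    """Per-reaction activity scores; ``None`` marks unconstrained reactions."""

    scores: Mapping[str, Optional[float]]
    provenance: str = ""

    def constrained(self) -> dict[str, float]:
        return {r: v for r, v in self.scores.items() if v is not None}


def compute_activities(
    model: MetabolicModel, expr: Mapping[str, float], provenance: str = ""
) -> ReactionActivity:
    scores = {r.id: gpr_activity(r.gpr, expr) for r in model.reactions}
    return ReactionActivity(scores=scores, provenance=provenance)


def apply_eflux(
    model: MetabolicModel, activities: ReactionActivity
) -> MetabolicModel:
    """Return a bounds-scaled copy of ``model``.

    scale_r = activity_r / max over constrained reactions of activity;
    both bounds are multiplied by scale_r (reversible reactions shrink
    symmetrically).  Exchange reactions and unconstrained reactions are
    exempt.  The stoichiometry is never touched.
    """
    constrained = {
        r: v
        for r, v in activities.constrained().items()
        if model.reaction(r).kind is not ReactionKind.EXCHANGE
    }
    if not constrained:
        raise EfluxError("no constrained reaction to scale")
    max_activity = max(constrained.values())
    if max_activity <= 0:
        raise EfluxError(
            "maximum reaction activity is 0: expression is degenerate"
        )
    out = model.copy()
    for rxn in out.reactions:
        if rxn.id not in constrained:
            continue
        scale = constrained[rxn.id] / max_activity
        rxn.lower_bound *= scale
        rxn.upper_bound *= scale
    return out


@dataclass(frozen=True)
class MediaSpec:
    """Extracellular metabolites available for uptake.

    ``uptake``: base ids (compartment-free) of permitted nutrients;
    ``default_uptake``: maximum uptake rate in mmol·gDW⁻¹·h⁻¹ applied to
    each of them.
    """

    uptake: frozenset[str]
    default_uptake: float = 10.0

    def __post_init__(self) -> None:
        if not self.uptake:
            raise EfluxError("media must allow at least one uptake metabolite")
        if self.default_uptake <= 0:
            raise EfluxError("default_uptake must be positive")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "MediaSpec":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            uptake=frozenset(data["uptake"]),
            default_uptake=float(data.get("default_uptake", 10.0)),
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {"uptake": sorted(self.uptake), "default_uptake": self.default_uptake}
            )
        )


def apply_media(model: MetabolicModel, media: MediaSpec) -> MetabolicModel:
    """Open uptake only for the media metabolites; close every other import.

    Sets the lower bound of each media exchange to −default_uptake and of
    all other exchanges to 0.  Secretion (upper) bounds are untouched.
    Idempotent.  Raises if a media metabolite has no exchange reaction.
    """
    out = model.copy()
    seen: set[str] = set()
    for ex in out.exchanges():
        met = out.metabolite(next(iter(ex.stoichiometry)))
        if met.base_id in media.uptake:
            ex.lower_bound = -media.default_uptake
            seen.add(met.base_id)
        else:
            ex.lower_bound = 0.0
    missing = sorted(media.uptake - seen)
    if missing:
        raise EfluxError(
            f"media metabolites without an exchange reaction: {missing}"
        )
    return out


def personalize(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    media: MediaSpec,
    sample: Optional[str] = None,
    group: Optional[str] = None,
) -> MetabolicModel:
    """Build one context-specific model for a sample or a group average.

    For a sample, that sample's normalized expression column is used; for
    a group, the per-gene arithmetic mean over the group's samples.  The
    chain is GPR activity → E-Flux bound scaling → media bounds.
    """
    if (sample is None) == (group is None):
        raise EfluxError("specify exactly one of sample or group")
    if expr.stage != "normalized":
        raise EfluxError("personalize expects normalized expression")
    if sample is not None:
        if sample not in expr.samples:
            raise EfluxError(f"unknown sample {sample!r}")
        profile = expr.values[sample]
        provenance = sample
    else:
        members = expr.group_samples(group)
        if not members:
            raise EfluxError(f"unknown or empty group {group!r}")
        profile = expr.values[members].mean(axis=1)
        provenance = f"group-mean:{group}"
    activities = compute_activities(model, profile.to_dict(), provenance)
    return apply_media(apply_eflux(model, activities), media)
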
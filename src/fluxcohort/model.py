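"""Core data model for compartmentalized constraint-based metabolic networks.

A :class:`MetabolicModel` is a stoichiometric network: metabolites with
compartment codes, reactions with flux bounds (mmol·gDW⁻¹·h⁻¹), boolean
GPR rules, pathway (subsystem) labels, and designated biomass and
objective reactions.  Conventions follow COBRA practice: exchange
reactions are written ``met_s <-> ∅`` with negative flux meaning uptake;
compartments are single-letter codes (c cytosol, m mitochondria,
l lysosome, g Golgi, r ER, x peroxisome, n nucleus, s extracellular).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .gpr import Gpr, parse_gpr

#: compartment code for the extracellular space
EXTRACELLULAR = "s"

DEFAULT_COMPARTMENTS = {
    "c": "cytosol",
    "m": "mitochondria",
    "l": "lysosome",
    "g": "golgi",
    "r": "endoplasmic reticulum",
    "x": "peroxisome",
    "n": "nucleus",
    EXTRACELLULAR: "extracellular",
}


class ModelError(ValueError):
    """Structural or invariant violation in a metabolic model."""


class ReactionKind(str, Enum):
    INTERNAL = "internal"
    TRANSPORT = "transport"
    EXCHANGE = "exchange"
    BIOMASS = "biomass"
    OBJECTIVE_DEMAND = "objective-demand"


def strip_compartment(met_id: str, compartment: str) -> str:
    """Base (compartment-free) id of a metabolite: ``glc__c`` -> ``glc``."""
    for sep in ("__", "_"):
        suffix = f"{sep}{compartment}"
        if met_id.endswith(suffix) and len(met_id) > len(suffix):
            return met_id[: -len(suffix)]
    return met_id


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    name: str = ""

    @property
    def base_id(self) -> str:
        """The compartment-free ("unique") form of the metabolite id."""
        return strip_compartment(self.id, self.compartment)


@dataclass
class Reaction:
    """A (possibly reversible) reaction with flux bounds and a GPR.

    ``stoichiometry`` maps metabolite id -> signed coefficient; negative
    coefficients are substrates, positive are products.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: Gpr = field(default_factory=Gpr)
    subsystem: str = ""
    kind: ReactionKind = ReactionKind.INTERNAL

    def __post_init__(self) -> None:
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def substrates(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]

    def compartments(self, model: "MetabolicModel") -> frozenset[str]:
        return frozenset(
            model.metabolite(m).compartment for m in self.stoichiometry
        )

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            subsystem=self.subsystem,
            kind=self.kind,
        )


@dataclass(frozen=True)
class MetabolicTask:
    """A feasibility test: can the network make the outputs from the inputs?

    ``allowed_inputs`` maps extracellular metabolite id -> maximum uptake
    rate; ``required_outputs`` maps extracellular metabolite id -> minimum
    production rate that must be attainable.
    """

    id: str
    allowed_inputs: Mapping[str, float]
    required_outputs: Mapping[str, float]
    description: str = ""


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    compartments: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENTS)
    )
    biomass_id: Optional[str] = None
    objective_id: Optional[str] = None

    def __post_init__(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise ModelError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise ModelError(f"unknown reaction {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.gpr.genes()
        return frozenset(out)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind is ReactionKind.EXCHANGE]

    def exchange_for(self, met_id: str) -> Reaction:
        for r in self.exchanges():
            if met_id in r.stoichiometry:
                return r
        raise ModelError(f"no exchange reaction for metabolite {met_id!r}")

    def subsystems(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            if r.subsystem:
                seen.setdefault(r.subsystem, None)
        return list(seen)

    # -- structure ---------------------------------------------------------
    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S matrix plus row (metabolite) and column (reaction) ids."""
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        pos = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, r in enumerate(self.reactions):
            for m, coef in r.stoichiometry.items():
                S[pos[m], j] = coef
        return S, met_ids, rxn_ids

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            compartments=dict(self.compartments),
            biomass_id=self.biomass_id,
            objective_id=self.objective_id,
        )

    def validate(self) -> None:
        """Check all structural invariants; raise :class:`ModelError` if violated."""
        seen = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ModelError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
            if m.compartment not in self.compartments:
                raise ModelError(
                    f"metabolite {m.id}: undeclared compartment {m.compartment!r}"
                )
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise ModelError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            for met_id in r.stoichiometry:
                self.metabolite(met_id)  # raises if missing
            self._check_kind(r)
        for attr in ("biomass_id", "objective_id"):
            rid = getattr(self, attr)
            if rid is not None and rid not in self._rxn_index:
                raise ModelError(f"{attr} {rid!r} does not resolve to a reaction")

    def _check_kind(self, r: Reaction) -> None:
        comps = r.compartments(self)
        single_extracellular = (
            len(r.stoichiometry) == 1
            and next(iter(comps)) == EXTRACELLULAR
        )
        if (r.kind is ReactionKind.EXCHANGE) != single_extracellular:
            raise ModelError(
                f"reaction {r.id}: kind={r.kind.value} inconsistent with an "
                "exchange being exactly one extracellular metabolite"
            )
        if r.kind is ReactionKind.TRANSPORT and len(comps) < 2:
            raise ModelError(
                f"reaction {r.id}: transport must span >= 2 compartments"
            )
        if (
            r.kind in (ReactionKind.INTERNAL, ReactionKind.BIOMASS)
            and len(comps) >= 2
        ):
            raise ModelError(
                f"reaction {r.id}: spans {sorted(comps)} but is not flagged "
                "as transport"
            )


def infer_kind(
    stoichiometry: Mapping[str, float],
    compartment_of: Mapping[str, str],
    rxn_id: str = "",
    biomass_id: Optional[str] = None,
    objective_id: Optional[str] = None,
) -> ReactionKind:
    """Classify a reaction from its stoichiometry and the designated ids."""
    if rxn_id and rxn_id == biomass_id:
        return ReactionKind.BIOMASS
    if rxn_id and rxn_id == objective_id:
        return ReactionKind.OBJECTIVE_DEMAND
    comps = {compartment_of[m] for m in stoichiometry}
    if len(stoichiometry) == 1 and comps == {EXTRACELLULAR}:
        return ReactionKind.EXCHANGE
    if len(comps) >= 2:
        return ReactionKind.TRANSPORT
    return ReactionKind.INTERNAL


# ---------------------------------------------------------------------------
# dead-end pruning
# ---------------------------------------------------------------------------

def find_dead_end_metabolites(model: MetabolicModel) -> set[str]:
    """Metabolites that appear only as substrate or only as product.

    Reversible reactions contribute their metabolites on both sides, and
    exchange reactions count as both producer and consumer of their
    metabolite (the boundary can absorb or supply it).
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in model.reactions:
        if r.kind is ReactionKind.EXCHANGE or r.reversible:
            for m in r.stoichiometry:
                produced.add(m)
                consumed.add(m)
        else:
            for m, coef in r.stoichiometry.items():
                (produced if coef > 0 else consumed).add(m)
    present = {m for r in model.reactions for m in r.stoichiometry}
    return {m for m in present if not (m in produced and m in consumed)}


def remove_dead_ends(model: MetabolicModel) -> MetabolicModel:
    """Iteratively remove dead-end metabolites and their reactions.

    Runs to a fixed point: removing a reaction can orphan further
    metabolites, so sweeps repeat until no dead end remains.  Orphaned
    metabolites are dropped from the model.  Raises :class:`ModelError`
    if pruning would remove the biomass or objective reaction, or if the
    model is empty.
    """
    if not model.reactions:
        raise ModelError("cannot prune an empty model")
    current = model.copy()
    while True:
        dead = find_dead_end_metabolites(current)
        if not dead:
            break
        keep = [
            r for r in current.reactions
            if not (set(r.stoichiometry) & dead)
        ]
        removed_ids = {r.id for r in current.reactions} - {r.id for r in keep}
        for attr in ("biomass_id", "objective_id"):
            rid = getattr(current, attr)
            if rid is not None and rid in removed_ids:
                raise ModelError(
                    f"dead-end pruning would remove the {attr.split('_')[0]} "
                    f"reaction {rid!r}"
                )
        if not keep:
            raise ModelError("dead-end pruning removed every reaction")
        used = {m for r in keep for m in r.stoichiometry}
        current = MetabolicModel(
            id=current.id,
            metabolites=[m for m in current.metabolites if m.id in used],
            reactions=keep,
            compartments=dict(current.compartments),
            biomass_id=current.biomass_id,
            objective_id=current.objective_id,
        )
    return current


# ---------------------------------------------------------------------------
# statistics and task checking
# ---------------------------------------------------------------------------

def model_stats(model: MetabolicModel) -> dict[str, int]:
    """Counts of reactions, metabolites and genes (union of GPR leaves)."""
    return {
        "reactions": len(model.reactions),
        "metabolites": len(model.metabolites),
        "genes": len(model.genes),
    }


@dataclass(frozen=True)
class TaskResult:
    task_id: str
    passed: bool
    output_fluxes: Mapping[str, float]


def check_tasks(
    model: MetabolicModel, tasks: Sequence[MetabolicTask]
) -> dict[str, TaskResult]:
    """LP feasibility check of metabolic tasks on a model.

    For each task all exchange uptakes are closed, the allowed inputs are
    opened to their stated maxima, and each required output's exchange is
    maximized; the task passes iff every output can reach its minimum
    production.  Bounds are modified on a copy; the input model is left
    untouched.
    """
    from .fva import fba  # local import to avoid a cycle

    base = fba(model, objective_id=None)
    if base.status != "optimal":
        raise ModelError(
            f"base model has no steady-state solution (status={base.status})"
        )

    results: dict[str, TaskResult] = {}
    for task in tasks:
        work = model.copy()
        for ex in work.exchanges():
            ex.lower_bound = 0.0
        for met_id, max_uptake in task.allowed_inputs.items():
            work.exchange_for(met_id).lower_bound = -abs(max_uptake)
        fluxes: dict[str, float] = {}
        passed = True
        for met_id, min_prod in task.required_outputs.items():
            ex = work.exchange_for(met_id)
            sol = fba(work, objective_id=ex.id, sense="max")
            achieved = sol.objective_value if sol.status == "optimal" else 0.0
            fluxes[met_id] = achieved
            if achieved < min_prod - 1e-9:
                passed = False
        results[task.id] = TaskResult(task.id, passed, fluxes)
    return results
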
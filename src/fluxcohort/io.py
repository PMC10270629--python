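"""Model serialization: a JSON dialect and SBML Level 3 with the fbc package.

The JSON dialect is a direct transcription of :class:`MetabolicModel`
(documented in docs/methods.md).  SBML I/O uses python-libsbml: flux
bounds as fbc parameters, GPRs as fbc gene-product associations, the
model objective as the active fbc objective and the biomass reaction as
a second (inactive) fbc objective, subsystems in reaction notes.
Round-tripping either format reproduces stoichiometry, bounds, GPR
strings and subsystems exactly.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Union

import libsbml

from .gpr import BoolOp, GeneRef, Gpr, GprNode, parse_gpr
from .model import (
    DEFAULT_COMPARTMENTS,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    ReactionKind,
    model_stats,
)


class FormatError(ValueError):
    """Malformed model file."""


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "compartments": dict(model.compartments),
        "biomass_id": model.biomass_id,
        "objective_id": model.objective_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string(),
                "subsystem": r.subsystem,
                "kind": r.kind.value,
            }
            for r in model.reactions
        ],
    }


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(
                id=m["id"], compartment=m["compartment"], name=m.get("name", "")
            )
            for m in data["metabolites"]
        ]
        reactions = []
        for r in data["reactions"]:
            try:
                reactions.append(
                    Reaction(
                        id=r["id"],
                        stoichiometry={
                            k: float(v) for k, v in r["stoichiometry"].items()
                        },
                        lower_bound=float(r["lower_bound"]),
                        upper_bound=float(r["upper_bound"]),
                        gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                        subsystem=r.get("subsystem", ""),
                        kind=ReactionKind(r.get("kind", "internal")),
                    )
                )
            except (ModelError, ValueError) as exc:
                raise FormatError(f"reaction {r.get('id', '?')!r}: {exc}") from exc
        model = MetabolicModel(
            id=data.get("id", "model"),
            metabolites=metabolites,
            reactions=reactions,
            compartments=dict(data.get("compartments", DEFAULT_COMPARTMENTS)),
            biomass_id=data.get("biomass_id"),
            objective_id=data.get("objective_id"),
        )
    except KeyError as exc:
        raise FormatError(f"missing required field {exc}") from exc
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML (Level 3 Version 1, fbc version 2)
# ---------------------------------------------------------------------------

def _sanitize(sid: str) -> str:
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in sid)
    return out if out and not out[0].isdigit() else f"_{out}"


def _gpr_to_fbc(node: GprNode, assoc, gene_ids: dict[str, str]) -> None:
    if isinstance(node, GeneRef):
        ref = assoc.createGeneProductRef()
        ref.setGeneProduct(gene_ids[node.gene])
        return
    container = assoc.createAnd() if node.op == "and" else assoc.createOr()
    for child in node.children:
        _gpr_to_fbc(child, container, gene_ids)


def _fbc_to_gpr(assoc, labels: dict[str, str]) -> GprNode:
    if assoc.isGeneProductRef():
        return GeneRef(labels[assoc.getGeneProduct()])
    op = "and" if assoc.isFbcAnd() else "or"
    children = tuple(
        _fbc_to_gpr(assoc.getAssociation(i), labels)
        for i in range(assoc.getNumAssociations())
    )
    return children[0] if len(children) == 1 else BoolOp(op, children)


def write_sbml(model: MetabolicModel, path: Union[str, Path]) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sanitize(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for code, name in model.compartments.items():
        comp = sbml_model.createCompartment()
        comp.setId(_sanitize(code))
        comp.setName(name)
        comp.setConstant(True)

    met_sid = {}
    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sid = f"M_{_sanitize(m.id)}"
        met_sid[m.id] = sid
        sp.setId(sid)
        if m.name:
            sp.setName(m.name)
        sp.setCompartment(_sanitize(m.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    gene_sid = {}
    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        sid = f"G_{_sanitize(gene)}"
        gene_sid[gene] = sid
        gp.setId(sid)
        gp.setLabel(gene)

    def bound_param(value: float, tag: str) -> str:
        pid = f"P_{tag}"
        par = sbml_model.createParameter()
        par.setId(pid)
        par.setValue(value)
        par.setConstant(True)
        return pid

    for i, r in enumerate(model.reactions):
        rx = sbml_model.createReaction()
        rid = f"R_{_sanitize(r.id)}"
        rx.setId(rid)
        rx.setName(r.id)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        if r.subsystem:
            rx.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {r.subsystem}</p></body>"
            )
        for met_id, coef in r.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(met_sid[met_id])
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound, f"lb_{i}"))
        rplug.setUpperFluxBound(bound_param(r.upper_bound, f"ub_{i}"))
        if not r.gpr.is_empty:
            assoc = rplug.createGeneProductAssociation()
            _gpr_to_fbc(r.gpr.root, assoc, gene_sid)

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(f"R_{_sanitize(model.objective_id)}")
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")
    if model.biomass_id is not None:
        obj = mplug.createObjective()
        obj.setId("biomass_obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(f"R_{_sanitize(model.biomass_id)}")
        fo.setCoefficient(1.0)

    libsbml.writeSBMLToFile(doc, str(path))


def read_sbml(path: Union[str, Path]) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError("SBML file contains no model element")
    mplug = sbml_model.getPlugin("fbc")

    compartments = {}
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        compartments[comp.getId()] = comp.getName() or comp.getId()

    metabolites = []
    met_by_sid = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        mid = sp.getId()
        mid = mid[2:] if mid.startswith("M_") else mid
        met_by_sid[sp.getId()] = mid
        metabolites.append(
            Metabolite(id=mid, compartment=sp.getCompartment(), name=sp.getName())
        )

    labels = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            labels[gp.getId()] = gp.getLabel() or gp.getId()

    objective_id = None
    biomass_id = None
    if mplug is not None:
        for i in range(mplug.getNumObjectives()):
            obj = mplug.getObjective(i)
            if obj.getNumFluxObjectives() == 0:
                continue
            target = obj.getFluxObjective(0).getReaction()
            target = target[2:] if target.startswith("R_") else target
            if obj.getId() == "biomass_obj":
                biomass_id = target
            elif obj.getId() == mplug.getActiveObjectiveId() or objective_id is None:
                objective_id = target

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rid = rx.getId()
        rid = rid[2:] if rid.startswith("R_") else rid
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            met = met_by_sid[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            met = met_by_sid[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb, ub = -math.inf, math.inf
        gpr = Gpr(None)
        if rplug is not None:
            lb_par = sbml_model.getParameter(rplug.getLowerFluxBound())
            ub_par = sbml_model.getParameter(rplug.getUpperFluxBound())
            if lb_par is not None:
                lb = lb_par.getValue()
            if ub_par is not None:
                ub = ub_par.getValue()
            assoc = rplug.getGeneProductAssociation()
            if assoc is not None:
                gpr = Gpr(_fbc_to_gpr(assoc.getAssociation(), labels))
        subsystem = ""
        if rx.isSetNotes():
            notes = rx.getNotesString()
            marker = "SUBSYSTEM: "
            if marker in notes:
                subsystem = notes.split(marker, 1)[1].split("<")[0].strip()
        compartment_of = {m.id: m.compartment for m in metabolites}
        from .model import infer_kind

        kind = infer_kind(stoich, compartment_of, rid, biomass_id, objective_id)
        try:
            reactions.append(
                Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    gpr=gpr,
                    subsystem=subsystem,
                    kind=kind,
                )
            )
        except ModelError as exc:
            raise FormatError(f"reaction element {rx.getId()!r}: {exc}") from exc

    model = MetabolicModel(
        id=sbml_model.getId() or "model",
        metabolites=metabolites,
        reactions=reactions,
        compartments=compartments,
        biomass_id=biomass_id,
        objective_id=objective_id,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# front door
# ---------------------------------------------------------------------------

def write_model(
    model: MetabolicModel, path: Union[str, Path], format: Optional[str] = None
) -> None:
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        path.write_text(json.dumps(model_to_dict(model), indent=1))
    elif fmt == "sbml":
        write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def read_model(path: Union[str, Path], format: Optional[str] = None) -> MetabolicModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
        return model_from_dict(data)
    if fmt == "sbml":
        return read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model_stats(model: MetabolicModel, path: Union[str, Path]) -> None:
    stats = model_stats(model)
    lines = ["quantity\tcount"] + [f"{k}\t{v}" for k, v in stats.items()]
    Path(path).write_text("\n".join(lines) + "\n")
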
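"""Overlap enrichment of perturbed reactions over reaction sets.

Reaction sets come in three kinds built from the context-specific model:
pathway sets (reactions sharing a subsystem label), metabolite sets
(reactions in which a metabolite participates as substrate or product,
in compartmentalized or base-id form), and compartment sets.  Each set
is scored with the one-sided hypergeometric tail and with the coverage
score 100·k/K (the percentage of the set's reactions that are
perturbed); BH correction is applied within each set kind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffflux import bh_adjust
from .model import MetabolicModel, ReactionKind

logger = logging.getLogger(__name__)


def hypergeom_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``N`` universe size, ``K`` set size, ``n`` draws (perturbed count),
    ``k`` overlap.  Exact tail sum of the pmf.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"inconsistent counts N={N}, K={K}, n={n}, k={k}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class ReactionSet:
    id: str
    kind: str  # pathway | metabolite | compartment
    members: frozenset[str]


def pathway_sets(model: MetabolicModel) -> list[ReactionSet]:
    by_subsystem: dict[str, set[str]] = {}
    for r in model.reactions:
        if r.subsystem:
            by_subsystem.setdefault(r.subsystem, set()).add(r.id)
    return [
        ReactionSet(name, "pathway", frozenset(members))
        for name, members in sorted(by_subsystem.items())
    ]


def metabolite_sets(
    model: MetabolicModel, collapse_compartments: bool = False
) -> list[ReactionSet]:
    """One set per metabolite: every reaction where it is substrate or product.

    ``collapse_compartments=True`` pools compartment instances of a
    metabolite under its base id (the "unique" metabolite form).
    """
    by_met: dict[str, set[str]] = {}
    for r in model.reactions:
        for met_id in r.stoichiometry:
            key = model.metabolite(met_id).base_id if collapse_compartments else met_id
            by_met.setdefault(key, set()).add(r.id)
    return [
        ReactionSet(met, "metabolite", frozenset(members))
        for met, members in sorted(by_met.items())
    ]


def compartment_sets(model: MetabolicModel) -> list[ReactionSet]:
    """Non-transport reactions grouped by their (single) compartment."""
    by_comp: dict[str, set[str]] = {}
    for r in model.reactions:
        comps = r.compartments(model)
        if len(comps) != 1:
            continue  # transport reactions span compartments; excluded
        by_comp.setdefault(next(iter(comps)), set()).add(r.id)
    return [
        ReactionSet(comp, "compartment", frozenset(members))
        for comp, members in sorted(by_comp.items())
    ]


def enrich(
    perturbed: Iterable[str],
    sets: Sequence[ReactionSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of the perturbed reactions in each set.

    Returns one row per set: N, K, n, k, score (= 100·k/K), p, q (BH over
    the tested sets), sorted by q then descending score.  An empty
    perturbed set yields an empty frame with a warning.
    """
    universe = set(universe)
    perturbed = set(perturbed)
    if not perturbed <= universe:
        raise ValueError("perturbed reactions must be a subset of the universe")
    columns = ["kind", "N", "K", "n", "k", "score", "p", "q"]
    if not perturbed:
        logger.warning("empty perturbed set: nothing to enrich")
        return pd.DataFrame(columns=columns)
    N, n = len(universe), len(perturbed)
    rows = {}
    for s in sets:
        members = s.members & universe
        if not members:
            continue
        K = len(members)
        k = len(members & perturbed)
        rows[s.id] = {
            "kind": s.kind,
            "N": N,
            "K": K,
            "n": n,
            "k": k,
            "score": 100.0 * k / K,
            "p": hypergeom_p(N, K, n, k),
        }
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=columns)
    out.index.name = "set"
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["q", "score"], ascending=[True, False])


def enrich_model(
    model: MetabolicModel,
    perturbed: Iterable[str],
    kind: str,
    collapse_compartments: bool = False,
) -> pd.DataFrame:
    """Enrichment against sets derived from the model.

    The universe is every model reaction carrying the relevant
    annotation: a subsystem label for pathways, any stoichiometric
    participation for metabolites, a single compartment for compartments.
    """
    if kind == "pathway":
        sets = pathway_sets(model)
    elif kind == "metabolite":
        sets = metabolite_sets(model, collapse_compartments)
    elif kind == "compartment":
        sets = compartment_sets(model)
    else:
        raise ValueError(f"unknown set kind {kind!r}")
    universe = set().union(*(s.members for s in sets)) if sets else set()
    perturbed = set(perturbed) & universe
    return enrich(perturbed, sets, universe)


def compartment_summary(
    perturbed: Iterable[str], model: MetabolicModel
) -> pd.DataFrame:
    """Raw and adjusted per-compartment distribution of perturbed reactions.

    Transport reactions are excluded from both numerator and denominator
    of the adjusted percentage (= 100 · perturbed-in-compartment /
    reactions-in-compartment); each remaining reaction lives in exactly
    one compartment.  A multi-compartment reaction not flagged as
    transport is a consistency error.
    """
    perturbed = set(perturbed)
    counts: dict[str, int] = {}
    totals: dict[str, int] = {}
    for r in model.reactions:
        comps = r.compartments(model)
        if len(comps) >= 2:
            if r.kind is not ReactionKind.TRANSPORT:
                raise ValueError(
                    f"reaction {r.id} spans {sorted(comps)} but is not "
                    "flagged as transport"
                )
            continue
        if r.kind is ReactionKind.TRANSPORT:
            continue
        comp = next(iter(comps))
        totals[comp] = totals.get(comp, 0) + 1
        if r.id in perturbed:
            counts[comp] = counts.get(comp, 0) + 1
    rows = {
        comp: {
            "perturbed": counts.get(comp, 0),
            "total": totals[comp],
            "adjusted_pct": 100.0 * counts.get(comp, 0) / totals[comp],
        }
        for comp in sorted(totals)
        if counts.get(comp, 0) > 0
    }
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=["perturbed", "total", "adjusted_pct"]
    )
    out.index.name = "compartment"
    return out
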
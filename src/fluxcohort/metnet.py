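"""Metabolite-centric network built from perturbed reactions.

Nodes are unique (compartment-free) metabolites; an undirected edge
joins a substrate and a product of the same perturbed reaction.
Transport and exchange reactions and currency metabolites (ubiquitous
cofactors) are excluded so that connectivity reflects actual metabolic
conversions.  Nodes carry the adjusted p-value from metabolite
enrichment; filtering at q <= 0.05 leaves the significantly dysregulated
subnetwork whose connected components are the result of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import networkx as nx

from .model import MetabolicModel, ReactionKind

logger = logging.getLogger(__name__)

#: default currency metabolites, by base id (lower-cased comparison)
DEFAULT_CURRENCY = frozenset(
    {
        "h2o", "h", "atp", "adp", "amp", "pi", "ppi",
        "nad", "nadh", "nadp", "nadph", "fad", "fadh2",
        "coa", "co2", "o2",
    }
)


@dataclass
class MetaboliteNetwork:
    """Undirected metabolite graph; edges remember their supporting reactions."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def components(self) -> list[set[str]]:
        """Connected components sorted by size (desc), then smallest member."""
        comps = [set(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), min(c)))


def build_network(
    perturbed_reactions: Iterable[str],
    model: MetabolicModel,
    currency: frozenset[str] = DEFAULT_CURRENCY,
) -> MetaboliteNetwork:
    """Connect substrate/product base-id pairs of each perturbed reaction.

    Transport and exchange reactions contribute nothing; currency
    metabolites are dropped before pairing; every surviving
    substrate–product pair becomes an edge (self-loops from a base id on
    both sides are skipped).
    """
    currency_lc = {c.lower() for c in currency}
    net = MetaboliteNetwork()
    for rxn_id in sorted(set(perturbed_reactions)):
        r = model.reaction(rxn_id)
        if r.kind in (ReactionKind.TRANSPORT, ReactionKind.EXCHANGE):
            continue
        def base_ids(side: list[str]) -> list[str]:
            out = []
            for met_id in side:
                base = model.metabolite(met_id).base_id
                if base.lower() not in currency_lc:
                    out.append(base)
            return out
        for sub in base_ids(r.substrates()):
            for prod in base_ids(r.products()):
                if sub == prod:
                    continue
                edge = net.graph.edges.get((sub, prod))
                if edge is None:
                    net.graph.add_edge(sub, prod, reactions={rxn_id})
                else:
                    edge["reactions"].add(rxn_id)
    if net.graph.number_of_nodes() == 0:
        logger.warning("metabolite network is empty after filtering")
    return net


def filter_significant(
    net: MetaboliteNetwork,
    metabolite_q: Mapping[str, float],
    q_threshold: float = 0.05,
) -> MetaboliteNetwork:
    """Keep only nodes whose enrichment q-value is <= the threshold.

    Nodes missing from ``metabolite_q`` are removed too.  Components are
    recomputed on the filtered graph (accessible via ``components()``).
    """
    keep = {
        n
        for n in net.graph.nodes
        if n in metabolite_q and metabolite_q[n] <= q_threshold
    }
    out = MetaboliteNetwork(graph=net.graph.subgraph(keep).copy())
    for n in out.graph.nodes:
        out.graph.nodes[n]["q"] = float(metabolite_q[n])
    return out


def components(net: MetaboliteNetwork) -> list[set[str]]:
    return net.components()


def write_sif(net: MetaboliteNetwork, path: Union[str, Path]) -> None:
    """SIF export (``a interacts b`` per edge), loadable by Cytoscape."""
    lines = []
    for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
        lines.append(f"{a}\tinteracts\t{b}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(net: MetaboliteNetwork, path: Union[str, Path]) -> None:
    g = net.graph.copy()
    for _, _, data in g.edges(data=True):
        if isinstance(data.get("reactions"), set):
            data["reactions"] = ",".join(sorted(data["reactions"]))
    nx.write_graphml(g, str(path))
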
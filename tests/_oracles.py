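"""Independent oracles used by the test suite.

Each implements the quantity under test by a different route than the
package (exhaustive enumeration, brute force, closed form, or a
third-party solver), so agreement is evidence of correctness rather
than repetition.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from fluxcohort.fva import DEFAULT_BOUND
from fluxcohort.model import MetabolicModel


# ---------------------------------------------------------------------------
# FVA by polytope vertex enumeration
# ---------------------------------------------------------------------------

def fva_by_vertex_enumeration(model: MetabolicModel, tol: float = 1e-7) -> pd.DataFrame:
    """Exact flux ranges of {Sv=0, lb<=v<=ub} from its polytope vertices.

    Parameterizes the null space of S and enumerates all candidate
    vertices as intersections of d active box constraints; valid only for
    small bounded instances (<= ~10 reactions).
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    lb = np.array([max(r.lower_bound, -DEFAULT_BOUND) for r in model.reactions])
    ub = np.array([min(r.upper_bound, DEFAULT_BOUND) for r in model.reactions])

    N = null_space(S)
    d = N.shape[1]
    if d == 0:
        v = np.zeros(n)
        ok = np.all(v >= lb - tol) and np.all(v <= ub + tol)
        assert ok, "zero flux infeasible: polytope empty"
        return pd.DataFrame({"minimum": v, "maximum": v}, index=rxn_ids)

    # inequality rows: N t <= ub  and  -N t <= -lb
    A = np.vstack([N, -N])
    b = np.concatenate([ub, -lb])
    vertices = []
    for rows in itertools.combinations(range(2 * n), d):
        A_sub = A[list(rows)]
        if np.linalg.matrix_rank(A_sub) < d:
            continue
        t, *_ = np.linalg.lstsq(A_sub, b[list(rows)], rcond=None)
        if not np.allclose(A_sub @ t, b[list(rows)], atol=1e-8):
            continue
        if np.all(A @ t <= b + tol):
            vertices.append(N @ t)
    assert vertices, "no feasible vertex found"
    V = np.array(vertices)
    return pd.DataFrame(
        {"minimum": V.min(axis=0), "maximum": V.max(axis=0)}, index=rxn_ids
    )


# ---------------------------------------------------------------------------
# connected components by union-find
# ---------------------------------------------------------------------------

def components_by_union_find(nodes, edges):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted(groups.values(), key=lambda c: (-len(c), min(c)))


# ---------------------------------------------------------------------------
# hypergeometric tail by exhaustive enumeration
# ---------------------------------------------------------------------------

def hypergeom_tail_by_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) summed directly over the hypergeometric pmf via comb()."""
    total = comb(N, n)
    hits = sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    )
    return hits / total


# ---------------------------------------------------------------------------
# cobra conversion (third-party FBA/FVA route)
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    import cobra

    cb = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment)
        for m in model.metabolites
    }
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = max(r.lower_bound, -DEFAULT_BOUND)
        cr.upper_bound = min(r.upper_bound, DEFAULT_BOUND)
        rxns.append(cr)
    cb.add_reactions(rxns)
    for r in model.reactions:
        cb.reactions.get_by_id(r.id).add_metabolites(
            {mets[m]: c for m, c in r.stoichiometry.items()}
        )
    return cb
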
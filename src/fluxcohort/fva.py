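"""Flux balance analysis (FBA) and flux variability analysis (FVA).

Both solve linear programs over the steady-state flux polytope
``{v : S v = 0, lb <= v <= ub}``.  FBA returns one optimum of a single
objective; FVA reports, per reaction, the attainable minimum and maximum
flux after fixing the model objective at a fraction γ of its optimum and
(optionally) holding biomass production above a fraction β of a shared
healthy-reference optimum — the viability floor used when comparing
personalized models.

LPs are solved with the HiGHS solvers behind scipy.optimize.linprog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import MetabolicModel, ModelError

logger = logging.getLogger(__name__)

#: cap applied to infinite bounds before handing the LP to the solver
DEFAULT_BOUND = 1000.0

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass(frozen=True)
class FbaResult:
    status: str
    objective_value: float
    fluxes: Optional[pd.Series]


@dataclass(frozen=True)
class FvaConfig:
    """Settings for flux variability analysis.

    objective_fraction (γ): the model objective is held at γ · its own
    optimum during FVA (1.0 fixes it at the optimum).
    biomass_fraction (β): biomass flux is held at β · ``biomass_reference``;
    the reference is the biomass optimum of the healthy group-average
    model, shared by every individual so that all cohort members face the
    same viability floor.
    """

    objective_fraction: float = 1.0
    biomass_fraction: float = 0.8
    biomass_reference: Optional[float] = None
    tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if not (0 < self.objective_fraction <= 1):
            raise ValueError("objective_fraction must be in (0, 1]")
        if not (0 < self.biomass_fraction <= 1):
            raise ValueError("biomass_fraction must be in (0, 1]")


def _capped_bounds(model: MetabolicModel) -> list[tuple[float, float]]:
    out = []
    for r in model.reactions:
        lb = max(r.lower_bound, -DEFAULT_BOUND)
        ub = min(r.upper_bound, DEFAULT_BOUND)
        out.append((lb, ub))
    return out


def _solve(S, c, bounds):
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    return res, _STATUS.get(res.status, "numerical")


def fba(
    model: MetabolicModel,
    objective_id: Optional[str] = None,
    sense: str = "max",
) -> FbaResult:
    """Solve one flux balance LP.

    ``objective_id=None`` runs a pure feasibility check (zero objective).
    Infeasibility is reported through ``status``, never raised, so cohort
    runs can continue past individual models.
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    c = np.zeros(len(rxn_ids))
    if objective_id is not None:
        j = rxn_ids.index(model.reaction(objective_id).id)
        c[j] = -1.0 if sense == "max" else 1.0
    res, status = _solve(S, c, _capped_bounds(model))
    if status != "optimal":
        return FbaResult(status, float("nan"), None)
    value = float(res.x[c != 0][0]) if objective_id is not None else 0.0
    return FbaResult(status, value, pd.Series(res.x, index=rxn_ids))


def fva(model: MetabolicModel, config: FvaConfig = FvaConfig()) -> pd.DataFrame:
    """Per-reaction attainable flux ranges under the configured constraints.

    Returns a DataFrame indexed by reaction id with columns ``minimum``,
    ``maximum`` and ``status``.  Raises :class:`ModelError` when the
    constrained model is infeasible (callers doing cohort runs catch this
    per individual).
    """
    work = model.copy()

    if config.biomass_reference is not None:
        if work.biomass_id is None:
            raise ModelError("biomass_reference given but model has no biomass_id")
        floor = config.biomass_fraction * config.biomass_reference
        bio = work.reaction(work.biomass_id)
        bio.lower_bound = max(bio.lower_bound, floor)
        if bio.lower_bound > bio.upper_bound:
            raise ModelError(
                f"biomass floor {floor:.6g} exceeds the upper bound of "
                f"{bio.id}; individual infeasible"
            )

    if work.objective_id is not None:
        opt = fba(work, work.objective_id, sense="max")
        if opt.status != "optimal":
            raise ModelError(
                f"objective FBA {opt.status} under biomass constraint"
            )
        obj = work.reaction(work.objective_id)
        target = config.objective_fraction * opt.objective_value
        obj.lower_bound = max(obj.lower_bound, target - config.tolerance)

    S, _, rxn_ids = model.stoichiometric_matrix()  # stoichiometry is shared
    bounds = _capped_bounds(work)
    n = len(rxn_ids)
    mins = np.full(n, np.nan)
    maxs = np.full(n, np.nan)
    statuses = []
    for j in range(n):
        lb, ub = bounds[j]
        if ub - lb <= config.tolerance:
            mins[j], maxs[j] = lb, ub
            statuses.append("optimal")
            continue
        c = np.zeros(n)
        c[j] = 1.0
        lo_res, lo_status = _solve(S, c, bounds)
        c[j] = -1.0
        hi_res, hi_status = _solve(S, c, bounds)
        if lo_status != "optimal" or hi_status != "optimal":
            statuses.append(lo_status if lo_status != "optimal" else hi_status)
            continue
        lo, hi = float(lo_res.x[j]), float(hi_res.x[j])
        # clip solver jitter back into the declared bounds
        mins[j] = min(max(lo, lb), ub)
        maxs[j] = min(max(hi, lb), ub)
        if mins[j] > maxs[j]:
            mins[j] = maxs[j] = (mins[j] + maxs[j]) / 2
        statuses.append("optimal")
    out = pd.DataFrame(
        {"minimum": mins, "maximum": maxs, "status": statuses}, index=rxn_ids
    )
    out.index.name = "reaction"
    if out["status"].ne("optimal").all():
        raise ModelError("FVA infeasible for every reaction")
    return out


@dataclass
class CohortFluxRanges:
    """Tidy per-sample FVA results: one row per (sample, reaction)."""

    table: pd.DataFrame  # columns: sample, reaction, minimum, maximum, status
    infeasible_samples: list[str] = field(default_factory=list)

    def matrix(self, which: str) -> pd.DataFrame:
        """Pivot to sample × reaction for ``which`` in {'minimum','maximum'}."""
        return self.table.pivot(index="sample", columns="reaction", values=which)


def cohort_fva(
    models: Mapping[str, MetabolicModel],
    config: FvaConfig,
    groups: Optional[Mapping[str, str]] = None,
) -> CohortFluxRanges:
    """Run FVA on every personalized model of a cohort.

    Individuals whose constrained model is infeasible are excluded (and
    logged); if ``groups`` is given and every member of some group is
    infeasible, the run aborts with diagnostics.  The result only depends
    on the models, never on iteration order.
    """
    if groups is not None:
        groups = dict(groups)
    frames = []
    infeasible: list[str] = []
    for sample_id in models:
        try:
            ranges = fva(models[sample_id], config)
        except ModelError as exc:
            logger.warning("sample %s excluded from FVA: %s", sample_id, exc)
            infeasible.append(sample_id)
            continue
        block = ranges.reset_index()
        block.insert(0, "sample", sample_id)
        frames.append(block)
    if not frames:
        raise ModelError("no feasible personalized model in the cohort")
    table = pd.concat(frames, ignore_index=True)
    if groups is not None:
        feasible = set(table["sample"])
        for group in sorted(set(groups.values())):
            members = {s for s, g in groups.items() if g == group and s in models}
            if members and not (members & feasible):
                raise ModelError(
                    f"every sample of group {group!r} was infeasible"
                )
    if infeasible:
        logger.warning(
            "cohort FVA: %d/%d samples infeasible", len(infeasible), len(models)
        )
    return CohortFluxRanges(table=table, infeasible_samples=infeasible)
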
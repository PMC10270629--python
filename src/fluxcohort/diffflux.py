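"""Two-group statistics on personalized FVA fluxes.

For every reaction, the per-individual minimum fluxes and maximum fluxes
are compared between groups with Welch's unequal-variance t-test; each
family (min, max) is corrected with Benjamini–Hochberg separately, and a
reaction is called perturbed when either adjusted p-value falls below
the FDR threshold (default 0.1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fva import CohortFluxRanges

logger = logging.getLogger(__name__)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's t statistic, Satterthwaite df, and two-sided p-value.

    Degenerate conventions keep cohort runs total: when both groups have
    zero variance, equal means give (t=0, p=1) and different means give
    (t=±inf, p=0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, float(len(x) + len(y) - 2), 1.0
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return sign * np.inf, float(len(x) + len(y) - 2), 0.0
    with warnings.catch_warnings():
        # near-identical groups trigger a harmless precision warning; the
        # resulting huge |t| / tiny p is exactly what the caller wants
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x, y, equal_var=False)
    se2 = vx / len(x) + vy / len(y)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    return float(t), float(df), float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DiffFluxResult:
    """Per-reaction differential-flux table.

    Columns: t_min, p_min, q_min, t_max, p_max, q_max, n_healthy,
    n_disease, perturbed.  ``alpha`` records the FDR threshold used.
    """

    table: pd.DataFrame
    alpha: float
    group_a: str
    group_b: str

    @property
    def perturbed_reactions(self) -> list[str]:
        return list(self.table.index[self.table["perturbed"]])


def call_perturbed(
    flux_set: CohortFluxRanges,
    groups: pd.Series,
    alpha: float = 0.1,
) -> DiffFluxResult:
    """Welch-test min and max fluxes per reaction; BH within each family.

    ``groups`` maps sample id -> group label (exactly two labels, each
    with >= 2 feasible samples).  Reactions missing for some samples
    (infeasible individuals) are tested on the available ones when both
    groups retain >= 2, otherwise skipped with a log message.  A reaction
    is perturbed iff q_min < alpha or q_max < alpha.
    """
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    ga, gb = labels
    table = flux_set.table
    feasible = groups.loc[groups.index.intersection(set(table["sample"]))]
    a_samples = set(feasible.index[feasible == ga])
    b_samples = set(feasible.index[feasible == gb])
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError(
            "both groups need >= 2 feasible samples "
            f"({ga}: {len(a_samples)}, {gb}: {len(b_samples)})"
        )

    rows = {}
    skipped = []
    for reaction, block in table.groupby("reaction", sort=True):
        block = block.set_index("sample")
        a = block.index.intersection(a_samples)
        b = block.index.intersection(b_samples)
        if len(a) < 2 or len(b) < 2:
            skipped.append(reaction)
            continue
        t_min, _, p_min = welch_t(block.loc[a, "minimum"], block.loc[b, "minimum"])
        t_max, _, p_max = welch_t(block.loc[a, "maximum"], block.loc[b, "maximum"])
        rows[reaction] = {
            "t_min": t_min,
            "p_min": p_min,
            "t_max": t_max,
            "p_max": p_max,
            "n_healthy": len(a),
            "n_disease": len(b),
        }
    if skipped:
        logger.warning(
            "%d reactions skipped (fewer than 2 feasible samples per group)",
            len(skipped),
        )
    if not rows:
        raise ValueError("no reaction had enough feasible samples to test")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "reaction"
    out["q_min"] = bh_adjust(out["p_min"].to_numpy())
    out["q_max"] = bh_adjust(out["p_max"].to_numpy())
    out["perturbed"] = (out["q_min"] < alpha) | (out["q_max"] < alpha)
    return DiffFluxResult(table=out, alpha=alpha, group_a=ga, group_b=gb)


def write_diff_flux(
    result: DiffFluxResult, path, subsystems: dict[str, str] | None = None
) -> None:
    out = result.table.copy()
    if subsystems:
        out.insert(0, "subsystem", [subsystems.get(r, "") for r in out.index])
    out.to_csv(path, sep="\t")
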
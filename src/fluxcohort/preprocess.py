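"""RNA-Seq count preprocessing for expression-constrained modeling.

Pipeline order is fixed: filter lowly expressed genes on raw counts,
then normalize (median-of-ratios size factors, gene-length adjustment to
counts-per-kilobase, log2(x+1)).  The normalized values feed GPR
activity scoring, so they must be non-negative and comparable between
samples but need no differential-expression machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd


class PreprocessError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values with lengths and group labels.

    ``values``: DataFrame, genes in rows, samples in columns, non-negative.
    ``gene_lengths``: Series (bp) over the same genes.
    ``sample_groups``: Series mapping sample -> group label.
    ``stage``: "raw" counts or "normalized" log2 values.
    """

    values: pd.DataFrame
    gene_lengths: pd.Series
    sample_groups: pd.Series
    stage: str = "raw"

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise PreprocessError("expression values must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.values.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            missing = self.gene_lengths.index[
                self.gene_lengths.isna() | (self.gene_lengths <= 0)
            ]
            raise PreprocessError(
                f"every gene needs a positive length; offending: "
                f"{list(missing[:5])}"
            )
        self.sample_groups = self.sample_groups.reindex(self.values.columns)
        if self.sample_groups.isna().any():
            raise PreprocessError("every sample needs a group label")
        if self.stage not in ("raw", "normalized"):
            raise PreprocessError(f"unknown stage {self.stage!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, group: str) -> list[str]:
        return list(self.sample_groups.index[self.sample_groups == group])

    def groups(self) -> list[str]:
        return sorted(self.sample_groups.unique())


def filter_low_expressed(
    expr: ExpressionMatrix, min_count: float = 5, min_fraction: float = 0.25
) -> ExpressionMatrix:
    """Keep genes reaching ``min_count`` reads in >= ``min_fraction`` of samples.

    Applied to raw counts before normalization; the sample set is never
    changed.  Raises if no gene survives (thresholds likely wrong for the
    data at hand).
    """
    if expr.stage != "raw":
        raise PreprocessError("filtering applies to raw counts")
    frac = (expr.values >= min_count).mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        raise PreprocessError(
            "all genes removed by the low-expression filter; review "
            f"min_count={min_count}, min_fraction={min_fraction}"
        )
    return ExpressionMatrix(
        values=expr.values.loc[keep].copy(),
        gene_lengths=expr.gene_lengths.loc[keep].copy(),
        sample_groups=expr.sample_groups.copy(),
        stage="raw",
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The per-gene geometric mean is taken over genes with positive counts
    in every sample; each sample's factor is the median of its ratios to
    those reference values.
    """
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise PreprocessError(
            "size factors undefined: no gene has positive counts in all samples"
        )
    ref = counts.loc[positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    factors = {}
    for sample in counts.columns:
        ratios = np.log(ref[sample]) - log_geo_mean
        factors[sample] = float(np.exp(np.median(ratios)))
    s = pd.Series(factors)
    if (s <= 0).any() or not np.isfinite(s).all():
        raise PreprocessError("degenerate size factor encountered")
    return s


def normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Between-sample normalization with gene-length adjustment.

    value = log2( count / size_factor / (length_kb) + 1 ); zero counts map
    to zero.  Output stage is "normalized".
    """
    if expr.stage != "raw":
        raise PreprocessError("normalize expects raw (filtered) counts")
    s = size_factors(expr.values)
    length_kb = expr.gene_lengths / 1000.0
    scaled = expr.values.div(s, axis=1).div(length_kb, axis=0)
    values = np.log2(scaled + 1.0)
    return ExpressionMatrix(
        values=values,
        gene_lengths=expr.gene_lengths.copy(),
        sample_groups=expr.sample_groups.copy(),
        stage="normalized",
    )


def preprocess(
    expr: ExpressionMatrix, min_count: float = 5, min_fraction: float = 0.25
) -> ExpressionMatrix:
    """Filter then normalize (the fixed pipeline order)."""
    return normalize(filter_low_expressed(expr, min_count, min_fraction))


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def read_expression(
    counts_path: Union[str, Path],
    lengths_path: Union[str, Path],
    groups_path: Union[str, Path],
) -> ExpressionMatrix:
    """Assemble an :class:`ExpressionMatrix` from three TSV files.

    counts: genes in rows, samples in columns; lengths: columns gene,
    length; groups: columns sample, group.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(
        values=counts, gene_lengths=lengths, sample_groups=groups, stage="raw"
    )


def write_expression(expr: ExpressionMatrix, out_dir: Union[str, Path], prefix: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr.values.to_csv(out / f"{prefix}_values.tsv", sep="\t")
    expr.gene_lengths.rename("length").to_csv(out / f"{prefix}_gene_lengths.tsv", sep="\t")
    expr.sample_groups.rename("group").to_csv(out / f"{prefix}_sample_groups.tsv", sep="\t")
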
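#!/usr/bin/env python
"""Preprocess the counts and extract the context-specific model.

Low-expressed genes are filtered (≥5 reads in ≥25% of samples),
counts are normalized (median-of-ratios, counts-per-kilobase,
log2(x+1)), and the context model is extracted from the healthy group
mean (inactive reactions dropped, dead ends pruned to a fixed point).
"""

from common import FIXTURE, RESULTS, ensure_dirs
from fluxcohort.io import write_model, write_model_stats
from fluxcohort.model import model_stats
from fluxcohort.pipeline import extract_context_model
from fluxcohort.preprocess import preprocess, read_expression, write_expression
from fluxcohort.io import read_model

ensure_dirs()

expr = read_expression(FIXTURE / "counts.tsv", FIXTURE / "gene_lengths.tsv",
                       FIXTURE / "sample_groups.tsv")
normalized = preprocess(expr)
write_expression(normalized, RESULTS, "normalized")

template = read_model(FIXTURE / "model.json")
context = extract_context_model(template, normalized)
write_model(context, RESULTS / "context_model.json")
write_model_stats(context, RESULTS / "model_stats.tsv")

n_removed = len(expr.genes) - len(normalized.genes)
print(f"filtered {n_removed} low-expressed genes; "
      f"{len(normalized.genes)} retained")
before, after = model_stats(template), model_stats(context)
print(f"context model: {after['reactions']}/{before['reactions']} reactions "
      f"retained after activity filtering and dead-end pruning")
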
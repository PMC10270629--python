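#!/usr/bin/env python
"""Simulate the study cohort: toy muscle-like model + RNA-Seq counts.

Writes the metabolic model (JSON + SBML), the raw count matrix with gene
lengths and group labels, the media definition, and the ground-truth
record of what was planted (two pathways at 50% expression in the
disease group).
"""

import json

from common import FIXTURE, STUDY_SPEC, ensure_dirs
from fluxcohort.io import write_model
from fluxcohort.model import model_stats
from fluxcohort.synthetic import default_media, make_cohort, make_model

ensure_dirs()

model = make_model(STUDY_SPEC)
expr, truth = make_cohort(model, STUDY_SPEC)

write_model(model, FIXTURE / "model.json")
write_model(model, FIXTURE / "model.xml", format="sbml")
expr.values.to_csv(FIXTURE / "counts.tsv", sep="\t")
expr.gene_lengths.rename("length").to_csv(FIXTURE / "gene_lengths.tsv", sep="\t")
expr.sample_groups.rename("group").to_csv(FIXTURE / "sample_groups.tsv", sep="\t")
default_media(model).to_yaml(FIXTURE / "media.yaml")
(FIXTURE / "ground_truth.json").write_text(json.dumps({
    "perturbed_pathways": list(truth.perturbed_pathways),
    "perturbed_genes": sorted(truth.perturbed_genes),
    "perturbed_reactions": sorted(truth.perturbed_reactions),
    "coupled_reactions": sorted(truth.coupled_reactions),
    "effect_size": truth.effect_size,
}, indent=1))

stats = model_stats(model)
print(f"template model: {stats['reactions']} reactions, "
      f"{stats['metabolites']} metabolites, {stats['genes']} genes")
print(f"cohort: {expr.values.shape[0]} genes x {expr.values.shape[1]} samples")
print(f"planted: {sorted(truth.perturbed_pathways)} "
      f"({len(truth.perturbed_reactions)} pathway reactions) at "
      f"effect size {truth.effect_size}")
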
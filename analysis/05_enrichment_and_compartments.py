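#!/usr/bin/env python
"""Enrich perturbed reactions over pathway, metabolite and compartment sets.

Each set gets the coverage score (100·k/K) and a one-sided
hypergeometric p with BH correction within its kind; the compartment
summary excludes transport reactions from numerator and denominator.
"""

import pandas as pd

from common import RESULTS, ensure_dirs
from fluxcohort.enrichment import compartment_summary, enrich_model
from fluxcohort.io import read_model

ensure_dirs()

context = read_model(RESULTS / "context_model.json")
diff = pd.read_csv(RESULTS / "diff_flux.tsv", sep="\t", index_col=0)
perturbed = list(diff.index[diff["perturbed"]])

pathway = enrich_model(context, perturbed, "pathway")
metab = enrich_model(context, perturbed, "metabolite")
metab_unique = enrich_model(context, perturbed, "metabolite",
                            collapse_compartments=True)
comp = compartment_summary(perturbed, context)

pathway.to_csv(RESULTS / "enrichment_pathway.tsv", sep="\t")
metab.to_csv(RESULTS / "enrichment_metabolite.tsv", sep="\t")
metab_unique.to_csv(RESULTS / "enrichment_metabolite_unique.tsv", sep="\t")
comp.to_csv(RESULTS / "compartment_summary.tsv", sep="\t")

print("top pathways by adjusted p:")
print(pathway.head(4)[["K", "k", "score", "q"]].to_string())
print("\nper-compartment adjusted percentages (transport excluded):")
print(comp.to_string())
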
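#!/usr/bin/env python
"""Select exchange-flux markers with the GA-wrapped SVM.

Uses a second cohort carrying one planted, cleanly separating exchange
flux (the glycerolipid product exporter knocked down in disease).
Candidates are all exchange reactions; each contributes its
per-individual FVA min and max flux as features.  The GA (population
300, ≤100 generations, stop at 90% CV accuracy) is repeated 20 times
and features are ranked by selection frequency; reactions at ≥80% form
the marker panel.
"""

import json

from common import MARKER_SPEC, RESULTS, SEED, ensure_dirs
from fluxcohort.eflux import personalize
from fluxcohort.fva import FvaConfig, cohort_fva, fba
from fluxcohort.markers import (
    GaConfig,
    build_feature_table,
    detect_shifted_exchanges,
    evaluate_svm,
    select_markers,
)
from fluxcohort.pipeline import extract_context_model, personalize_cohort
from fluxcohort.preprocess import preprocess
from fluxcohort.synthetic import default_media, make_cohort, make_model
from fluxcohort.fva import fva

ensure_dirs()

model = make_model(MARKER_SPEC)
media = default_media(model)
expr, truth = make_cohort(model, MARKER_SPEC)
pre = preprocess(expr)
context = extract_context_model(model, pre)

avg_h = personalize(context, pre, media, group="healthy")
avg_d = personalize(context, pre, media, group="disease")
config = FvaConfig(biomass_reference=fba(avg_h, context.biomass_id).objective_value)
flux = cohort_fva(personalize_cohort(context, pre, media), config,
                  pre.sample_groups)

shifted = detect_shifted_exchanges(
    fva(avg_h, config), fva(avg_d, config),
    [r.id for r in context.exchanges()], delta=0.1,
)
print(f"shifted exchange candidates (group-average models): {shifted}")

exchanges = [r.id for r in context.exchanges()]
table = build_feature_table(flux, exchanges, pre.sample_groups)
panel, results = select_markers(table, exchanges, GaConfig(seed=SEED + 100),
                                n_repeats=20)

full_cv = evaluate_svm(table, folds=10, repeats=20, seed=SEED)
panel_cv = evaluate_svm(table, panel.panel_features(), folds=10, repeats=20,
                        seed=SEED)

table.X.to_csv(RESULTS / "marker_feature_table.tsv", sep="\t")
panel.reaction_frequencies.to_csv(RESULTS / "marker_frequencies.tsv", sep="\t")
(RESULTS / "marker_panel.json").write_text(json.dumps({
    "candidates": panel.candidates,
    "top_ranked": panel.top_ranked,
    "n_repeats": panel.n_repeats,
    "frequency_threshold": panel.frequency_threshold,
    "planted_marker": truth.separating_exchange,
    "full_cv": full_cv.mean,
    "panel_cv": panel_cv.mean,
}, indent=1))

print(f"top-ranked markers (freq >= 80% of {panel.n_repeats} GA runs): "
      f"{panel.top_ranked}")
print(f"planted marker {truth.separating_exchange} frequency: "
      f"{panel.reaction_frequencies[truth.separating_exchange]:.0f}%")
print(f"all-features CV accuracy: {full_cv.mean['accuracy']:.3f}; "
      f"panel CV accuracy: {panel_cv.mean['accuracy']:.3f}")
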
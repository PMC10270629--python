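"""Shared paths and study conditions for the numbered analysis scripts.

Every script reads earlier artifacts from ``results/`` and writes its own
there, so the chain 01 → 08 reproduces the whole study from one seed.
"""

from __future__ import annotations

from pathlib import Path

from fluxcohort.synthetic import SyntheticSpec

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
FIXTURE = RESULTS / "fixture"

SEED = 7

# primary cohort: two pathways knocked down to 50% expression
STUDY_SPEC = SyntheticSpec(seed=SEED, template="core", n_healthy=20,
                           n_disease=20, effect_size=0.5)

# marker cohort: no pathway effect, one planted separating exchange
MARKER_SPEC = SyntheticSpec(seed=SEED + 100, template="core", effect_size=1.0,
                            perturbed_pathways=(),
                            separating_exchange="EX_gllprod",
                            n_healthy=20, n_disease=20)


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    FIXTURE.mkdir(parents=True, exist_ok=True)
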
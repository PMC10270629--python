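"""End-to-end orchestration of the cohort flux analysis.

Stages: preprocess counts → extract the context-specific model from the
healthy group mean → personalize per individual (E-Flux + media) →
cohort FVA under the mitochondrial-ATP objective with the biomass
viability floor → differential flux statistics → pathway/metabolite/
compartment enrichment → metabolite network components → (optionally)
marker selection.  ``run_study`` is the programmatic entry point;
``run`` drives it from a YAML config and writes every artifact plus a
provenance manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from . import __version__
from .diffflux import DiffFluxResult, call_perturbed, write_diff_flux
from .eflux import MediaSpec, apply_media, compute_activities, personalize
from .enrichment import compartment_summary, enrich_model
from .fva import CohortFluxRanges, FvaConfig, cohort_fva, fba, fva
from .markers import (
    FeatureTable,
    GaConfig,
    MarkerPanel,
    SvmEvaluation,
    build_feature_table,
    detect_shifted_exchanges,
    evaluate_svm,
    select_markers,
)
from .metnet import (
    DEFAULT_CURRENCY,
    MetaboliteNetwork,
    build_network,
    filter_significant,
    write_graphml,
    write_sif,
)
from .model import MetabolicModel, ModelError, model_stats, remove_dead_ends
from .preprocess import ExpressionMatrix, preprocess, read_expression
from .io import read_model, write_model, write_model_stats

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StudyParams:
    """All analysis thresholds, at their study defaults."""

    min_count: float = 5.0
    min_fraction: float = 0.25
    alpha: float = 0.1  # FDR threshold for perturbed reactions
    network_q: float = 0.05  # metabolite significance cut in the network
    biomass_fraction: float = 0.8
    objective_fraction: float = 1.0
    shift_delta: float = 0.1
    currency: frozenset[str] = DEFAULT_CURRENCY
    cv_folds: int = 10
    cv_repeats: int = 100
    n_ga_repeats: int = 100
    frequency_threshold: float = 80.0
    ga: GaConfig = field(default_factory=GaConfig)


def extract_context_model(
    template: MetabolicModel,
    expr: ExpressionMatrix,
    group: str = "healthy",
    activity_threshold: float = 0.0,
) -> MetabolicModel:
    """Context-specific model from a group's mean expression.

    Reactions whose GPR activity under the group mean is at or below the
    threshold are considered inactive and removed; dead ends are then
    pruned to a fixed point.  The surviving reactions keep the template's
    original bounds — personalization re-scales them per individual.
    """
    members = expr.group_samples(group)
    if not members:
        raise ModelError(f"no samples in group {group!r}")
    profile = expr.values[members].mean(axis=1).to_dict()
    activities = compute_activities(template, profile, f"group-mean:{group}")
    inactive = {
        rid
        for rid, a in activities.scores.items()
        if a is not None and a <= activity_threshold
    }
    kept = [r.copy() for r in template.reactions if r.id not in inactive]
    if template.biomass_id in inactive or template.objective_id in inactive:
        raise ModelError("context extraction would remove biomass/objective")
    used = {m for r in kept for m in r.stoichiometry}
    pruned = MetabolicModel(
        id=f"{template.id}_context",
        metabolites=[m for m in template.metabolites if m.id in used],
        reactions=kept,
        compartments=dict(template.compartments),
        biomass_id=template.biomass_id,
        objective_id=template.objective_id,
    )
    return remove_dead_ends(pruned)


@dataclass
class StudyResult:
    normalized: ExpressionMatrix
    context_model: MetabolicModel
    biomass_reference: float
    flux_set: CohortFluxRanges
    diff: DiffFluxResult
    pathway_enrichment: pd.DataFrame
    metabolite_enrichment: pd.DataFrame  # compartmentalized ids
    metabolite_enrichment_unique: pd.DataFrame  # base ids
    compartments: pd.DataFrame
    network: MetaboliteNetwork
    significant_network: MetaboliteNetwork
    components: list[set[str]]
    group_ranges: dict[str, pd.DataFrame] = field(default_factory=dict)
    shifted_exchanges: list[str] = field(default_factory=list)
    feature_table: Optional[FeatureTable] = None
    panel: Optional[MarkerPanel] = None
    panel_cv: Optional[SvmEvaluation] = None
    full_cv: Optional[SvmEvaluation] = None


def personalize_cohort(
    context: MetabolicModel,
    normalized: ExpressionMatrix,
    media: MediaSpec,
) -> dict[str, MetabolicModel]:
    return {
        sample: personalize(context, normalized, media, sample=sample)
        for sample in normalized.samples
    }


def run_study(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    media: MediaSpec,
    params: StudyParams = StudyParams(),
    with_markers: bool = False,
    seed: int = 0,
) -> StudyResult:
    """Run the full analysis in memory; see the module docstring for stages."""
    normalized = preprocess(expr, params.min_count, params.min_fraction)
    context = extract_context_model(model, normalized)

    avg_healthy = personalize(context, normalized, media, group="healthy")
    avg_disease = personalize(context, normalized, media, group="disease")
    bio = fba(avg_healthy, context.biomass_id, sense="max")
    if bio.status != "optimal":
        raise ModelError(f"healthy group-average biomass FBA {bio.status}")
    reference = bio.objective_value

    config = FvaConfig(
        objective_fraction=params.objective_fraction,
        biomass_fraction=params.biomass_fraction,
        biomass_reference=reference,
    )
    personalized = personalize_cohort(context, normalized, media)
    flux_set = cohort_fva(personalized, config, normalized.sample_groups)
    diff = call_perturbed(flux_set, normalized.sample_groups, params.alpha)
    perturbed = diff.perturbed_reactions

    pathway_enr = enrich_model(context, perturbed, "pathway")
    met_enr = enrich_model(context, perturbed, "metabolite")
    met_enr_unique = enrich_model(
        context, perturbed, "metabolite", collapse_compartments=True
    )
    comp = compartment_summary(perturbed, context)

    network = build_network(perturbed, context, params.currency)
    met_q = met_enr_unique["q"].to_dict()
    significant = filter_significant(network, met_q, params.network_q)

    result = StudyResult(
        normalized=normalized,
        context_model=context,
        biomass_reference=reference,
        flux_set=flux_set,
        diff=diff,
        pathway_enrichment=pathway_enr,
        metabolite_enrichment=met_enr,
        metabolite_enrichment_unique=met_enr_unique,
        compartments=comp,
        network=network,
        significant_network=significant,
        components=significant.components(),
    )

    h_ranges = fva(_named(avg_healthy, "avg_healthy"), config)
    d_ranges = fva(_named(avg_disease, "avg_disease"), config)
    result.group_ranges = {"healthy": h_ranges, "disease": d_ranges}
    exchange_ids = [r.id for r in context.exchanges()]
    result.shifted_exchanges = detect_shifted_exchanges(
        h_ranges, d_ranges, exchange_ids, params.shift_delta
    )

    if with_markers and result.shifted_exchanges:
        table = build_feature_table(
            flux_set, result.shifted_exchanges, normalized.sample_groups
        )
        result.feature_table = table
        ga = GaConfig(
            population=params.ga.population,
            generations=params.ga.generations,
            fitness_stop=params.ga.fitness_stop,
            crossover_rate=params.ga.crossover_rate,
            mutation_rate=params.ga.mutation_rate,
            tournament_size=params.ga.tournament_size,
            elitism=params.ga.elitism,
            cv_folds=params.cv_folds,
            seed=seed,
        )
        panel, _ = select_markers(
            table,
            result.shifted_exchanges,
            ga,
            n_repeats=params.n_ga_repeats,
            frequency_threshold=params.frequency_threshold,
        )
        result.panel = panel
        result.full_cv = evaluate_svm(
            table, folds=params.cv_folds, repeats=params.cv_repeats, seed=seed
        )
        if panel.top_ranked:
            result.panel_cv = evaluate_svm(
                table,
                panel.panel_features(),
                folds=params.cv_folds,
                repeats=params.cv_repeats,
                seed=seed,
            )
    return result


def _named(model: MetabolicModel, name: str) -> MetabolicModel:
    out = model.copy()
    out.id = name
    return out


# ---------------------------------------------------------------------------
# config-driven run
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    model_path: str
    counts_path: str
    lengths_path: str
    groups_path: str
    media_path: str
    out_dir: str
    seed: int
    params: StudyParams = field(default_factory=StudyParams)
    with_markers: bool = False

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "seed" not in data:
            raise ValueError("config must declare a seed for every stochastic stage")
        params = StudyParams(**data.get("params", {}))
        if "ga" in data:
            ga_args = dict(data["ga"])
            ga_args.setdefault("seed", data["seed"])
            params.ga = GaConfig(**ga_args)
        cfg = cls(
            model_path=data["model"],
            counts_path=data["counts"],
            lengths_path=data["lengths"],
            groups_path=data["groups"],
            media_path=data["media"],
            out_dir=data.get("out_dir", "results"),
            seed=int(data["seed"]),
            params=params,
            with_markers=bool(data.get("with_markers", False)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("model_path", "counts_path", "lengths_path",
                     "groups_path", "media_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p}")


def run(config: PipelineConfig) -> Path:
    """Execute the full pipeline from files; returns the result directory.

    Every intermediate artifact is written; a failure halts with the
    stage name while earlier outputs stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        model = read_model(config.model_path)
        expr = read_expression(
            config.counts_path, config.lengths_path, config.groups_path
        )
        media = MediaSpec.from_yaml(config.media_path)

        stage = "analysis"
        result = run_study(
            model, expr, media, config.params,
            with_markers=config.with_markers, seed=config.seed,
        )

        stage = "write"
        result.normalized.values.to_csv(out / "normalized_expression.tsv", sep="\t")
        write_model(result.context_model, out / "context_model.json")
        write_model_stats(result.context_model, out / "model_stats.tsv")
        result.flux_set.table.to_csv(out / "flux_ranges.tsv", sep="\t", index=False)
        subsystems = {r.id: r.subsystem for r in result.context_model.reactions}
        write_diff_flux(result.diff, out / "diff_flux.tsv", subsystems)
        result.pathway_enrichment.to_csv(out / "enrichment_pathway.tsv", sep="\t")
        result.metabolite_enrichment.to_csv(
            out / "enrichment_metabolite.tsv", sep="\t"
        )
        result.metabolite_enrichment_unique.to_csv(
            out / "enrichment_metabolite_unique.tsv", sep="\t"
        )
        result.compartments.to_csv(out / "compartment_summary.tsv", sep="\t")
        write_sif(result.significant_network, out / "network.sif")
        write_graphml(result.significant_network, out / "network.graphml")
        (out / "components.json").write_text(
            json.dumps([sorted(c) for c in result.components], indent=1)
        )
        for group, ranges in result.group_ranges.items():
            ranges.to_csv(out / f"group_fva_{group}.tsv", sep="\t")
        summary = {
            "biomass_reference": result.biomass_reference,
            "n_perturbed": len(result.diff.perturbed_reactions),
            "n_components": len(result.components),
            "shifted_exchanges": result.shifted_exchanges,
            "infeasible_samples": result.flux_set.infeasible_samples,
        }
        if result.panel is not None:
            summary["top_ranked_markers"] = result.panel.top_ranked
            result.panel.reaction_frequencies.to_csv(
                out / "marker_frequencies.tsv", sep="\t"
            )
            if result.panel_cv is not None:
                summary["panel_cv"] = result.panel_cv.mean
            if result.full_cv is not None:
                summary["full_cv"] = result.full_cv.mean
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        _write_manifest(config, out)
    except Exception as exc:  # halt with stage context, keep partial outputs
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return out


def _write_manifest(config: PipelineConfig, out: Path) -> None:
    payload = {
        "seed": config.seed,
        "params": _jsonable(asdict(config.params)),
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in ("model_path", "counts_path", "lengths_path",
                         "groups_path", "media_path")
        },
        "versions": {
            "fluxcohort": __version__,
            "python": platform.python_version(),
        },
    }
    (out / "manifest.json").write_text(json.dumps(payload, indent=1))


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _sha256(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
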
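"""Synthetic toy metabolic models and two-group expression cohorts.

The generator emulates the statistical structure the analysis assumes: a
compartmentalized toy network (substrate uptake → enzyme chains in a
home compartment → product secretion, plus a glycolysis/oxidative-
phosphorylation backbone feeding a mitochondrial ATP demand and a
biomass drain) and negative-binomial RNA-Seq counts over its genes plus
filler genes.  A disease effect is planted at the gene level — the
expression of chosen pathways' genes is multiplied by ``effect_size`` in
the disease group only — so that the E-Flux → FVA → statistics chain is
what must transduce it.  Every generation call is deterministic given
its seed, and the returned ground-truth record scores every downstream
stage.

Templates: ``mini`` (16 reactions, 3 compartments) for fast nulls and
unit fixtures; ``core`` (~83 reactions, 7 compartments, 8 labeled
pathways) for end-to-end recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .eflux import MediaSpec
from .model import (
    EXTRACELLULAR,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKind,
)
from .preprocess import ExpressionMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic experiment.

    ``effect_size`` multiplies the disease-group expression means of all
    genes in ``perturbed_pathways`` (1.0 = exchangeable null).  The
    optional ``separating_exchange`` drives that exchange's pathway genes
    to a clean, low-noise knockdown (``separating_effect``, dispersion
    divided by 20) so its flux features separate the groups — the
    planted marker for feature-selection experiments.
    """

    seed: int
    template: str = "core"
    n_healthy: int = 20
    n_disease: int = 20
    perturbed_pathways: tuple[str, ...] = (
        "glycerolipid metabolism",
        "keratan sulfate biosynthesis",
    )
    effect_size: float = 0.5
    nb_dispersion: float = 0.1
    mean_range: tuple[float, float] = (50.0, 2000.0)
    length_range: tuple[int, int] = (500, 3000)
    n_filler_genes: int = 65
    n_low_genes: int = 10
    separating_exchange: Optional[str] = None
    separating_effect: float = 0.1

    def __post_init__(self) -> None:
        if self.n_healthy < 2 or self.n_disease < 2:
            raise ValueError("need at least 2 samples per group")
        if not (0 < self.effect_size <= 1):
            raise ValueError("effect_size must lie in (0, 1]")
        if self.template not in ("mini", "core"):
            raise ValueError(f"unknown template {self.template!r}")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for scoring downstream stages."""

    perturbed_pathways: tuple[str, ...]
    perturbed_genes: frozenset[str]
    perturbed_reactions: frozenset[str]  # pathway chain reactions
    coupled_reactions: frozenset[str]  # their transports and exchanges
    separating_exchange: Optional[str]
    effect_size: float


# ---------------------------------------------------------------------------
# model templates
# ---------------------------------------------------------------------------

CORE_PATHWAYS: tuple[tuple[str, str, str], ...] = (
    # (subsystem name, metabolite slug, home compartment)
    ("glycerolipid metabolism", "gll", "c"),
    ("amino acid metabolism", "aam", "c"),
    ("keratan sulfate biosynthesis", "ker", "g"),
    ("chondroitin sulfate biosynthesis", "cho", "g"),
    ("cholesterol ester metabolism", "che", "l"),
    ("carnitine shuttle", "car", "r"),
    ("inositol phosphate metabolism", "ino", "c"),
    ("glycerophospholipid metabolism", "gpl", "m"),
)
CORE_CHAIN_STEPS = 3


@dataclass
class TemplateLayout:
    """Deterministic bookkeeping of a template's structure."""

    pathway_genes: dict[str, frozenset[str]]  # subsystem -> gene set
    pathway_chain: dict[str, list[str]]  # subsystem -> chain reaction ids
    pathway_coupled: dict[str, list[str]]  # subsystem -> transports + exchanges
    pathway_exchanges: dict[str, tuple[str, str]]  # (substrate EX, product EX)
    backbone_genes: frozenset[str]
    declared_sizes: dict[str, int]
    pathway_out_gene: dict[str, str] = field(default_factory=dict)


def _mini_template() -> tuple[MetabolicModel, TemplateLayout]:
    comps = {"c": "cytosol", "m": "mitochondria", EXTRACELLULAR: "extracellular"}
    mets = [
        ("glc_s", EXTRACELLULAR), ("glc_c", "c"), ("pyr_s", EXTRACELLULAR),
        ("pyr_c", "c"), ("pyr_m", "m"), ("o2_s", EXTRACELLULAR), ("o2_m", "m"),
        ("co2_s", EXTRACELLULAR), ("co2_m", "m"), ("ala_s", EXTRACELLULAR),
        ("ala_c", "c"), ("atp_c", "c"), ("atp_m", "m"),
    ]
    metabolites = [Metabolite(id=m, compartment=c) for m, c in mets]
    EX, TR, IN = ReactionKind.EXCHANGE, ReactionKind.TRANSPORT, ReactionKind.INTERNAL
    reactions = [
        Reaction("EX_glc", {"glc_s": -1}, -10, 1000, "", "exchange", EX),
        Reaction("EX_o2", {"o2_s": -1}, -10, 1000, "", "exchange", EX),
        Reaction("EX_co2", {"co2_s": -1}, 0, 1000, "", "exchange", EX),
        Reaction("EX_ala", {"ala_s": -1}, -10, 1000, "", "exchange", EX),
        Reaction("EX_pyr", {"pyr_s": -1}, -10, 1000, "", "exchange", EX),
        Reaction("GLCt", {"glc_s": -1, "glc_c": 1}, 0, 1000, "g_glct", "transport", TR),
        Reaction("O2tm", {"o2_s": -1, "o2_m": 1}, 0, 1000, "", "transport", TR),
        Reaction("CO2tm", {"co2_m": -1, "co2_s": 1}, 0, 1000, "", "transport", TR),
        Reaction("ALAt", {"ala_s": -1, "ala_c": 1}, -1000, 1000,
                 "g_alat1 or g_alat2", "transport", TR),
        Reaction("PYRt", {"pyr_s": -1, "pyr_c": 1}, -1000, 1000, "g_pyrt",
                 "transport", TR),
        Reaction("GLYC", {"glc_c": -1, "pyr_c": 2, "atp_c": 2}, 0, 10,
                 "g_glyc1 and g_glyc2", "glycolysis", IN),
        Reaction("ALATA", {"ala_c": -1, "pyr_c": 1}, -10, 10, "g_alata",
                 "alanine metabolism", IN),
        Reaction("PYRtm", {"pyr_c": -1, "pyr_m": 1}, 0, 1000, "", "transport", TR),
        Reaction("OXPHOS", {"pyr_m": -1, "o2_m": -3, "co2_m": 3, "atp_m": 15},
                 0, 10, "(g_ox1 and g_ox2) or g_ox3",
                 "oxidative phosphorylation", IN),
        Reaction("BIOMASS", {"glc_c": -0.2, "ala_c": -0.1, "atp_c": -2}, 0, 1000,
                 "", "biomass", ReactionKind.BIOMASS),
        Reaction("ATPM", {"atp_m": -1}, 0, 1000, "", "energy demand",
                 ReactionKind.OBJECTIVE_DEMAND),
    ]
    model = MetabolicModel(
        id="mini",
        metabolites=metabolites,
        reactions=reactions,
        compartments=comps,
        biomass_id="BIOMASS",
        objective_id="ATPM",
    )
    model.validate()
    layout = TemplateLayout(
        pathway_genes={
            "glycolysis": frozenset({"g_glyc1", "g_glyc2"}),
            "alanine metabolism": frozenset({"g_alata"}),
            "oxidative phosphorylation": frozenset({"g_ox1", "g_ox2", "g_ox3"}),
        },
        pathway_chain={
            "glycolysis": ["GLYC"],
            "alanine metabolism": ["ALATA"],
            "oxidative phosphorylation": ["OXPHOS"],
        },
        pathway_coupled={
            "glycolysis": ["GLCt", "EX_glc"],
            "alanine metabolism": ["ALAt", "EX_ala"],
            "oxidative phosphorylation": ["PYRtm", "O2tm", "CO2tm", "EX_o2", "EX_co2"],
        },
        pathway_exchanges={
            "glycolysis": ("EX_glc", "EX_pyr"),
            "alanine metabolism": ("EX_ala", "EX_pyr"),
            "oxidative phosphorylation": ("EX_o2", "EX_co2"),
        },
        backbone_genes=frozenset(
            {"g_glct", "g_alat1", "g_alat2", "g_pyrt", "g_glyc1", "g_glyc2",
             "g_ox1", "g_ox2", "g_ox3"}
        ),
        declared_sizes={"reactions": 16, "metabolites": 13, "genes": 10},
    )
    return model, layout


def _core_template() -> tuple[MetabolicModel, TemplateLayout]:
    comps = {
        "c": "cytosol", "m": "mitochondria", "g": "golgi", "l": "lysosome",
        "r": "endoplasmic reticulum", EXTRACELLULAR: "extracellular",
    }
    EX, TR, IN = ReactionKind.EXCHANGE, ReactionKind.TRANSPORT, ReactionKind.INTERNAL
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []

    def add_met(mid: str, comp: str) -> str:
        metabolites.append(Metabolite(id=mid, compartment=comp))
        return mid

    # --- backbone: glucose -> pyruvate -> mitochondrial ATP; biomass drain
    for mid, comp in [
        ("glc_s", EXTRACELLULAR), ("glc_c", "c"), ("pyr_c", "c"), ("pyr_m", "m"),
        ("o2_s", EXTRACELLULAR), ("o2_m", "m"), ("co2_s", EXTRACELLULAR),
        ("co2_m", "m"), ("atp_c", "c"), ("atp_m", "m"), ("h_c", "c"),
    ]:
        add_met(mid, comp)
    reactions += [
        Reaction("EX_glc", {"glc_s": -1}, -10, 1000, "", "exchange", EX),
        Reaction("EX_o2", {"o2_s": -1}, -10, 1000, "", "exchange", EX),
        Reaction("EX_co2", {"co2_s": -1}, 0, 1000, "", "exchange", EX),
        Reaction("GLCt", {"glc_s": -1, "glc_c": 1}, 0, 1000, "", "transport", TR),
        Reaction("O2tm", {"o2_s": -1, "o2_m": 1}, 0, 1000, "", "transport", TR),
        Reaction("CO2tm", {"co2_m": -1, "co2_s": 1}, 0, 1000, "", "transport", TR),
        Reaction("GLYC", {"glc_c": -1, "pyr_c": 2, "atp_c": 2, "h_c": 2}, 0, 20,
                 "g_glyc1 and g_glyc2", "glycolysis", IN),
        Reaction("PYRtm", {"pyr_c": -1, "pyr_m": 1}, 0, 1000, "", "transport", TR),
        # the OR-sum of three highly expressed subunits keeps this the
        # per-sample maximum activity, so the E-Flux denominator never
        # couples to pathway genes
        Reaction("OXPHOS", {"pyr_m": -1, "o2_m": -3, "co2_m": 3, "atp_m": 15},
                 0, 20, "g_ox1 or g_ox2 or g_ox3", "oxidative phosphorylation", IN),
        Reaction("HSINK", {"h_c": -1}, 0, 1000, "", "ion balance", IN),
        Reaction("ATPM", {"atp_m": -1}, 0, 1000, "", "energy demand",
                 ReactionKind.OBJECTIVE_DEMAND),
    ]
    backbone_genes = frozenset({"g_glyc1", "g_glyc2", "g_ox1", "g_ox2", "g_ox3"})

    pathway_genes: dict[str, frozenset[str]] = {}
    pathway_chain: dict[str, list[str]] = {}
    pathway_coupled: dict[str, list[str]] = {}
    pathway_exchanges: dict[str, tuple[str, str]] = {}
    pathway_out_gene: dict[str, str] = {}

    for name, slug, home in CORE_PATHWAYS:
        sub_s = add_met(f"{slug}sub_{EXTRACELLULAR}", EXTRACELLULAR)
        prod_s = add_met(f"{slug}prod_{EXTRACELLULAR}", EXTRACELLULAR)
        chain_mets = [add_met(f"{slug}{i}_{home}", home)
                      for i in range(CORE_CHAIN_STEPS + 1)]
        ex_sub, ex_prod = f"EX_{slug}sub", f"EX_{slug}prod"
        t_in, t_out = f"{slug.upper()}tin", f"{slug.upper()}tout"
        spill = f"{slug.upper()}spill"
        out_gene = f"g_{slug}out"
        # the exporter carries its own gene and the end product has a free
        # overflow sink, so the product exchange flux is governed by the
        # exporter's expression alone — a clean single-feature marker site
        reactions += [
            Reaction(ex_sub, {sub_s: -1}, -10, 1000, "", "exchange", EX),
            Reaction(ex_prod, {prod_s: -1}, 0, 1000, "", "exchange", EX),
            Reaction(t_in, {sub_s: -1, chain_mets[0]: 1}, 0, 1000, "",
                     "transport", TR),
            Reaction(t_out, {chain_mets[-1]: -1, prod_s: 1}, 0, 10, out_gene,
                     "transport", TR),
            Reaction(spill, {chain_mets[-1]: -1}, 0, 1000, "", "overflow", IN),
        ]
        genes: set[str] = set()
        chain_ids = []
        # two parallel isoform reactions per conversion step: each
        # intermediate then touches four pathway reactions, which gives
        # metabolite-level enrichment adequate power at toy scale
        for i in range(CORE_CHAIN_STEPS):
            for iso in ("a", "b"):
                rid = f"{slug.upper()}{i + 1}{iso}"
                if i == 0 and iso == "a":
                    rule = f"g_{slug}1a1 and g_{slug}1a2"
                    genes |= {f"g_{slug}1a1", f"g_{slug}1a2"}
                else:
                    gene = f"g_{slug}{i + 1}{iso}"
                    rule = gene
                    genes.add(gene)
                stoich = {chain_mets[i]: -1.0, chain_mets[i + 1]: 1.0}
                if i == 1 and iso == "a" and home == "c":
                    stoich["h_c"] = 1.0  # currency by-product, dropped in the network
                reactions.append(Reaction(rid, stoich, 0, 10, rule, name, IN))
                chain_ids.append(rid)
        genes.add(out_gene)
        pathway_genes[name] = frozenset(genes)
        pathway_chain[name] = chain_ids
        pathway_coupled[name] = [t_in, t_out, spill, ex_sub, ex_prod]
        pathway_exchanges[name] = (ex_sub, ex_prod)
        pathway_out_gene[name] = out_gene

    # biomass drains glucose, ATP and a mid-chain amino acid intermediate
    reactions.append(
        Reaction("BIOMASS", {"glc_c": -0.2, "aam2_c": -0.1, "atp_c": -2.0},
                 0, 1000, "", "biomass", ReactionKind.BIOMASS)
    )
    model = MetabolicModel(
        id="core",
        metabolites=metabolites,
        reactions=reactions,
        compartments=comps,
        biomass_id="BIOMASS",
        objective_id="ATPM",
    )
    model.validate()
    layout = TemplateLayout(
        pathway_genes=pathway_genes,
        pathway_chain=pathway_chain,
        pathway_coupled=pathway_coupled,
        pathway_exchanges=pathway_exchanges,
        backbone_genes=backbone_genes,
        declared_sizes={
            "reactions": len(reactions),
            "metabolites": len(metabolites),
            "genes": len(model.genes),
        },
        pathway_out_gene=pathway_out_gene,
    )
    return model, layout


def template_layout(template: str) -> TemplateLayout:
    if template == "mini":
        return _mini_template()[1]
    if template == "core":
        return _core_template()[1]
    raise ValueError(f"unknown template {template!r}")


def make_model(spec: SyntheticSpec) -> MetabolicModel:
    """Materialize the template model (deterministic; seed-independent)."""
    if spec.template == "mini":
        return _mini_template()[0]
    return _core_template()[0]


def default_media(model: MetabolicModel, default_uptake: float = 10.0) -> MediaSpec:
    """Media from the template's nutrient exchanges (those with uptake open)."""
    uptake = {
        model.metabolite(next(iter(ex.stoichiometry))).base_id
        for ex in model.exchanges()
        if ex.lower_bound < 0
    }
    return MediaSpec(uptake=frozenset(uptake), default_uptake=default_uptake)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _gene_table(
    model: MetabolicModel, spec: SyntheticSpec, layout: TemplateLayout,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-gene baseline mean, dispersion and length (deterministic per seed)."""
    model_genes = sorted(model.genes)
    filler = [f"gene_fill_{i:03d}" for i in range(spec.n_filler_genes)]
    low = [f"gene_low_{i:02d}" for i in range(spec.n_low_genes)]
    genes = model_genes + filler + low
    lo, hi = spec.mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))
    table = pd.DataFrame({"mean": means}, index=pd.Index(genes, name="gene"))
    # backbone enzymes are highly expressed so the per-sample E-Flux
    # normalization denominator stays stable
    table.loc[list(layout.backbone_genes), "mean"] = rng.uniform(
        0.9 * hi, hi, size=len(layout.backbone_genes)
    )
    table.loc[low, "mean"] = 0.5  # planted below the count filter
    table["dispersion"] = spec.nb_dispersion
    table["length"] = rng.integers(
        spec.length_range[0], spec.length_range[1] + 1, size=len(genes)
    )
    return table


def _ground_truth(spec: SyntheticSpec, layout: TemplateLayout) -> GroundTruth:
    for pathway in spec.perturbed_pathways:
        if pathway not in layout.pathway_genes:
            raise ValueError(f"perturbed pathway {pathway!r} not in the model")
    genes: set[str] = set()
    chain: set[str] = set()
    coupled: set[str] = set()
    for pathway in spec.perturbed_pathways:
        genes |= layout.pathway_genes[pathway]
        chain |= set(layout.pathway_chain[pathway])
        coupled |= set(layout.pathway_coupled[pathway])
    if spec.separating_exchange is not None:
        sep_pathway = _separating_pathway(spec, layout)
        out_gene = layout.pathway_out_gene.get(sep_pathway)
        if out_gene is not None:
            genes.add(out_gene)
        _, ex_prod = layout.pathway_exchanges[sep_pathway]
        coupled |= {ex_prod}
    return GroundTruth(
        perturbed_pathways=spec.perturbed_pathways,
        perturbed_genes=frozenset(genes),
        perturbed_reactions=frozenset(chain),
        coupled_reactions=frozenset(coupled),
        separating_exchange=spec.separating_exchange,
        effect_size=spec.effect_size,
    )


def _separating_pathway(spec: SyntheticSpec, layout: TemplateLayout) -> str:
    for pathway, (ex_sub, ex_prod) in layout.pathway_exchanges.items():
        if spec.separating_exchange in (ex_sub, ex_prod):
            return pathway
    raise ValueError(
        f"separating_exchange {spec.separating_exchange!r} is not a pathway "
        "exchange of this template"
    )


def _sample_counts(
    rng: np.random.Generator,
    gene_table: pd.DataFrame,
    samples: list[str],
    mean_factor: pd.Series,
) -> pd.DataFrame:
    mu = (gene_table["mean"] * mean_factor).to_numpy()
    disp = gene_table["dispersion"].to_numpy()
    r = np.where(disp > 0, 1.0 / np.maximum(disp, 1e-12), np.inf)
    data = {}
    for sample in samples:
        counts = np.zeros(len(mu), dtype=int)
        pos = mu > 0
        nb = pos & np.isfinite(r)
        counts[nb] = rng.negative_binomial(r[nb], r[nb] / (r[nb] + mu[nb]))
        po = pos & ~np.isfinite(r)
        counts[po] = rng.poisson(mu[po])
        data[sample] = counts
    return pd.DataFrame(data, index=gene_table.index)


def _cohort(
    model: MetabolicModel,
    spec: SyntheticSpec,
    layout: TemplateLayout,
    rng: np.random.Generator,
    n_healthy: int,
    n_disease: int,
    prefix: str = "",
) -> ExpressionMatrix:
    gene_table = _gene_table(model, spec, layout, rng)
    genes = gene_table.index

    disease_mean = pd.Series(1.0, index=genes)
    for pathway in spec.perturbed_pathways:
        if pathway not in layout.pathway_genes:
            raise ValueError(f"perturbed pathway {pathway!r} not in the model")
        for gene in layout.pathway_genes[pathway]:
            disease_mean[gene] = spec.effect_size
    if spec.separating_exchange is not None:
        sep_pathway = _separating_pathway(spec, layout)
        if sep_pathway not in layout.pathway_out_gene:
            raise ValueError(
                f"template has no exporter gene for pathway {sep_pathway!r}"
            )
        sep_gene = layout.pathway_out_gene[sep_pathway]
        # clean marker signal: strong knockdown, low noise in both groups
        disease_mean[sep_gene] = spec.separating_effect
        gene_table.loc[sep_gene, "dispersion"] = spec.nb_dispersion / 20

    ones = pd.Series(1.0, index=genes)
    healthy_samples = [f"{prefix}H{i + 1:03d}" for i in range(n_healthy)]
    disease_samples = [f"{prefix}D{i + 1:03d}" for i in range(n_disease)]
    counts_h = _sample_counts(rng, gene_table, healthy_samples, ones)
    counts_d = _sample_counts(rng, gene_table, disease_samples, disease_mean)
    counts = pd.concat([counts_h, counts_d], axis=1)
    groups = pd.Series(
        ["healthy"] * n_healthy + ["disease"] * n_disease,
        index=healthy_samples + disease_samples,
    )
    return ExpressionMatrix(
        values=counts,
        gene_lengths=gene_table["length"].astype(float),
        sample_groups=groups,
        stage="raw",
    )


def make_cohort(
    model: MetabolicModel, spec: SyntheticSpec
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Raw two-group count cohort plus its ground-truth record."""
    layout = template_layout(spec.template)
    rng = np.random.default_rng(spec.seed)
    expr = _cohort(
        model, spec, layout, rng, spec.n_healthy, spec.n_disease
    )
    return expr, _ground_truth(spec, layout)


def make_external_cohort(
    model: MetabolicModel,
    spec: SyntheticSpec,
    shift_labels: float = 0.0,
) -> tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """A fresh cohort from the same generative process, for validation.

    ``shift_labels`` relabels that fraction of disease-generated samples
    as healthy and tags them subgroup "confounder" (samples whose biology
    is disease-like but whose label says healthy), reproducing a
    confounded validation set.  Returns (cohort, subgroups, truth).
    """
    if not (0 <= shift_labels <= 1):
        raise ValueError("shift_labels must lie in [0, 1]")
    layout = template_layout(spec.template)
    rng = np.random.default_rng(spec.seed + 10007)
    expr = _cohort(
        model, spec, layout, rng, spec.n_healthy, spec.n_disease, prefix="V"
    )
    subgroups = pd.Series("core", index=expr.samples)
    disease_samples = expr.group_samples("disease")
    n_shift = int(round(shift_labels * len(disease_samples)))
    shifted = list(rng.choice(disease_samples, size=n_shift, replace=False))
    groups = expr.sample_groups.copy()
    groups[shifted] = "healthy"
    subgroups[shifted] = "confounder"
    expr = ExpressionMatrix(
        values=expr.values,
        gene_lengths=expr.gene_lengths,
        sample_groups=groups,
        stage="raw",
    )
    return expr, subgroups, _ground_truth(spec, layout)
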
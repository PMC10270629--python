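"""Flux-based metabolite marker discovery.

Candidate markers are exchange reactions whose attainable flux range in
the disease group-average model is shifted against the healthy one
(interval-Jaccard rule).  Each candidate contributes two features — its
per-individual FVA minimum and maximum flux — to an SVM classifier
(polynomial kernel, degree 2) evaluated by stratified 10-fold
cross-validation.  A binary genetic algorithm wraps the SVM to search
feature subsets; repeating the GA and ranking features by selection
frequency yields the marker panel, which can then be validated on an
external cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "disease"  # the positive class for sensitivity/specificity


# ---------------------------------------------------------------------------
# shifted exchange detection
# ---------------------------------------------------------------------------

def interval_jaccard(
    a: tuple[float, float], b: tuple[float, float], abs_tol: float = 1e-6
) -> float:
    """Overlap/union similarity of two closed intervals in [0, 1].

    Point intervals (width below ``abs_tol``) are compared by endpoint
    distance: identical points give 1, separated points 0.
    """
    lo_a, hi_a = a
    lo_b, hi_b = b
    union = max(hi_a, hi_b) - min(lo_a, lo_b)
    if union <= abs_tol:
        return 1.0 if abs(lo_a - lo_b) <= abs_tol and abs(hi_a - hi_b) <= abs_tol else 0.0
    inter = max(0.0, min(hi_a, hi_b) - max(lo_a, lo_b))
    return inter / union


def detect_shifted_exchanges(
    h_ranges: pd.DataFrame,
    d_ranges: pd.DataFrame,
    exchange_ids: Iterable[str],
    delta: float = 0.1,
    abs_tol: float = 1e-6,
) -> list[str]:
    """Exchange reactions whose disease flux range is shifted.

    ``h_ranges``/``d_ranges`` are FVA tables (columns minimum/maximum)
    from the healthy and disease group-average models under identical
    settings.  An exchange is a candidate iff the interval Jaccard
    similarity of its two ranges is < 1 − delta.  Non-exchange reactions
    are never candidates.
    """
    if set(h_ranges.index) != set(d_ranges.index):
        raise ValueError("healthy and disease FVA tables cover different reactions")
    out = []
    for rxn in exchange_ids:
        if rxn not in h_ranges.index:
            raise ValueError(f"exchange {rxn!r} missing from the FVA tables")
        h = (h_ranges.loc[rxn, "minimum"], h_ranges.loc[rxn, "maximum"])
        d = (d_ranges.loc[rxn, "minimum"], d_ranges.loc[rxn, "maximum"])
        if interval_jaccard(h, d, abs_tol) < 1.0 - delta:
            out.append(rxn)
    return out


# ---------------------------------------------------------------------------
# classifier metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with disease as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("confusion matrix is empty")


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """accuracy, sensitivity and specificity; undefined ratios are NaN."""
    total = cm.tp + cm.tn + cm.fp + cm.fn
    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")
    return {
        "accuracy": (cm.tp + cm.tn) / total,
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
    }


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def feature_name(reaction_id: str, which: str) -> str:
    return f"{reaction_id}|{which}"


def feature_reaction(name: str) -> str:
    return name.rsplit("|", 1)[0]


@dataclass
class FeatureTable:
    """Sample × feature matrix with class labels.

    Features are named ``<exchange reaction>|min`` / ``|max``; rows are
    the feasible individuals.  ``subgroups`` optionally tags samples
    (e.g. a confounder subgroup) for label-filtered validation.
    """

    X: pd.DataFrame
    labels: pd.Series
    subgroups: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.X.index)
        if self.labels.isna().any():
            raise ValueError("every sample needs a class label")
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if self.subgroups is not None:
            self.subgroups = self.subgroups.reindex(self.X.index)

    @property
    def features(self) -> list[str]:
        return list(self.X.columns)

    def exclude_subgroup(self, subgroup: str) -> "FeatureTable":
        if self.subgroups is None:
            raise ValueError("feature table carries no subgroup annotation")
        keep = self.X.index[self.subgroups != subgroup]
        return FeatureTable(
            X=self.X.loc[keep].copy(),
            labels=self.labels.loc[keep].copy(),
            subgroups=self.subgroups.loc[keep].copy(),
        )


def build_feature_table(
    flux_set,
    candidate_reactions: Sequence[str],
    groups: pd.Series,
    subgroups: Optional[pd.Series] = None,
) -> FeatureTable:
    """Assemble min/max flux features for the candidates from cohort FVA.

    Samples excluded from the FVA run (infeasible) are dropped; every
    candidate contributes exactly two features.
    """
    mins = flux_set.matrix("minimum")
    maxs = flux_set.matrix("maximum")
    cols = {}
    for rxn in candidate_reactions:
        if rxn not in mins.columns:
            raise ValueError(f"candidate reaction {rxn!r} absent from FVA results")
        cols[feature_name(rxn, "min")] = mins[rxn]
        cols[feature_name(rxn, "max")] = maxs[rxn]
    X = pd.DataFrame(cols)
    return FeatureTable(X=X, labels=groups.reindex(X.index), subgroups=subgroups)


# ---------------------------------------------------------------------------
# SVM evaluation
# ---------------------------------------------------------------------------

@dataclass
class SvmEvaluation:
    mean: dict[str, float]
    per_repeat: pd.DataFrame  # columns accuracy, sensitivity, specificity


def _pooled_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    pos = y_true == POSITIVE_LABEL
    pred_pos = y_pred == POSITIVE_LABEL
    return ConfusionMatrix(
        tp=int(np.sum(pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def evaluate_svm(
    table: FeatureTable,
    feature_subset: Optional[Sequence[str]] = None,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    C: float = 1.0,
    coef0: float = 1.0,
) -> SvmEvaluation:
    """Stratified k-fold CV of a degree-2 polynomial SVM.

    Standardization is fit on the training folds only (leak-free); test
    predictions of one repeat are pooled into a single confusion matrix.
    Identical seeds give identical fold assignments and metrics.
    """
    features = list(feature_subset) if feature_subset is not None else table.features
    if not features:
        raise ValueError("empty feature subset")
    missing = [f for f in features if f not in table.X.columns]
    if missing:
        raise ValueError(f"features absent from the table: {missing}")
    y = table.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X = table.X[features].to_numpy(dtype=float)

    records = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        y_pred = np.empty_like(y)
        for train, test in skf.split(X, y):
            clf = make_pipeline(
                StandardScaler(),
                SVC(kernel="poly", degree=2, C=C, coef0=coef0),
            )
            clf.fit(X[train], y[train])
            y_pred[test] = clf.predict(X[test])
        records.append(metrics(_pooled_confusion(y, y_pred)))
    per_repeat = pd.DataFrame(records)
    return SvmEvaluation(mean=per_repeat.mean().to_dict(), per_repeat=per_repeat)


# ---------------------------------------------------------------------------
# genetic algorithm wrapper
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaConfig:
    """Binary GA settings; defaults follow the study design.

    population 300 chromosomes, at most 100 generations, early stop once
    the best fitness (CV accuracy of the SVM on the encoded subset)
    reaches 0.90.  ``mutation_rate=None`` means 1/chromosome-length.
    """

    population: int = 300
    generations: int = 100
    fitness_stop: float = 0.90
    crossover_rate: float = 0.8
    mutation_rate: Optional[float] = None
    tournament_size: int = 2
    elitism: int = 1
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ValueError("population must be positive")
        for name in ("crossover_rate", "fitness_stop"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_rate is not None and not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate must lie in [0, 1]")


@dataclass
class GaResult:
    chromosome: np.ndarray  # boolean mask over table features
    selected_features: list[str]
    fitness: float
    trace: list[float]  # best fitness per generation
    generations_run: int


def ga_select(table: FeatureTable, config: GaConfig) -> GaResult:
    """Evolve a feature subset maximizing SVM cross-validation accuracy.

    Tournament selection, uniform crossover, per-bit flip mutation,
    elitism.  The all-zero chromosome gets fitness 0 without touching the
    SVM.  Terminates at ``fitness_stop`` or the generation cap.
    """
    features = table.features
    L = len(features)
    if L < 2:
        raise ValueError("need at least 2 features to select from")
    rng = np.random.default_rng(config.seed)
    mut_rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / L

    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = chrom.tobytes()
        if key not in cache:
            if not chrom.any():
                cache[key] = 0.0
            else:
                subset = [f for f, bit in zip(features, chrom) if bit]
                ev = evaluate_svm(
                    table, subset, folds=config.cv_folds, repeats=1,
                    seed=config.seed,
                )
                cache[key] = ev.mean["accuracy"]
        return cache[key]

    pop = rng.integers(0, 2, size=(config.population, L)).astype(bool)
    trace: list[float] = []
    best_chrom, best_fit = pop[0].copy(), -1.0
    gen = 0
    for gen in range(1, config.generations + 1):
        fits = np.array([fitness(c) for c in pop])
        idx = int(np.argmax(fits))
        if fits[idx] > best_fit:
            best_fit, best_chrom = float(fits[idx]), pop[idx].copy()
        trace.append(best_fit)
        if best_fit >= config.fitness_stop:
            break
        if gen == config.generations:
            break
        # elitism
        elite_idx = np.argsort(fits)[::-1][: config.elitism]
        next_pop = [pop[i].copy() for i in elite_idx]
        while len(next_pop) < config.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population, size=config.tournament_size)
                winner = contenders[int(np.argmax(fits[contenders]))]
                parents.append(pop[winner].copy())
            a, b = parents
            if rng.random() < config.crossover_rate:
                mask = rng.random(L) < 0.5
                a[mask], b[mask] = b[mask].copy(), a[mask].copy()
            for child in (a, b):
                flip = rng.random(L) < mut_rate
                child[flip] = ~child[flip]
                if len(next_pop) < config.population:
                    next_pop.append(child)
        pop = np.array(next_pop)
    selected = [f for f, bit in zip(features, best_chrom) if bit]
    return GaResult(
        chromosome=best_chrom,
        selected_features=selected,
        fitness=best_fit,
        trace=trace,
        generations_run=gen,
    )


# ---------------------------------------------------------------------------
# frequency ranking and validation
# ---------------------------------------------------------------------------

@dataclass
class MarkerPanel:
    """GA selection frequencies and the resulting top-ranked reactions."""

    candidates: list[str]
    feature_frequencies: pd.Series  # % of GA repeats containing the feature
    reaction_frequencies: pd.Series  # max over the reaction's two features
    top_ranked: list[str]
    n_repeats: int
    frequency_threshold: float = 80.0

    def panel_features(self) -> list[str]:
        return [
            feature_name(r, which)
            for r in self.top_ranked
            for which in ("min", "max")
        ]


def rank_features(
    subsets: Sequence[Iterable[str]],
    candidates: Sequence[str],
    frequency_threshold: float = 80.0,
) -> MarkerPanel:
    """Frequency-rank features across GA repeats.

    frequency(feature) = 100 · (# subsets containing it) / (# subsets);
    a reaction scores the max of its min/max features, and reactions at
    or above the threshold form the top-ranked panel.
    """
    if not subsets:
        raise ValueError("need at least one GA subset")
    n = len(subsets)
    all_features = [
        feature_name(r, which) for r in candidates for which in ("min", "max")
    ]
    counts = {f: 0 for f in all_features}
    for subset in subsets:
        for f in set(subset):
            if f in counts:
                counts[f] += 1
    feat_freq = pd.Series(
        {f: 100.0 * c / n for f, c in counts.items()}, name="frequency"
    )
    rxn_freq = pd.Series(
        {
            r: max(
                feat_freq[feature_name(r, "min")], feat_freq[feature_name(r, "max")]
            )
            for r in candidates
        },
        name="frequency",
    )
    top = [r for r in candidates if rxn_freq[r] >= frequency_threshold]
    return MarkerPanel(
        candidates=list(candidates),
        feature_frequencies=feat_freq,
        reaction_frequencies=rxn_freq,
        top_ranked=top,
        n_repeats=n,
        frequency_threshold=frequency_threshold,
    )


def select_markers(
    table: FeatureTable,
    candidates: Sequence[str],
    config: GaConfig,
    n_repeats: int = 100,
    frequency_threshold: float = 80.0,
) -> tuple[MarkerPanel, list[GaResult]]:
    """Repeat the GA and rank features by selection frequency."""
    results = []
    for i in range(n_repeats):
        cfg = GaConfig(
            population=config.population,
            generations=config.generations,
            fitness_stop=config.fitness_stop,
            crossover_rate=config.crossover_rate,
            mutation_rate=config.mutation_rate,
            tournament_size=config.tournament_size,
            elitism=config.elitism,
            cv_folds=config.cv_folds,
            seed=config.seed + i,
        )
        results.append(ga_select(table, cfg))
    panel = rank_features(
        [r.selected_features for r in results], candidates, frequency_threshold
    )
    return panel, results


def validate_panel(
    panel: MarkerPanel,
    external_table: FeatureTable,
    exclude_subgroup: Optional[str] = None,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> SvmEvaluation:
    """Evaluate the top-ranked panel on an external cohort.

    Optionally drops a tagged subgroup first (e.g. confounded
    normoglycemic samples).  Raises if any panel feature is missing from
    the external table.
    """
    features = panel.panel_features()
    missing = [f for f in features if f not in external_table.X.columns]
    if missing:
        raise ValueError(f"panel features missing from external table: {missing}")
    table = external_table
    if exclude_subgroup is not None:
        table = table.exclude_subgroup(exclude_subgroup)
    return evaluate_svm(table, features, folds=folds, repeats=repeats, seed=seed)
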
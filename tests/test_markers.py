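import numpy as np
import pandas as pd
import pytest

from fluxcohort.markers import (
    ConfusionMatrix,
    FeatureTable,
    GaConfig,
    build_feature_table,
    detect_shifted_exchanges,
    evaluate_svm,
    feature_name,
    ga_select,
    interval_jaccard,
    metrics,
    rank_features,
    validate_panel,
)


class TestShiftDetection:
    def ranges(self, mapping):
        return pd.DataFrame(
            {"minimum": {k: v[0] for k, v in mapping.items()},
             "maximum": {k: v[1] for k, v in mapping.items()}}
        )

    def test_identical_ranges_not_shifted(self):
        h = self.ranges({"EX_a": (-10, 0)})
        assert detect_shifted_exchanges(h, h.copy(), ["EX_a"]) == []

    def test_half_overlap_is_shifted(self):
        # J = 5/10 = 0.5 < 0.9
        h = self.ranges({"EX_a": (-10, 0)})
        d = self.ranges({"EX_a": (-5, 0)})
        assert detect_shifted_exchanges(h, d, ["EX_a"]) == ["EX_a"]
        assert interval_jaccard((-10, 0), (-5, 0)) == pytest.approx(0.5)

    def test_non_exchange_reaction_never_candidate(self):
        h = self.ranges({"EX_a": (-10, 0), "R1": (0, 10)})
        d = self.ranges({"EX_a": (-10, 0), "R1": (5, 10)})
        assert detect_shifted_exchanges(h, d, ["EX_a"]) == []

    def test_point_intervals_compared_by_endpoint(self):
        assert interval_jaccard((3.0, 3.0), (3.0, 3.0)) == 1.0
        assert interval_jaccard((3.0, 3.0), (4.0, 4.0)) == 0.0

    def test_mismatched_reaction_sets_rejected(self):
        h = self.ranges({"EX_a": (-10, 0)})
        d = self.ranges({"EX_b": (-10, 0)})
        with pytest.raises(ValueError):
            detect_shifted_exchanges(h, d, ["EX_a"])


class TestMetrics:
    def test_worked_example(self):
        out = metrics(ConfusionMatrix(tp=3, tn=4, fp=1, fn=2))
        assert out == {
            "accuracy": pytest.approx(0.7),
            "sensitivity": pytest.approx(0.6),
            "specificity": pytest.approx(0.8),
        }

    def test_perfect_classifier(self):
        out = metrics(ConfusionMatrix(tp=5, tn=5, fp=0, fn=0))
        assert all(v == 1.0 for v in out.values())

    def test_empty_positive_class_gives_nan_sensitivity(self):
        out = metrics(ConfusionMatrix(tp=0, tn=5, fp=2, fn=0))
        assert np.isnan(out["sensitivity"])
        assert out["specificity"] == pytest.approx(5 / 7)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, tn=1, fp=1, fn=1)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=0, tn=0, fp=0, fn=0)

    def test_matches_direct_arithmetic_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 30, size=4))
            if tp + tn + fp + fn == 0:
                continue
            out = metrics(ConfusionMatrix(tp, tn, fp, fn))
            assert out["accuracy"] == pytest.approx((tp + tn) / (tp + tn + fp + fn))
            if tp + fn:
                assert out["sensitivity"] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert out["specificity"] == pytest.approx(tn / (tn + fp))


def noisy_table(n_per_group=20, n_features=10, separating=True, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"h{i}" for i in range(n_per_group)] + [
        f"d{i}" for i in range(n_per_group)
    ]
    labels = pd.Series(
        ["healthy"] * n_per_group + ["disease"] * n_per_group, index=samples
    )
    X = pd.DataFrame(
        rng.normal(size=(2 * n_per_group, n_features)),
        index=samples,
        columns=[feature_name(f"EX_n{i}", "max") for i in range(n_features)],
    )
    if separating:
        X["EX_sep|max"] = np.r_[
            rng.normal(5, 0.2, n_per_group), rng.normal(1, 0.2, n_per_group)
        ]
    return FeatureTable(X=X, labels=labels)


class TestEvaluateSvm:
    def test_perfectly_separating_feature_scores_one(self):
        table = noisy_table()
        ev = evaluate_svm(table, ["EX_sep|max"], repeats=3, seed=1)
        assert ev.mean["accuracy"] == 1.0
        assert (ev.per_repeat["accuracy"] == 1.0).all()

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(4)
        table = noisy_table(separating=False)
        shuffled = table.labels.sample(frac=1.0, random_state=9)
        shuffled.index = table.labels.index
        table = FeatureTable(X=table.X, labels=shuffled)
        ev = evaluate_svm(table, repeats=20, seed=5)
        assert 0.4 <= ev.mean["accuracy"] <= 0.6

    def test_reproducible_under_same_seed(self):
        table = noisy_table()
        a = evaluate_svm(table, repeats=2, seed=3)
        b = evaluate_svm(table, repeats=2, seed=3)
        pd.testing.assert_frame_equal(a.per_repeat, b.per_repeat)

    def test_single_class_rejected(self):
        table = noisy_table()
        labels = pd.Series("healthy", index=table.X.index)
        with pytest.raises(ValueError, match="single class"):
            evaluate_svm(FeatureTable(X=table.X, labels=labels))

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_svm(noisy_table(), [])

    def test_missing_feature_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            evaluate_svm(noisy_table(), ["EX_ghost|max"])


class TestGa:
    config = GaConfig(population=40, generations=8, cv_folds=5, seed=0)

    def test_recovers_planted_feature_and_stops_early(self):
        hits = 0
        for seed in range(5):
            table = noisy_table(n_per_group=15, n_features=19, seed=seed)
            cfg = GaConfig(population=40, generations=8, cv_folds=5, seed=seed)
            res = ga_select(table, cfg)
            assert res.fitness >= cfg.fitness_stop
            assert res.generations_run < cfg.generations
            hits += "EX_sep|max" in res.selected_features
        assert hits >= 4

    def test_all_noise_runs_to_generation_cap(self):
        table = noisy_table(n_per_group=10, n_features=8, separating=False, seed=3)
        cfg = GaConfig(population=20, generations=4, cv_folds=5, seed=1)
        res = ga_select(table, cfg)
        assert res.generations_run == cfg.generations
        assert max(res.trace) < cfg.fitness_stop

    def test_degenerate_hill_has_constant_trace(self):
        # population of one with no variation operators cannot improve
        table = noisy_table(n_per_group=10, n_features=5, separating=False, seed=2)
        cfg = GaConfig(
            population=1, generations=5, crossover_rate=0.0, mutation_rate=0.0,
            elitism=1, cv_folds=5, seed=2,
        )
        res = ga_select(table, cfg)
        assert len(set(res.trace)) == 1

    def test_fitness_stop_above_one_rejected(self):
        with pytest.raises(ValueError):
            GaConfig(fitness_stop=1.01)

    def test_trace_is_monotone_best_so_far(self):
        table = noisy_table(n_per_group=10, n_features=8, separating=False, seed=5)
        res = ga_select(table, GaConfig(population=15, generations=4, cv_folds=5, seed=4))
        assert (np.diff(res.trace) >= 0).all()

    def test_needs_two_features(self):
        table = noisy_table(n_per_group=5, n_features=1, separating=False)
        with pytest.raises(ValueError):
            ga_select(table, self.config)


class TestRanking:
    def test_frequency_counting_and_threshold(self):
        candidates = ["EX_a", "EX_b"]
        subsets = [["EX_a|max"]] * 85 + [["EX_b|min"]] * 15
        panel = rank_features(subsets, candidates)
        assert panel.feature_frequencies["EX_a|max"] == pytest.approx(85.0)
        assert panel.reaction_frequencies["EX_a"] == pytest.approx(85.0)
        assert panel.top_ranked == ["EX_a"]

    def test_boundary_below_threshold_excluded(self):
        subsets = [["EX_a|max"]] * 79 + [[]] * 21
        panel = rank_features(subsets, ["EX_a"])
        assert panel.top_ranked == []
        panel80 = rank_features([["EX_a|max"]] * 80 + [[]] * 20, ["EX_a"])
        assert panel80.top_ranked == ["EX_a"]

    def test_reaction_scores_max_of_its_features(self):
        subsets = [["EX_a|min"], ["EX_a|max"], ["EX_a|max"], []]
        panel = rank_features(subsets, ["EX_a"], frequency_threshold=50.0)
        assert panel.reaction_frequencies["EX_a"] == pytest.approx(50.0)

    def test_adding_a_subset_never_decreases_counts(self):
        subsets = [["EX_a|max"], ["EX_a|max", "EX_b|min"]]
        before = rank_features(subsets, ["EX_a", "EX_b"])
        after = rank_features(subsets + [["EX_a|max"]], ["EX_a", "EX_b"])
        raw_before = before.feature_frequencies * len(subsets) / 100
        raw_after = after.feature_frequencies * (len(subsets) + 1) / 100
        assert (raw_after >= raw_before - 1e-9).all()

    def test_needs_at_least_one_subset(self):
        with pytest.raises(ValueError):
            rank_features([], ["EX_a"])


class TestValidatePanel:
    def panel(self):
        return rank_features([["EX_sep|max", "EX_sep|min"]] * 10, ["EX_sep"])

    def test_validates_on_external_cohort(self):
        table = noisy_table(seed=8)
        table.X["EX_sep|min"] = 0.0
        ev = validate_panel(self.panel(), table, seed=1)
        assert ev.mean["accuracy"] == 1.0

    def test_missing_features_listed(self):
        table = noisy_table(separating=False)
        with pytest.raises(ValueError, match="EX_sep"):
            validate_panel(self.panel(), table)

    def test_subgroup_exclusion(self):
        table = noisy_table(seed=9)
        table.X["EX_sep|min"] = 0.0
        sub = pd.Series("core", index=table.X.index)
        sub.iloc[:5] = "confounder"
        table = FeatureTable(X=table.X, labels=table.labels, subgroups=sub)
        ev = validate_panel(self.panel(), table, exclude_subgroup="confounder", seed=1)
        assert ev.mean["accuracy"] == 1.0
        with pytest.raises(ValueError):
            validate_panel(self.panel(), noisy_table(seed=9), exclude_subgroup="x")


class TestFeatureTable:
    def test_build_from_cohort_fva(self, mini_model):
        from fluxcohort.fva import CohortFluxRanges

        rows = []
        for s in ("h1", "d1"):
            for rxn in ("EX_glc", "EX_ala"):
                rows.append({"sample": s, "reaction": rxn, "minimum": -1.0,
                             "maximum": 2.0, "status": "optimal"})
        fs = CohortFluxRanges(table=pd.DataFrame(rows))
        groups = pd.Series({"h1": "healthy", "d1": "disease"})
        table = build_feature_table(fs, ["EX_glc", "EX_ala"], groups)
        assert list(table.X.columns) == [
            "EX_glc|min", "EX_glc|max", "EX_ala|min", "EX_ala|max"
        ]
        assert table.X.shape == (2, 4)

    def test_unknown_candidate_rejected(self):
        from fluxcohort.fva import CohortFluxRanges

        fs = CohortFluxRanges(
            table=pd.DataFrame(
                [{"sample": "s", "reaction": "EX_a", "minimum": 0.0,
                  "maximum": 1.0, "status": "optimal"}]
            )
        )
        with pytest.raises(ValueError):
            build_feature_table(fs, ["EX_zz"], pd.Series({"s": "healthy"}))
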
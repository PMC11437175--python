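"""Confusion counting, the paper-convention metrics, k-fold consistency,
ground-truth PR sweeps and the species-deletion experiment."""

import numpy as np
import pandas as pd
import pytest

from taxrefine.evaluation import (
    ConfusionCounts,
    benchmark_classifiers,
    confusion_counts,
    ground_truth_report,
    kfold_consistency,
    kfold_split,
    metrics_frame,
    precision_recall_f1,
    species_deletion_experiment,
)
from taxrefine.refiner import PredictionSet, RankPrediction, TaxonomyRefiner
from taxrefine.synthetic import corrupt_annotations
from taxrefine.taxonomy import AnnotationSet, Lineage
from tests.conftest import features_from_community

FAST = dict(hidden_sizes=(256, 256), epochs=40, batch_size=128, random_state=0)


def lineage_set(mapping):
    return AnnotationSet({cid: Lineage(cid, labels) for cid, labels in mapping.items()})


def prediction_set(mapping, score=0.9):
    from taxrefine.taxonomy import RANKS

    return PredictionSet(
        {
            cid: tuple(
                RankPrediction(RANKS[d], path[: d + 1], score)
                for d in range(len(path))
            )
            for cid, path in mapping.items()
        }
    )


class TestConfusion:
    def test_perfect_agreement(self):
        ref = lineage_set({f"c{i}": ("A", "B") for i in range(10)})
        pred = prediction_set({f"c{i}": ("A", "B") for i in range(10)})
        c = confusion_counts(pred, ref, "phylum")
        assert (c.tp, c.fp, c.fn) == (10, 0, 0)

    def test_mixed_counts_by_definition(self):
        ref = lineage_set({f"c{i}": ("A",) for i in range(10)})
        # 9 predicted, 8 of them equal, 1 different, 1 missing
        mapping = {f"c{i}": ("A",) for i in range(8)}
        mapping["c8"] = ("Z",)
        pred = prediction_set(mapping)
        c = confusion_counts(pred, ref, "domain")
        assert (c.tp, c.fp, c.fn) == (8, 1, 1)

    def test_empty_predictions_are_all_fn(self):
        ref = lineage_set({f"c{i}": ("A", "B", "C") for i in range(5)})
        c = confusion_counts(PredictionSet({}), ref, "class")
        assert (c.tp, c.fp, c.fn) == (0, 0, 5)

    def test_restricted_to_contigs_with_a_reference_label_at_rank(self):
        ref = lineage_set({"c1": ("A",), "c2": ("A", "B")})
        pred = prediction_set({"c1": ("A", "X"), "c2": ("A", "B")})
        c = confusion_counts(pred, ref, "phylum")
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)  # c1 has no phylum reference

    def test_full_path_identity_a_right_name_under_wrong_parent_is_fp(self):
        ref = lineage_set({"c1": ("A", "B", "G")})
        pred = prediction_set({"c1": ("A", "Z", "G")})
        c = confusion_counts(pred, ref, "class")
        assert (c.tp, c.fp, c.fn) == (0, 1, 0)


class TestMetrics:
    def test_worked_example(self):
        p, r, f1 = precision_recall_f1(ConfusionCounts(8, 1, 1, "species"))
        assert round(p, 4) == 0.8889
        assert round(r, 4) == 0.8
        assert round(f1, 4) == 0.8421

    def test_zero_over_zero_convention(self):
        assert precision_recall_f1(ConfusionCounts(0, 0, 0, "species")) == (0, 0, 0)

    def test_perfect(self):
        assert precision_recall_f1(ConfusionCounts(10, 0, 0, "species")) == (1, 1, 1)

    def test_adding_a_true_positive_never_hurts(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            tp, fp, fn = rng.integers(0, 30, size=3)
            before = precision_recall_f1(ConfusionCounts(tp, fp, fn, "x"))
            after = precision_recall_f1(ConfusionCounts(tp + 1, fp, fn, "x"))
            assert all(a >= b - 1e-12 for a, b in zip(after, before))

    def test_recall_never_exceeds_textbook_recall(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            tp, fp, fn = rng.integers(0, 30, size=3)
            _, recall, _ = precision_recall_f1(ConfusionCounts(tp, fp, fn, "x"))
            textbook = tp / (tp + fn) if tp + fn else 0.0
            assert recall <= textbook + 1e-12


class TestKfoldSplit:
    def test_balanced_partition(self):
        fa = kfold_split([f"c{i}" for i in range(10)], k=5, seed=0)
        sizes = sorted(len(fa.members(f)) for f in range(5))
        assert sizes == [2, 2, 2, 2, 2]
        assert set().union(*(fa.members(f) for f in range(5))) == set(fa.folds)

    def test_remainder_goes_to_early_folds(self):
        fa = kfold_split([f"c{i}" for i in range(11)], k=5, seed=1)
        assert sorted((len(fa.members(f)) for f in range(5)), reverse=True) == [3, 2, 2, 2, 2]

    def test_deterministic_per_seed(self):
        ids = [f"c{i}" for i in range(20)]
        assert kfold_split(ids, 5, 3).folds == kfold_split(ids, 5, 3).folds
        assert kfold_split(ids, 5, 3).folds != kfold_split(ids, 5, 4).folds

    def test_too_few_ids_is_an_error(self):
        with pytest.raises(ValueError, match="folds"):
            kfold_split(["a", "b"], k=5)


class TestKfoldConsistency:
    def test_separable_fixture_reaches_high_species_precision(
        self, small_community, small_features
    ):
        table, preds = kfold_consistency(
            small_features,
            small_community.truth,
            estimator=TaxonomyRefiner(**FAST),
            k=5,
            seed=0,
        )
        species = table[table["rank"] == "species"].iloc[0]
        assert species.precision >= 0.9
        # every annotated contig is predicted exactly once
        assert set(preds.records) == set(small_community.truth.annotated_ids())

    def test_permuted_labels_fall_to_chance(self, small_community, small_features):
        """Shuffling lineages across contigs destroys the feature-label
        signal; consistency precision drops to about the majority-class
        rate computed analytically from the label frequencies."""
        rng = np.random.default_rng(13)
        ids = list(small_community.truth.lineages)
        perm = rng.permutation(len(ids))
        shuffled = AnnotationSet(
            {
                ids[i]: Lineage(ids[i], small_community.truth.get(ids[int(p)]).labels)
                for i, p in enumerate(perm)
            }
        )
        table, _ = kfold_consistency(
            small_features, shuffled, estimator=TaxonomyRefiner(**FAST), k=5, seed=0
        )
        species = table[table["rank"] == "species"].iloc[0]
        counts = pd.Series(
            [lin.labels for lin in shuffled.lineages.values()]
        ).value_counts()
        majority_rate = counts.iloc[0] / counts.sum()
        # binomial slack: 4 sigma around the majority-class baseline
        sigma = np.sqrt(majority_rate * (1 - majority_rate) / counts.sum())
        assert species.precision <= majority_rate + 4 * sigma

    def test_boundary_one_contig_per_fold(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(5, 6))
        from taxrefine.features import FeatureMatrix

        fm = type("FM", (), {"values": X, "contig_ids": tuple(f"c{i}" for i in range(5))})()
        ann = lineage_set({f"c{i}": ("A", "B") for i in range(5)})
        table, preds = kfold_consistency(
            fm, ann, estimator=TaxonomyRefiner(hidden_sizes=(4,), epochs=2, batch_size=4),
            k=5, seed=0,
        )
        assert len(preds.records) == 5


class TestGroundTruthReport:
    def test_constant_scores_give_constant_pr(self):
        truth = lineage_set({f"c{i}": ("A", "B") for i in range(6)})
        pred = prediction_set({f"c{i}": ("A", "B") for i in range(6)}, score=1.0)
        report = ground_truth_report(pred, truth, thresholds=(0.5, 0.9, 1.0))
        phylum = report[report["rank"] == "phylum"]
        assert phylum.precision.nunique() == 1

    def test_fp_is_monotone_nonincreasing_in_threshold(
        self, small_community, small_features
    ):
        from taxrefine.refiner import train, predict

        corrupted = corrupt_annotations(small_community.truth, error_rate=0.3, seed=5)
        model = train(small_features, corrupted, **FAST)
        preds = predict(model, small_features)
        report = ground_truth_report(
            preds, small_community.truth, thresholds=(0.5, 0.7, 0.9, 0.95)
        )
        for _, group in report.groupby("rank"):
            fps = group.sort_values("threshold").FP.tolist()
            assert fps == sorted(fps, reverse=True)

    def test_empty_truth_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            ground_truth_report(PredictionSet({}), lineage_set({"c1": ()}))


class TestSpeciesDeletion:
    def test_unknown_species_is_an_error(self, small_community, small_features):
        with pytest.raises(ValueError, match="not present"):
            species_deletion_experiment(
                small_features, small_community.truth, ["NoSuchSpecies"],
                estimator=TaxonomyRefiner(hidden_sizes=(8,), epochs=1, batch_size=32),
            )

    def test_distinct_species_recovers_genus(self, small_community, small_features):
        """Deleting one of two sibling species: the genus survives in the
        tree via the sibling, and the deleted species' contigs recover it."""
        species = small_community.species_lineages[0][-1]
        report = species_deletion_experiment(
            small_features, small_community.truth, [species],
            estimator=TaxonomyRefiner(**FAST),
        )
        row = report.iloc[0]
        assert row.n_contigs == 25
        assert row.genus_correct >= 0.9

    def test_near_identical_sibling_absorbs_deleted_contigs(self):
        """Two sibling species with indistinguishable features: deleting
        one routes most of its contigs to the survivor at species rank.
        Verified against a nearest-centroid intuition: identical centroids
        make the surviving sibling the only plausible species."""
        rng = np.random.default_rng(21)
        n = 60
        # siblings share a structured centroid; an outgroup is far away
        centroid = rng.normal(0.0, 2.0, size=8)
        X = np.vstack(
            [
                centroid + rng.normal(0.0, 0.3, size=(n, 8)),         # species P (deleted)
                centroid + 0.05 + rng.normal(0.0, 0.3, size=(n, 8)),  # species Q (twin)
                -centroid + rng.normal(0.0, 0.3, size=(n, 8)),        # outgroup R
            ]
        )
        ids = [f"c{i}" for i in range(3 * n)]
        base = ("D", "Ph", "Cl", "Or", "Fa")
        paths = (
            [base + ("G", "P")] * n
            + [base + ("G", "Q")] * n
            + [base + ("H", "R")] * n
        )
        ann = AnnotationSet({cid: Lineage(cid, p) for cid, p in zip(ids, paths)})
        fm = type("FM", (), {"values": X, "contig_ids": tuple(ids)})()
        report = species_deletion_experiment(
            fm, ann, ["P"],
            estimator=TaxonomyRefiner(hidden_sizes=(64, 64), epochs=40,
                                      batch_size=64, random_state=0),
        )
        row = report.iloc[0]
        assert row.most_assigned == "Q"
        assert row.most_assigned_count >= n / 2
        assert row.feature_correlation > 0.9


def test_benchmark_ranks_lower_noise_first(small_community, small_features):
    low = corrupt_annotations(small_community.truth, error_rate=0.05, seed=3)
    high = corrupt_annotations(small_community.truth, error_rate=0.4, seed=3)
    report = benchmark_classifiers(
        small_features,
        {"low_noise": low, "high_noise": high},
        truth=small_community.truth,
        estimator=TaxonomyRefiner(**FAST),
        k=5,
        seed=0,
    )
    species = report[(report["rank"] == "species") & (report.metric == "consistency")]
    by_name = species.set_index("classifier").precision
    assert by_name["low_noise"] > by_name["high_noise"]
    assert "spearman" in report.attrs


def test_benchmark_requires_two_sets(small_community, small_features):
    with pytest.raises(ValueError, match="two"):
        benchmark_classifiers(small_features, {"only": small_community.truth})
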
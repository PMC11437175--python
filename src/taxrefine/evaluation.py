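"""Evaluation: per-rank confusion metrics, the k-fold self-consistency
benchmark, ground-truth comparison with PR curves, and the species-deletion
(novel-taxon) experiment.

Metric conventions
------------------
Counting is per rank, restricted to contigs where the reference has a
label at that rank. TP means both labels present and identical (identity is
on the *full path* down to the rank, so a correct species name under a
wrong genus never counts), FP means both present but different, FN means
the reference has a label where the prediction has none.

    precision = TP / (TP + FP)
    recall    = TP / (TP + FP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Note the FP term in the recall denominator: this recall is deliberately
stricter than the textbook TP / (TP + FN) and never exceeds it. Any 0/0
evaluates to 0.

The k-fold benchmark scores a classifier *without ground truth*: its
annotated contigs are split into k folds, the refiner is trained on k-1
folds (with the output-space tree rebuilt from the training folds only, so
held-out label identities never leak into the output space) and predicts
the held-out fold at score threshold 0.5; held-out predictions are
concatenated and compared against the classifier's own annotations. The
more self-inconsistent a classifier's labels are given the features, the
lower this precision — which is what makes it a ranking signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.base import clone

from .features import FeatureMatrix
from .refiner import PredictionSet, TaxonomyRefiner, decode_probabilities
from .taxonomy import RANKS, AnnotationSet, Lineage


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    rank: str


def confusion_counts(pred: PredictionSet, ref: AnnotationSet, rank: str) -> ConfusionCounts:
    """Count TP/FP/FN at one rank over contigs the reference labels there."""
    rank_idx = RANKS.index(rank)
    tp = fp = fn = 0
    for cid, lin in ref.lineages.items():
        if lin.depth <= rank_idx:
            continue
        ref_path = lin.labels[: rank_idx + 1]
        pred_path = pred.path_at(cid, rank)
        if pred_path is None:
            fn += 1
        elif pred_path == ref_path:
            tp += 1
        else:
            fp += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, rank=rank)


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 under the FP-in-recall-denominator
    convention; 0/0 maps to 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def metrics_frame(pred: PredictionSet, ref: AnnotationSet, threshold: float | None = None) -> pd.DataFrame:
    """Per-rank long-format metric table for one prediction set."""
    rows = []
    for rank in RANKS:
        c = confusion_counts(pred, ref, rank)
        if c.tp + c.fp + c.fn == 0:
            continue
        p, r, f1 = precision_recall_f1(c)
        rows.append(
            {"rank": rank, "threshold": threshold, "TP": c.tp, "FP": c.fp, "FN": c.fn,
             "precision": p, "recall": r, "f1": f1}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FoldAssignment:
    folds: dict[str, int]
    k: int
    seed: int

    def members(self, fold: int) -> list[str]:
        return [cid for cid, f in self.folds.items() if f == fold]


def kfold_split(contig_ids: Sequence[str], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Uniform random balanced partition, deterministic per seed."""
    ids = list(contig_ids)
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(ids) < k:
        raise ValueError(f"cannot split {len(ids)} contigs into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = {ids[idx]: i % k for i, idx in enumerate(order)}
    return FoldAssignment(folds=folds, k=k, seed=seed)


def kfold_consistency(
    features: FeatureMatrix,
    annotations: AnnotationSet,
    estimator: TaxonomyRefiner | None = None,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, PredictionSet]:
    """Self-consistency benchmark: held-out refiner predictions vs the
    classifier's own annotations.

    Returns the per-rank metric table and the concatenated held-out
    predictions (every annotated contig predicted exactly once).
    """
    estimator = estimator if estimator is not None else TaxonomyRefiner()
    annotated = [cid for cid in features.contig_ids if annotations.get(cid).labels]
    assignment = kfold_split(annotated, k=k, seed=seed)
    row_of = {cid: i for i, cid in enumerate(features.contig_ids)}

    combined: dict[str, tuple] = {}
    for fold in range(k):
        held = assignment.members(fold)
        train_ids = [cid for cid in annotated if assignment.folds[cid] != fold]
        X_train = features.values[[row_of[cid] for cid in train_ids]]
        y_train = [annotations.get(cid).labels for cid in train_ids]
        model = clone(estimator)
        model.set_params(random_state=estimator.random_state + fold)
        try:
            model.fit(X_train, y_train)
        except Exception as exc:  # noqa: BLE001 - annotate fold before re-raising
            raise RuntimeError(f"training failed on fold {fold}: {exc}") from exc
        X_held = features.values[[row_of[cid] for cid in held]]
        preds = model.predict(X_held, contig_ids=held).filter(threshold)
        combined.update(preds.records)

    predictions = PredictionSet(combined)
    return metrics_frame(predictions, annotations, threshold=threshold), predictions


def ground_truth_report(
    pred: PredictionSet,
    truth: AnnotationSet,
    thresholds: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99),
) -> pd.DataFrame:
    """Per-rank, per-threshold precision/recall sweep against ground truth.

    Ranks with no ground-truth label anywhere are omitted. The rows at each
    threshold form one point of the PR curve; the 0.95 row is the default
    operating point.
    """
    if not any(lin.labels for lin in truth.lineages.values()):
        raise ValueError("ground truth is empty")
    frames = []
    for threshold in sorted(thresholds):
        frames.append(metrics_frame(pred.filter(threshold), truth, threshold=threshold))
    return pd.concat(frames, ignore_index=True)


def species_deletion_experiment(
    features: FeatureMatrix,
    annotations: AnnotationSet,
    species_to_delete: Sequence[str],
    estimator: TaxonomyRefiner | None = None,
) -> pd.DataFrame:
    """Novel-taxon simulation: hide some species' labels, see what the
    refiner does with their contigs.

    Each named species' contig lineages are truncated to the genus rank
    before training (so the species vanishes from the output space unless a
    sibling keeps the genus populated). Reported per deleted species:

    * ``genus_correct`` — fraction of its contigs recovering the true genus;
    * ``species_assigned`` — fraction receiving *some* species label (these
      are false positives at species rank; 1 minus this is the share of
      correctly missing labels);
    * ``most_assigned`` / ``most_assigned_count`` — the species most often
      assigned to them, the absorption pattern seen with close relatives;
    * ``feature_correlation`` — Pearson correlation between the mean
      feature vectors of the deleted and the most-assigned species.
    """
    estimator = estimator if estimator is not None else TaxonomyRefiner()
    by_species: dict[str, list[str]] = {}
    for cid, lin in annotations.lineages.items():
        if lin.depth == len(RANKS):
            by_species.setdefault(lin.labels[-1], []).append(cid)
    unknown = [s for s in species_to_delete if s not in by_species]
    if unknown:
        raise ValueError(f"species not present in the annotations: {unknown}")

    deleted_ids = {s: by_species[s] for s in species_to_delete}
    modified = {
        cid: (lin.truncate("genus") if lin.labels and lin.labels[-1] in species_to_delete
              and lin.depth == len(RANKS) else lin)
        for cid, lin in annotations.lineages.items()
    }
    y = [modified[cid].labels if cid in modified else () for cid in features.contig_ids]
    model = clone(estimator)
    model.fit(features.values, y)
    predictions = model.predict(features.values, contig_ids=list(features.contig_ids))

    row_of = {cid: i for i, cid in enumerate(features.contig_ids)}
    rows = []
    for species in species_to_delete:
        ids = deleted_ids[species]
        true_genus = annotations.get(ids[0]).labels[:6]
        genus_hits = sum(predictions.path_at(cid, "genus") == true_genus for cid in ids)
        assigned = [predictions.path_at(cid, "species") for cid in ids]
        assigned = [p for p in assigned if p is not None]
        most, most_count, corr = None, 0, np.nan
        if assigned:
            names, counts = np.unique([p[-1] for p in assigned], return_counts=True)
            most = str(names[np.argmax(counts)])
            most_count = int(counts.max())
            if most in by_species:
                deleted_mean = features.values[[row_of[c] for c in ids]].mean(axis=0)
                assigned_mean = features.values[
                    [row_of[c] for c in by_species[most] if c not in ids]
                ].mean(axis=0)
                corr = float(pearsonr(deleted_mean, assigned_mean)[0])
        rows.append(
            {
                "species": species,
                "n_contigs": len(ids),
                "genus_correct": genus_hits / len(ids),
                "species_assigned": len(assigned) / len(ids),
                "most_assigned": most,
                "most_assigned_count": most_count,
                "feature_correlation": corr,
            }
        )
    return pd.DataFrame(rows)


def benchmark_classifiers(
    features: FeatureMatrix,
    annotation_sets: Mapping[str, AnnotationSet],
    truth: AnnotationSet | None = None,
    estimator: TaxonomyRefiner | None = None,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank >= 2 classifiers by k-fold consistency precision.

    When ground truth is supplied, each classifier's annotations are also
    scored directly against it and a per-rank Spearman correlation between
    the consistency ranking and the truth ranking is attached — agreement
    close to 1 means the ground-truth-free benchmark ranks classifiers the
    same way the truth does.
    """
    if len(annotation_sets) < 2:
        raise ValueError("benchmarking needs at least two annotation sets")
    rows = []
    for name, annotations in annotation_sets.items():
        table, _ = kfold_consistency(
            features, annotations, estimator=estimator, k=k, seed=seed
        )
        table = table.assign(classifier=name, metric="consistency")
        rows.append(table)
        if truth is not None:
            ident = PredictionSet(
                {
                    cid: _lineage_as_prediction(lin)
                    for cid, lin in annotations.lineages.items()
                    if lin.labels
                }
            )
            rows.append(
                metrics_frame(ident, truth).assign(classifier=name, metric="truth")
            )
    report = pd.concat(rows, ignore_index=True)
    if truth is not None:
        corr_rows = []
        for rank in RANKS:
            sub = report[report["rank"] == rank]
            cons = sub[sub.metric == "consistency"].set_index("classifier")["precision"]
            tru = sub[sub.metric == "truth"].set_index("classifier")["precision"]
            common = cons.index.intersection(tru.index)
            if len(common) >= 2:
                rho = spearmanr(cons[common], tru[common])[0]
                corr_rows.append({"rank": rank, "spearman": rho})
        report.attrs["spearman"] = pd.DataFrame(corr_rows)
    return report


def _lineage_as_prediction(lin: Lineage) -> tuple:
    from .refiner import RankPrediction

    return tuple(
        RankPrediction(RANKS[d], lin.labels[: d + 1], 1.0) for d in range(lin.depth)
    )
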
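"""The taxonomy refiner: a scikit-learn-style estimator over the network.

``TaxonomyRefiner.fit`` builds the output-space tree from the annotated
subset of the training lineages, trains the MLP under the hierarchical
loss, and ``predict`` decodes every contig greedily rank by rank: starting
at the root, the child of the current node with the highest aggregated
likelihood is selected; its label is emitted with that likelihood as the
score if it exceeds 0.5 (strictly), otherwise decoding stops and this rank
and everything below is left unannotated. Scores are therefore always in
(0.5, 1] and non-increasing with depth, and at most one child of any node
can clear the threshold, so decoding is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .network import (
    MLP,
    Adam,
    aggregate_likelihoods,
    hierarchical_loss_and_grad,
    leaf_softmax,
    path_node_matrix,
)
from .taxonomy import LINEAGE_SEP, RANKS, AnnotationSet, Lineage, TaxTree

SCORE_FLOOR = 0.5
DEFAULT_SCORE_THRESHOLD = 0.95
CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class RankPrediction:
    rank: str
    path: tuple[str, ...]  # full path down to this rank
    score: float

    @property
    def label(self) -> str:
        return self.path[-1]


@dataclass
class PredictionSet:
    """Per-contig, per-rank predicted labels with likelihood scores.

    For each contig the emitted ranks form a contiguous prefix of the rank
    ladder and scores are non-increasing with depth.
    """

    records: dict[str, tuple[RankPrediction, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def path_at(self, contig_id: str, rank: str) -> tuple[str, ...] | None:
        for pred in self.records.get(contig_id, ()):
            if pred.rank == rank:
                return pred.path
        return None

    def filter(self, threshold: float) -> "PredictionSet":
        """Drop every (label, score) with score below the threshold."""
        if not SCORE_FLOOR <= threshold <= 1.0:
            raise ValueError("threshold must be in [0.5, 1]")
        return PredictionSet(
            {
                cid: tuple(p for p in preds if p.score >= threshold)
                for cid, preds in self.records.items()
            }
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contig_id": cid,
                "rank": p.rank,
                "label": p.label,
                "lineage": LINEAGE_SEP.join(p.path),
                "score": p.score,
            }
            for cid, preds in self.records.items()
            for p in preds
        ]
        return pd.DataFrame(rows, columns=["contig_id", "rank", "label", "lineage", "score"])

    def to_wide_frame(self) -> pd.DataFrame:
        rows = []
        for cid, preds in self.records.items():
            row: dict[str, object] = {"contig_id": cid}
            for p in preds:
                row[p.rank] = p.label
                row[f"{p.rank}_score"] = p.score
            rows.append(row)
        cols = ["contig_id"] + [c for r in RANKS for c in (r, f"{r}_score")]
        return pd.DataFrame(rows).reindex(columns=cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "PredictionSet":
        records: dict[str, list[RankPrediction]] = {}
        for row in frame.itertuples(index=False):
            records.setdefault(str(row.contig_id), []).append(
                RankPrediction(row.rank, tuple(row.lineage.split(LINEAGE_SEP)), float(row.score))
            )
        return cls({cid: tuple(preds) for cid, preds in records.items()})

    @classmethod
    def from_csv(cls, path: str | Path) -> "PredictionSet":
        return cls.from_long_frame(pd.read_csv(path))


def filter_predictions(predictions: PredictionSet, threshold: float) -> PredictionSet:
    return predictions.filter(threshold)


def decode_probabilities(
    leaf_probs: np.ndarray, tree: TaxTree, contig_ids: Sequence[str]
) -> PredictionSet:
    """Greedy thresholded top-down decoding of leaf probability vectors."""
    leaf_probs = np.atleast_2d(np.asarray(leaf_probs, dtype=np.float64))
    if leaf_probs.shape[0] != len(contig_ids):
        raise ValueError("one probability vector per contig id is required")
    node_lik = aggregate_likelihoods(leaf_probs, tree)
    records: dict[str, tuple[RankPrediction, ...]] = {}
    # deterministic tie-break: children ordered by lowest descendant leaf index
    child_order = {
        nid: sorted(
            tree.children(nid),
            key=lambda c: int(np.argmax(tree.leaf_mask[c] > 0)),
        )
        for nid in range(tree.n_nodes)
        if tree.children(nid)
    }
    for i, cid in enumerate(contig_ids):
        preds: list[RankPrediction] = []
        current = 0
        while True:
            children = child_order.get(current)
            if not children:
                break
            liks = node_lik[i, children]
            best = children[int(np.argmax(liks))]
            score = float(node_lik[i, best])
            if not score > SCORE_FLOOR:
                break
            node = tree.node(best)
            preds.append(RankPrediction(RANKS[node.rank], node.path, min(score, 1.0)))
            current = best
        records[cid] = tuple(preds)
    return PredictionSet(records)


class TaxonomyRefiner(BaseEstimator):
    """MLP refiner of per-contig taxonomic annotations.

    Parameters mirror the published training regime: four hidden layers of
    512 units with batch normalisation (eps 1e-5, momentum 0.1), leaky ReLU
    (slope 0.01) and dropout 0.2, trained for 100 epochs with batch size
    1024 under Adam. The batch size is reduced automatically when the
    annotated set is smaller; there is no early stopping and no internal
    validation split. Unannotated contigs are excluded from training but
    predicted like any other.

    Attributes set by :meth:`fit` (scikit-learn convention): ``tree_``,
    ``network_``, ``loss_trace_``, ``n_features_in_``.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (512, 512, 512, 512),
        leaky_slope: float = 0.01,
        batchnorm_eps: float = 1e-5,
        batchnorm_momentum: float = 0.1,
        dropout: float = 0.2,
        epochs: int = 100,
        batch_size: int = 1024,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.leaky_slope = leaky_slope
        self.batchnorm_eps = batchnorm_eps
        self.batchnorm_momentum = batchnorm_momentum
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------

    @staticmethod
    def _as_label_tuples(y: Sequence) -> list[tuple[str, ...]]:
        out = []
        for item in y:
            if isinstance(item, Lineage):
                out.append(item.labels)
            elif item is None:
                out.append(())
            else:
                out.append(tuple(item))
        return out

    def fit(self, X, y) -> "TaxonomyRefiner":
        """Train on the annotated rows of ``X``.

        ``y`` is a sequence of lineages (label tuples or :class:`Lineage`),
        row-aligned with ``X``; empty lineages mark unannotated contigs.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        labels = self._as_label_tuples(y)
        if len(labels) != X.shape[0]:
            raise ValueError(
                f"feature/annotation mismatch: {X.shape[0]} rows, {len(labels)} lineages"
            )
        annotated = [i for i, lab in enumerate(labels) if lab]
        if not annotated:
            raise ValueError("no annotated contigs to train on")

        self.tree_ = TaxTree(labels[i] for i in annotated)
        targets = np.array([self.tree_.resolve(labels[i]) for i in annotated])
        paths = path_node_matrix(self.tree_, targets)
        X_train = X[annotated]
        n_train = len(annotated)

        rng = np.random.default_rng(self.random_state)
        self.network_ = MLP(
            in_dim=X.shape[1],
            out_dim=self.tree_.n_leaves,
            hidden_sizes=tuple(self.hidden_sizes),
            leaky_slope=self.leaky_slope,
            bn_eps=self.batchnorm_eps,
            bn_momentum=self.batchnorm_momentum,
            dropout=self.dropout,
            rng=rng,
        )
        optimizer = Adam(self.network_.params, lr=self.learning_rate)
        batch_size = min(self.batch_size, n_train)

        self.loss_trace_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n_train)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n_train, batch_size):
                idx = order[start : start + batch_size]
                logits, caches = self.network_.forward(X_train[idx], train=True, rng=rng)
                loss, dlogits = hierarchical_loss_and_grad(logits, self.tree_, paths[idx])
                grads = self.network_.backward(dlogits, caches)
                optimizer.step(grads)
                epoch_loss += loss
                n_batches += 1
            self.loss_trace_.append(epoch_loss / n_batches)
        self.n_features_in_ = X.shape[1]
        return self

    # -- inference -------------------------------------------------------

    def _check_fitted_X(self, X) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise RuntimeError("this TaxonomyRefiner instance is not fitted yet")
        X = np.asarray(X, dtype=np.float64)
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, the model was trained with {self.n_features_in_}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Leaf likelihoods (softmax over logits), dropout off, BN in
        inference mode."""
        X = self._check_fitted_X(X)
        logits, _ = self.network_.forward(X, train=False)
        return leaf_softmax(logits)

    def predict(self, X, contig_ids: Sequence[str] | None = None) -> PredictionSet:
        """Greedy thresholded per-rank decoding for every row of ``X``."""
        X = self._check_fitted_X(X)
        if contig_ids is None:
            contig_ids = [str(i) for i in range(X.shape[0])]
        if len(contig_ids) != X.shape[0]:
            raise ValueError("one contig id per feature row is required")
        return decode_probabilities(self.predict_proba(X), self.tree_, contig_ids)

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint with a versioned header binding the tree and the
        feature width the weights were trained against."""
        if not hasattr(self, "network_"):
            raise RuntimeError("cannot save an unfitted model")
        payload = {
            "version": CHECKPOINT_VERSION,
            "tree_hash": self.tree_.content_hash(),
            "tree_paths": self.tree_.leaf_paths()
            + [self.tree_.node(t).path for t in range(1, self.tree_.n_nodes)],
            "n_features_in": self.n_features_in_,
            "params": self.get_params(),
            "weights": self.network_.params,
            "running": self.network_.running,
            "loss_trace": self.loss_trace_,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "TaxonomyRefiner":
        payload = joblib.load(path)
        if payload.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {payload.get('version')!r}")
        model = cls(**payload["params"])
        model.tree_ = TaxTree(payload["tree_paths"])
        if model.tree_.content_hash() != payload["tree_hash"]:
            raise ValueError("checkpoint tree hash mismatch")
        model.n_features_in_ = payload["n_features_in"]
        model.network_ = MLP(
            in_dim=model.n_features_in_,
            out_dim=model.tree_.n_leaves,
            hidden_sizes=tuple(model.hidden_sizes),
            leaky_slope=model.leaky_slope,
            bn_eps=model.batchnorm_eps,
            bn_momentum=model.batchnorm_momentum,
            dropout=model.dropout,
            rng=np.random.default_rng(0),
        )
        model.network_.params = payload["weights"]
        model.network_.running = payload["running"]
        model.loss_trace_ = payload["loss_trace"]
        return model


# -- thin functional wrappers -------------------------------------------


def train(
    features,
    annotations: AnnotationSet | Mapping[str, Lineage],
    **params,
) -> TaxonomyRefiner:
    """Fit a refiner on a FeatureMatrix and an AnnotationSet."""
    lineages = annotations.lineages if isinstance(annotations, AnnotationSet) else annotations
    y = [lineages[cid].labels if cid in lineages else () for cid in features.contig_ids]
    return TaxonomyRefiner(**params).fit(features.values, y)


def predict(model: TaxonomyRefiner, features) -> PredictionSet:
    """Decode predictions for every contig in a FeatureMatrix."""
    return model.predict(features.values, contig_ids=features.contig_ids)
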
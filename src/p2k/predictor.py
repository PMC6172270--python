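"""Tree-ensemble interaction predictor and its evaluation machinery.

The classifier is an extremely-randomized-trees ensemble (1000 trees by
default) over the pair feature vectors; its score for a candidate pair is
the fraction of trees voting for the positive class, a value in [0, 1].
Evaluation follows the leave-one-complex-out protocol: for each complex,
the contact statistics, their decomposition and the classifier are rebuilt
from the remaining complexes only, the held-out complex's candidate pairs
are scored, and ranking quality is summarized by the area under the ROC
curve.  Because both the deep knowledge and the ensemble are refit per
fold, no statistic of the held-out complex ever reaches its own training.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.metrics import roc_auc_score

from .contacts import build_contact_frequency_matrix
from .data import ComplexSample
from .features import (
    DeepKnowledge,
    build_deep_knowledge,
    enumerate_candidates,
    featurize_candidates,
)
from .residuals import statistical_residuals

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 1000


@dataclass
class TrainingSet:
    """Feature matrix with labels and per-row complex provenance."""

    features: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=object)
        n = self.features.shape[0]
        if self.labels.shape != (n,) or self.provenance.shape != (n,):
            raise ValueError("features, labels and provenance must align row-wise")


@dataclass
class TrainedPredictor:
    """A fitted ensemble plus the input dimension it validates against."""

    ensemble: ExtraTreesClassifier
    n_features: int
    n_trees: int
    seed: int | None


@dataclass
class EvaluationReport:
    """Per-complex AUCs with their mean and dispersion.

    Both the standard deviation and the standard error of the per-complex
    AUCs are reported.  Optional top-N confusion counts and the derived
    metrics are attached when a ranking cutoff was evaluated.
    """

    aucs: dict[str, float]
    skipped: list[str] = field(default_factory=list)
    confusion: dict[str, float] | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(list(self.aucs.values())))

    @property
    def sd_auc(self) -> float:
        return float(np.std(list(self.aucs.values()), ddof=1)) if len(self.aucs) > 1 else 0.0

    @property
    def se_auc(self) -> float:
        return self.sd_auc / math.sqrt(len(self.aucs)) if self.aucs else 0.0

    def summary(self) -> str:
        lines = [f"{'complex':<16}AUC"]
        lines += [f"{cid:<16}{auc:.5f}" for cid, auc in self.aucs.items()]
        lines.append(f"{'mean':<16}{self.mean_auc:.5f}")
        lines.append(f"{'sd':<16}{self.sd_auc:.5f}")
        lines.append(f"{'se':<16}{self.se_auc:.5f}")
        if self.skipped:
            lines.append(f"skipped (single class): {', '.join(self.skipped)}")
        return "\n".join(lines)


def train(
    training: TrainingSet,
    n_trees: int = DEFAULT_N_TREES,
    seed: int | None = None,
) -> TrainedPredictor:
    """Fit the extremely-randomized-trees ensemble on a training set.

    Deterministic for a given seed.  Requires at least one example of each
    class.
    """
    classes = np.unique(training.labels)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")
    ensemble = ExtraTreesClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    ensemble.fit(training.features, training.labels)
    return TrainedPredictor(
        ensemble=ensemble,
        n_features=training.features.shape[1],
        n_trees=n_trees,
        seed=seed,
    )


def score(model: TrainedPredictor, features: np.ndarray) -> np.ndarray:
    """Positive-class probability for each feature vector, in input order."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features per vector, got {features.shape[1]}"
        )
    positive_col = list(model.ensemble.classes_).index(1)
    return model.ensemble.predict_proba(features)[:, positive_col]


def rank_top_n(scores: np.ndarray, n: int) -> np.ndarray:
    """Boolean mask marking exactly the ``n`` top-scoring pairs positive.

    Ties are broken by stable input order, so among equal scores the
    earliest pairs win.
    """
    scores = np.asarray(scores, dtype=float)
    if n > scores.size:
        raise ValueError(f"cannot take top {n} of {scores.size} scores")
    order = np.argsort(-scores, kind="stable")
    mask = np.zeros(scores.size, dtype=bool)
    mask[order[:n]] = True
    return mask


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Precision, recall, specificity and F1 from confusion counts.

    A zero denominator yields 0 for the affected metric (logged), which
    keeps degenerate rankings comparable.
    """
    counts = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    if any(v < 0 for v in counts.values()):
        raise ValueError("confusion counts must be non-negative")
    if all(v == 0 for v in counts.values()):
        raise ValueError("confusion counts must not all be zero")

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.info("%s denominator is zero; reporting 0 by convention", name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    f1 = ratio(2 * precision * recall, precision + recall, "F1")
    return {
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney statistic with tie correction)."""
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC AUC requires both classes among the labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def featurize_complex(
    sample: ComplexSample,
    knowledge: DeepKnowledge,
    k: int,
    negative_ratio: float | None = None,
    rng: np.random.Generator | None = None,
) -> TrainingSet:
    """Encode every candidate pair of a complex against given knowledge.

    ``negative_ratio`` optionally subsamples negatives to that multiple of
    the positive count (seeded by ``rng``); by default all negatives are
    kept.
    """
    contexts = list(enumerate_candidates(sample.seq_a, sample.seq_b, k))
    labels = np.array(
        [1 if sample.label(c.pos_a, c.pos_b) else 0 for c in contexts], dtype=int
    )
    if negative_ratio is not None:
        n_pos = int(labels.sum())
        n_keep = int(round(negative_ratio * n_pos))
        neg_idx = np.flatnonzero(labels == 0)
        if n_keep < neg_idx.size:
            if rng is None:
                raise ValueError("negative subsampling requires an rng")
            keep = rng.choice(neg_idx, size=n_keep, replace=False)
            chosen = np.sort(np.concatenate([np.flatnonzero(labels == 1), keep]))
            contexts = [contexts[i] for i in chosen]
            labels = labels[chosen]
    features = featurize_candidates(contexts, knowledge)
    provenance = np.full(len(contexts), sample.identifier, dtype=object)
    return TrainingSet(features=features, labels=labels, provenance=provenance)


def knowledge_from_samples(
    samples: Sequence[ComplexSample], n_components: int = 6,
    residual_kind: str = "adjusted",
) -> DeepKnowledge:
    """Deep knowledge (residuals + decomposition) from samples' positives."""
    type_pairs = [tp for s in samples for tp in s.positive_type_pairs()]
    cfm = build_contact_frequency_matrix(type_pairs)
    srv = statistical_residuals(cfm, kind=residual_kind)
    return build_deep_knowledge(srv, n_components=n_components)


def loco_folds(
    samples: Sequence[ComplexSample],
) -> Iterator[tuple[ComplexSample, list[ComplexSample]]]:
    """Yield (held-out complex, training complexes) for every fold."""
    for held in samples:
        yield held, [s for s in samples if s.identifier != held.identifier]


def leave_one_complex_out(
    samples: Sequence[ComplexSample],
    k: int = 3,
    n_components: int = 6,
    n_trees: int = DEFAULT_N_TREES,
    seed: int | None = None,
    negative_ratio: float | None = None,
    residual_kind: str = "adjusted",
) -> EvaluationReport:
    """Leave-one-complex-out cross-validation of the full pipeline.

    For every fold the contact statistics and their decomposition are
    recomputed from the training complexes' positives only, the ensemble is
    refit, and the held-out complex's candidate pairs are scored.  A
    held-out complex whose pairs are all one class is skipped with a
    warning.
    """
    if len(samples) < 2:
        raise ValueError("leave-one-complex-out needs at least 2 complexes")
    ids = [s.identifier for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("complex identifiers must be unique")

    rng = np.random.default_rng(seed)
    aucs: dict[str, float] = {}
    skipped: list[str] = []
    for held, training_samples in loco_folds(samples):
        held_labels = np.array(
            [
                1 if held.label(c.pos_a, c.pos_b) else 0
                for c in enumerate_candidates(held.seq_a, held.seq_b, k)
            ]
        )
        if np.unique(held_labels).size < 2:
            logger.warning(
                "complex %s has a single class; skipped from evaluation",
                held.identifier,
            )
            skipped.append(held.identifier)
            continue
        knowledge = knowledge_from_samples(
            training_samples, n_components=n_components, residual_kind=residual_kind
        )
        parts = [
            featurize_complex(s, knowledge, k, negative_ratio, rng)
            for s in training_samples
        ]
        training = TrainingSet(
            features=np.concatenate([p.features for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            provenance=np.concatenate([p.provenance for p in parts]),
        )
        assert held.identifier not in set(training.provenance)
        fold_seed = None if seed is None else int(rng.integers(0, 2**31 - 1))
        model = train(training, n_trees=n_trees, seed=fold_seed)
        held_set = featurize_complex(held, knowledge, k)
        aucs[held.identifier] = roc_auc(score(model, held_set.features), held_set.labels)
    return EvaluationReport(aucs=aucs, skipped=skipped)
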
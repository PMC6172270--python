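"""Model/Results surface tying the pipeline together.

:class:`InteractionModel` is built from a collection of labeled complexes
(sequence pairs plus their positive contact pairs).  ``fit`` runs the full
pipeline — contact frequency matrix, statistical residual space,
principal-component decomposition, feature construction, ensemble training
— and returns an :class:`InteractionResults` carrying the fitted artifacts,
a ``summary()`` table, pair prediction for new sequence pairs, and the
leave-one-complex-out evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import build_contact_frequency_matrix
from .data import ComplexSample
from .features import DeepKnowledge, enumerate_candidates, featurize_candidates
from .predictor import (
    DEFAULT_N_TREES,
    EvaluationReport,
    TrainedPredictor,
    TrainingSet,
    featurize_complex,
    knowledge_from_samples,
    leave_one_complex_out,
    rank_top_n,
    score,
    train,
)
from .residuals import classify_significance


class InteractionModel:
    """Sequence-based residue-pair interaction model over labeled complexes.

    Parameters
    ----------
    complexes
        Training complexes with known positive pairs.
    k
        Neighbors per side in the sequence window (default 3, giving
        126-dimensional features with 6 components).
    n_components
        Principal components retained from the residual space (default 6).
    n_trees
        Trees in the extremely-randomized ensemble (default 1000).
    negative_ratio
        Optional negatives-per-positive subsampling ratio per complex; by
        default every negative pair is kept.
    residual_kind
        ``"adjusted"`` (default) or ``"standardized"`` residuals.
    """

    def __init__(
        self,
        complexes: Sequence[ComplexSample],
        k: int = 3,
        n_components: int = 6,
        n_trees: int = DEFAULT_N_TREES,
        negative_ratio: float | None = None,
        residual_kind: str = "adjusted",
    ) -> None:
        if not complexes:
            raise ValueError("at least one training complex is required")
        self.complexes = list(complexes)
        self.k = k
        self.n_components = n_components
        self.n_trees = n_trees
        self.negative_ratio = negative_ratio
        self.residual_kind = residual_kind

    def fit(self, seed: int | None = None) -> "InteractionResults":
        """Run the full pipeline on all training complexes."""
        rng = np.random.default_rng(seed)
        knowledge = knowledge_from_samples(
            self.complexes,
            n_components=self.n_components,
            residual_kind=self.residual_kind,
        )
        parts = [
            featurize_complex(s, knowledge, self.k, self.negative_ratio, rng)
            for s in self.complexes
        ]
        training = TrainingSet(
            features=np.concatenate([p.features for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            provenance=np.concatenate([p.provenance for p in parts]),
        )
        ensemble_seed = None if seed is None else int(rng.integers(0, 2**31 - 1))
        predictor = train(training, n_trees=self.n_trees, seed=ensemble_seed)
        return InteractionResults(
            model=self, knowledge=knowledge, predictor=predictor,
            training=training, seed=seed,
        )

    def evaluate_loco(self, seed: int | None = None) -> EvaluationReport:
        """Leave-one-complex-out cross-validation at this model's settings."""
        return leave_one_complex_out(
            self.complexes,
            k=self.k,
            n_components=self.n_components,
            n_trees=self.n_trees,
            seed=seed,
            negative_ratio=self.negative_ratio,
            residual_kind=self.residual_kind,
        )


@dataclass
class InteractionResults:
    """Fitted pipeline artifacts with prediction and reporting methods."""

    model: InteractionModel
    knowledge: DeepKnowledge
    predictor: TrainedPredictor
    training: TrainingSet
    seed: int | None

    def predict_pairs(
        self, seq_a: str, seq_b: str, top: int | None = None
    ) -> pd.DataFrame:
        """Score every residue pair of two sequences.

        Returns a DataFrame with 1-based positions, residue letters, the
        ensemble score and the score rank (1 = best, ties in input order).
        With ``top``, only the ``top`` highest-ranked pairs are returned.
        """
        contexts = list(enumerate_candidates(seq_a, seq_b, self.model.k))
        features = featurize_candidates(contexts, self.knowledge)
        scores = score(self.predictor, features)
        order = np.argsort(-scores, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(order) + 1)
        frame = pd.DataFrame(
            {
                "pos_a": [c.pos_a + 1 for c in contexts],
                "res_a": [c.center_a for c in contexts],
                "pos_b": [c.pos_b + 1 for c in contexts],
                "res_b": [c.center_b for c in contexts],
                "score": scores,
                "rank": ranks,
            }
        )
        if top is not None:
            mask = rank_top_n(scores, top)
            frame = frame[mask].sort_values("rank").reset_index(drop=True)
        return frame

    def summary(self) -> str:
        """Human-readable account of the fitted pipeline."""
        n_pos = int(self.training.labels.sum())
        n_all = int(self.training.labels.size)
        srv = self.knowledge.srv
        mask = classify_significance(srv)
        fractions = self.knowledge.model.variance_fractions
        lines = [
            "Residue-residue interaction model",
            "=" * 46,
            f"training complexes        {len(self.model.complexes)}",
            f"candidate pairs           {n_all}",
            f"positive pairs            {n_pos}",
            f"contact table total N     {int(srv.grand_total) if np.isfinite(srv.grand_total) else 'n/a'}",
            f"significant cells (+/-)   {int((mask.classes == 1).sum())}/{int((mask.classes == -1).sum())}",
            f"neighbors per side (k)    {self.model.k}",
            f"feature dimension         {self.predictor.n_features}",
            f"components retained       {self.model.n_components}",
            "variance fractions        "
            + ", ".join(f"{f:.2%}" for f in fractions),
            f"ensemble trees            {self.predictor.n_trees}",
            f"fit seed                  {self.seed}",
        ]
        return "\n".join(lines)
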
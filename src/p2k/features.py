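"""Feature-vector construction for candidate residue pairs.

A candidate is a residue i on sequence A paired with a residue j on
sequence B.  Its encoding combines, for a window of k neighbors on each
side of both residues:

* block 1 — the principal-component score of every window residue on each
  of the M retained components (2 windows x (2k+1) residues x M features,
  residue-major);
* block 2 — for each of the 2k+1 aligned window pairs, the symmetric
  average of the two re-projected residual entries on each component
  ((2k+1) x M features, pair-major).

Window positions past a terminus, and unknown letters, carry the pad symbol
and contribute zeros.  The windows are aligned antiparallel: position p of
window A pairs with position 2k-p of window B, so the centers always pair
with each other and the two strands read toward each other, e.g. windows
``PVKAAFV`` / ``ITLVAFE`` yield the pairs P-E, V-F, K-A, A-V, A-L, F-T,
V-I.

Total length is ``2(2k+1)M + (2k+1)M = 3M(2k+1)``; with the default M = 6
components this is the 18(2k+1) ladder 18, 54, 90, 126 for k = 0..3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .alphabet import ALPHABET, INDEX, PAD
from .decomposition import (
    PrincipalComponentModel,
    ReprojectedMatrix,
    projection_table,
    reprojected_spaces,
)
from .residuals import ResidualMatrix

DEFAULT_NEIGHBORS = 3


@dataclass(frozen=True)
class ResiduePairContext:
    """A candidate pair with its sequence windows.

    ``window_a``/``window_b`` have length 2k+1 and are centered on the pair;
    off-sequence and unknown positions hold the pad symbol.  Positions are
    0-based indices into the source sequences.
    """

    window_a: str
    window_b: str
    k: int
    pos_a: int
    pos_b: int

    def __post_init__(self) -> None:
        width = 2 * self.k + 1
        if len(self.window_a) != width or len(self.window_b) != width:
            raise ValueError(f"windows must have length {width}")
        if self.center_a == PAD or self.center_b == PAD:
            raise ValueError("center letters must be real residues")

    @property
    def center_a(self) -> str:
        return self.window_a[self.k]

    @property
    def center_b(self) -> str:
        return self.window_b[self.k]

    def aligned_pairs(self) -> list[tuple[str, str]]:
        """The 2k+1 antiparallel window pairs, A left-to-right."""
        return [
            (self.window_a[p], self.window_b[2 * self.k - p])
            for p in range(2 * self.k + 1)
        ]


def _window(seq: str, center: int, k: int) -> str:
    letters = []
    for p in range(center - k, center + k + 1):
        if 0 <= p < len(seq) and seq[p] in INDEX:
            letters.append(seq[p])
        else:
            letters.append(PAD)
    return "".join(letters)


def extract_context(
    seq_a: str, i: int, seq_b: str, j: int, k: int = DEFAULT_NEIGHBORS
) -> ResiduePairContext:
    """Window the two sequences around a candidate pair.

    ``i`` and ``j`` are 0-based positions; both centers must lie within
    their sequences and be standard residues.
    """
    if not 0 <= i < len(seq_a):
        raise IndexError(f"center {i} out of bounds for sequence of length {len(seq_a)}")
    if not 0 <= j < len(seq_b):
        raise IndexError(f"center {j} out of bounds for sequence of length {len(seq_b)}")
    if k < 0:
        raise ValueError("k must be >= 0")
    return ResiduePairContext(
        window_a=_window(seq_a, i, k),
        window_b=_window(seq_b, j, k),
        k=k,
        pos_a=i,
        pos_b=j,
    )


def enumerate_candidates(
    seq_a: str, seq_b: str, k: int = DEFAULT_NEIGHBORS
) -> Iterator[ResiduePairContext]:
    """All |A| x |B| candidate contexts in row-major order (i outer, j inner).

    Positions whose letter is not a standard residue are skipped (they
    cannot be a window center).
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    for i in range(len(seq_a)):
        if seq_a[i] not in INDEX:
            continue
        for j in range(len(seq_b)):
            if seq_b[j] not in INDEX:
                continue
            yield extract_context(seq_a, i, seq_b, j, k)


def feature_length(k: int, n_components: int = 6) -> int:
    """Dimensionality of the encoding: 3 * M * (2k+1)."""
    return 3 * n_components * (2 * k + 1)


def assemble_feature_vector(
    context: ResiduePairContext,
    projections: pd.DataFrame,
    rsrvs: Sequence[ReprojectedMatrix | np.ndarray],
    symmetric_average: bool = True,
) -> np.ndarray:
    """Encode one candidate pair against the deep-knowledge tables.

    Parameters
    ----------
    context
        The windowed candidate pair.
    projections
        Residue-indexed score table with one column per component
        (``projection_table`` output).
    rsrvs
        One re-projected residual matrix per component, in PC order.
    symmetric_average
        Average the (a, b) and (b, a) entries of each re-projected matrix
        (default); if False the ordered (a, b) entry is used as-is.
    """
    n_pcs = projections.shape[1]
    if len(rsrvs) < n_pcs:
        raise ValueError(
            f"need re-projected matrices for all {n_pcs} components, got {len(rsrvs)}"
        )
    mats = [m.rsrv if isinstance(m, ReprojectedMatrix) else np.asarray(m) for m in rsrvs]
    scores = projections.to_numpy()
    row_of = {aa: r for r, aa in enumerate(projections.index)}

    width = 2 * context.k + 1
    block1 = np.zeros((2 * width, n_pcs))
    for slot, letter in enumerate(context.window_a + context.window_b):
        r = row_of.get(letter)
        if r is not None:
            block1[slot] = scores[r, :n_pcs]

    block2 = np.zeros((width, n_pcs))
    for p, (a, b) in enumerate(context.aligned_pairs()):
        ra, rb = row_of.get(a), row_of.get(b)
        if ra is None or rb is None:
            continue  # pad or unknown letter: zero features
        for m in range(n_pcs):
            entry = mats[m][ra, rb]
            if symmetric_average:
                entry = 0.5 * (entry + mats[m][rb, ra])
            block2[p, m] = entry

    return np.concatenate([block1.ravel(), block2.ravel()])


@dataclass
class DeepKnowledge:
    """The disentangled statistics a predictor is built on.

    Bundles the residual space of the training contacts, its
    principal-component model, the residue score table and the
    re-projected matrices of the retained components.
    """

    srv: ResidualMatrix
    model: PrincipalComponentModel
    projections: pd.DataFrame
    rsrvs: list[ReprojectedMatrix]

    @property
    def n_components(self) -> int:
        return self.model.n_components


def build_deep_knowledge(
    srv: ResidualMatrix, n_components: int = 6
) -> DeepKnowledge:
    """Decompose a residual space and precompute scores and re-projections."""
    from .decomposition import decompose

    model = decompose(srv, n_components=n_components)
    return DeepKnowledge(
        srv=srv,
        model=model,
        projections=projection_table(srv, model),
        rsrvs=reprojected_spaces(srv, model),
    )


def featurize_candidates(
    contexts: Sequence[ResiduePairContext],
    knowledge: DeepKnowledge,
    symmetric_average: bool = True,
) -> np.ndarray:
    """Stack the encodings of many candidates into an (n, d) matrix."""
    if not contexts:
        k = 0
        return np.zeros((0, feature_length(k, knowledge.n_components)))
    return np.stack(
        [
            assemble_feature_vector(
                ctx, knowledge.projections, knowledge.rsrvs, symmetric_average
            )
            for ctx in contexts
        ]
    )
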
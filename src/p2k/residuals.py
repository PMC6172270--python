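"""Statistical residual vector space (SRV) of a contact frequency matrix.

Each observed contact count o_ij is compared with the count expected if
residue types met at random given the matrix margins, e_ij = r_i c_j / N.
The deviation is expressed as an adjusted standardized residual

    d_ij = (o_ij - e_ij) / sqrt( e_ij (1 - r_i/N) (1 - c_j/N) )

which is approximately standard normal under independence, so |d_ij| > 1.96
marks a residue-type pairing as enriched (positive) or depleted (negative)
at the 95% confidence level.  The residual matrix is treated as a vector
space whose rows — one 20-vector per residue type — are the inputs to the
principal-component analysis downstream.

A plain standardized residual (o - e)/sqrt(e) is available for sensitivity
analysis via ``kind="standardized"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import ALPHABET
from .contacts import ContactFrequencyMatrix

DEFAULT_Z = 1.96

POSITIVE_SIGNIFICANT = 1
IRRELEVANT = 0
NEGATIVE_SIGNIFICANT = -1

_MASK_SYMBOLS = {POSITIVE_SIGNIFICANT: "+", NEGATIVE_SIGNIFICANT: "-", IRRELEVANT: "."}


@dataclass
class ResidualMatrix:
    """Adjusted standardized residuals of a contact frequency matrix.

    ``residuals`` houses the statistical residuals d_ij; ``expected`` the
    independence expectations e_ij.  ``undefined`` flags cells whose
    expectation or variance is zero — their residual is stored as 0 and they
    never enter significance classification.
    """

    residuals: np.ndarray
    expected: np.ndarray
    row_totals: np.ndarray
    column_totals: np.ndarray
    grand_total: float
    undefined: np.ndarray
    alphabet_order: str = ALPHABET
    kind: str = "adjusted"

    def to_frame(self) -> pd.DataFrame:
        letters = list(self.alphabet_order)
        return pd.DataFrame(self.residuals, index=letters, columns=letters)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="")

    @classmethod
    def from_tsv(cls, path) -> "ResidualMatrix":
        """Load a residual matrix written by :meth:`to_tsv`.

        Margins and expectations are not stored in the TSV; the loaded
        object carries the residuals only, which is all the decomposition
        stage needs.
        """
        frame = pd.read_csv(path, sep="\t", index_col=0)
        resid = frame.to_numpy(dtype=float)
        n = resid.shape[0]
        labels = [str(x) for x in frame.index]
        order = "".join(labels) if all(len(x) == 1 for x in labels) else tuple(labels)
        return cls(
            residuals=resid,
            expected=np.full((n, n), np.nan),
            row_totals=np.full(n, np.nan),
            column_totals=np.full(n, np.nan),
            grand_total=float("nan"),
            undefined=np.zeros((n, n), dtype=bool),
            alphabet_order=order,
        )


@dataclass
class SignificanceMask:
    """Per-cell significance classes at threshold z (default 1.96).

    ``classes`` holds +1 (residual > z), -1 (residual < -z) or 0; the
    inequalities are strict, so a residual exactly at +-z is irrelevant.
    """

    classes: np.ndarray
    threshold: float = DEFAULT_Z
    alphabet_order: str = ALPHABET

    def to_frame(self) -> pd.DataFrame:
        letters = list(self.alphabet_order)
        symbols = np.vectorize(_MASK_SYMBOLS.get)(self.classes)
        return pd.DataFrame(symbols, index=letters, columns=letters)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="")


def _as_counts(table: ContactFrequencyMatrix | np.ndarray) -> tuple[np.ndarray, str | tuple]:
    if isinstance(table, ContactFrequencyMatrix):
        return table.counts.astype(float), table.alphabet_order
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ValueError("count table must be 2-dimensional")
    return counts, tuple(f"r{i + 1}" for i in range(counts.shape[0]))


def expected_frequency(cfm: ContactFrequencyMatrix | np.ndarray) -> np.ndarray:
    """Independence expectation e_ij = r_i c_j / N from the matrix margins.

    Accepts the 20x20 contact matrix or any plain 2-D count table.
    """
    counts, _ = _as_counts(cfm)
    grand = counts.sum()
    if grand <= 0:
        raise ValueError("expected frequencies undefined for an all-zero matrix")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    return np.outer(rows, cols) / grand


def statistical_residuals(
    cfm: ContactFrequencyMatrix | np.ndarray, kind: str = "adjusted"
) -> ResidualMatrix:
    """Convert contact counts into the statistical residual matrix.

    Parameters
    ----------
    cfm
        The 20x20 contact frequency matrix, or any plain 2-D count table.
    kind
        ``"adjusted"`` (default) for the margin-corrected adjusted
        standardized residual; ``"standardized"`` for the plain
        (o - e)/sqrt(e) variant.
    """
    if kind not in ("adjusted", "standardized"):
        raise ValueError(f"unknown residual kind {kind!r}")
    counts, order = _as_counts(cfm)
    grand = counts.sum()
    if grand <= 0:
        raise ValueError("residuals undefined for an all-zero matrix")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    expected = np.outer(rows, cols) / grand

    if kind == "adjusted":
        variance = expected * np.outer(1.0 - rows / grand, 1.0 - cols / grand)
    else:
        variance = expected.copy()

    undefined = variance <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        residuals = (counts - expected) / np.sqrt(variance)
    residuals[undefined] = 0.0

    return ResidualMatrix(
        residuals=residuals,
        expected=expected,
        row_totals=rows,
        column_totals=cols,
        grand_total=grand,
        undefined=undefined,
        alphabet_order=order,
        kind=kind,
    )


def classify_significance(
    srv: ResidualMatrix, z: float = DEFAULT_Z
) -> SignificanceMask:
    """Classify each cell as enriched, depleted or irrelevant at level z."""
    classes = np.zeros(srv.residuals.shape, dtype=np.int8)
    classes[srv.residuals > z] = POSITIVE_SIGNIFICANT
    classes[srv.residuals < -z] = NEGATIVE_SIGNIFICANT
    classes[srv.undefined] = IRRELEVANT
    return SignificanceMask(
        classes=classes, threshold=z, alphabet_order=srv.alphabet_order
    )
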
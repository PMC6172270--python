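"""Principal-component decomposition of the statistical residual space.

The rows of the residual matrix (one residue vector per residue type) are
treated as observations and its columns as variables.  Columns are centered
by their means and the sample covariance is eigendecomposed; no variance
scaling is applied, because the residuals already share a common statistical
scale.  Projecting the residue vectors onto a component gives each residue a
scalar score on that axis; re-projecting the scores back through the
component's loadings (an outer product, without re-adding the means) yields
a rank-1 matrix in the original residue-by-residue coordinates — the
re-projected residual space that exposes which pairings the component
captures.

Principal components are numbered from 1 in all public interfaces, matching
how they are discussed (PC1, PC2, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .residuals import ResidualMatrix

DEFAULT_N_COMPONENTS = 6


@dataclass
class PrincipalComponentModel:
    """Centered covariance eigendecomposition of a residual matrix.

    ``components[m]`` is the (unit-norm) loading vector of PC ``m+1``;
    eigenvalues are sorted descending and variance fractions are relative to
    the total variance (trace of the covariance), so they sum to at most 1.
    The sign of each component is fixed so its largest-magnitude loading is
    positive; quantities that depend on the sign are comparable across runs
    but may differ by a global sign from other software.
    """

    column_means: np.ndarray
    components: np.ndarray  # (n_components, n_variables)
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    n_components: int
    labels: list[str]

    def component(self, pc: int) -> np.ndarray:
        """Loading vector of 1-based component ``pc``."""
        if not 1 <= pc <= self.n_components:
            raise ValueError(
                f"pc must be in 1..{self.n_components}, got {pc}"
            )
        return self.components[pc - 1]

    def to_json(self, path) -> None:
        payload = {
            "labels": self.labels,
            "column_means": self.column_means.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "components": self.components.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PrincipalComponentModel":
        with open(path) as fh:
            payload = json.load(fh)
        components = np.asarray(payload["components"], dtype=float)
        return cls(
            column_means=np.asarray(payload["column_means"], dtype=float),
            components=components,
            eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
            variance_fractions=np.asarray(payload["variance_fractions"], dtype=float),
            n_components=components.shape[0],
            labels=list(payload["labels"]),
        )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|loading| entry is positive."""
    fixed = components.copy()
    for m in range(fixed.shape[0]):
        pivot = np.argmax(np.abs(fixed[m]))
        if fixed[m, pivot] < 0:
            fixed[m] = -fixed[m]
    return fixed


def decompose(
    srv: ResidualMatrix | np.ndarray,
    n_components: int = DEFAULT_N_COMPONENTS,
    labels: list[str] | None = None,
) -> PrincipalComponentModel:
    """Eigendecompose the column-centered covariance of the residual rows.

    Accepts a :class:`ResidualMatrix` or a bare 2-D array whose rows are the
    observations.  ``n_components`` components are retained (at most the
    number of variables).  The covariance uses the n-1 divisor; the divisor
    does not affect loadings or scores, only the reported eigenvalues.
    """
    if isinstance(srv, ResidualMatrix):
        data = srv.residuals
        labels = labels if labels is not None else list(srv.alphabet_order)
    else:
        data = np.asarray(srv, dtype=float)
        if labels is None:
            labels = [f"row{i + 1}" for i in range(data.shape[0])]
    n_obs, n_var = data.shape
    if not 1 <= n_components <= n_var:
        raise ValueError(f"n_components must be in 1..{n_var}, got {n_components}")

    means = data.mean(axis=0)
    centered = data - means
    cov = centered.T @ centered / max(n_obs - 1, 1)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    components = _fix_signs(eigenvectors[:, order].T)

    total_variance = np.trace(cov)
    fractions = (
        eigenvalues / total_variance if total_variance > 0 else np.zeros_like(eigenvalues)
    )
    return PrincipalComponentModel(
        column_means=means,
        components=components[:n_components],
        eigenvalues=eigenvalues[:n_components],
        variance_fractions=fractions[:n_components],
        n_components=n_components,
        labels=labels,
    )


def project(
    srv: ResidualMatrix | np.ndarray,
    model: PrincipalComponentModel,
    pc: int,
) -> np.ndarray:
    """Score each residue vector on 1-based component ``pc``.

    The score of row i is ``(row_i - mu) . v_pc``; scores sum to zero when
    the input is the matrix the model was fitted on.
    """
    data = srv.residuals if isinstance(srv, ResidualMatrix) else np.asarray(srv, float)
    return (data - model.column_means) @ model.component(pc)


def projection_table(
    srv: ResidualMatrix | np.ndarray, model: PrincipalComponentModel
) -> pd.DataFrame:
    """Scores of every residue vector on every retained component.

    Rows are labeled by the model's row labels, columns ``PC1..PCM``.
    """
    data = srv.residuals if isinstance(srv, ResidualMatrix) else np.asarray(srv, float)
    scores = (data - model.column_means) @ model.components.T
    return pd.DataFrame(
        scores,
        index=model.labels,
        columns=[f"PC{m}" for m in range(1, model.n_components + 1)],
    )


@dataclass
class ReprojectedMatrix:
    """Rank-1 re-projection of one component's scores into residue space."""

    rsrv: np.ndarray
    pc_index: int
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rsrv, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="")


def reproject(
    scores: np.ndarray, model: PrincipalComponentModel, pc: int
) -> ReprojectedMatrix:
    """Map component scores back to the original coordinates.

    The result is the outer product ``scores (x) v_pc``; column means are
    deliberately not re-added, so the matrix isolates exactly the structure
    the component carries.
    """
    scores = np.asarray(scores, dtype=float)
    v = model.component(pc)
    if scores.shape != (len(model.labels),):
        raise ValueError(
            f"scores must have length {len(model.labels)}, got {scores.shape}"
        )
    return ReprojectedMatrix(rsrv=np.outer(scores, v), pc_index=pc, labels=model.labels)


def reprojected_spaces(
    srv: ResidualMatrix | np.ndarray, model: PrincipalComponentModel
) -> list[ReprojectedMatrix]:
    """Re-projected matrix for every retained component, in PC order."""
    return [
        reproject(project(srv, model, pc), model, pc)
        for pc in range(1, model.n_components + 1)
    ]


def correlate_projection_with_scale(
    scores: pd.Series | dict, scale: pd.Series | dict
) -> tuple[float, float]:
    """Pearson correlation between component scores and a residue property.

    Both inputs are residue-indexed; the correlation runs over the residues
    they share.  Returns ``(r, two-sided p)`` from the usual t-distributed
    test.

    Raises
    ------
    ValueError
        On fewer than 3 shared residues, or zero variance in either input.
    """
    scores = pd.Series(scores, dtype=float)
    scale = pd.Series(scale, dtype=float)
    shared = scores.index.intersection(scale.index)
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared residues, got {len(shared)}")
    x = scores.loc[shared].to_numpy()
    y = scale.loc[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)
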
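"""Jaccard dissimilarity and principal coordinates (PCO) ordination.

The binary presence/absence matrix is turned into pairwise Jaccard
dissimilarities d(i,j) = 1 - |Ai & Aj| / |Ai | Aj|, then embedded by
classical (Gower-centered) principal coordinates analysis; the variance
explained by each axis is the share of its eigenvalue among the positive
eigenvalues.  Negative eigenvalues (a non-Euclidean dissimilarity) are
reported but excluded from the variance denominator, and no Cailliez or
Lingoes correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .pathways import PresenceAbsenceMatrix

#: eigenvalues within this relative tolerance of zero are treated as null axes
_EIG_TOL = 1e-9


@dataclass
class DissimilarityMatrix:
    genome_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.genome_ids):
            raise ValueError("dissimilarity matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("Jaccard dissimilarities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genome_ids, columns=self.genome_ids)


def jaccard(matrix: PresenceAbsenceMatrix) -> DissimilarityMatrix:
    """Pairwise binary Jaccard dissimilarity between genome rows.

    A pair of genomes with no features at all is defined as distance 0
    (identical emptiness) and triggers a warning, since feature-free genomes
    are degenerate inputs.
    """
    x = matrix.data.to_numpy()
    if x.shape[0] < 2:
        raise ValueError("need at least 2 genomes")
    if not ((x == 0) | (x == 1)).all():
        raise ValueError("matrix must be binary")
    x = x.astype(float)
    inter = x @ x.T
    row_sums = x.sum(axis=1)
    union = row_sums[:, None] + row_sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    empty_pairs = union == 0
    if empty_pairs.any():
        n_empty = int((row_sums == 0).sum())
        warnings.warn(
            f"{n_empty} genome(s) have no features; both-empty pairs get distance 0"
        )
        d[empty_pairs] = 0.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DissimilarityMatrix(matrix.genome_ids, d)


@dataclass
class OrdinationResult:
    """PCO embedding: coordinates for positive axes, all eigenvalues."""

    coordinates: pd.DataFrame  # genomes x positive axes
    eigenvalues: np.ndarray  # all, descending
    variance_explained: np.ndarray  # percent per positive axis

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pco(D: DissimilarityMatrix) -> OrdinationResult:
    """Classical PCO: Gower double-centering of -D^2/2 + eigendecomposition.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues only.  The sign of each axis is fixed by making its
    largest-magnitude coordinate positive; among equal magnitudes the
    earliest genome (input order) wins, so the output is deterministic.
    """
    d = D.values
    n = d.shape[0]
    a = -0.5 * d * d
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    b = (b + b.T) / 2.0
    eigvals, eigvecs = eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    positive = eigvals > _EIG_TOL * scale
    pos_vals = eigvals[positive]
    pos_vecs = eigvecs[:, positive]
    coords = pos_vecs * np.sqrt(pos_vals)[None, :]
    for j in range(coords.shape[1]):
        col = coords[:, j]
        pivot = np.argmax(np.abs(col))
        if col[pivot] < 0:
            coords[:, j] = -col
    total_pos = pos_vals.sum()
    var = 100.0 * pos_vals / total_pos if total_pos > 0 else np.zeros_like(pos_vals)
    frame = pd.DataFrame(
        coords,
        index=D.genome_ids,
        columns=[f"PCO{j + 1}" for j in range(coords.shape[1])],
    )
    return OrdinationResult(frame, eigenvalues=eigvals, variance_explained=var)


def variance_explained(result: OrdinationResult, axis: int) -> float:
    """Percent of variance on 1-based ``axis``: 100 * l_axis / sum(positive l)."""
    if not (1 <= axis <= len(result.eigenvalues)):
        raise ValueError("axis out of range")
    if axis > result.n_axes:
        raise ValueError(f"axis {axis} has a non-positive eigenvalue")
    return float(result.variance_explained[axis - 1])


def plot_ordination(
    result: OrdinationResult,
    taxon_map: dict[str, str] | None = None,
    path=None,
    axes: tuple[int, int] = (1, 2),
):
    """Scatter of two PCO axes, coloured by taxon group; saves to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax1, ax2 = axes
    fig, ax = plt.subplots(figsize=(6, 5))
    coords = result.coordinates
    groups = (
        sorted({taxon_map[g] for g in coords.index})
        if taxon_map
        else ["all"]
    )
    for group in groups:
        if taxon_map:
            idx = [g for g in coords.index if taxon_map[g] == group]
        else:
            idx = list(coords.index)
        ax.scatter(
            coords.loc[idx, f"PCO{ax1}"],
            coords.loc[idx, f"PCO{ax2}"],
            label=group,
            s=25,
            alpha=0.8,
        )
    ax.set_xlabel(f"PCO{ax1} ({variance_explained(result, ax1):.1f}%)")
    ax.set_ylabel(f"PCO{ax2} ({variance_explained(result, ax2):.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
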
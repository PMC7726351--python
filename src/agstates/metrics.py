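"""Compositional transforms, Bray-Curtis distances and PCoA ordination.

Bray-Curtis on relative-abundance rows equals half the L1 distance and is
bounded by [0, 1]. PCoA is classical scaling of the double-centred squared
distance matrix; Bray-Curtis is non-Euclidean, so negative eigenvalues can
occur — they are kept in the eigenvalue report but excluded from the
coordinates and from the variance-explained denominator.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import AbundanceTable, ValidationError


def hellinger(table: AbundanceTable) -> AbundanceTable:
    """Square-root transform of a proportions table.

    Each output row has unit Euclidean norm (zero rows stay zero), which
    makes Euclidean distances on the result ecologically well-behaved.
    """
    if table.unit != "proportions":
        raise ValidationError("hellinger requires a proportions table")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return AbundanceTable(np.sqrt(table.data), unit="hellinger")


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix: BC(x, y) = sum|x-y| / sum(x+y)."""
    zero = table.zero_sum_samples()
    if zero:
        raise ValidationError(
            f"Bray-Curtis undefined for all-zero sample(s): {zero}; drop them first"
        )
    if len(table.sample_ids) < 2:
        raise ValidationError("Bray-Curtis needs at least two samples")
    condensed = pdist(table.data.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed, checks=False), ids=table.sample_ids)


@dataclass
class Ordination:
    """PCoA result: sample coordinates on the retained (positive) axes."""

    samples: pd.DataFrame  # samples x axes, columns PCo1, PCo2, ...
    eigvals: pd.Series  # all eigenvalues, decreasing (negatives included)
    proportion_explained: pd.Series  # per retained axis, over positive eigvals


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical scaling (principal coordinates analysis).

    Coordinates are built only from positive eigenvalues; the fraction of
    variance explained per axis is taken relative to the sum of positive
    eigenvalues. Requesting more axes than there are positive eigenvalues
    truncates with a warning.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    # double-centre -0.5 * D^2
    b = -0.5 * d**2
    row = b.mean(axis=0)
    b = b - row[None, :] - row[:, None] + b.mean()
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    n_pos = int(np.sum(eigvals > tol))
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    axes = [f"PCo{i + 1}" for i in range(n_axes)]
    pos_sum = eigvals[:n_pos].sum() if n_pos else 1.0
    return Ordination(
        samples=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigvals=pd.Series(eigvals, index=[f"PCo{i + 1}" for i in range(n)]),
        proportion_explained=pd.Series(eigvals[:n_axes] / pos_sum, index=axes),
    )


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_ordination(ordination: Ordination, path: str | Path) -> None:
    """Write coordinates plus an eigenvalue sidecar (<path>.eigvals.tsv)."""
    ordination.samples.to_csv(path, sep="\t", index_label="sample_id")
    side = pd.DataFrame({"eigval": ordination.eigvals})
    side["proportion_explained"] = ordination.proportion_explained.reindex(side.index)
    side.to_csv(str(path) + ".eigvals.tsv", sep="\t", index_label="axis")
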
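"""Post-processing of clustering/annotation outputs.

Two steps sit between the external clustering + similarity search and the
community analysis: a cluster-retention filter on per-sample sequence
counts, and truncation of each cluster's best-hit lineage to the deepest
taxonomic rank supported by its percent identity (Yarza-style thresholds:
94.5 genus, 86.5 family, 82.0 order, 78.5 class, 75.0 phylum).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import AbundanceTable, ValidationError

#: taxonomic ranks from shallowest to deepest
RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class RankThresholds:
    """Minimum best-hit percent identity required to keep each rank."""

    genus: float = 94.5
    family: float = 86.5
    order: float = 82.0
    class_: float = 78.5
    phylum: float = 75.0

    def __post_init__(self) -> None:
        seq = [getattr(self, r if r != "class" else "class_") for r in reversed(RANKS)]
        if not all(a > b for a, b in zip(seq, seq[1:])):
            raise ValidationError("rank thresholds must strictly decrease from genus to phylum")

    def threshold(self, rank: str) -> float:
        return getattr(self, rank if rank != "class" else "class_")

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "RankThresholds":
        return cls(**{(k if k != "class" else "class_"): v for k, v in d.items()})


def supported_rank(identity: float, thresholds: RankThresholds | None = None) -> str | None:
    """Deepest rank whose identity threshold the best hit meets (inclusive).

    Returns ``None`` when the identity falls below the phylum threshold.
    """
    thresholds = thresholds or RankThresholds()
    if not 0 <= identity <= 100:
        raise ValidationError(f"percent identity {identity} outside [0, 100]")
    for rank in reversed(RANKS):  # genus first
        if identity >= thresholds.threshold(rank):
            return rank
    return None


def truncate_lineage(
    lineage: Mapping[str, str],
    identity: float,
    thresholds: RankThresholds | None = None,
) -> dict[str, str]:
    """Replace ranks deeper than the supported one with placeholders.

    The placeholder ``<parent>_unclassified_<rank>`` carries the name of
    the deepest retained ancestor so that aggregation at a deep rank keeps
    shallow-rank information (e.g. a family-only hit aggregates into a
    single family-labelled genus bin).
    """
    keep = supported_rank(identity, thresholds)
    keep_depth = RANKS.index(keep) if keep is not None else -1
    out: dict[str, str] = {}
    parent = ""
    for depth, rank in enumerate(RANKS):
        if depth <= keep_depth:
            name = str(lineage.get(rank, "") or "")
            out[rank] = name
            if name:
                parent = name
        else:
            out[rank] = f"{parent}_unclassified_{rank}" if parent else f"unclassified_{rank}"
    return out


def filter_clusters(
    counts: pd.DataFrame,
    min_per_sample: int = 5,
    require_all_samples: bool = False,
) -> pd.DataFrame:
    """Apply the cluster-retention filter to a clusters x samples count table.

    A cluster is retained iff its count reaches ``min_per_sample`` in at
    least one sample (permissive default); ``require_all_samples=True``
    demands it in every sample.
    """
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        as_float = counts.to_numpy(dtype=float)
        if not np.allclose(as_float, np.round(as_float)):
            raise ValidationError("cluster counts must be integers")
        values = np.round(as_float).astype(np.int64)
    if np.any(values < 0):
        raise ValidationError("cluster counts must be non-negative")
    if require_all_samples:
        keep = (values >= min_per_sample).all(axis=1)
    else:
        keep = (values >= min_per_sample).any(axis=1)
    return counts.loc[keep]


def read_best_hits(path: str | Path) -> pd.DataFrame:
    """Read a tabular best-hit table (cluster_id, identity, lineage ranks)."""
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str})
    needed = {"cluster_id", "identity"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"best-hit table missing column(s): {sorted(missing)}")
    return df.set_index("cluster_id")


def assign_taxonomy(
    best_hits: pd.DataFrame,
    thresholds: RankThresholds | None = None,
) -> pd.DataFrame:
    """Truncate every cluster's lineage; returns a cluster x rank frame."""
    rows = {}
    for cluster_id, row in best_hits.iterrows():
        lineage = {r: row.get(r, "") for r in RANKS}
        rows[cluster_id] = truncate_lineage(lineage, float(row["identity"]), thresholds)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))


def aggregate_rank(
    table: AbundanceTable,
    lineages: pd.DataFrame,
    rank: str = "genus",
) -> AbundanceTable:
    """Sum cluster columns sharing the same (possibly placeholder) rank name.

    Total abundance per sample is conserved exactly; clusters without a
    lineage entry are pooled under ``unassigned``.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}")
    labels = [
        str(lineages.loc[t, rank]) if t in lineages.index else "unassigned"
        for t in table.taxon_ids
    ]
    grouped = table.data.T.groupby(pd.Index(labels, name=rank), sort=True).sum().T
    return AbundanceTable(grouped, unit=table.unit)
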
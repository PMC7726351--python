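"""Tabular I/O: abundance tables, sample metadata, run configuration.

All tables are UTF-8 tab-separated. Abundance tables are held internally as
samples x taxa :class:`pandas.DataFrame` with a unit flag; proportions are
always on the 0-1 scale (percent values are converted at the config
boundary, never inside the analysis code).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

WASTEWATER_TYPES = ("simple", "complex_monomeric", "complex_polymeric", "transition")
FRACTIONS = ("mixed", "granules", "flocs")
METADATA_COLUMNS = ("sample_id", "reactor_id", "day", "wastewater_type", "fraction")

#: units an AbundanceTable may carry. "hellinger" marks square-root
#: transformed proportions (rows have unit Euclidean norm, not unit sum).
UNITS = ("counts", "proportions", "hellinger")


class ValidationError(ValueError):
    """Raised when a table or metadata set violates its invariants."""


@dataclass
class AbundanceTable:
    """A samples x taxa abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id, columns are taxon ids.
    unit:
        One of ``counts``, ``proportions`` or ``hellinger``.
    """

    data: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon id(s): {dupes}")
        values = self.data.to_numpy(dtype=float)
        if np.any(values < 0):
            bad = self.data.index[(values < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative abundance values in sample(s): {bad}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite abundance values")
        zero = self.zero_sum_samples()
        if zero:
            warnings.warn(f"sample(s) with all-zero abundances retained: {zero}", stacklevel=2)
        if self.unit == "proportions":
            sums = values.sum(axis=1)
            off = ~np.isclose(sums, 1.0, rtol=0, atol=1e-9) & (sums > 0)
            if np.any(off):
                bad = self.data.index[off].tolist()
                raise ValidationError(f"proportion rows do not sum to 1: {bad}")
        elif self.unit == "hellinger":
            norms = np.sqrt((values**2).sum(axis=1))
            off = ~np.isclose(norms, 1.0, rtol=0, atol=1e-9) & (norms > 0)
            if np.any(off):
                bad = self.data.index[off].tolist()
                raise ValidationError(f"hellinger rows do not have unit norm: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def taxon_ids(self) -> list[str]:
        return self.data.columns.tolist()

    def zero_sum_samples(self) -> list[str]:
        sums = self.data.to_numpy(dtype=float).sum(axis=1)
        return self.data.index[sums == 0].tolist()

    def to_proportions(self) -> "AbundanceTable":
        """Row-normalize to relative abundances (idempotent).

        All-zero rows are kept as zeros (they are flagged at construction
        and excluded from distance computations downstream).
        """
        if self.unit == "hellinger":
            raise ValidationError("cannot normalize a hellinger-transformed table")
        sums = self.data.sum(axis=1)
        safe = sums.replace(0, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-row warning already issued once
            return AbundanceTable(self.data.div(safe, axis=0), unit="proportions")

    def subset(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"unknown sample id(s): {missing}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return AbundanceTable(self.data.loc[list(sample_ids)], unit=self.unit)


def read_abundance_table(
    path: str | Path,
    unit: str = "counts",
    orientation: str = "samples",
    metadata: pd.DataFrame | None = None,
) -> AbundanceTable:
    """Read a tab-separated abundance table.

    ``orientation`` is ``samples`` (samples in rows), ``taxa`` (taxa in
    rows; the table is transposed) or ``auto`` (resolved against
    ``metadata`` sample ids; requires metadata).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "auto":
        if metadata is None:
            raise ValidationError("orientation='auto' requires a metadata table")
        known = set(metadata["sample_id"].astype(str))
        if set(df.index) <= known:
            pass
        elif set(df.columns) <= known:
            df = df.T
        else:
            raise ValidationError("could not auto-detect orientation from metadata sample ids")
    elif orientation == "taxa":
        df = df.T
    elif orientation != "samples":
        raise ValidationError(f"unknown orientation {orientation!r}")
    return AbundanceTable(df.astype(float), unit=unit)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "reactor_id": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing column(s): {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate metadata sample id(s): {dupes}")
    if (meta["day"].astype(int) < 0).any():
        raise ValidationError("metadata days must be >= 0")
    bad_ww = set(meta["wastewater_type"]) - set(WASTEWATER_TYPES)
    if bad_ww:
        raise ValidationError(f"unknown wastewater_type value(s): {sorted(bad_ww)}")
    bad_fr = set(meta["fraction"]) - set(FRACTIONS)
    if bad_fr:
        raise ValidationError(f"unknown fraction value(s): {sorted(bad_fr)}")
    meta = meta.copy()
    meta["day"] = meta["day"].astype(int)
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


@dataclass
class Dataset:
    """An abundance table joined with its per-sample metadata.

    ``meta`` is indexed by sample id and row-aligned with ``table.data``.
    """

    table: AbundanceTable
    meta: pd.DataFrame

    def filter(
        self,
        fraction: str | None = None,
        wastewater_type: str | None = None,
        reactor_id: str | None = None,
    ) -> "Dataset":
        mask = pd.Series(True, index=self.meta.index)
        if fraction is not None:
            mask &= self.meta["fraction"] == fraction
        if wastewater_type is not None:
            mask &= self.meta["wastewater_type"] == wastewater_type
        if reactor_id is not None:
            mask &= self.meta["reactor_id"] == reactor_id
        ids = self.meta.index[mask].tolist()
        return Dataset(self.table.subset(ids), self.meta.loc[ids])

    def temporal_order(self) -> list[str]:
        """Sample ids sorted by (day, reactor_id) — the pooled succession order."""
        return self.meta.sort_values(["day", "reactor_id"], kind="stable").index.tolist()

    def sort_temporal(self) -> "Dataset":
        order = self.temporal_order()
        return Dataset(self.table.subset(order), self.meta.loc[order])


def join_metadata(table: AbundanceTable, meta: pd.DataFrame) -> Dataset:
    meta = validate_metadata(meta)
    indexed = meta.set_index("sample_id")
    missing = [s for s in table.sample_ids if s not in indexed.index]
    if missing:
        raise ValidationError(f"sample(s) missing from metadata: {missing}")
    return Dataset(table, indexed.loc[table.sample_ids])


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Analysis parameters.

    Proportion-like parameters are stored on the 0-1 scale; the YAML
    surface accepts ``*_percent`` keys which are divided by 100 on load.
    """

    state_threshold: float = 0.5
    state_min_size: int = 4
    alpha: float = 0.01
    abundance_cutoff: float = 0.01  # 1 %
    pseudo_count: float = 0.005  # 0.5 %
    rank_thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "genus": 94.5,
            "family": 86.5,
            "order": 82.0,
            "class": 78.5,
            "phylum": 75.0,
        }
    )
    fraction_min_samples: int = 4
    join_tolerance_days: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.state_threshold < 1:
            raise ValidationError("state_threshold must be in (0, 1)")
        if self.state_min_size < 2:
            raise ValidationError("state_min_size must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for pct_key, key in (
            ("abundance_cutoff_percent", "abundance_cutoff"),
            ("pseudo_count_percent", "pseudo_count"),
        ):
            if pct_key in raw:
                raw[key] = raw.pop(pct_key) / 100.0
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    def as_dict(self) -> dict:
        return {
            "state_threshold": self.state_threshold,
            "state_min_size": self.state_min_size,
            "alpha": self.alpha,
            "abundance_cutoff": self.abundance_cutoff,
            "pseudo_count": self.pseudo_count,
            "rank_thresholds": dict(self.rank_thresholds),
            "fraction_min_samples": self.fraction_min_samples,
            "join_tolerance_days": self.join_tolerance_days,
            "seed": self.seed,
        }
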
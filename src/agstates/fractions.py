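"""Granule vs floc enrichment within a stable state.

Within a state where granule and floc sub-samples were collected
separately for at least four samples per fraction, the mean proportions
of the abundant taxa are compared with two-sided t-tests on pseudo-counted
abundances (a 0.5 % pseudo-count damps noise in very low-abundance taxa),
Bonferroni-corrected over the number of taxa actually compared.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset, ValidationError
from .states import StableState


class StateSkipped(RuntimeError):
    """Raised when a state lacks the sample support for the comparison."""


def compare_fractions(
    dataset: Dataset,
    state: StableState,
    taxa: list[str] | None = None,
    alpha: float = 0.01,
    pseudo: float = 0.005,
    min_samples: int = 4,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-taxon granule/floc comparison inside one stable state.

    ``taxa`` restricts the comparison (normally to the abundant taxa);
    the Bonferroni threshold is ``alpha / n_taxa_compared``. Enrichment
    direction is the sign of the pseudo-counted log2 ratio
    granules / flocs (positive = granule-enriched).
    """
    if state.start_day is None or state.end_day is None:
        raise ValidationError("state must carry day annotations")
    table = dataset.table.to_proportions() if dataset.table.unit == "counts" else dataset.table
    meta = dataset.meta
    in_span = (meta["day"] >= state.start_day) & (meta["day"] <= state.end_day)
    sub = meta[in_span & meta["fraction"].isin(["granules", "flocs"])]
    gran_ids = sub.index[sub["fraction"] == "granules"].tolist()
    floc_ids = sub.index[sub["fraction"] == "flocs"].tolist()
    if len(gran_ids) < min_samples or len(floc_ids) < min_samples:
        raise StateSkipped(
            f"state {state.state_id}: {len(gran_ids)} granule / {len(floc_ids)} floc "
            f"samples, need >= {min_samples} per fraction"
        )
    cols = list(taxa) if taxa is not None else list(table.data.columns)
    missing = [t for t in cols if t not in table.data.columns]
    if missing:
        raise ValidationError(f"taxa absent from table: {missing}")
    gran = table.data.loc[gran_ids, cols].to_numpy() + pseudo
    floc = table.data.loc[floc_ids, cols].to_numpy() + pseudo
    threshold = alpha / len(cols)
    if paired:
        if len(gran_ids) != len(floc_ids):
            raise ValidationError("paired comparison needs equal granule/floc sample counts")
        test = stats.ttest_rel(gran, floc, axis=0)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            test = stats.ttest_ind(gran, floc, axis=0, equal_var=False)
    mean_g, mean_f = gran.mean(axis=0), floc.mean(axis=0)
    out = pd.DataFrame(
        {
            "state": state.state_id,
            "mean_granules": mean_g - pseudo,
            "mean_flocs": mean_f - pseudo,
            "log2_ratio": np.log2(mean_g / mean_f),
            "p_value": test.pvalue,
        },
        index=pd.Index(cols, name="taxon"),
    )
    out["significant"] = out["p_value"] < threshold
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_taxa_compared"] = len(cols)
    return out


def fraction_matrix(comparisons: list[pd.DataFrame]) -> pd.DataFrame:
    """Taxa x states matrix of signed enrichment (log2 ratio, * = significant)."""
    pieces = {}
    for comp in comparisons:
        state_id = comp["state"].iloc[0]
        pieces[f"state_{state_id}"] = comp.apply(
            lambda r: f"{r.log2_ratio:+.3f}{'*' if r.significant else ''}", axis=1
        )
    return pd.DataFrame(pieces)
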
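"""Divergent / abundant / discriminant taxon classification.

Stable-state samples are grouped by influent wastewater type. A taxon is
*divergent* when its Hellinger-transformed mean differs significantly
(two-sided Welch t-test, Bonferroni-corrected at alpha / n_taxa) between
at least one pair of wastewater types; *abundant* when its mean relative
abundance exceeds the cutoff (default 1 %) in at least one type at stable
state; and *discriminant* when it is both.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable, ValidationError
from .metrics import hellinger

#: the three influent regimes compared in the screen
COMPARED_TYPES = ("simple", "complex_monomeric", "complex_polymeric")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-comparison significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    return alpha / n_tests


def _pair_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised Welch t-test p-values per taxon (columns).

    Pairs where both groups have zero variance are degenerate: p is 1
    when the means agree and NaN (skipped) otherwise.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue
    zero_var = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    equal_means = np.isclose(a.mean(axis=0), b.mean(axis=0))
    p = np.where(zero_var & equal_means, 1.0, p)
    p = np.where(zero_var & ~equal_means, np.nan, p)
    return p


def group_samples(labels: pd.DataFrame) -> pd.Series:
    """Map stable-state samples to their state's wastewater type.

    Transition samples (no state) and states whose modal type is not one
    of the three compared influent regimes are excluded.
    """
    in_state = labels["state"] != "transition"
    grouped = labels.loc[in_state, "state_wastewater_type"]
    return grouped[grouped.isin(COMPARED_TYPES)].astype(str)


def divergent_taxa(
    table: AbundanceTable,
    groups: pd.Series,
    alpha: float = 0.01,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Pairwise Welch t-tests on Hellinger means between wastewater types.

    ``groups`` maps sample id -> wastewater type (stable-state samples
    only). ``n_tests`` defaults to the number of taxa, matching a
    Bonferroni correction over the taxon universe.
    """
    if table.unit == "counts":
        table = table.to_proportions()
    if table.unit == "proportions":
        table = hellinger(table)
    groups = groups.loc[[s for s in groups.index if s in table.data.index]]
    data = table.data.loc[groups.index]
    n_tests = n_tests if n_tests is not None else len(table.taxon_ids)
    threshold = bonferroni_threshold(alpha, n_tests)
    present = [t for t in COMPARED_TYPES if (groups == t).sum() > 0]
    result = pd.DataFrame(index=table.data.columns)
    for t in present:
        result[f"mean_hellinger_{t}"] = data.loc[groups[groups == t].index].mean(axis=0)
    pcols = []
    for t1, t2 in itertools.combinations(present, 2):
        a = data.loc[groups[groups == t1].index].to_numpy()
        b = data.loc[groups[groups == t2].index].to_numpy()
        col = f"p_{t1}_vs_{t2}"
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"pair {t1} vs {t2} skipped: fewer than 2 samples in a group", stacklevel=2
            )
            result[col] = np.nan
        else:
            result[col] = _pair_pvalues(a, b)
        pcols.append(col)
    pvals = result[pcols] if pcols else pd.DataFrame(index=result.index)
    result["min_p"] = pvals.min(axis=1) if pcols else np.nan
    result["divergent"] = (pvals < threshold).any(axis=1) if pcols else False
    result.attrs["bonferroni_threshold"] = threshold
    result.attrs["n_tests"] = n_tests
    return result


def abundant_taxa(
    table: AbundanceTable,
    groups: pd.Series,
    cutoff: float = 0.01,
) -> pd.DataFrame:
    """Mean raw relative abundance per type; abundant iff > cutoff somewhere."""
    if table.unit == "counts":
        table = table.to_proportions()
    if table.unit != "proportions":
        raise ValidationError("abundance screen needs raw relative abundances")
    groups = groups.loc[[s for s in groups.index if s in table.data.index]]
    data = table.data.loc[groups.index]
    present = [t for t in COMPARED_TYPES if (groups == t).sum() > 0]
    result = pd.DataFrame(index=table.data.columns)
    for t in present:
        result[f"mean_abundance_{t}"] = data.loc[groups[groups == t].index].mean(axis=0)
    means = result[[f"mean_abundance_{t}" for t in present]]
    result["abundant"] = (means > cutoff).any(axis=1) if present else False
    return result


def discriminant_taxa(
    divergent: pd.DataFrame, abundant: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Combine the two screens: discriminant = divergent AND abundant."""
    if not divergent.index.equals(abundant.index):
        raise ValidationError("divergent and abundant screens cover different taxon sets")
    merged = divergent.join(abundant)
    merged["discriminant"] = merged["divergent"] & merged["abundant"]
    summary = {
        "n_taxa": int(len(merged)),
        "n_divergent": int(merged["divergent"].sum()),
        "n_abundant": int(merged["abundant"].sum()),
        "n_discriminant": int(merged["discriminant"].sum()),
    }
    return merged, summary


def screen_taxa(
    table: AbundanceTable,
    labels: pd.DataFrame,
    alpha: float = 0.01,
    cutoff: float = 0.01,
    n_tests: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full screen from a genus-level table and per-sample state labels."""
    groups = group_samples(labels)
    div = divergent_taxa(table, groups, alpha=alpha, n_tests=n_tests)
    ab = abundant_taxa(table, groups, cutoff=cutoff)
    merged, summary = discriminant_taxa(div, ab)
    merged.attrs.update(div.attrs)
    return merged, summary


def format_summary(summary: dict[str, int]) -> str:
    return (
        f"taxa tested: {summary['n_taxa']}\n"
        f"divergent: {summary['n_divergent']}\n"
        f"abundant: {summary['n_abundant']}\n"
        f"discriminant: {summary['n_discriminant']}\n"
    )
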
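"""Reactor performance: removal efficiencies, SVI, taxon correlations.

Nutrient removal is 100 * (influent - effluent) / influent, computed per
analyte from a tidy logbook of concentrations at the sampling points
I (influent), AN (end of anaerobic phase) and S (end of aerobic phase).
Total-nitrogen removal compares the effluent inorganic N pool
(NH4 + NO3 + NO2) with the influent N (TKN when logged, otherwise NH4).

The sludge volume index after t minutes of settling is
SVI_t = (V / V_tot) / TS with TS in g of dry solids per ml of mixed
liquor, so SVI carries ml per g; lower is better settling and the ratio
SVI_30 / SVI_10 approaches 1 for sludge fully settled by 10 min.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset, ValidationError

SAMPLING_POINTS = ("I", "AN", "S")
ANALYTES = ("NH4-N", "NO3-N", "NO2-N", "PO4-P", "TKN")


def removal_efficiency(influent: float, effluent: float) -> float:
    """Percent removal; NaN (with a warning) when the influent is zero."""
    if influent < 0 or effluent < 0:
        raise ValidationError("concentrations must be non-negative")
    if influent == 0:
        warnings.warn("removal efficiency undefined for zero influent", stacklevel=2)
        return float("nan")
    return 100.0 * (influent - effluent) / influent


def svi(v: float, v_tot: float, ts: float) -> float:
    """Sludge volume index (ml/g) from settled volume, total volume and TS.

    ``ts`` is g of dry solids per ml of mixed liquor.
    """
    if ts <= 0:
        raise ValidationError("TS must be > 0")
    if v_tot <= 0:
        raise ValidationError("V_tot must be > 0")
    if not 0 <= v <= v_tot:
        raise ValidationError("settled volume must satisfy 0 <= V <= V_tot")
    return (v / v_tot) / ts


def svi_ratio(svi_late: float, svi_early: float) -> float:
    """Ratio of a later- to an earlier-time SVI (e.g. SVI_30 / SVI_10)."""
    if svi_early <= 0:
        raise ValidationError("denominator SVI must be > 0")
    return svi_late / svi_early


def read_performance_log(path: str | Path) -> pd.DataFrame:
    """Tidy logbook TSV: day, reactor_id, point, analyte, concentration."""
    df = pd.read_csv(path, sep="\t", dtype={"reactor_id": str})
    needed = {"day", "reactor_id", "point", "analyte", "concentration"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"performance log missing column(s): {sorted(missing)}")
    bad = set(df["point"]) - set(SAMPLING_POINTS)
    if bad:
        raise ValidationError(f"unknown sampling point(s): {sorted(bad)}")
    if (df["concentration"] < 0).any():
        raise ValidationError("concentrations must be non-negative")
    return df


def compute_removals(
    log: pd.DataFrame, exclude_days: dict[str, list[int]] | None = None
) -> pd.DataFrame:
    """Per (day, reactor) removal percentages from a tidy logbook.

    ``exclude_days`` maps reactor id -> days to drop (operational
    incidents). Columns: NH4_removal, P_removal, TN_removal (inorganic
    effluent N vs influent N), TN_removal_tkn when TKN was logged.
    """
    wide = log.pivot_table(
        index=["day", "reactor_id"], columns=["analyte", "point"], values="concentration"
    )
    rows = []
    for (day, reactor), row in wide.iterrows():
        if exclude_days and day in exclude_days.get(reactor, []):
            continue

        def conc(analyte: str, point: str) -> float:
            try:
                return float(row[(analyte, point)])
            except KeyError:
                return float("nan")

        nh4_i, nh4_s = conc("NH4-N", "I"), conc("NH4-N", "S")
        p_i, p_s = conc("PO4-P", "I"), conc("PO4-P", "S")
        n_out = np.nansum([nh4_s, conc("NO3-N", "S"), conc("NO2-N", "S")])
        tkn_i = conc("TKN", "I")
        rec = {"day": day, "reactor_id": reactor}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec["NH4_removal"] = (
                removal_efficiency(nh4_i, nh4_s) if np.isfinite([nh4_i, nh4_s]).all() else np.nan
            )
            rec["P_removal"] = (
                removal_efficiency(p_i, p_s) if np.isfinite([p_i, p_s]).all() else np.nan
            )
            rec["TN_removal"] = (
                removal_efficiency(nh4_i, n_out) if np.isfinite(nh4_i) else np.nan
            )
            rec["TN_removal_tkn"] = (
                removal_efficiency(tkn_i, n_out) if np.isfinite(tkn_i) else np.nan
            )
        rec["PO4_AN"] = conc("PO4-P", "AN")
        rows.append(rec)
    return pd.DataFrame(rows)


def _nearest_join(
    taxa_meta: pd.DataFrame, perf: pd.DataFrame, tolerance_days: int
) -> pd.DataFrame:
    """Match each biomass sample to the nearest-day performance record
    within the tolerance window, per reactor (ties toward the earlier day)."""
    out = []
    for sample_id, row in taxa_meta.iterrows():
        cand = perf[perf["reactor_id"] == row["reactor_id"]]
        if cand.empty:
            continue
        gaps = (cand["day"] - row["day"]).abs()
        best = gaps.idxmin()
        if gaps.loc[best] <= tolerance_days:
            out.append({"sample_id": sample_id, "perf_index": best})
    return pd.DataFrame(out)


def correlate_performance(
    dataset: Dataset,
    perf: pd.DataFrame,
    taxa: list[str] | None = None,
    variables: list[str] | None = None,
    tolerance_days: int = 3,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and p between taxon abundances and performance variables.

    Samples are joined to records on (day, reactor) within
    ``tolerance_days``. Returns (r, p) DataFrames, taxa x variables;
    pairs with fewer than ``min_pairs`` complete observations are NaN
    with a warning.
    """
    table = dataset.table.to_proportions() if dataset.table.unit == "counts" else dataset.table
    mixed = dataset.meta[dataset.meta["fraction"] == "mixed"]
    match = _nearest_join(mixed, perf, tolerance_days)
    if match.empty:
        raise ValidationError("no biomass sample matched a performance record")
    cols = list(taxa) if taxa is not None else list(table.data.columns)
    variables = variables or [
        c for c in perf.columns if c not in ("day", "reactor_id") and perf[c].notna().any()
    ]
    x = table.data.loc[match["sample_id"], cols].to_numpy(dtype=float)
    y = perf.loc[match["perf_index"], variables].to_numpy(dtype=float)
    r = np.full((len(cols), len(variables)), np.nan)
    p = np.full_like(r, np.nan)
    for j in range(len(variables)):
        ok = np.isfinite(y[:, j])
        n = int(ok.sum())
        if n < min_pairs:
            warnings.warn(
                f"variable {variables[j]!r}: only {n} complete pairs; skipped", stacklevel=2
            )
            continue
        for i in range(len(cols)):
            xi = x[ok, i]
            if np.std(xi) == 0 or np.std(y[ok, j]) == 0:
                continue
            res = stats.pearsonr(xi, y[ok, j])
            r[i, j], p[i, j] = res.statistic, res.pvalue
    idx = pd.Index(cols, name="taxon")
    return (
        pd.DataFrame(r, index=idx, columns=variables),
        pd.DataFrame(p, index=idx, columns=variables),
    )
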
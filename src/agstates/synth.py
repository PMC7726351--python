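"""Synthetic multi-reactor compositional time series with known truth.

The generator emulates the structure of a granular-sludge community
time-series study: two sequencing-batch reactors sampled weekly, a
succession of influent regimes each holding a characteristic community,
Dirichlet-multinomial count noise around each regime mean, optional
paired granule/floc sub-samples with planted enrichment, and performance
series linearly linked to planted taxa.

Regime means are built as a shared power-law background (40 % of mass)
plus a regime-specific block of dominant taxa (60 % of mass), so that
within-regime Bray-Curtis stays well below the 0.5 stable-state
threshold while cross-regime distances exceed it. The Dirichlet
concentration (default 200) sets within-regime noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import AbundanceTable, Dataset, ValidationError, join_metadata

DEFAULT_N_TAXA = 269  # genus-level universe size of a typical long-term study
DEFAULT_CONCENTRATION = 200.0
DEFAULT_DEPTH = 20000
WEEK = 7


@dataclass
class RegimeSpec:
    """One community regime: day span, reactors, mean composition, noise."""

    label: str
    day_start: int
    day_end: int
    reactors: tuple[str, ...]
    wastewater_type: str
    mean_composition: np.ndarray
    concentration: float = DEFAULT_CONCENTRATION
    fraction_enrichment: np.ndarray | None = None  # granule/floc multiplier per taxon
    collect_fractions: bool = False
    performance_baseline: dict[str, float] = field(default_factory=dict)
    taxon_linkage: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self, n_taxa: int) -> None:
        comp = np.asarray(self.mean_composition, dtype=float)
        if comp.shape != (n_taxa,):
            raise ValidationError(f"regime {self.label}: composition length != {n_taxa}")
        if np.any(comp <= 0):
            raise ValidationError(f"regime {self.label}: composition must be positive")
        if not np.isclose(comp.sum(), 1.0, atol=1e-9):
            raise ValidationError(f"regime {self.label}: composition must sum to 1")
        if self.concentration <= 0:
            raise ValidationError(f"regime {self.label}: concentration must be > 0")
        if self.day_end < self.day_start:
            raise ValidationError(f"regime {self.label}: empty day span")


@dataclass
class SyntheticTruth:
    """Ground truth for every planted effect."""

    regime_of_sample: pd.Series  # sample id -> regime label (mixed samples)
    divergent_taxa: list[str]
    abundant_taxa: list[str]
    discriminant_taxa: list[str]
    enriched_taxa: dict[str, float]  # taxon -> granule/floc enrichment multiplier
    performance_linkage: dict[str, dict[str, float]]  # variable -> {taxon: coeff}
    crash_day: int | None
    seed: int

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "seed": int(self.seed),
            "divergent_taxa": list(self.divergent_taxa),
            "abundant_taxa": list(self.abundant_taxa),
            "discriminant_taxa": list(self.discriminant_taxa),
            "enriched_taxa": {k: float(v) for k, v in self.enriched_taxa.items()},
            "performance_linkage": {
                v: {t: float(c) for t, c in link.items()}
                for v, link in self.performance_linkage.items()
            },
            "crash_day": None if self.crash_day is None else int(self.crash_day),
            "regime_of_sample": {k: str(v) for k, v in self.regime_of_sample.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _check_overlaps(specs: list[RegimeSpec]) -> None:
    per_reactor: dict[str, list[tuple[int, int, str]]] = {}
    for spec in specs:
        for reactor in spec.reactors:
            per_reactor.setdefault(reactor, []).append((spec.day_start, spec.day_end, spec.label))
    for reactor, spans in per_reactor.items():
        spans.sort()
        for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"regimes {l1!r} and {l2!r} overlap in reactor {reactor}"
                )


def generate_timeseries(
    specs: list[RegimeSpec],
    n_taxa: int = DEFAULT_N_TAXA,
    sampling_depth: int = DEFAULT_DEPTH,
    seed: int = 0,
    interval_days: int = WEEK,
) -> tuple[AbundanceTable, pd.DataFrame, SyntheticTruth]:
    """Draw weekly Dirichlet-multinomial samples for every regime.

    For regimes with ``collect_fractions``, paired granule and floc
    sub-samples are drawn from the mixed sample's underlying composition
    re-weighted by sqrt(enrichment) and 1/sqrt(enrichment) respectively,
    so the expected granule/floc abundance ratio equals the multiplier.
    Deterministic for a fixed seed.
    """
    for spec in specs:
        spec.validate(n_taxa)
    _check_overlaps(specs)
    rng = np.random.default_rng(seed)
    taxa = [f"g{i + 1:03d}" for i in range(n_taxa)]
    rows, meta_rows, regime_labels = [], [], {}
    for spec in sorted(specs, key=lambda s: (s.day_start, s.label)):
        enrich = (
            np.asarray(spec.fraction_enrichment, dtype=float)
            if spec.fraction_enrichment is not None
            else np.ones(n_taxa)
        )
        for day in range(spec.day_start, spec.day_end + 1, interval_days):
            for reactor in sorted(spec.reactors):
                p = rng.dirichlet(spec.concentration * spec.mean_composition)
                sid = f"{reactor}_d{day:04d}_mixed"
                rows.append((sid, rng.multinomial(sampling_depth, p)))
                meta_rows.append((sid, reactor, day, spec.wastewater_type, "mixed"))
                regime_labels[sid] = spec.label
                if spec.collect_fractions:
                    g = p * np.sqrt(enrich)
                    f = p / np.sqrt(enrich)
                    for frac, comp in (("granules", g / g.sum()), ("flocs", f / f.sum())):
                        fid = f"{reactor}_d{day:04d}_{frac}"
                        rows.append((fid, rng.multinomial(sampling_depth, comp)))
                        meta_rows.append((fid, reactor, day, spec.wastewater_type, frac))
    ids = [r[0] for r in rows]
    table = AbundanceTable(
        pd.DataFrame([r[1] for r in rows], index=ids, columns=taxa, dtype=float),
        unit="counts",
    )
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "reactor_id", "day", "wastewater_type", "fraction"]
    )
    truth = _derive_truth(specs, taxa, regime_labels, seed)
    return table, meta, truth


def _derive_truth(
    specs: list[RegimeSpec],
    taxa: list[str],
    regime_labels: dict[str, str],
    seed: int,
    cutoff: float = 0.01,
) -> SyntheticTruth:
    comp = {s.label: np.asarray(s.mean_composition, dtype=float) for s in specs}
    by_type: dict[str, list[np.ndarray]] = {}
    for s in specs:
        by_type.setdefault(s.wastewater_type, []).append(comp[s.label])
    type_means = {t: np.mean(v, axis=0) for t, v in by_type.items()}
    arr = np.stack(list(type_means.values()))
    divergent = [
        taxa[i] for i in range(len(taxa)) if arr[:, i].max() - arr[:, i].min() > 1e-6
    ]
    abundant = [taxa[i] for i in range(len(taxa)) if arr[:, i].max() > cutoff]
    discriminant = sorted(set(divergent) & set(abundant), key=taxa.index)
    enriched: dict[str, float] = {}
    linkage: dict[str, dict[str, float]] = {}
    for s in specs:
        if s.fraction_enrichment is not None and s.collect_fractions:
            e = np.asarray(s.fraction_enrichment, dtype=float)
            for i in np.nonzero(~np.isclose(e, 1.0))[0]:
                enriched[taxa[i]] = float(e[i])
        for var, link in s.taxon_linkage.items():
            linkage.setdefault(var, {}).update(link)
    crash = [s for s in specs if s.label.endswith("_postcrash")]
    crash_day = min(s.day_start for s in crash) if crash else None
    return SyntheticTruth(
        regime_of_sample=pd.Series(regime_labels, name="regime"),
        divergent_taxa=divergent,
        abundant_taxa=abundant,
        discriminant_taxa=discriminant,
        enriched_taxa=enriched,
        performance_linkage=linkage,
        crash_day=crash_day,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scenario presets


def _background(n_taxa: int, exponent: float = 1.5, offset: float = 5.0) -> np.ndarray:
    """Shared power-law background over the taxon universe."""
    w = (np.arange(n_taxa) + offset) ** -exponent
    return w / w.sum()


def _regime_mean(
    n_taxa: int,
    dominant: np.ndarray,
    dominant_mass: float = 0.6,
    dominant_decay: float = 0.75,
) -> np.ndarray:
    """Background (1 - dominant_mass) plus a geometric block on ``dominant``."""
    mean = (1.0 - dominant_mass) * _background(n_taxa)
    shares = dominant_decay ** np.arange(len(dominant))
    mean[dominant] += dominant_mass * shares / shares.sum()
    return mean / mean.sum()


_TYPE_CYCLE = ("simple", "complex_monomeric", "complex_polymeric")


def default_scenario(
    n_taxa: int = DEFAULT_N_TAXA,
    n_regimes: int = 3,
    weeks_per_regime: int = 10,
    reactors: tuple[str, ...] = ("RA", "RB"),
    concentration: float = DEFAULT_CONCENTRATION,
    n_dominant: int = 8,
) -> list[RegimeSpec]:
    """Successive regimes with disjoint dominant blocks in both reactors.

    Dominant blocks are taken from the mid-tail of the background ranking
    (indices 30 onward) so each dominant taxon is rare outside its own
    regime but never absent, and the head of the background supplies
    abundant-but-never-divergent taxa.
    """
    specs = []
    for k in range(n_regimes):
        dominant = np.arange(30 + k * n_dominant, 30 + (k + 1) * n_dominant)
        specs.append(
            RegimeSpec(
                label=f"regime{k + 1}",
                day_start=k * weeks_per_regime * WEEK,
                day_end=(k + 1) * weeks_per_regime * WEEK - 1,
                reactors=reactors,
                wastewater_type=_TYPE_CYCLE[k % len(_TYPE_CYCLE)],
                mean_composition=_regime_mean(n_taxa, dominant),
                concentration=concentration,
            )
        )
    return specs


def two_regime_scenario(
    n_taxa: int = DEFAULT_N_TAXA, weeks_per_regime: int = 10
) -> list[RegimeSpec]:
    return default_scenario(n_taxa=n_taxa, n_regimes=2, weeks_per_regime=weeks_per_regime)


def phage_crash_scenario(
    n_taxa: int = DEFAULT_N_TAXA,
    weeks: int = 20,
    crash_week: int = 10,
    reactors: tuple[str, ...] = ("RA",),
    concentration: float = DEFAULT_CONCENTRATION,
) -> list[RegimeSpec]:
    """A dominant-organism collapse mid-regime (e.g. a phage predation event).

    One taxon holds 60 % of the community; at the crash day it is removed
    and the composition renormalized, so the community jumps by a
    Bray-Curtis distance of about its lost share and the detector should
    open a new state at the crash boundary.
    """
    dominant = np.array([30])
    pre = _regime_mean(n_taxa, dominant, dominant_mass=0.6)
    post = pre.copy()
    post[dominant] = 1e-6
    post = post / post.sum()
    return [
        RegimeSpec(
            label="crash_pre",
            day_start=0,
            day_end=crash_week * WEEK - 1,
            reactors=reactors,
            wastewater_type="simple",
            mean_composition=pre,
            concentration=concentration,
        ),
        RegimeSpec(
            label="crash_postcrash",
            day_start=crash_week * WEEK,
            day_end=weeks * WEEK - 1,
            reactors=reactors,
            wastewater_type="simple",
            mean_composition=post,
            concentration=concentration,
        ),
    ]


def with_fractions(
    specs: list[RegimeSpec],
    enriched: dict[int, float],
    regime_labels: list[str] | None = None,
) -> list[RegimeSpec]:
    """Enable paired granule/floc sampling with planted enrichment.

    ``enriched`` maps taxon index -> granule/floc abundance multiplier
    (>1 granule-enriched, <1 floc-enriched).
    """
    n_taxa = len(specs[0].mean_composition)
    mult = np.ones(n_taxa)
    for idx, m in enriched.items():
        mult[idx] = m
    for spec in specs:
        if regime_labels is None or spec.label in regime_labels:
            spec.collect_fractions = True
            spec.fraction_enrichment = mult
    return specs


def with_performance_linkage(
    specs: list[RegimeSpec], linkage: dict[str, dict[int, float]]
) -> list[RegimeSpec]:
    """Attach variable -> {taxon index: coefficient} linear links."""
    for var, link in linkage.items():
        named = {f"g{i + 1:03d}": float(c) for i, c in link.items()}
        specs[0].taxon_linkage.setdefault(var, {}).update(named)
    return specs


def generate_performance(
    meta: pd.DataFrame,
    table: AbundanceTable,
    truth: SyntheticTruth,
    noise_sd: float = 2.0,
    seed: int = 0,
    baselines: dict[str, float] | None = None,
    interval_days: int = 2 * WEEK,
) -> pd.DataFrame:
    """Bi-weekly performance series linearly linked to planted taxa.

    Each variable is baseline + sum(coeff * relative abundance) + Gaussian
    noise, evaluated on the mixed sample of every ``interval_days``-th
    sampling day per reactor. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    props = table.to_proportions() if table.unit == "counts" else table
    baselines = baselines or {v: 80.0 for v in truth.performance_linkage}
    mixed = meta[meta["fraction"] == "mixed"].copy()
    rows = []
    for reactor, grp in mixed.groupby("reactor_id"):
        days = sorted(grp["day"].unique())
        for day in days[:: max(1, interval_days // WEEK)]:
            sid = grp.loc[(grp["day"] == day), "sample_id"].iloc[0]
            rec = {"day": day, "reactor_id": reactor}
            for var, link in truth.performance_linkage.items():
                value = baselines.get(var, 0.0)
                for taxon, coeff in link.items():
                    value += coeff * float(props.data.loc[sid, taxon])
                rec[var] = value + rng.normal(0.0, noise_sd)
            rows.append(rec)
    return pd.DataFrame(rows).sort_values(["reactor_id", "day"]).reset_index(drop=True)


def make_dataset(
    table: AbundanceTable, meta: pd.DataFrame
) -> Dataset:
    return join_metadata(table, meta)
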
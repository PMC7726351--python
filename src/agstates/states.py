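"""Stable-state detection on community distance time series.

A stable state is a maximal run of temporally successive samples whose
pairwise Bray-Curtis distances all fall strictly below a threshold
(default 0.5). Because the all-pairs-below-threshold property is
hereditary (every sub-window of a valid window is valid), the maximal
windows of an n-sample series can be found with a two-pointer sweep in
O(n^2) distance lookups.

Maximal windows may overlap; reported states must be disjoint. Overlaps
are resolved greedily in temporal order: accept the earliest-starting
maximal window (ties broken toward the longer one), remove its samples,
and recurse on the remaining segments. Samples belonging to no accepted
window are "transition" samples.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .io import Dataset, ValidationError
from .metrics import bray_curtis

TRANSITION_LABEL = "transition"


@dataclass
class StableState:
    """A maximal temporally contiguous sample cluster under the threshold."""

    state_id: int
    sample_ids: list[str]
    mean_within_distance: float
    start_day: int | None = None
    end_day: int | None = None
    reactors: tuple[str, ...] = ()
    wastewater_type: str | None = None

    @property
    def size(self) -> int:
        return len(self.sample_ids)


def _reach(d: np.ndarray, threshold: float) -> np.ndarray:
    """reach[i] = largest j such that all pairs within [i..j] are < threshold."""
    n = d.shape[0]
    reach = np.empty(n, dtype=int)
    far = 0
    for i in range(n):
        far = max(far, i)
        # extending right stays valid for later i by heredity
        while far + 1 < n and np.all(d[far + 1, i : far + 1] < threshold):
            far += 1
        reach[i] = far
    return reach


def _maximal_windows(d: np.ndarray, lo: int, hi: int, threshold: float) -> list[tuple[int, int]]:
    """All maximal valid windows inside the index segment [lo, hi]."""
    if hi < lo:
        return []
    sub = d[lo : hi + 1, lo : hi + 1]
    reach = _reach(sub, threshold)
    out = []
    for i in range(hi - lo + 1):
        if i == 0 or reach[i - 1] < reach[i]:
            out.append((lo + i, lo + reach[i]))
    return out


def _greedy_disjoint(
    d: np.ndarray, lo: int, hi: int, threshold: float, min_size: int
) -> list[tuple[int, int]]:
    candidates = [
        w for w in _maximal_windows(d, lo, hi, threshold) if w[1] - w[0] + 1 >= min_size
    ]
    if not candidates:
        return []
    start, end = min(candidates, key=lambda w: (w[0], -(w[1] - w[0])))
    return (
        _greedy_disjoint(d, lo, start - 1, threshold, min_size)
        + [(start, end)]
        + _greedy_disjoint(d, end + 1, hi, threshold, min_size)
    )


def detect_stable_states(
    dm: DistanceMatrix,
    order: Sequence[str],
    threshold: float = 0.5,
    min_size: int = 4,
) -> list[StableState]:
    """Detect disjoint stable states along a temporal sample ordering.

    Parameters
    ----------
    dm:
        Pairwise distance matrix over (at least) the ordered samples.
    order:
        Sample ids in temporal succession; must all be present in ``dm``.
    threshold:
        Strict upper bound on every within-state pairwise distance.
    min_size:
        Minimum number of samples for a window to count as a state.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must be in (0, 1)")
    if min_size < 2:
        raise ValidationError("min_size must be >= 2")
    missing = [s for s in order if s not in set(dm.ids)]
    if missing:
        raise ValidationError(f"sample(s) missing from distance matrix: {missing}")
    if len(set(order)) != len(order):
        raise ValidationError("temporal order contains duplicate sample ids")
    idx = [dm.index(s) for s in order]
    d = np.asarray(dm.data, dtype=float)[np.ix_(idx, idx)]
    windows = _greedy_disjoint(d, 0, len(order) - 1, threshold, min_size)
    states = []
    for k, (start, end) in enumerate(sorted(windows), start=1):
        block = d[start : end + 1, start : end + 1]
        m = end - start + 1
        mean_within = float(block[np.triu_indices(m, k=1)].mean())
        states.append(
            StableState(
                state_id=k,
                sample_ids=list(order[start : end + 1]),
                mean_within_distance=mean_within,
            )
        )
    return states


def annotate_states(states: list[StableState], meta: pd.DataFrame) -> list[StableState]:
    """Fill day span, reactor coverage and modal wastewater type per state."""
    for st in states:
        rows = meta.loc[st.sample_ids]
        st.start_day = int(rows["day"].min())
        st.end_day = int(rows["day"].max())
        st.reactors = tuple(sorted(rows["reactor_id"].unique()))
        modal = rows["wastewater_type"].mode()
        st.wastewater_type = str(sorted(modal)[0]) if len(modal) else None
    return states


def assign_state_labels(states: list[StableState], meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample state label ("transition" outside every state)."""
    labels = pd.Series(TRANSITION_LABEL, index=meta.index, dtype=object, name="state")
    types = pd.Series(pd.NA, index=meta.index, dtype=object, name="state_wastewater_type")
    for st in states:
        labels.loc[st.sample_ids] = str(st.state_id)
        types.loc[st.sample_ids] = st.wastewater_type
    out = meta.copy()
    out["state"] = labels
    out["state_wastewater_type"] = types
    return out


def find_stable_states(
    dataset: Dataset,
    threshold: float = 0.5,
    min_size: int = 4,
    mode: str = "pooled",
) -> tuple[list[StableState], pd.DataFrame]:
    """End-to-end detection on a joined dataset.

    Only ``fraction == "mixed"`` samples enter detection (floc/granule
    sub-samples supplement the mixed sample and are labelled afterwards as
    transition). ``mode`` is ``pooled`` (both reactors in one (day,
    reactor)-ordered succession, so parallel reactors can share a state)
    or ``per-reactor``.
    """
    mixed = dataset.filter(fraction="mixed")
    zero = mixed.table.zero_sum_samples()
    if zero:
        keep = [s for s in mixed.table.sample_ids if s not in zero]
        mixed = Dataset(mixed.table.subset(keep), mixed.meta.loc[keep])
    props = mixed.table.to_proportions() if mixed.table.unit == "counts" else mixed.table
    mixed = Dataset(props, mixed.meta)
    if mode == "pooled":
        order = mixed.temporal_order()
        dm = bray_curtis(mixed.table)
        states = detect_stable_states(dm, order, threshold, min_size)
    elif mode == "per-reactor":
        states = []
        for reactor in sorted(mixed.meta["reactor_id"].unique()):
            sub = mixed.filter(reactor_id=reactor)
            if len(sub.table.sample_ids) < 2:
                continue
            dm = bray_curtis(sub.table)
            states.extend(detect_stable_states(dm, sub.temporal_order(), threshold, min_size))
        states = annotate_states(states, mixed.meta)
        states.sort(key=lambda s: (s.start_day, s.sample_ids[0]))
        for k, st in enumerate(states, start=1):
            st.state_id = k
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    annotate_states(states, mixed.meta)
    labels = assign_state_labels(states, dataset.meta)
    return states, labels


def state_summary(states: list[StableState]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "state": [s.state_id for s in states],
            "n_samples": [s.size for s in states],
            "start_day": [s.start_day for s in states],
            "end_day": [s.end_day for s in states],
            "reactors": [",".join(s.reactors) for s in states],
            "wastewater_type": [s.wastewater_type for s in states],
            "mean_within_distance": [s.mean_within_distance for s in states],
        }
    ).set_index("state")


def write_state_outputs(
    states: list[StableState], labels: pd.DataFrame, out_dir: str | Path
) -> None:
    out_dir = Path(out_dir)
    labels.to_csv(out_dir / "state_labels.tsv", sep="\t", index_label="sample_id")
    state_summary(states).to_csv(out_dir / "state_summary.tsv", sep="\t")
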
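import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from agstates.io import ValidationError, join_metadata
from agstates.states import (
    assign_state_labels,
    annotate_states,
    detect_stable_states,
    find_stable_states,
    state_summary,
)
from agstates import synth

from helpers import block_distance_matrix, brute_force_states, random_distance_matrix


def _dm(d):
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(d.shape[0])])


def _ids(n):
    return [f"s{i}" for i in range(n)]


class TestDetection:
    def test_homogeneous_series_is_one_state(self):
        d = block_distance_matrix([10], within=0.2, between=0.2)
        states = detect_stable_states(_dm(d), _ids(10), threshold=0.5, min_size=4)
        assert len(states) == 1
        assert states[0].sample_ids == _ids(10)
        assert states[0].mean_within_distance == pytest.approx(0.2)

    def test_two_blocks_give_two_states(self):
        d = block_distance_matrix([6, 6], within=0.1, between=0.8)
        states = detect_stable_states(_dm(d), _ids(12), threshold=0.5, min_size=4)
        assert [s.size for s in states] == [6, 6]
        assert states[0].sample_ids == _ids(12)[:6]

    def test_mid_series_outlier_splits_and_stays_unassigned(self):
        d = block_distance_matrix([11], within=0.2, between=0.2)
        d[5, :] = d[:, 5] = 0.6
        d[5, 5] = 0.0
        states = detect_stable_states(_dm(d), _ids(11), threshold=0.5, min_size=2)
        assert [s.sample_ids for s in states] == [_ids(11)[:5], _ids(11)[6:]]

    def test_window_below_min_size_is_no_state(self):
        d = block_distance_matrix([3, 8], within=0.1, between=0.9)
        states = detect_stable_states(_dm(d), _ids(11), threshold=0.5, min_size=4)
        assert [s.size for s in states] == [8]

    def test_strict_inequality_at_threshold(self):
        """Pairs at exactly the threshold do not join a state."""
        d = block_distance_matrix([6], within=0.5, between=0.5)
        assert detect_stable_states(_dm(d), _ids(6), threshold=0.5, min_size=2) == []

    def test_missing_sample_in_order_rejected(self):
        d = block_distance_matrix([4], within=0.1, between=0.1)
        with pytest.raises(ValidationError, match="missing"):
            detect_stable_states(_dm(d), _ids(4) + ["ghost"], 0.5, 2)

    def test_matches_brute_force_enumerator(self, rng):
        """Exhaustive-oracle equivalence over random distance series."""
        for _ in range(50):
            n = int(rng.integers(4, 21))
            min_size = int(rng.integers(2, 5))
            d = random_distance_matrix(rng, n)
            got = detect_stable_states(_dm(d), _ids(n), threshold=0.5, min_size=min_size)
            expected = brute_force_states(d, threshold=0.5, min_size=min_size)
            assert [(s.sample_ids[0], s.sample_ids[-1]) for s in got] == [
                (f"s{i}", f"s{j}") for i, j in expected
            ]

    def test_maximal_window_grows_with_threshold(self, rng):
        """Raising the threshold never shrinks the maximal valid window
        around a fixed sample (heredity of the all-pairs condition)."""
        from agstates.states import _maximal_windows

        for _ in range(20):
            n = 15
            d = random_distance_matrix(rng, n)
            probe = int(rng.integers(0, n))
            sizes = []
            for thr in (0.3, 0.5, 0.7, 0.9):
                windows = [
                    j - i + 1
                    for i, j in _maximal_windows(d, 0, n - 1, thr)
                    if i <= probe <= j
                ]
                sizes.append(max(windows))
            assert sizes == sorted(sizes)


class TestLabels:
    def _meta(self, n, ww="simple"):
        return pd.DataFrame(
            {
                "reactor_id": ["RA"] * n,
                "day": np.arange(n) * 7,
                "wastewater_type": [ww] * n,
                "fraction": ["mixed"] * n,
            },
            index=pd.Index(_ids(n), name="sample_id"),
        )

    def test_modal_wastewater_type(self):
        d = block_distance_matrix([7], within=0.1, between=0.1)
        meta = self._meta(7)
        meta.loc[["s5", "s6"], "wastewater_type"] = "transition"
        states = annotate_states(
            detect_stable_states(_dm(d), _ids(7), 0.5, 4), meta
        )
        assert states[0].wastewater_type == "simple"

    def test_no_states_all_transition(self):
        d = block_distance_matrix([5], within=0.9, between=0.9)
        meta = self._meta(5)
        labels = assign_state_labels(
            detect_stable_states(_dm(d), _ids(5), 0.5, 2), meta
        )
        assert (labels["state"] == "transition").all()

    def test_state_summary_spans_days(self):
        d = block_distance_matrix([5], within=0.1, between=0.1)
        meta = self._meta(5)
        states = annotate_states(detect_stable_states(_dm(d), _ids(5), 0.5, 2), meta)
        summary = state_summary(states)
        assert summary.loc[1, "start_day"] == 0
        assert summary.loc[1, "end_day"] == 28


class TestPipelineRecovery:
    def test_planted_regimes_recovered(self):
        """Full pipeline (normalize, Bray-Curtis, detect at 0.5) on the
        default 3-regime, 2-reactor scenario recovers the regimes."""
        specs = synth.default_scenario()
        table, meta, truth = synth.generate_timeseries(specs, seed=7)
        ds = join_metadata(table, meta)
        states, labels = find_stable_states(ds)
        assert len(states) == 3
        for st in states:
            regimes = truth.regime_of_sample.loc[st.sample_ids]
            assert regimes.nunique() == 1

    def test_per_reactor_mode_splits_reactors(self):
        specs = synth.default_scenario(n_regimes=1, weeks_per_regime=8)
        table, meta, _ = synth.generate_timeseries(specs, seed=7)
        ds = join_metadata(table, meta)
        states, _ = find_stable_states(ds, mode="per-reactor")
        assert len(states) == 2
        assert sorted(s.reactors for s in states) == [("RA",), ("RB",)]

    def test_floc_granule_samples_excluded_from_detection(self):
        specs = synth.with_fractions(synth.default_scenario(n_regimes=1), {31: 3.0})
        table, meta, _ = synth.generate_timeseries(specs, seed=7)
        ds = join_metadata(table, meta)
        states, labels = find_stable_states(ds)
        members = {s for st in states for s in st.sample_ids}
        frac_ids = set(ds.meta.index[ds.meta["fraction"] != "mixed"])
        assert not members & frac_ids
        assert (labels.loc[sorted(frac_ids), "state"] == "transition").all()
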
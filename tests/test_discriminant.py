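import numpy as np
import pandas as pd
import pytest

from agstates.discriminant import (
    abundant_taxa,
    bonferroni_threshold,
    discriminant_taxa,
    divergent_taxa,
    group_samples,
    screen_taxa,
)
from agstates.io import AbundanceTable, ValidationError


def _table(arr, ids=None, unit="proportions"):
    arr = np.asarray(arr, dtype=float)
    ids = ids or [f"s{i}" for i in range(arr.shape[0])]
    cols = [f"t{j}" for j in range(arr.shape[1])]
    return AbundanceTable(pd.DataFrame(arr, index=ids, columns=cols), unit=unit)


def _groups(counts):
    """n samples per wastewater type, ids s0, s1, ..."""
    labels = []
    for t, n in counts.items():
        labels += [t] * n
    return pd.Series(labels, index=[f"s{i}" for i in range(len(labels))])


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [
            (0.01, 269, 3.72e-5),
            (0.01, 34, 2.94e-4),
            (0.01, 29, 3.45e-4),
            (0.05, 1, 0.05),
        ],
    )
    def test_corrected_thresholds(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=5e-3)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.01, 0)


class TestDivergent:
    def test_identical_groups_not_divergent(self, rng):
        base = rng.dirichlet(np.ones(4) * 50, size=1)
        arr = np.tile(base, (12, 1))
        res = divergent_taxa(_table(arr), _groups({"simple": 6, "complex_monomeric": 6}))
        assert not res["divergent"].any()
        # degenerate zero-variance equal-mean pairs report p = 1
        assert (res["min_p"] == 1.0).all()

    def test_large_shift_detected(self, rng):
        """A five-within-SD mean shift at n=20/group has power ~1 even at
        the Bonferroni threshold."""
        n = 20
        a = np.clip(rng.normal(0.30, 0.01, size=n), 0.05, 0.9)
        b = np.clip(rng.normal(0.40, 0.01, size=n), 0.05, 0.9)
        arr = np.zeros((2 * n, 3))
        arr[:n, 0] = a
        arr[n:, 0] = b
        arr[:, 1] = 0.3
        arr[:, 2] = 1 - arr[:, 0] - arr[:, 1]
        res = divergent_taxa(
            _table(arr), _groups({"simple": n, "complex_monomeric": n}), n_tests=269
        )
        assert bool(res.loc["t0", "divergent"])
        assert not bool(res.loc["t1", "divergent"])

    def test_single_sample_group_skipped_with_warning(self, rng):
        arr = rng.dirichlet(np.ones(3) * 30, size=7)
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = divergent_taxa(
                _table(arr), _groups({"simple": 6, "complex_monomeric": 1})
            )
        assert res["min_p"].isna().all()

    def test_invariant_to_orderings(self, rng):
        arr = rng.dirichlet(np.ones(5) * 30, size=12)
        table = _table(arr)
        groups = _groups({"simple": 6, "complex_polymeric": 6})
        res1 = divergent_taxa(table, groups)
        shuffled_samples = table.data.sample(frac=1, random_state=1)
        shuffled = AbundanceTable(
            shuffled_samples[table.data.columns[::-1]], unit="proportions"
        )
        res2 = divergent_taxa(shuffled, groups)
        pd.testing.assert_series_equal(
            res1["min_p"].sort_index(), res2["min_p"].sort_index()
        )


class TestAbundant:
    def test_everywhere_rare_not_abundant(self):
        arr = np.full((6, 2), 0.005)
        arr[:, 1] = 0.995
        res = abundant_taxa(_table(arr), _groups({"simple": 3, "complex_monomeric": 3}))
        assert not bool(res.loc["t0", "abundant"])

    def test_abundant_in_one_type_suffices(self):
        arr = np.zeros((6, 2))
        arr[:4, 0] = 0.002  # two types at 0.2 %
        arr[4:, 0] = 0.03  # one type at 3 %
        arr[:, 1] = 1 - arr[:, 0]
        res = abundant_taxa(
            _table(arr),
            _groups({"simple": 2, "complex_monomeric": 2, "complex_polymeric": 2}),
        )
        assert bool(res.loc["t0", "abundant"])

    def test_zero_cutoff_every_present_taxon_abundant(self, rng):
        arr = rng.dirichlet(np.ones(4) * 30, size=4)
        res = abundant_taxa(_table(arr), _groups({"simple": 4}), cutoff=0.0)
        assert res["abundant"].all()


class TestDiscriminant:
    def test_logical_and_of_flags(self, rng):
        arr = rng.dirichlet(np.ones(3) * 30, size=8)
        table = _table(arr)
        groups = _groups({"simple": 4, "complex_monomeric": 4})
        div = divergent_taxa(table, groups)
        ab = abundant_taxa(table, groups)
        div.loc["t0", "divergent"] = True
        ab.loc["t0", "abundant"] = False
        merged, summary = discriminant_taxa(div, ab)
        assert not bool(merged.loc["t0", "discriminant"])
        assert summary["n_discriminant"] <= min(summary["n_divergent"], summary["n_abundant"])

    def test_mismatched_taxon_sets_rejected(self, rng):
        arr = rng.dirichlet(np.ones(3) * 30, size=8)
        groups = _groups({"simple": 4, "complex_monomeric": 4})
        div = divergent_taxa(_table(arr), groups)
        ab = abundant_taxa(_table(arr), groups).iloc[:-1]
        with pytest.raises(ValidationError):
            discriminant_taxa(div, ab)


class TestGrouping:
    def test_transition_samples_excluded(self):
        labels = pd.DataFrame(
            {
                "state": ["1", "1", "transition", "2"],
                "state_wastewater_type": ["simple", "simple", pd.NA, "complex_monomeric"],
            },
            index=[f"s{i}" for i in range(4)],
        )
        groups = group_samples(labels)
        assert groups.index.tolist() == ["s0", "s1", "s3"]

    def test_null_design_family_wise_control(self, rng):
        """With no group differences and Bonferroni at 0.01 over 269 taxa,
        false divergent calls are (nearly) absent."""
        from agstates import synth

        comp = synth._regime_mean(269, np.arange(30, 38))
        false_counts = []
        for _ in range(20):
            props = rng.dirichlet(200 * comp, size=30)
            table = _table(props, ids=[f"s{i}" for i in range(30)])
            groups = _groups({"simple": 10, "complex_monomeric": 10, "complex_polymeric": 10})
            res = divergent_taxa(table, groups, alpha=0.01)
            false_counts.append(int(res["divergent"].sum()))
        assert np.mean(false_counts) < 0.05
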
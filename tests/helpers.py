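"""Independent oracles and small builders shared across the test suite."""
from __future__ import annotations

import numpy as np
import pandas as pd


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric matrix with zero diagonal and entries uniform in [0, 1]."""
    d = rng.uniform(0, 1, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


def brute_force_states(d: np.ndarray, threshold: float, min_size: int) -> list[tuple[int, int]]:
    """Exhaustive enumeration of disjoint stable-state windows.

    Tests every contiguous window for the all-pairs condition and
    two-sided maximality, then resolves overlaps greedily (earliest
    start, ties to the longer window) recursing on the remainder.
    Quadratic-times-linear; only usable for small n.
    """
    n = d.shape[0]

    def valid(i: int, j: int) -> bool:
        for a in range(i, j + 1):
            for b in range(a + 1, j + 1):
                if not d[a, b] < threshold:
                    return False
        return True

    def solve(lo: int, hi: int) -> list[tuple[int, int]]:
        windows = [
            (i, j)
            for i in range(lo, hi + 1)
            for j in range(i, hi + 1)
            if valid(i, j)
            and (i == lo or not valid(i - 1, j))
            and (j == hi or not valid(i, j + 1))
            and j - i + 1 >= min_size
        ]
        if not windows:
            return []
        start, end = min(windows, key=lambda w: (w[0], -(w[1] - w[0])))
        return solve(lo, start - 1) + [(start, end)] + solve(end + 1, hi)

    return solve(0, n - 1)


def block_distance_matrix(blocks: list[int], within: float, between: float) -> np.ndarray:
    """Block-diagonal distance structure: `blocks` gives each block's size."""
    n = sum(blocks)
    d = np.full((n, n), between)
    start = 0
    for size in blocks:
        d[start : start + size, start : start + size] = within
        start += size
    np.fill_diagonal(d, 0.0)
    return d


def proportions_frame(rng: np.random.Generator, n_samples: int, n_taxa: int) -> pd.DataFrame:
    raw = rng.dirichlet(np.ones(n_taxa), size=n_samples)
    return pd.DataFrame(
        raw,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)],
    )
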
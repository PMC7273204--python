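"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's dynamic programs: warping
paths are enumerated exhaustively, and the ground-truth grouping search is
an explicit recursion over all ordered non-overlapping windows.  They are
only feasible for tiny instances, which is their point.
"""

from __future__ import annotations

import functools

import numpy as np
import pytest

from eventdtw import Signal, WarpSpec, generate_companion_pair, make_uniform_signal


# ---------------------------------------------------------------------------
# exhaustive warping-path oracle
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def all_paths(n: int, m: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """Every admissible warping path on an (n, m) grid as link tuples."""
    table: dict[tuple[int, int], list] = {(0, 0): [((0, 0),)]}
    for i in range(n):
        for j in range(m):
            if (i, j) == (0, 0):
                continue
            acc = []
            for pi, pj in ((i - 1, j - 1), (i - 1, j), (i, j - 1)):
                if pi >= 0 and pj >= 0:
                    acc.extend(p + ((i, j),) for p in table[(pi, pj)])
            table[(i, j)] = acc
    return tuple(table[(n - 1, m - 1)])


@functools.lru_cache(maxsize=None)
def _padded_flat_paths(n: int, m: int) -> np.ndarray:
    """All paths as a padded matrix of flat cost-matrix indices.

    Padding points at index n*m, which callers must map to cost 0.
    """
    paths = all_paths(n, m)
    width = max(len(p) for p in paths)
    out = np.full((len(paths), width), n * m, dtype=np.int64)
    for row, p in enumerate(paths):
        idx = [i * m + j for i, j in p]
        out[row, : len(idx)] = idx
    return out

def brute_force_min_cost(cost: np.ndarray) -> float:
    """Minimum cumulative cost over every admissible path, by enumeration."""
    n, m = cost.shape
    flat = np.append(cost.ravel(), 0.0)
    return float(flat[_padded_flat_paths(n, m)].sum(axis=1).min())


def path_cost(cost: np.ndarray, links) -> float:
    """Cumulative cost of one explicit path."""
    return float(sum(cost[i, j] for i, j in links))


# ---------------------------------------------------------------------------
# exhaustive grouping oracle
# ---------------------------------------------------------------------------

def brute_force_grouping(r_warp: Signal, q: Signal, d: int):
    """Best ordered non-overlapping d-window grouping, by full recursion.

    Returns (total_cost, tuple_of_group_starts) minimizing the summed
    (t, v)-plane Euclidean distance between each companion observation and
    its window of d consecutive warped-reference observations.  Ties break
    toward lexicographically smaller starts.
    """
    tw, vw = r_warp.timestamps, r_warp.values

    def window_cost(j: int, s: int) -> float:
        return float(
            np.hypot(tw[s : s + d] - q.timestamps[j], vw[s : s + d] - q.values[j]).sum()
        )

    n_r, n_q = len(tw), len(q)
    best = (np.inf, None)

    def recurse(j: int, min_start: int, acc: float, starts: tuple):
        nonlocal best
        if j == n_q:
            if acc < best[0]:
                best = (acc, starts)
            return
        for s in range(min_start, n_r - d * (n_q - j) + 1):
            recurse(j + 1, s + d, acc + window_cost(j, s), starts + (s,))

    recurse(0, 0, 0.0, ())
    return best


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture()
def sine100() -> Signal:
    """A length-100 two-cycle sine on a uniform time base."""
    return make_uniform_signal(np.sin(np.linspace(0.0, 4.0 * np.pi, 100)))


@pytest.fixture()
def companion_factory():
    """Factory producing (R, R', Q, optimal) tuples for given length and d."""

    def make(length: int = 100, d: int = 5, shift_scale: float = 8.0, seed: int = 0):
        gen = np.random.default_rng(seed)
        t = np.arange(length)
        v = np.sin(2 * np.pi * 2.3 * t / length) + 0.5 * np.sin(
            2 * np.pi * 4.1 * t / length + gen.uniform(0, 2 * np.pi)
        )
        R = make_uniform_signal(v)
        spec = WarpSpec(shift_scale=shift_scale)
        r_warp, q, opt = generate_companion_pair(R, d, spec)
        return R, r_warp, q, opt

    return make
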
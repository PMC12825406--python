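"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (exhaustive enumeration, direct
definitional arithmetic) and shares no code with the package's
implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def compositions(total: int, caps: list[int]):
    """All integer allocations of ``total`` over parts with per-part caps."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for x in range(min(total, caps[0]) + 1):
        for rest in compositions(total - x, caps[1:]):
            yield (x,) + rest


def all_tables(row_totals: list[int], col_totals: list[int]):
    """All nonnegative integer matrices with the given marginals."""
    n = len(row_totals)
    out: list[np.ndarray] = []

    def rec(i, cols, acc):
        if i == n:
            if all(cj == 0 for cj in cols):
                out.append(np.array(acc))
            return
        for row in compositions(row_totals[i], list(cols)):
            rec(i + 1, tuple(cj - x for cj, x in zip(cols, row)), acc + [row])

    rec(0, tuple(col_totals), [])
    return out


def table_entropy(table: np.ndarray) -> float:
    m = table.sum()
    h = 0.0
    for x in table.ravel():
        if x > 0:
            p = x / m
            h -= p * math.log(p)
    return h


def entropy_extremes(row_totals, col_totals) -> tuple[float, float]:
    ents = [table_entropy(t) for t in all_tables(list(row_totals), list(col_totals))]
    return max(ents), min(ents)


def kl_d(alloc, total, q) -> float:
    d = 0.0
    for x, qj in zip(alloc, q):
        if x > 0:
            p = x / total
            d += p * math.log(p / qj)
    return d


def d_extremes(total: int, q, caps) -> tuple[float, float]:
    ds = [kl_d(a, total, q) for a in compositions(total, list(caps))]
    return max(ds), min(ds)


def nodf_naive(binary: np.ndarray) -> float:
    """Direct set-based NODF implementation."""
    b = binary > 0

    def pairs(mat):
        rows = [set(np.nonzero(row)[0]) for row in mat]
        vals, count = [], 0
        for u, v in itertools.combinations(range(len(rows)), 2):
            count += 1
            hi, lo = (u, v) if len(rows[u]) > len(rows[v]) else (v, u)
            if len(rows[hi]) == len(rows[lo]) or len(rows[lo]) == 0:
                vals.append(0.0)
            else:
                vals.append(100.0 * len(rows[hi] & rows[lo]) / len(rows[lo]))
        return sum(vals), count

    rs, rn = pairs(b)
    cs, cn = pairs(b.T)
    return (rs + cs) / (rn + cn)


def set_partitions(items: list):
    """All partitions of a list into unordered nonempty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield [[first]] + part


def qw_direct(weights: np.ndarray, row_mod, col_mod) -> float:
    F = weights.sum()
    k = weights.sum(axis=1)
    d = weights.sum(axis=0)
    q = 0.0
    for i in range(weights.shape[0]):
        for j in range(weights.shape[1]):
            if row_mod[i] == col_mod[j]:
                q += weights[i, j] - k[i] * d[j] / F
    return q / F


def best_modularity(weights: np.ndarray) -> float:
    """Exhaustive search over all joint partitions of rows and columns."""
    n_r, n_c = weights.shape
    nodes = [("r", i) for i in range(n_r)] + [("c", j) for j in range(n_c)]
    best = -2.0
    for part in set_partitions(nodes):
        rm = np.zeros(n_r, dtype=int)
        cm = np.zeros(n_c, dtype=int)
        for mid, block in enumerate(part):
            for level, idx in block:
                (rm if level == "r" else cm)[idx] = mid
        best = max(best, qw_direct(weights, rm, cm))
    return best


def random_count_matrix(rng, max_dim=4, max_total=12, min_dim=2):
    """Random small count matrix with no empty rows/columns."""
    while True:
        nr = int(rng.integers(min_dim, max_dim + 1))
        nc = int(rng.integers(min_dim, max_dim + 1))
        total = int(rng.integers(max(nr, nc), max_total + 1))
        t = rng.multinomial(total, np.ones(nr * nc) / (nr * nc)).reshape(nr, nc)
        if t.sum(axis=1).min() > 0 and t.sum(axis=0).min() > 0:
            return t
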
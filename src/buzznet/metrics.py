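"""Network-level structure of weighted bipartite networks.

Implements the four network-level descriptors used throughout:

* ``h2prime`` -- complementary network specialisation H2', the Shannon
  entropy of the interaction distribution standardized between the
  marginal-constrained extremes (0 = interactions follow partner
  availability, 1 = maximal reciprocal specialisation);
* ``nodf`` -- binary nestedness by paired overlap and decreasing fill
  (0..100);
* ``modularity_qw`` / ``find_modules`` -- Barber-style weighted bipartite
  modularity and a seeded multi-restart label-propagation optimizer;
* ``weighted_generality`` -- effective mean number of partners per trophic
  level (exponential Shannon entropy, weighted by species totals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import InteractionMatrix
from .utils import to_integer_matrix


def _as_weights(matrix) -> np.ndarray:
    if isinstance(matrix, InteractionMatrix):
        return np.asarray(matrix.weights, dtype=float)
    return np.asarray(matrix, dtype=float)


def shannon_entropy(weights: np.ndarray, base: float = np.e) -> float:
    """Shannon entropy of the normalized positive entries."""
    w = np.asarray(weights, dtype=float).ravel()
    w = w[w > 0]
    if w.size == 0:
        return 0.0
    p = w / w.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


# ---------------------------------------------------------------------------
# Integer-table machinery for the H2 extremes
# ---------------------------------------------------------------------------

def _table_entropy(table: np.ndarray) -> float:
    return shannon_entropy(table)


def _cell_h(x: np.ndarray, m: float) -> np.ndarray:
    """Per-cell entropy contribution -p ln p with p = x/m (0 at x=0)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    p = x[pos] / m
    out[pos] = -p * np.log(p)
    return out


def _h1(x: float, m: float) -> float:
    if x <= 0:
        return 0.0
    p = x / m
    return -p * math.log(p)


def _apply_move(
    t: np.ndarray,
    plus: list[tuple[int, int]],
    minus: list[tuple[int, int]],
    m: float,
    maximize: bool,
) -> bool:
    """Try a marginal-preserving cycle transfer; apply it if it improves.

    The table entropy is concave along any transfer direction, so
    maximization only ever needs single-unit steps, while minimization is
    optimized at the endpoint (the largest feasible transfer).
    """
    t_max = min(int(t[c]) for c in minus)
    if t_max <= 0:
        return False
    step = 1 if maximize else t_max
    old = sum(_h1(t[c], m) for c in plus) + sum(_h1(t[c], m) for c in minus)
    new = sum(_h1(t[c] + step, m) for c in plus) + sum(
        _h1(t[c] - step, m) for c in minus
    )
    sign = 1.0 if maximize else -1.0
    if sign * (new - old) > 1e-12:
        for c in plus:
            t[c] += step
        for c in minus:
            t[c] -= step
        return True
    return False


def _hillclimb_entropy(table: np.ndarray, maximize: bool, max_sweeps: int = 500) -> np.ndarray:
    """Polish an integer table by marginal-preserving cycle transfers.

    Sweeps over all 2x2 transfer cycles (and, for small tables, all 3x3
    six-cycles) applying any move that improves the entropy in the
    requested direction, until a local optimum is reached.
    """
    t = table.astype(np.int64).copy()
    m = float(t.sum())
    if m <= 0:
        return t
    n_r, n_c = t.shape
    deep = n_r * n_c <= 36 and n_r >= 3 and n_c >= 3
    for _ in range(max_sweeps):
        improved = False
        for i in range(n_r):
            for k in range(n_r):
                if i == k:
                    continue
                for j in range(n_c):
                    for l in range(n_c):
                        if l == j:
                            continue
                        improved |= _apply_move(
                            t, [(i, j), (k, l)], [(i, l), (k, j)], m, maximize
                        )
        if deep:
            import itertools

            for rows in itertools.permutations(range(n_r), 3):
                for cols in itertools.permutations(range(n_c), 3):
                    i1, i2, i3 = rows
                    j1, j2, j3 = cols
                    improved |= _apply_move(
                        t,
                        [(i1, j1), (i2, j2), (i3, j3)],
                        [(i1, j2), (i2, j3), (i3, j1)],
                        m,
                        maximize,
                    )
        if not improved:
            break
    return t


def max_entropy_table(row_totals: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Integer table with the given marginals of (near-)maximal entropy.

    Largest-remainder allocation of the independence expectations
    floor(A_i A_j / m), unit repair to restore the marginals, then a
    marginal-preserving 2x2-transfer ascent.
    """
    r = np.asarray(row_totals, dtype=np.int64)
    c = np.asarray(col_totals, dtype=np.int64)
    m = int(r.sum())
    if m != int(c.sum()):
        raise ValueError("marginal sums differ")
    expected = np.outer(r, c) / m
    table = np.floor(expected).astype(np.int64)
    r_def = r - table.sum(axis=1)
    c_def = c - table.sum(axis=0)
    # distribute the deficit by descending remainder where both margins allow
    remainders = expected - table
    order = np.argsort(-remainders, axis=None)
    for flat in order:
        i, j = np.unravel_index(flat, table.shape)
        if r_def[i] > 0 and c_def[j] > 0:
            table[i, j] += 1
            r_def[i] -= 1
            c_def[j] -= 1
    # any residue (possible when remainders misalign): greedy fill
    while r_def.sum() > 0:
        i = int(np.argmax(r_def))
        j = int(np.argmax(c_def))
        add = min(r_def[i], c_def[j])
        table[i, j] += add
        r_def[i] -= add
        c_def[j] -= add
    return _hillclimb_entropy(table, maximize=True)


def _pack_greedy(r: np.ndarray, c: np.ndarray, exact_fit_first: bool) -> np.ndarray:
    """Greedy packing: allocate min(remaining row, remaining column) to the
    pair of largest remaining marginals; the ``exact_fit_first`` variant
    first pairs any row and column with equal remaining totals (which the
    plain rule tends to split, fragmenting the table)."""
    r = r.copy()
    c = c.copy()
    table = np.zeros((r.size, c.size), dtype=np.int64)
    while r.sum() > 0:
        pair = None
        if exact_fit_first:
            for i in np.argsort(-r):
                if r[i] <= 0:
                    continue
                matches = np.nonzero(c == r[i])[0]
                if matches.size:
                    pair = (int(i), int(matches[0]))
                    break
        if pair is None:
            pair = (int(np.argmax(r)), int(np.argmax(c)))
        i, j = pair
        add = min(r[i], c[j])
        table[i, j] += add
        r[i] -= add
        c[j] -= add
    return table


def _subset_exact(values: list[tuple[int, int]], target: int) -> list[int] | None:
    """Indices of a subset of (index, value) pairs summing exactly to target."""
    reachable: dict[int, list[int]] = {0: []}
    for idx, val in values:
        updates = {}
        for s, picked in reachable.items():
            ns = s + val
            if ns <= target and ns not in reachable:
                updates[ns] = picked + [idx]
        reachable.update(updates)
        if target in reachable:
            return reachable[target]
    return reachable.get(target)


def _pack_subset(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Packing that fills the largest remaining column with a subset of
    remaining row totals summing exactly to it, when one exists; otherwise
    falls back to the largest-pair rule for that step."""
    r = r.copy()
    c = c.copy()
    table = np.zeros((r.size, c.size), dtype=np.int64)
    while r.sum() > 0:
        j = int(np.argmax(c))
        live = [(int(i), int(r[i])) for i in np.nonzero(r > 0)[0]]
        subset = (
            _subset_exact(live, int(c[j])) if c[j] <= 100_000 else None
        )
        if subset:
            for i in subset:
                table[i, j] += r[i]
                c[j] -= r[i]
                r[i] = 0
        else:
            i = int(np.argmax(r))
            add = min(r[i], c[j])
            table[i, j] += add
            r[i] -= add
            c[j] -= add
    return table


def min_entropy_table(row_totals: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Integer table with the given marginals of (near-)minimal entropy.

    Several greedy packings (largest-pair, exact-fit-first, and
    subset-fit in both orientations), each polished by a cycle-transfer
    descent; the lowest-entropy result wins.
    """
    r = np.asarray(row_totals, dtype=np.int64)
    c = np.asarray(col_totals, dtype=np.int64)
    if r.sum() != c.sum():
        raise ValueError("marginal sums differ")
    starts = [
        _pack_greedy(r, c, exact_fit_first=False),
        _pack_greedy(r, c, exact_fit_first=True),
        _pack_subset(r, c),
        _pack_subset(c, r).T,
    ]
    candidates = [_hillclimb_entropy(s, maximize=False) for s in starts]
    return min(candidates, key=_table_entropy)


@dataclass(frozen=True)
class H2Result:
    h2: float
    h2_max: float
    h2_min: float
    h2_prime: float
    mode: str
    degenerate: bool = False


def h2prime(matrix, mode: str = "continuous") -> H2Result:
    """Network-level complementary specialisation H2'.

    H2 is the Shannon entropy of p_ij = a_ij / m over positive cells;
    H2' = (H2_max - H2) / (H2_max - H2_min), clipped to [0, 1].

    ``continuous`` mode uses the analytic extremes: H2_max = sum of the two
    marginal entropies (the independence surface) and H2_min = max of the
    marginal entropies (the joint entropy of a maximally specialised
    coupling). ``integer_heuristic`` mode computes both extremes as integer
    tables sharing the observed marginals (largest-remainder/greedy
    allocation with a 2x2-transfer polish), matching the discrete
    standardization used for count data.

    Degenerate matrices (a single non-empty row or column) have
    H2_max = H2_min; they return H2' = 0 with the ``degenerate`` flag.
    """
    w = _as_weights(matrix)
    m = w.sum()
    if m <= 0:
        raise ValueError("H2' undefined for an all-zero matrix")
    rows = w.sum(axis=1)
    cols = w.sum(axis=0)
    h2 = shannon_entropy(w)
    if (rows > 0).sum() < 2 or (cols > 0).sum() < 2:
        h_deg = max(shannon_entropy(rows), shannon_entropy(cols))
        return H2Result(h2, h_deg, h_deg, 0.0, mode, degenerate=True)
    if mode == "continuous":
        h_rows = shannon_entropy(rows)
        h_cols = shannon_entropy(cols)
        h_max = h_rows + h_cols
        h_min = max(h_rows, h_cols)
    elif mode == "integer_heuristic":
        ints, _ = to_integer_matrix(w)
        r = ints.sum(axis=1)
        c = ints.sum(axis=0)
        h_max = _table_entropy(max_entropy_table(r, c))
        h_min = _table_entropy(min_entropy_table(r, c))
        h2 = _table_entropy(ints)
    else:
        raise ValueError(f"unknown H2' mode {mode!r}")
    if h_max - h_min <= 1e-12:
        return H2Result(h2, h_max, h_min, 0.0, mode, degenerate=True)
    prime = float(np.clip((h_max - h2) / (h_max - h_min), 0.0, 1.0))
    return H2Result(float(h2), float(h_max), float(h_min), prime, mode)


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

def nodf(matrix, binarize_threshold: float = 0.0) -> float:
    """Binary nestedness by paired overlap and decreasing fill (0..100).

    Presence = weight > ``binarize_threshold``. For every ordered pair of
    rows (and of columns) the paired nestedness is 0 unless the first is
    strictly more filled, in which case it is 100 x (shared presences) /
    (fill of the sparser); NODF averages over all row and column pairs.
    """
    w = _as_weights(matrix)
    if w.size == 0 or w.shape[0] < 2 or w.shape[1] < 2:
        raise ValueError("NODF needs at least a 2x2 matrix")
    b = (w > binarize_threshold).astype(np.int64)
    if b.sum() == 0:
        raise ValueError("NODF undefined for an empty binary matrix")

    def axis_sum(mat: np.ndarray) -> tuple[float, int]:
        fills = mat.sum(axis=1)
        n = mat.shape[0]
        total = 0.0
        for u in range(n):
            for v in range(u + 1, n):
                hi, lo = (u, v) if fills[u] > fills[v] else (v, u)
                if fills[hi] == fills[lo] or fills[lo] == 0:
                    continue
                shared = int(np.minimum(mat[hi], mat[lo]).sum())
                total += 100.0 * shared / fills[lo]
        return total, n * (n - 1) // 2

    row_sum, row_pairs = axis_sum(b)
    col_sum, col_pairs = axis_sum(b.T)
    return float((row_sum + col_sum) / (row_pairs + col_pairs))


# ---------------------------------------------------------------------------
# Weighted bipartite modularity
# ---------------------------------------------------------------------------

@dataclass
class ModulePartition:
    """Joint assignment of plant and bee nodes to modules.

    ``assignment`` maps ("plants"|"bees", label) to a module id; ``qw`` is
    the Barber weighted bipartite modularity of that assignment.
    """

    assignment: dict[tuple[str, str], int]
    qw: float
    n_modules: int
    restarts_used: int
    seed: int
    row_modules: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    col_modules: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def _qw(weights: np.ndarray, row_mod: np.ndarray, col_mod: np.ndarray) -> float:
    F = weights.sum()
    if F <= 0:
        raise ValueError("modularity undefined for an all-zero matrix")
    k = weights.sum(axis=1)
    d = weights.sum(axis=0)
    B = weights - np.outer(k, d) / F
    same = row_mod[:, None] == col_mod[None, :]
    return float(B[same].sum() / F)


def modularity_qw(matrix, partition) -> float:
    """Barber weighted modularity Q_w of a given joint partition.

    Q_w = (1/F) sum_ij (a_ij - k_i d_j / F) [module(plant i) == module(bee j)].
    """
    w = _as_weights(matrix)
    if isinstance(partition, ModulePartition):
        if partition.row_modules.size == w.shape[0]:
            return _qw(w, partition.row_modules, partition.col_modules)
        if not isinstance(matrix, InteractionMatrix):
            raise ValueError("need an InteractionMatrix to map labels")
        row_mod = np.array(
            [partition.assignment[("plants", l)] for l in matrix.row_labels]
        )
        col_mod = np.array(
            [partition.assignment[("bees", l)] for l in matrix.col_labels]
        )
        return _qw(w, row_mod, col_mod)
    row_mod, col_mod = partition
    row_mod = np.asarray(row_mod, dtype=int)
    col_mod = np.asarray(col_mod, dtype=int)
    if row_mod.size != w.shape[0] or col_mod.size != w.shape[1]:
        raise ValueError("partition does not cover all nodes")
    return _qw(w, row_mod, col_mod)


def _sweep(
    weights: np.ndarray,
    row_mod: np.ndarray,
    col_mod: np.ndarray,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Node-wise best-label moves until no move increases Q_w."""
    F = weights.sum()
    k = weights.sum(axis=1)
    d = weights.sum(axis=0)
    n_r, n_c = weights.shape

    def move(idx: int, own: np.ndarray, other: np.ndarray, contrib: np.ndarray) -> bool:
        labels = np.unique(np.concatenate([row_mod, col_mod]))
        fresh = int(labels.max()) + 1
        scores = {int(L): float(contrib[other == L].sum()) for L in labels}
        best_label = min(scores, key=lambda L: (-scores[L], L))
        best = scores[best_label]
        if best < 0:
            best_label, best = fresh, 0.0
        current = scores.get(int(own[idx]), 0.0)
        if best_label != own[idx] and best > current + 1e-15:
            own[idx] = best_label
            return True
        return False

    for _ in range(max_iter):
        changed = False
        # rows: S_i(L) = sum_{j in L} (a_ij - k_i d_j / F)
        for i in range(n_r):
            changed |= move(i, row_mod, col_mod, weights[i] - k[i] * d / F)
        for j in range(n_c):
            changed |= move(j, col_mod, row_mod, weights[:, j] - d[j] * k / F)
        if not changed:
            break
    return row_mod, col_mod


def _canonical(row_mod: np.ndarray, col_mod: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mapping: dict[int, int] = {}
    for L in list(row_mod) + list(col_mod):
        if int(L) not in mapping:
            mapping[int(L)] = len(mapping)
    return (
        np.array([mapping[int(L)] for L in row_mod]),
        np.array([mapping[int(L)] for L in col_mod]),
    )


def find_modules(matrix, n_restarts: int = 20, seed: int = 0) -> ModulePartition:
    """Maximize Q_w by seeded multi-restart weighted label propagation.

    The first restart initializes every plant in its own module; subsequent
    restarts draw a random initial module count and assignment. Each
    restart runs node-wise best-move sweeps to a local optimum; the best
    partition over restarts is kept. Ties in label choice break to the
    lowest module id, so results are deterministic under the seed.
    """
    w = _as_weights(matrix)
    if w.sum() <= 0:
        raise ValueError("cannot partition an all-zero matrix")
    n_r, n_c = w.shape
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            row_mod = np.arange(n_r)
        else:
            n_init = int(rng.integers(1, n_r + 1))
            row_mod = rng.integers(0, n_init, n_r)
        # initialize columns with their best label given the row labels
        F = w.sum()
        k = w.sum(axis=1)
        d = w.sum(axis=0)
        col_mod = np.empty(n_c, dtype=np.int64)
        for j in range(n_c):
            contrib = w[:, j] - d[j] * k / F
            scores = {
                int(L): float(contrib[row_mod == L].sum())
                for L in np.unique(row_mod)
            }
            col_mod[j] = min(scores, key=lambda L: (-scores[L], L))
        row_mod, col_mod = _sweep(w, row_mod.astype(np.int64).copy(), col_mod)
        q = _qw(w, row_mod, col_mod)
        if best is None or q > best[0] + 1e-15:
            best = (q, row_mod.copy(), col_mod.copy())
    q, row_mod, col_mod = best
    row_mod, col_mod = _canonical(row_mod, col_mod)
    assignment: dict[tuple[str, str], int] = {}
    if isinstance(matrix, InteractionMatrix):
        for l, L in zip(matrix.row_labels, row_mod):
            assignment[("plants", l)] = int(L)
        for l, L in zip(matrix.col_labels, col_mod):
            assignment[("bees", l)] = int(L)
    else:
        for i, L in enumerate(row_mod):
            assignment[("plants", str(i))] = int(L)
        for j, L in enumerate(col_mod):
            assignment[("bees", str(j))] = int(L)
    return ModulePartition(
        assignment=assignment,
        qw=float(q),
        n_modules=int(len(np.unique(np.concatenate([row_mod, col_mod])))),
        restarts_used=max(1, n_restarts),
        seed=seed,
        row_modules=row_mod,
        col_modules=col_mod,
    )


# ---------------------------------------------------------------------------
# Generality
# ---------------------------------------------------------------------------

def weighted_generality(matrix, level: str = "bees") -> float:
    """Effective mean number of partners at one trophic level.

    For each species k at the level, n_k = 2^H_k with H_k the base-2
    Shannon entropy of its interaction distribution; generality is the
    weighted mean sum_k (A_k / F) n_k over non-empty species.
    """
    w = _as_weights(matrix)
    if level == "bees":
        w = w.T
    elif level != "plants":
        raise ValueError("level must be 'bees' or 'plants'")
    totals = w.sum(axis=1)
    F = totals.sum()
    if F <= 0:
        raise ValueError(f"no interactions at level {level!r}")
    out = 0.0
    for k in range(w.shape[0]):
        if totals[k] <= 0:
            continue
        n_k = 2.0 ** shannon_entropy(w[k], base=2)
        out += (totals[k] / F) * n_k
    return float(out)
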
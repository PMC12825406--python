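"""Species-level indices: d', strength, and c/z module roles.

* ``dprime`` -- complementary specialisation of one species: the
  Kullback-Leibler divergence of its partner-use distribution from partner
  availability, standardized between the discrete minimum and maximum
  attainable with the species' interaction total;
* ``species_strength`` -- sum over partners of the partner's dependency on
  the focal species;
* ``cz_values`` -- among-module participation coefficient c and
  within-module standardized degree z, given a module partition;
* ``classify_role`` -- the peripheral / module-hub / connector /
  network-hub taxonomy with thresholds z = 2.5 and c = 0.62.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import FunctionalGroupMap, InteractionMatrix
from .metrics import ModulePartition
from .utils import to_integer_matrix


# ---------------------------------------------------------------------------
# d'
# ---------------------------------------------------------------------------

def _kl(alloc: np.ndarray, total: float, q: np.ndarray) -> float:
    """d = sum_j p'_j ln(p'_j / q_j) for an allocation of ``total`` units."""
    p = np.asarray(alloc, dtype=float) / total
    pos = p > 0
    return float((p[pos] * np.log(p[pos] / q[pos])).sum())


def _unit_descent(
    alloc: np.ndarray, total: int, q: np.ndarray, caps: np.ndarray, maximize: bool
) -> np.ndarray:
    """Exchange mass between partners while d improves.

    d is convex along any pairwise exchange direction: minimization is
    exact under single-unit moves, while maximization improves (if at all)
    at the endpoint, so the full feasible block is moved.
    """
    alloc = alloc.astype(np.int64).copy()
    sign = 1.0 if maximize else -1.0
    for _ in range(10 * total + 10):
        best_gain, best_move = 1e-12, None
        d0 = _kl(alloc, total, q)
        for src in np.nonzero(alloc > 0)[0]:
            for dst in np.nonzero(alloc < caps)[0]:
                if src == dst:
                    continue
                step = (
                    int(min(alloc[src], caps[dst] - alloc[dst]))
                    if maximize
                    else 1
                )
                alloc[src] -= step
                alloc[dst] += step
                gain = sign * (_kl(alloc, total, q) - d0)
                alloc[src] += step
                alloc[dst] -= step
                if gain > best_gain:
                    best_gain, best_move = gain, (src, dst, step)
        if best_move is None:
            break
        src, dst, step = best_move
        alloc[src] -= step
        alloc[dst] += step
    return alloc


def dmax_allocation(total: int, q: np.ndarray, caps: np.ndarray) -> np.ndarray:
    """Concentrate the focal total on the partners of smallest availability.

    Greedy by ascending q_j, each partner capped by its own marginal total.
    Because concentrating on a single slightly-commoner partner can beat
    splitting across two rare ones, every "anchor one partner first" start
    is also tried; each start is polished by an endpoint-exchange ascent
    and the best allocation wins.
    """
    order = np.lexsort((np.arange(q.size), q))

    def greedy(first: int | None) -> np.ndarray | None:
        alloc = np.zeros(q.size, dtype=np.int64)
        remaining = int(total)
        seq = list(order) if first is None else [first] + [
            j for j in order if j != first
        ]
        for j in seq:
            if remaining <= 0:
                break
            take = min(remaining, int(caps[j]))
            alloc[j] = take
            remaining -= take
        return None if remaining > 0 else alloc

    starts = [greedy(None)] + [greedy(j) for j in range(q.size)]
    starts = [s for s in starts if s is not None]
    if not starts:
        raise ValueError("partner totals cannot absorb the focal total")
    polished = [
        _unit_descent(s, int(total), q, caps, maximize=True) for s in starts
    ]
    return max(polished, key=lambda a: _kl(a, total, q))


def dmin_allocation(total: int, q: np.ndarray, caps: np.ndarray) -> np.ndarray:
    """Allocation matching the expected proportions total * q_j.

    Largest-remainder rounding (capped), then a single-unit exchange
    descent, which is exact for this separable-convex minimization.
    """
    expected = np.minimum(total * q, caps)
    alloc = np.floor(expected).astype(np.int64)
    residue = int(total) - int(alloc.sum())
    remainders = expected - alloc
    for j in np.lexsort((np.arange(q.size), -remainders)):
        if residue <= 0:
            break
        room = int(caps[j]) - alloc[j]
        add = min(room, residue)
        alloc[j] += add
        residue -= add
    if residue > 0:
        raise ValueError("partner totals cannot absorb the focal total")
    return _unit_descent(alloc, int(total), q, caps, maximize=False)


@dataclass(frozen=True)
class DPrimeResult:
    d: float
    d_min: float
    d_max: float
    d_prime: float
    clipped: bool = False


def dprime(matrix, species: str | int, level: str = "bees") -> DPrimeResult:
    """Species-level complementary specialisation d' in [0, 1].

    Partner availability q_j is the partner marginal total over the grand
    total. The discrete extremes d_min / d_max use integer allocations of
    the focal total over partners capped at partner totals; real-valued
    currencies are first rounded to faithful integer counts.
    """
    if isinstance(matrix, InteractionMatrix):
        w = matrix.weights
        labels = matrix.col_labels if level == "bees" else matrix.row_labels
        idx = labels.index(species) if isinstance(species, str) else int(species)
    else:
        w = np.asarray(matrix, dtype=float)
        idx = int(species)
    if level == "bees":
        w = w.T
    elif level != "plants":
        raise ValueError("level must be 'bees' or 'plants'")
    ints, _ = to_integer_matrix(w)
    focal = ints[idx]
    total = int(focal.sum())
    if total <= 0:
        raise ValueError(f"species {species!r} has no interactions")
    partner_totals = ints.sum(axis=0)
    m = ints.sum()
    q = partner_totals / m
    usable = partner_totals > 0
    d = _kl(focal[usable], total, q[usable])
    d_max_alloc = dmax_allocation(total, q[usable], partner_totals[usable])
    d_min_alloc = dmin_allocation(total, q[usable], partner_totals[usable])
    d_max = _kl(d_max_alloc, total, q[usable])
    d_min = _kl(d_min_alloc, total, q[usable])
    if d_max - d_min <= 1e-12:
        return DPrimeResult(d, d_min, d_max, 0.0)
    raw = (d - d_min) / (d_max - d_min)
    prime = float(np.clip(raw, 0.0, 1.0))
    return DPrimeResult(d, d_min, d_max, prime, clipped=not (0.0 <= raw <= 1.0))


# ---------------------------------------------------------------------------
# strength
# ---------------------------------------------------------------------------

def species_strength(matrix, level: str = "bees") -> np.ndarray:
    """Sum over partners of the partner's dependency on each species.

    Strength of bee j = sum_i a_ij / A_i over non-empty plant rows (and
    symmetrically for plants). Strengths at a level sum to the number of
    non-empty partner species.
    """
    w = np.asarray(
        matrix.weights if isinstance(matrix, InteractionMatrix) else matrix,
        dtype=float,
    )
    if level == "bees":
        totals = w.sum(axis=1, keepdims=True)
        dep = np.divide(w, totals, out=np.zeros_like(w), where=totals > 0)
        return dep.sum(axis=0)
    if level == "plants":
        totals = w.sum(axis=0, keepdims=True)
        dep = np.divide(w, totals, out=np.zeros_like(w), where=totals > 0)
        return dep.sum(axis=1)
    raise ValueError("level must be 'bees' or 'plants'")


# ---------------------------------------------------------------------------
# c / z and roles
# ---------------------------------------------------------------------------

Z_THRESHOLD = 2.5
C_THRESHOLD = 0.62


@dataclass(frozen=True)
class CZResult:
    c: float
    z: float
    z_defined: bool


def cz_values(
    matrix,
    partition: ModulePartition,
    degree_mode: str = "binary",
) -> tuple[list[CZResult], list[CZResult]]:
    """Participation coefficient c and within-module degree z per species.

    k_{i,t} counts the focal node's links (binary) or summed weights
    (weighted) to partners in module t. c_i = 1 - sum_t (k_{i,t}/k_i)^2;
    z_i standardizes the within-own-module degree against same-level
    members of the same module (z = 0 with a flag when the SD is zero or
    the module has a single member at that level). Returns (plant results,
    bee results) in matrix order.
    """
    if degree_mode not in ("binary", "weighted"):
        raise ValueError("degree_mode must be 'binary' or 'weighted'")
    w = np.asarray(
        matrix.weights if isinstance(matrix, InteractionMatrix) else matrix,
        dtype=float,
    )
    if degree_mode == "binary":
        w = (w > 0).astype(float)
    row_mod = partition.row_modules
    col_mod = partition.col_modules
    if row_mod.size != w.shape[0] or col_mod.size != w.shape[1]:
        raise ValueError("partition does not cover the matrix")
    modules = np.unique(np.concatenate([row_mod, col_mod]))

    def one_level(mat: np.ndarray, own: np.ndarray, other: np.ndarray) -> list[CZResult]:
        # k_by_mod[i, t]: node i's links to partners in module t
        k_by_mod = np.stack(
            [mat[:, other == t].sum(axis=1) for t in modules], axis=1
        )
        k_tot = k_by_mod.sum(axis=1)
        results = []
        k_own = np.array(
            [
                k_by_mod[i, int(np.searchsorted(modules, own[i]))]
                for i in range(mat.shape[0])
            ]
        )
        for i in range(mat.shape[0]):
            if k_tot[i] <= 0:
                results.append(CZResult(0.0, 0.0, False))
                continue
            shares = k_by_mod[i] / k_tot[i]
            c = float(1.0 - (shares**2).sum())
            members = np.nonzero(own == own[i])[0]
            vals = k_own[members]
            sd = vals.std(ddof=0)
            if members.size < 2 or sd == 0:
                results.append(CZResult(c, 0.0, False))
            else:
                results.append(
                    CZResult(c, float((k_own[i] - vals.mean()) / sd), True)
                )
        return results

    plants = one_level(w, row_mod, col_mod)
    bees = one_level(w.T, col_mod, row_mod)
    return plants, bees


ROLES = ("peripheral", "module_hub", "connector", "network_hub")


def classify_role(c: float, z: float) -> str:
    """Four-way module role from (c, z); boundaries are inclusive (<=)."""
    if not (np.isfinite(c) and np.isfinite(z)):
        raise ValueError("c and z must be finite")
    if z <= Z_THRESHOLD:
        return "peripheral" if c <= C_THRESHOLD else "connector"
    return "module_hub" if c <= C_THRESHOLD else "network_hub"


# ---------------------------------------------------------------------------
# assembled species table
# ---------------------------------------------------------------------------

def species_table(
    matrix: InteractionMatrix,
    partition: ModulePartition,
    group_map: FunctionalGroupMap | None = None,
    degree_mode: str = "binary",
) -> pd.DataFrame:
    """Per-species d', strength, c, z and role for one network.

    Species with empty marginals are reported with missing metric values.
    """
    plants_cz, bees_cz = cz_values(matrix, partition, degree_mode)
    strength_p = species_strength(matrix, "plants")
    strength_b = species_strength(matrix, "bees")
    rows = []
    for level, labels, czs, strengths in (
        ("plants", matrix.row_labels, plants_cz, strength_p),
        ("bees", matrix.col_labels, bees_cz, strength_b),
    ):
        totals = (
            matrix.row_totals if level == "plants" else matrix.col_totals
        )
        for i, label in enumerate(labels):
            if totals[i] <= 0:
                rows.append(
                    {
                        "label": label,
                        "level": level,
                        "group": group_map.get(label, "") if group_map else "",
                        "d_prime": np.nan,
                        "strength": np.nan,
                        "c": np.nan,
                        "z": np.nan,
                        "role": "",
                    }
                )
                continue
            try:
                d_prime = dprime(matrix, label, level).d_prime
            except ValueError:
                # positive but negligible weight can round to an empty
                # integer profile; d' is then undefined and reported missing
                d_prime = np.nan
            cz = czs[i]
            rows.append(
                {
                    "label": label,
                    "level": level,
                    "group": group_map.get(label, "") if group_map else "",
                    "d_prime": d_prime,
                    "strength": float(strengths[i]),
                    "c": cz.c,
                    "z": cz.z,
                    "role": classify_role(cz.c, cz.z),
                }
            )
    return pd.DataFrame(rows)
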
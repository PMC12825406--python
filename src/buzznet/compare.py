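"""Cross-currency statistics and the assembled comparison report.

Species-level metrics (strength, d', c, z) computed on different network
currencies are compared by paired t-tests (pairing species with themselves
across networks) and Pearson correlation tests. Correlations are reported
among the visitation and single-visit efficacy currencies (VN, DN, RN)
only: performance networks share the visitation component by construction,
which would force positive correlations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import FunctionalGroupMap, InteractionMatrix
from .metrics import ModulePartition, h2prime, modularity_qw, nodf, weighted_generality


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    n_pairs: int
    n_dropped: int
    degenerate: bool = False


def _pair(values_a, values_b) -> tuple[np.ndarray, np.ndarray, int]:
    """Align two species -> value collections by label, dropping incomplete pairs."""
    if isinstance(values_a, Mapping) or isinstance(values_a, pd.Series):
        a = pd.Series(values_a, dtype=float)
        b = pd.Series(values_b, dtype=float)
        labels = a.index.intersection(b.index)
        dropped = (len(a) - len(labels)) + (len(b) - len(labels))
        a, b = a.loc[labels], b.loc[labels]
    else:
        a = pd.Series(np.asarray(values_a, dtype=float))
        b = pd.Series(np.asarray(values_b, dtype=float))
        if len(a) != len(b):
            raise ValueError("unlabelled vectors must have equal length")
        dropped = 0
    keep = a.notna() & b.notna()
    dropped += int((~keep).sum())
    return a[keep].to_numpy(), b[keep].to_numpy(), dropped


def paired_t(values_a, values_b) -> TTestResult:
    """Paired two-sided t-test on species-wise differences.

    Inputs may be label -> value mappings/Series (paired by species label,
    species missing from either side dropped and counted) or equal-length
    vectors. Zero-variance nonzero differences return an infinite-t guard
    with p ~ 0 and the ``degenerate`` flag.
    """
    a, b, dropped = _pair(values_a, values_b)
    n = a.size
    if n < 3:
        raise ValueError(f"paired t-test needs >= 3 complete pairs, got {n}")
    diffs = a - b
    df = n - 1
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs.mean(), 0.0):
            return TTestResult(0.0, df, 1.0, n, dropped, degenerate=True)
        t = float(np.inf) if diffs.mean() > 0 else float(-np.inf)
        return TTestResult(t, df, 0.0, n, dropped, degenerate=True)
    res = stats.ttest_rel(a, b)
    return TTestResult(float(res.statistic), df, float(res.pvalue), n, dropped)


@dataclass(frozen=True)
class CorTestResult:
    r: float
    t: float
    df: int
    p: float
    n: int
    degenerate: bool = False


def pearson_cor_test(x, y) -> CorTestResult:
    """Pearson correlation with the t-based two-sided test.

    r over n complete pairs; t = r sqrt(df / (1 - r^2)) with df = n - 2.
    Zero variance in either vector leaves r undefined (NaN, flagged).
    """
    x, y, _ = _pair(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"correlation test needs >= 3 pairs, got {n}")
    df = n - 2
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        return CorTestResult(float("nan"), float("nan"), df, float("nan"), n, True)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return CorTestResult(r, float(np.inf) * np.sign(r), df, 0.0, n)
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorTestResult(r, float(t), df, float(p), n)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _round(x, nd: int = 10):
    if isinstance(x, float):
        if not np.isfinite(x):
            return None if np.isnan(x) else ("inf" if x > 0 else "-inf")
        return round(x, nd)
    return x


def _series(table: pd.DataFrame, level: str, column: str) -> pd.Series:
    sel = table[table["level"] == level].set_index("label")[column]
    return sel.dropna()


CORRELATION_CURRENCIES = ("VN", "DN", "RN")
TTEST_CURRENCIES = ("VN", "FPN", "MPN")


def currency_report(
    matrices: Mapping[str, InteractionMatrix],
    partitions: Mapping[str, ModulePartition],
    species_tables: Mapping[str, pd.DataFrame],
    null_results: Mapping[str, Mapping[str, dict]] | None = None,
    h2_mode: str = "continuous",
) -> dict:
    """Structured cross-currency comparison report.

    Contains the network-level metric grid for all five currencies,
    species-level paired t-tests (VN/FPN/MPN), Pearson correlations among
    the non-composite currencies (VN/DN/RN) for strength, d', c and z at
    both levels, and the species whose module role changes across
    currencies. The report is a plain JSON-serializable dict with sorted
    keys and rounded floats, so regeneration is byte-identical.
    """
    missing = [c for c in ("VN", "DN", "RN", "FPN", "MPN") if c not in matrices]
    if missing:
        raise ValueError(f"missing currencies: {missing}")

    grid = {}
    for name, matrix in matrices.items():
        trimmed, dropped = matrix.drop_empty()
        entry = {
            "n_plants": trimmed.shape[0],
            "n_bees": trimmed.shape[1],
            "grand_total": _round(trimmed.total, 6),
            "h2_prime": _round(h2prime(trimmed, mode=h2_mode).h2_prime),
            "nodf": _round(nodf(trimmed)),
            "generality_plants": _round(weighted_generality(trimmed, "plants")),
            "generality_bees": _round(weighted_generality(trimmed, "bees")),
            "dropped_plants": sorted(dropped["plants"]),
            "dropped_bees": sorted(dropped["bees"]),
        }
        if name in partitions:
            entry["q_w"] = _round(partitions[name].qw)
            entry["n_modules"] = partitions[name].n_modules
        if null_results and name in null_results:
            entry["null_significance"] = {
                k: dict(sorted(v.items())) for k, v in null_results[name].items()
            }
        grid[name] = entry

    ttests = {}
    for metric in ("strength", "d_prime"):
        for level in ("plants", "bees"):
            for i, a in enumerate(TTEST_CURRENCIES):
                for b in TTEST_CURRENCIES[i + 1 :]:
                    if a not in species_tables or b not in species_tables:
                        continue
                    sa = _series(species_tables[a], level, metric)
                    sb = _series(species_tables[b], level, metric)
                    try:
                        res = paired_t(sa, sb)
                    except ValueError:
                        continue
                    ttests[f"{metric}.{level}.{a}_vs_{b}"] = {
                        "t": _round(res.t),
                        "df": res.df,
                        "p": _round(res.p),
                        "n_pairs": res.n_pairs,
                        "n_dropped": res.n_dropped,
                    }

    correlations = {}
    for metric in ("strength", "d_prime", "c", "z"):
        for level in ("plants", "bees"):
            for i, a in enumerate(CORRELATION_CURRENCIES):
                for b in CORRELATION_CURRENCIES[i + 1 :]:
                    if a not in species_tables or b not in species_tables:
                        continue
                    sa = _series(species_tables[a], level, metric)
                    sb = _series(species_tables[b], level, metric)
                    try:
                        res = pearson_cor_test(sa, sb)
                    except ValueError:
                        continue
                    correlations[f"{metric}.{level}.{a}_vs_{b}"] = {
                        "r": _round(res.r),
                        "t": _round(res.t),
                        "df": res.df,
                        "p": _round(res.p),
                        "n": res.n,
                    }

    role_changes: dict[str, dict[str, str]] = {}
    roles_by_currency = {
        name: table.set_index(["level", "label"])["role"]
        for name, table in species_tables.items()
    }
    all_nodes = sorted(
        {node for roles in roles_by_currency.values() for node in roles.index}
    )
    for level, label in all_nodes:
        roles = {
            name: str(roles_by_currency[name].get((level, label), ""))
            for name in sorted(roles_by_currency)
        }
        distinct = {r for r in roles.values() if r}
        if len(distinct) > 1:
            role_changes[f"{level}.{label}"] = roles

    return {
        "network_metrics": grid,
        "paired_t_tests": ttests,
        "correlations": correlations,
        "role_changes": role_changes,
    }


def report_to_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys, fixed formatting)."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=False)
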
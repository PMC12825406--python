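"""Fixed-marginal null ensembles and CI-based significance.

The null family holds both marginal totals of the interaction matrix fixed
and draws uniformly from the association-free (multivariate hypergeometric)
distribution of contingency tables, by pairing the fixed row-label multiset
with a uniformly permuted column-label multiset and tallying. Significance
of a metric is judged against the 2.5th/97.5th percentiles of the metric
over the null ensemble.

Real-valued currencies (per-visit efficacies and performance networks) are
first rounded to faithful integer count matrices, since the null family is
defined for integer tables; the scale is chosen by
:func:`buzznet.utils.to_integer_matrix` and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data_model import InteractionMatrix
from .utils import to_integer_matrix


def fixed_marginal_sample(
    row_totals: np.ndarray,
    col_totals: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One uniform-association table with the given integer marginals."""
    r = np.asarray(row_totals)
    c = np.asarray(col_totals)
    if np.any(r < 0) or np.any(c < 0):
        raise ValueError("marginal totals must be nonnegative")
    if not (
        np.allclose(r, np.round(r)) and np.allclose(c, np.round(c))
    ):
        raise ValueError("marginal totals must be integers")
    r = np.round(r).astype(np.int64)
    c = np.round(c).astype(np.int64)
    if r.sum() != c.sum():
        raise ValueError(
            f"marginal sums differ: rows {r.sum()} vs columns {c.sum()}"
        )
    row_idx = np.repeat(np.arange(r.size), r)
    col_idx = rng.permutation(np.repeat(np.arange(c.size), c))
    flat = np.bincount(row_idx * c.size + col_idx, minlength=r.size * c.size)
    return flat.reshape(r.size, c.size)


@dataclass
class NullEnsemble:
    """Observed metric versus its fixed-marginal null distribution."""

    metric_name: str
    observed: float
    null_values: list[float]
    ci_low: float
    ci_high: float
    significant: bool
    direction: str  # above / below / inside
    runs: int
    seed: int
    n_failures: int = 0
    integer_scale: float = 1.0

    def summary(self) -> dict:
        return {
            "metric": self.metric_name,
            "observed": self.observed,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "significant": self.significant,
            "direction": self.direction,
            "runs": self.runs,
            "seed": self.seed,
        }


def null_test(
    matrix,
    metric: Callable[[np.ndarray], float],
    runs: int = 1000,
    seed: int = 0,
    metric_name: str = "metric",
    max_failure_rate: float = 0.05,
) -> NullEnsemble:
    """Fixed-marginal significance test of a network metric.

    The metric is evaluated on the observed (integer-rounded) matrix and on
    ``runs`` null tables sharing its marginals; the 95% CI is the
    2.5th/97.5th percentile of the null values (linear interpolation), and
    the observation is significant when it falls strictly outside. Draws
    where the metric fails are recorded as missing; more than
    ``max_failure_rate`` failures aborts.
    """
    w = np.asarray(
        matrix.weights if isinstance(matrix, InteractionMatrix) else matrix,
        dtype=float,
    )
    ints, scale = to_integer_matrix(w)
    observed = float(metric(ints))
    rng = np.random.default_rng(seed)
    r = ints.sum(axis=1)
    c = ints.sum(axis=0)
    values: list[float] = []
    failures = 0
    for _ in range(runs):
        draw = fixed_marginal_sample(r, c, rng)
        try:
            value = float(metric(draw))
        except Exception:
            failures += 1
            continue
        if not np.isfinite(value):
            failures += 1
            continue
        values.append(value)
    if failures > max_failure_rate * runs:
        raise RuntimeError(
            f"{metric_name}: {failures}/{runs} null draws failed "
            f"(> {max_failure_rate:.0%}); diagnostics: marginals "
            f"r={r.tolist()} c={c.tolist()}"
        )
    ci_low, ci_high = np.percentile(values, [2.5, 97.5])
    if observed > ci_high:
        direction = "above"
    elif observed < ci_low:
        direction = "below"
    else:
        direction = "inside"
    return NullEnsemble(
        metric_name=metric_name,
        observed=observed,
        null_values=values,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        significant=direction != "inside",
        direction=direction,
        runs=runs,
        seed=seed,
        n_failures=failures,
        integer_scale=scale,
    )
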
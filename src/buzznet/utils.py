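"""Shared numeric helpers."""

from __future__ import annotations

import numpy as np


def is_integer_matrix(weights: np.ndarray, atol: float = 1e-9) -> bool:
    return bool(np.allclose(weights, np.round(weights), atol=atol))


def to_integer_matrix(
    weights: np.ndarray,
    target_total: float = 2000.0,
    rel_cell_tol: float = 0.005,
) -> tuple[np.ndarray, float]:
    """Round a nonnegative matrix to integer counts for marginal-fixing.

    Integer matrices pass through unchanged (scale 1). Real-valued matrices
    (per-visit efficacy and performance currencies) are rescaled by the
    smallest power of ten that (a) keeps the per-cell rounding error within
    ``rel_cell_tol`` of the grand total and (b) leaves a grand total of at
    least ``target_total`` counts, then rounded. Returns (integer matrix,
    scale); original-unit values are ``ints / scale``.
    """
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("cannot integerize an all-zero matrix")
    if is_integer_matrix(weights):
        return np.round(weights).astype(np.int64), 1.0
    scale = 10.0 ** np.ceil(np.log10(target_total / total))
    for _ in range(64):
        scaled = weights * scale
        rounded = np.round(scaled)
        if (
            rounded.sum() >= target_total / 2
            and np.abs(rounded / scale - weights).max() <= rel_cell_tol * total
        ):
            return rounded.astype(np.int64), float(scale)
        scale *= 10.0
    raise ValueError("could not find a faithful integer scaling")
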
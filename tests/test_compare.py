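import json

import numpy as np
import pandas as pd
import pytest

from buzznet.compare import (
    currency_report,
    paired_t,
    pearson_cor_test,
    report_to_json,
)
from buzznet.metrics import find_modules
from buzznet.species import species_table


def test_paired_t_identical_vectors():
    res = paired_t([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert res.t == 0.0
    assert res.p == 1.0


def test_paired_t_constant_shift_guard():
    a = np.arange(5, dtype=float)
    res = paired_t(a + 1.0, a)
    assert np.isinf(res.t) and res.t > 0
    assert res.p == 0.0
    assert res.degenerate


def test_paired_t_pairs_by_label_and_counts_drops():
    a = pd.Series({"s1": 1.0, "s2": 2.0, "s3": 3.0, "s4": 9.0})
    b = pd.Series({"s1": 1.5, "s2": 1.0, "s3": 4.0, "s5": 0.0})
    res = paired_t(a, b)
    assert res.n_pairs == 3
    assert res.n_dropped == 2


def test_paired_t_needs_three_pairs():
    with pytest.raises(ValueError):
        paired_t([1.0, 2.0], [2.0, 1.0])


def test_paired_t_power_at_one_sd_shift():
    """Rejection rate of a 1-SD shift at n=30 tracks the closed-form power."""
    from scipy import stats

    rng = np.random.default_rng(0)
    n, reps, alpha = 30, 400, 0.05
    rejections = 0
    for _ in range(reps):
        base = rng.normal(0.0, 1.0, n)
        shifted = base + rng.normal(1.0, 1.0, n)  # paired diff ~ N(1, 1)
        if paired_t(shifted, base).p < alpha:
            rejections += 1
    nc = 1.0 * np.sqrt(n)  # noncentrality for d = 1
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    power = 1 - stats.nct.cdf(tcrit, n - 1, nc) + stats.nct.cdf(-tcrit, n - 1, nc)
    assert rejections / reps == pytest.approx(power, abs=0.05)


def test_pearson_perfect_linear():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = pearson_cor_test(x, 2 * x)
    assert res.r == pytest.approx(1.0)
    assert res.p == 0.0


def test_pearson_t_from_r_and_df():
    """r = 0.72 at df = 29 gives t ~ 5.59 (the printed 5.57 reflects an
    unrounded r)."""
    r, df = 0.72, 29
    t = r * np.sqrt(df / (1 - r**2))
    assert t == pytest.approx(5.59, abs=0.01)
    # the same arithmetic via the public function
    rng = np.random.default_rng(1)
    x = rng.normal(size=31)
    res = pearson_cor_test(x, x + rng.normal(size=31))
    assert res.df == 29
    assert res.t == pytest.approx(
        res.r * np.sqrt(res.df / (1 - res.r**2)), abs=1e-12
    )


def test_pearson_zero_variance_flagged():
    res = pearson_cor_test([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
    assert np.isnan(res.r)
    assert res.degenerate


def test_pearson_type_one_error_rate():
    rng = np.random.default_rng(2)
    reps = 2000
    hits = 0
    for _ in range(reps):
        x = rng.normal(size=31)
        y = rng.normal(size=31)
        if pearson_cor_test(x, y).p < 0.05:
            hits += 1
    assert hits / reps == pytest.approx(0.05, abs=0.015)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def report_inputs(request):
    synth = request.getfixturevalue("synth")
    trimmed = synth["trimmed"]
    partitions = {
        name: find_modules(m, n_restarts=8, seed=i)
        for i, (name, m) in enumerate(trimmed.items())
    }
    tables = {
        name: species_table(m, partitions[name], synth["tables"].group_map)
        for name, m in trimmed.items()
    }
    return synth["matrices"], partitions, tables


def test_report_contains_metric_grid(report_inputs):
    matrices, partitions, tables = report_inputs
    report = currency_report(matrices, partitions, tables)
    assert set(report["network_metrics"]) == {"VN", "DN", "RN", "FPN", "MPN"}
    for entry in report["network_metrics"].values():
        for key in ("h2_prime", "nodf", "q_w", "generality_plants", "generality_bees"):
            assert key in entry
    # correlations restricted to non-composite currencies
    assert all(
        set(key.split(".")[2].split("_vs_")) <= {"VN", "DN", "RN"}
        for key in report["correlations"]
    )


def test_report_self_comparison_correlations_are_one(report_inputs):
    matrices, partitions, tables = report_inputs
    same_tables = {name: tables["VN"] for name in tables}
    report = currency_report(matrices, partitions, same_tables)
    for key, entry in report["correlations"].items():
        if entry["r"] is not None:
            assert entry["r"] == pytest.approx(1.0, abs=1e-9)


def test_report_regeneration_is_byte_identical(report_inputs):
    matrices, partitions, tables = report_inputs
    a = report_to_json(currency_report(matrices, partitions, tables))
    b = report_to_json(currency_report(matrices, partitions, tables))
    assert a == b
    json.loads(a)  # valid JSON
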
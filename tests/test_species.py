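import numpy as np
import pytest

from buzznet.data_model import InteractionMatrix
from buzznet.metrics import find_modules
from buzznet.species import (
    classify_role,
    cz_values,
    dmax_allocation,
    dmin_allocation,
    dprime,
    species_strength,
    species_table,
    _kl,
)

from _oracles import d_extremes, kl_d


# ---------------------------------------------------------------------------
# d'
# ---------------------------------------------------------------------------

def test_dprime_proportional_use_is_zero():
    # every bee uses plants proportionally to availability
    w = np.outer(np.array([4, 8]), np.array([3, 6, 3])) / 6.0
    w = np.round(w).astype(float)  # [[2,4,2],[4,8,4]] stays proportional
    res = dprime(w, 0, level="bees")
    assert res.d_prime == pytest.approx(0.0, abs=1e-12)


def test_dprime_exclusive_partner_is_one():
    w = np.array([[5.0, 0.0], [0.0, 3.0]])
    res = dprime(w, 0, level="bees")
    assert res.d_prime == pytest.approx(1.0)


def test_d_extremes_match_enumeration_toy():
    # 3 partners, focal total 4
    rng = np.random.default_rng(0)
    for _ in range(50):
        caps = rng.integers(1, 8, 3)
        total = int(min(4, caps.sum()))
        q = rng.dirichlet(np.ones(3))
        dmax_o, dmin_o = d_extremes(total, q, caps)
        got_max = _kl(dmax_allocation(total, q, caps), total, q)
        got_min = _kl(dmin_allocation(total, q, caps), total, q)
        assert got_max == pytest.approx(dmax_o, abs=1e-9)
        assert got_min == pytest.approx(dmin_o, abs=1e-9)


def test_dprime_zero_total_species_is_reported_missing():
    w = np.array([[1.0, 0.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="no interactions"):
        dprime(w, 1, level="bees")


def test_dprime_in_unit_interval_on_synthetic(synth):
    m = synth["trimmed"]["VN"]
    for j, bee in enumerate(m.col_labels):
        res = dprime(m, bee, "bees")
        assert 0.0 <= res.d_prime <= 1.0


# ---------------------------------------------------------------------------
# strength
# ---------------------------------------------------------------------------

def test_strength_exclusive_bee_on_all_plants():
    w = np.zeros((10, 2))
    w[:, 0] = 2.0
    assert species_strength(w, "bees")[0] == pytest.approx(10.0)


def test_strength_worked_example(toy_matrix):
    s = species_strength(toy_matrix, "bees")
    assert s[0] == pytest.approx(1.5)
    assert s[1] == pytest.approx(0.5)


def test_strength_sums_to_partner_count(synth):
    m = synth["trimmed"]["VN"]
    assert species_strength(m, "bees").sum() == pytest.approx(m.shape[0])
    assert species_strength(m, "plants").sum() == pytest.approx(m.shape[1])


# ---------------------------------------------------------------------------
# c / z
# ---------------------------------------------------------------------------

def _toy_partition(w, rm, cm):
    from buzznet.metrics import ModulePartition, _qw

    return ModulePartition(
        assignment={},
        qw=_qw(w, np.array(rm), np.array(cm)),
        n_modules=len(set(rm) | set(cm)),
        restarts_used=0,
        seed=0,
        row_modules=np.array(rm),
        col_modules=np.array(cm),
    )


def test_c_zero_when_all_links_within_module():
    w = np.zeros((3, 3))
    w[:2, :2] = 1.0
    w[2, 2] = 1.0
    part = _toy_partition(w, [0, 0, 1], [0, 0, 1])
    plants, bees = cz_values(w, part)
    assert plants[0].c == pytest.approx(0.0)
    assert bees[2].c == pytest.approx(0.0)


def test_c_half_for_even_split_across_two_modules():
    w = np.array([[1.0, 1.0]])
    part = _toy_partition(w, [0], [0, 1])
    plants, _ = cz_values(w, part)
    assert plants[0].c == pytest.approx(0.5)


def test_cz_match_hand_worked_toy():
    # 3 plants x 3 bees, modules {p0,p1,b0,b1} and {p2,b2}
    w = np.array(
        [
            [2.0, 1.0, 0.0],
            [1.0, 1.0, 1.0],
            [0.0, 0.0, 2.0],
        ]
    )
    part = _toy_partition(w, [0, 0, 1], [0, 0, 1])
    plants, bees = cz_values(w, part, degree_mode="binary")
    # plant degrees to module 0 (binary): p0: 2, p1: 2 -> sd 0 -> z flagged 0
    assert plants[0].z == 0.0 and not plants[0].z_defined
    # p0: both links in own module -> c = 0; p1: 2 of 3 in module 0
    assert plants[0].c == pytest.approx(0.0)
    assert plants[1].c == pytest.approx(1 - (2 / 3) ** 2 - (1 / 3) ** 2)
    # b2 alone in module 1 at its level -> z flagged
    assert bees[2].z == 0.0 and not bees[2].z_defined


def test_z_mean_zero_within_modules(synth):
    m = synth["trimmed"]["VN"]
    part = find_modules(m, n_restarts=10, seed=3)
    plants, bees = cz_values(m, part)
    for level, results, mods in (
        ("plants", plants, part.row_modules),
        ("bees", bees, part.col_modules),
    ):
        for mod in np.unique(mods):
            zs = [r.z for r, mm in zip(results, mods) if mm == mod and r.z_defined]
            if zs:
                assert np.mean(zs) == pytest.approx(0.0, abs=1e-9)


def test_c_below_one(synth):
    m = synth["trimmed"]["VN"]
    part = find_modules(m, n_restarts=10, seed=3)
    plants, bees = cz_values(m, part)
    assert all(0.0 <= r.c < 1.0 for r in plants + bees)


# ---------------------------------------------------------------------------
# roles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "c,z,expected",
    [
        (0.5, 3.0, "module_hub"),
        (0.62, 2.5, "peripheral"),  # boundaries are inclusive
        (0.7, 1.0, "connector"),
        (0.63, 2.51, "network_hub"),
        (0.0, 0.0, "peripheral"),
    ],
)
def test_classify_role_thresholds(c, z, expected):
    assert classify_role(c, z) == expected


def test_species_table_shape_and_roles(synth):
    m = synth["trimmed"]["VN"]
    part = find_modules(m, n_restarts=10, seed=3)
    table = species_table(m, part, synth["tables"].group_map)
    assert len(table) == m.shape[0] + m.shape[1]
    assert set(table.role.unique()) <= {
        "peripheral", "module_hub", "connector", "network_hub",
    }
    bees = table[table.level == "bees"]
    assert set(bees.group.unique()) <= {
        "flower_buzzing", "anther_buzzing", "robber", "thief",
    }
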
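import numpy as np
import pandas as pd
import pytest

from buzznet.data_model import ReferenceFlower, SingleVisitRecord
from buzznet.efficacy import (
    ClampDiagnostics,
    effectiveness_landscape,
    group_efficacy_summary,
    pollen_deposited,
    pollen_removed,
    reference_means,
    replicate_cv,
    scale_aliquot,
    single_visit_efficacies,
)


@pytest.mark.parametrize(
    "args,expected",
    [((50, 10, 240), 1200), ((0, 10, 240), 0), ((7.5, 30, 30), 7.5)],
)
def test_scale_aliquot(args, expected):
    assert scale_aliquot(*args) == pytest.approx(expected)


def test_scale_aliquot_rejects_bad_volumes():
    with pytest.raises(ValueError):
        scale_aliquot(10, 0, 240)
    with pytest.raises(ValueError):
        scale_aliquot(10, 300, 240)


def test_replicate_cv_constant_replicates():
    summary = replicate_cv([100] * 6)
    assert summary.cv == 0.0
    assert not summary.flagged


def test_replicate_cv_outlier_flagged():
    summary = replicate_cv([10, 1000])
    assert summary.cv == pytest.approx(1.386, abs=1e-3)
    assert summary.flagged


def test_replicate_cv_requires_two_replicates():
    with pytest.raises(ValueError):
        replicate_cv([10])


def test_replicate_cv_all_zero_flagged_with_reason():
    summary = replicate_cv([0, 0, 0])
    assert summary.cv is None
    assert summary.flagged
    assert "zero" in summary.reason


@pytest.mark.parametrize(
    "ref,remaining,expected,clamps",
    [(1000, 400, 600, 0), (1000, 1000, 0, 0), (1000, 1100, 0, 1)],
)
def test_pollen_removed_clamps(ref, remaining, expected, clamps):
    diag = ClampDiagnostics()
    assert pollen_removed(ref, remaining, diag) == expected
    assert diag.removal_clamped == clamps


@pytest.mark.parametrize(
    "stigma,control,expected,clamps",
    [(30, 5, 25, 0), (5, 5, 0, 0), (3, 5, 0, 1)],
)
def test_pollen_deposited_clamps(stigma, control, expected, clamps):
    diag = ClampDiagnostics()
    assert pollen_deposited(stigma, control, diag) == expected
    assert diag.deposition_clamped == clamps


def test_reference_means_exclude_flagged_flowers():
    refs = [
        ReferenceFlower("P1", "unvisited_anther_reference", (100.0,) * 6),
        ReferenceFlower("P1", "unvisited_anther_reference", (10.0, 1000.0, 10, 10, 10, 10)),
    ]
    means, _, flagged = reference_means(refs, aliquot_factor=1.0)
    assert means["P1"] == pytest.approx(100.0)
    assert flagged["P1"] == 1
    means_keep, _, _ = reference_means(refs, exclude_flagged=False, aliquot_factor=1.0)
    assert means_keep["P1"] > 100.0


def test_single_record_summary_is_identity():
    from buzznet.data_model import FunctionalGroupMap
    from buzznet.efficacy import EfficacyRecord

    gmap = FunctionalGroupMap.from_pairs([("B1", "robber"), ("B2", "thief")])
    effs = [
        EfficacyRecord("P1", "B1", 500.0, 2.0),
        EfficacyRecord("P1", "B2", 50.0, 1.0),
    ]
    by_group, by_pair = group_efficacy_summary(effs, gmap)
    row = by_pair[(by_pair.plant_species == "P1") & (by_pair.bee_species == "B1")]
    assert row.removal_mean.iloc[0] == 500.0
    assert np.isnan(row.removal_sd.iloc[0])  # n = 1 leaves SD undefined
    assert row.n.iloc[0] == 1


def test_summary_invariant_to_record_order(synth):
    effs = synth["efficacies"]
    gmap = synth["tables"].group_map
    a, _ = group_efficacy_summary(effs, gmap)
    b, _ = group_efficacy_summary(list(reversed(effs)), gmap)
    pd.testing.assert_frame_equal(a, b)


def test_group_means_recover_generator_anchors(synth):
    """Flower-buzzing deposition mean is near the configured 24.4 anchor."""
    by_group, _ = group_efficacy_summary(
        synth["efficacies"], synth["tables"].group_map
    )
    by_group = by_group.set_index("group")
    fb = by_group.loc["flower_buzzing"]
    assert fb.deposition_mean == pytest.approx(24.4, rel=0.25)
    # robbers remove clearly more than any other group
    rem = by_group["removal_mean"]
    assert rem["robber"] > 1.5 * rem.drop("robber").max()


def test_efficacies_are_nonnegative(synth):
    assert all(e.removal >= 0 and e.deposition >= 0 for e in synth["efficacies"])


def test_landscape_isoclines_product_levels():
    pts = pd.DataFrame(
        {"male": [2.0, 4.0], "female": [3.0, 1.0], "group": ["a", "b"]}
    )
    scape = effectiveness_landscape(pts, levels=[6.0])
    iso = scape.isocline(6.0)
    np.testing.assert_allclose(iso["male"] * iso["female"], 6.0)
    # the point (2, 3) lies on the level-6 isocline by the product definition
    assert 2.0 * 3.0 == pytest.approx(6.0)
    # inputs are not mutated
    assert list(pts.columns) == ["male", "female", "group"]


def test_landscape_levels_scale_with_coordinates():
    pts = pd.DataFrame({"male": [1.0, 4.0], "female": [2.0, 3.0]})
    base = effectiveness_landscape(pts)
    k = 5.0
    scaled = effectiveness_landscape(pts.assign(male=pts.male * k))
    np.testing.assert_allclose(
        np.asarray(scaled.isocline_levels), k * np.asarray(base.isocline_levels)
    )


def test_landscape_rejects_negative_coordinates():
    with pytest.raises(ValueError):
        effectiveness_landscape(pd.DataFrame({"male": [-1.0], "female": [1.0]}))
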
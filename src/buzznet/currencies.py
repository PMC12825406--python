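"""Building the five network currencies.

From a visitation matrix (VN) and per-visit efficacy records, build the
pollen deposition (DN) and removal/release (RN) matrices of mean per-visit
efficacy per plant x bee pair, and combine them with visitation into the
female (FPN = VN x DN) and male (MPN = VN x RN) performance networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import FunctionalGroupMap, InteractionMatrix, ValidationError
from .efficacy import EfficacyRecord

IMPUTATION_POLICIES = ("zero", "group_mean", "group_plant_mean", "bee_mean")


@dataclass
class ImputationReport:
    policy: str
    observed_cells: int
    imputed_cells: int
    zero_cells: int


def efficacy_matrix(
    efficacies: Sequence[EfficacyRecord],
    kind: str,
    plant_labels: Sequence[str],
    bee_labels: Sequence[str],
    group_map: FunctionalGroupMap | None = None,
    imputation: str = "group_plant_mean",
    visited: np.ndarray | None = None,
) -> tuple[InteractionMatrix, ImputationReport]:
    """Mean per-visit efficacy matrix (currency DN or RN).

    Cells are the mean single-visit efficacy over records for that pair.
    Pairs with no single-visit data are handled per ``imputation``:

    - ``zero``: left at 0;
    - ``group_mean``: mean over the bee's functional group;
    - ``group_plant_mean``: mean over the bee's group on that plant, falling
      back to the group mean, then 0 (default);
    - ``bee_mean``: the bee species' mean across plants, falling back to 0.

    When ``visited`` (boolean plants x bees) is given, only visited pairs
    are imputed; unvisited pairs stay 0 (they are absorbed by the zero visit
    count on combination anyway). Per-cell provenance is recorded as
    observed/imputed/zero.
    """
    if kind not in ("deposition", "removal"):
        raise ValueError("kind must be 'deposition' or 'removal'")
    if not efficacies:
        raise ValidationError("no single-visit efficacy records")
    if imputation not in IMPUTATION_POLICIES:
        raise ValueError(f"unknown imputation policy {imputation!r}")
    if imputation in ("group_mean", "group_plant_mean") and group_map is None:
        raise ValueError(f"policy {imputation!r} requires a functional group map")

    plants = [str(p) for p in plant_labels]
    bees = [str(b) for b in bee_labels]
    p_index = {p: i for i, p in enumerate(plants)}
    b_index = {b: j for j, b in enumerate(bees)}

    sums = np.zeros((len(plants), len(bees)))
    counts = np.zeros((len(plants), len(bees)), dtype=int)
    for rec in efficacies:
        if rec.plant_species not in p_index:
            raise ValidationError(f"unknown plant label {rec.plant_species!r}")
        if rec.bee_species not in b_index:
            raise ValidationError(f"unknown bee label {rec.bee_species!r}")
        value = rec.deposition if kind == "deposition" else rec.removal
        sums[p_index[rec.plant_species], b_index[rec.bee_species]] += value
        counts[p_index[rec.plant_species], b_index[rec.bee_species]] += 1

    weights = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    provenance = np.where(counts > 0, "observed", "zero").astype(object)

    if group_map is not None:
        group_map.require(bees)
    group_of = np.array([group_map[b] if group_map else "" for b in bees])

    # candidate cells for imputation: no data, but (if known) visited
    candidates = counts == 0
    if visited is not None:
        candidates &= np.asarray(visited, dtype=bool)

    if imputation != "zero":
        obs_mask = counts > 0
        for i in range(len(plants)):
            for j in range(len(bees)):
                if not candidates[i, j]:
                    continue
                value = None
                if imputation in ("group_mean", "group_plant_mean"):
                    same_group = group_of == group_of[j]
                    if imputation == "group_plant_mean":
                        sel = obs_mask[i] & same_group
                        if sel.any():
                            value = weights[i, sel].mean()
                    if value is None:
                        sel = obs_mask & same_group[None, :]
                        if sel.any():
                            value = weights[sel].mean()
                elif imputation == "bee_mean":
                    sel = obs_mask[:, j]
                    if sel.any():
                        value = weights[sel, j].mean()
                if value is not None:
                    weights[i, j] = value
                    provenance[i, j] = "imputed"

    currency = "DN" if kind == "deposition" else "RN"
    matrix = InteractionMatrix(weights, plants, bees, currency, provenance=provenance)
    report = ImputationReport(
        policy=imputation,
        observed_cells=int((provenance == "observed").sum()),
        imputed_cells=int((provenance == "imputed").sum()),
        zero_cells=int((provenance == "zero").sum()),
    )
    return matrix, report


def combine_currency(
    vn: InteractionMatrix, efficacy: InteractionMatrix
) -> InteractionMatrix:
    """Performance network: cell-wise visits x mean per-visit efficacy.

    DN efficacy yields the female performance network (FPN); RN yields the
    male performance network (MPN).
    """
    if vn.currency != "VN":
        raise ValidationError(f"first matrix must be VN, got {vn.currency}")
    if efficacy.currency not in ("DN", "RN"):
        raise ValidationError(
            f"second matrix must be DN or RN, got {efficacy.currency}"
        )
    if vn.row_labels != efficacy.row_labels or vn.col_labels != efficacy.col_labels:
        diff_r = set(vn.row_labels) ^ set(efficacy.row_labels)
        diff_c = set(vn.col_labels) ^ set(efficacy.col_labels)
        raise ValidationError(
            f"label frames differ: plants {sorted(diff_r)}, bees {sorted(diff_c)}"
        )
    currency = "FPN" if efficacy.currency == "DN" else "MPN"
    return InteractionMatrix(
        vn.weights * efficacy.weights,
        list(vn.row_labels),
        list(vn.col_labels),
        currency,
    )


def build_all_currencies(
    vn: InteractionMatrix,
    efficacies: Sequence[EfficacyRecord],
    group_map: FunctionalGroupMap,
    imputation: str = "group_plant_mean",
) -> tuple[dict[str, InteractionMatrix], dict[str, ImputationReport]]:
    """Build the five currencies {VN, DN, RN, FPN, MPN} on VN's label frame."""
    visited = vn.weights > 0
    reports: dict[str, ImputationReport] = {}
    dn, reports["DN"] = efficacy_matrix(
        efficacies, "deposition", vn.row_labels, vn.col_labels,
        group_map, imputation, visited,
    )
    rn, reports["RN"] = efficacy_matrix(
        efficacies, "removal", vn.row_labels, vn.col_labels,
        group_map, imputation, visited,
    )
    return (
        {
            "VN": vn,
            "DN": dn,
            "RN": rn,
            "FPN": combine_currency(vn, dn),
            "MPN": combine_currency(vn, rn),
        },
        reports,
    )
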
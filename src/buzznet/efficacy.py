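"""Single-visit pollen accounting: per-visit male and female efficacy.

Male performance per visit is pollen removed from the anthers, estimated by
subtracting the grains remaining after one visit from the mean grain count
of unvisited bagged reference flowers. Anther counts come from a
haemocytometer aliquot (default 10 ul of a 240 ul suspension) and are scaled
to whole-flower totals. Reference flowers carry 6 replicate aliquot counts;
their coefficient of variation flags inconsistent counts. Female performance
per visit is conspecific pollen on the stigma minus the mean count on
unvisited control flowers (self-pollination baseline). Negative differences
are clamped to zero and counted as diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    FunctionalGroupMap,
    ReferenceFlower,
    SingleVisitRecord,
    ValidationError,
)

DEFAULT_CV_THRESHOLD = 0.2
DEFAULT_ALIQUOT_VOLUME = 10.0
DEFAULT_TOTAL_VOLUME = 240.0


def scale_aliquot(
    chamber_count: float,
    aliquot_volume: float = DEFAULT_ALIQUOT_VOLUME,
    total_volume: float = DEFAULT_TOTAL_VOLUME,
) -> float:
    """Scale a counting-chamber aliquot count to grains per flower."""
    if aliquot_volume <= 0:
        raise ValueError("aliquot volume must be positive")
    if aliquot_volume > total_volume:
        raise ValueError("aliquot volume exceeds total suspension volume")
    if chamber_count < 0:
        raise ValueError("chamber count must be nonnegative")
    return chamber_count * (total_volume / aliquot_volume)


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    cv: float | None
    flagged: bool
    reason: str = ""


def replicate_cv(
    replicate_counts: Sequence[float],
    threshold: float = DEFAULT_CV_THRESHOLD,
) -> ReplicateSummary:
    """Mean and coefficient of variation of replicate aliquot counts.

    CV = sample SD / mean; flowers with CV above ``threshold`` are flagged
    as inconsistent counts. All-zero replicates leave the CV undefined.
    """
    counts = np.asarray(replicate_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("CV requires at least 2 replicates")
    if np.any(counts < 0):
        raise ValueError("replicate counts must be nonnegative")
    mean = float(counts.mean())
    if mean == 0:
        return ReplicateSummary(0.0, None, True, reason="all-zero replicates")
    cv = float(counts.std(ddof=1) / mean)
    return ReplicateSummary(mean, cv, cv > threshold)


@dataclass
class ClampDiagnostics:
    """Counts of negative raw differences clamped to zero."""

    removal_clamped: int = 0
    deposition_clamped: int = 0
    events: list[str] = field(default_factory=list)

    def note(self, kind: str, message: str) -> None:
        if kind == "removal":
            self.removal_clamped += 1
        else:
            self.deposition_clamped += 1
        self.events.append(message)


def pollen_removed(
    reference_mean: float,
    remaining: float,
    diagnostics: ClampDiagnostics | None = None,
) -> float:
    """Grains removed in one visit: reference mean minus grains remaining."""
    if reference_mean < 0 or remaining < 0:
        raise ValueError("pollen counts must be nonnegative")
    diff = reference_mean - remaining
    if diff < 0:
        if diagnostics is not None:
            diagnostics.note(
                "removal",
                f"remaining {remaining} exceeds reference mean {reference_mean}",
            )
        return 0.0
    return diff


def pollen_deposited(
    stigma_count: float,
    control_mean: float,
    diagnostics: ClampDiagnostics | None = None,
) -> float:
    """Grains deposited in one visit: stigma count minus control mean."""
    if stigma_count < 0 or control_mean < 0:
        raise ValueError("pollen counts must be nonnegative")
    diff = stigma_count - control_mean
    if diff < 0:
        if diagnostics is not None:
            diagnostics.note(
                "deposition",
                f"stigma count {stigma_count} below control mean {control_mean}",
            )
        return 0.0
    return diff


# ---------------------------------------------------------------------------
# Reference means with CV quality control
# ---------------------------------------------------------------------------

def reference_means(
    references: Iterable[ReferenceFlower],
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    exclude_flagged: bool = True,
    aliquot_factor: float = DEFAULT_TOTAL_VOLUME / DEFAULT_ALIQUOT_VOLUME,
) -> tuple[dict[str, float], dict[str, float], dict[str, int]]:
    """Per-plant reference (anther) and control (stigma) means.

    Anther reference flowers are aliquot counts scaled by ``aliquot_factor``
    to whole-flower totals; flowers whose replicate CV exceeds the threshold
    are excluded from the mean by default. Stigma controls are exhaustive
    counts and enter unscaled. Returns (anther means, stigma control means,
    per-plant count of flagged reference flowers).
    """
    anther: dict[str, list[float]] = {}
    stigma: dict[str, list[float]] = {}
    flagged: dict[str, int] = {}
    for ref in references:
        if ref.kind == "unvisited_anther_reference":
            if len(ref.replicate_counts) >= 2:
                summary = replicate_cv(ref.replicate_counts, cv_threshold)
                if summary.flagged:
                    flagged[ref.plant_species] = flagged.get(ref.plant_species, 0) + 1
                    if exclude_flagged:
                        continue
                mean = summary.mean
            else:
                mean = float(np.mean(ref.replicate_counts))
            anther.setdefault(ref.plant_species, []).append(mean * aliquot_factor)
        else:
            stigma.setdefault(ref.plant_species, []).append(
                float(np.mean(ref.replicate_counts))
            )
    anther_means = {p: float(np.mean(v)) for p, v in anther.items()}
    stigma_means = {p: float(np.mean(v)) for p, v in stigma.items()}
    return anther_means, stigma_means, flagged


@dataclass
class EfficacyRecord:
    plant_species: str
    bee_species: str
    removal: float
    deposition: float


def single_visit_efficacies(
    single_visits: Sequence[SingleVisitRecord],
    references: Sequence[ReferenceFlower],
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    exclude_flagged: bool = True,
    aliquot_factor: float = DEFAULT_TOTAL_VOLUME / DEFAULT_ALIQUOT_VOLUME,
    diagnostics: ClampDiagnostics | None = None,
) -> list[EfficacyRecord]:
    """Per-record removal and deposition efficacies.

    Anther counts are chamber aliquots, scaled by ``aliquot_factor`` before
    reference subtraction; stigma counts are exhaustive and compared to the
    control mean directly.
    """
    anther_means, stigma_means, _ = reference_means(
        references, cv_threshold, exclude_flagged, aliquot_factor
    )
    out = []
    for rec in single_visits:
        if rec.plant_species not in anther_means:
            raise ValidationError(
                f"no anther reference flowers for plant {rec.plant_species!r}"
            )
        control = stigma_means.get(rec.plant_species, 0.0)
        removal = pollen_removed(
            anther_means[rec.plant_species],
            rec.anther_count_remaining * aliquot_factor,
            diagnostics,
        )
        deposition = pollen_deposited(rec.stigma_count, control, diagnostics)
        out.append(
            EfficacyRecord(rec.plant_species, rec.bee_species, removal, deposition)
        )
    return out


def group_efficacy_summary(
    efficacies: Sequence[EfficacyRecord],
    group_map: FunctionalGroupMap,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean/SD/n of removal and deposition per functional group and per pair.

    Returns (by_group, by_pair) frames; cells with n = 1 report SD as NaN.
    """
    if not efficacies:
        raise ValidationError("no efficacy records to summarize")
    group_map.require(e.bee_species for e in efficacies)
    frame = pd.DataFrame(
        {
            "plant_species": [e.plant_species for e in efficacies],
            "bee_species": [e.bee_species for e in efficacies],
            "group": [group_map[e.bee_species] for e in efficacies],
            "removal": [e.removal for e in efficacies],
            "deposition": [e.deposition for e in efficacies],
        }
    )
    agg = {"removal": ["mean", "std", "count"], "deposition": ["mean", "std"]}
    by_group = frame.groupby("group", sort=True).agg(agg)
    by_group.columns = [
        "removal_mean", "removal_sd", "n", "deposition_mean", "deposition_sd",
    ]
    by_pair = frame.groupby(["plant_species", "bee_species"], sort=True).agg(agg)
    by_pair.columns = by_group.columns
    return by_group.reset_index(), by_pair.reset_index()


# ---------------------------------------------------------------------------
# Effectiveness landscape
# ---------------------------------------------------------------------------

@dataclass
class EffectivenessLandscape:
    """Quantity x quality landscape: points plus constant-product isoclines."""

    points: pd.DataFrame  # columns: label, group, male, female
    isocline_levels: list[float]

    def isocline(self, level: float, n: int = 200) -> pd.DataFrame:
        """Hyperbola male * female = level, sampled over the point range."""
        male_max = max(float(self.points["male"].max()), 1e-12)
        lo = level / male_max
        hi = max(float(self.points["female"].max()), lo * 10)
        female = np.geomspace(max(lo, 1e-12), hi, n)
        return pd.DataFrame({"female": female, "male": level / female})


def effectiveness_landscape(
    points: pd.DataFrame,
    levels: Sequence[float] | None = None,
    n_levels: int = 4,
) -> EffectivenessLandscape:
    """Build the plot-ready effectiveness landscape.

    ``points`` must carry ``male`` and ``female`` columns (per-pair or
    per-species efficacies); isoclines are hyperbolas of constant product
    (total effectiveness). Input frame is not mutated.
    """
    required = {"male", "female"}
    if not required <= set(points.columns):
        raise ValueError(f"points must have columns {sorted(required)}")
    coords = points[["male", "female"]].to_numpy(dtype=float)
    if np.any(~np.isfinite(coords)) or np.any(coords < 0):
        raise ValueError("coordinates must be finite and nonnegative")
    if levels is None:
        products = coords[:, 0] * coords[:, 1]
        positive = products[products > 0]
        if positive.size:
            levels = list(
                np.geomspace(positive.min(), positive.max(), n_levels)
            )
        else:
            levels = []
    return EffectivenessLandscape(points.copy(), [float(l) for l in levels])


def plot_landscape(landscape: EffectivenessLandscape, ax=None):
    """Render the landscape with matplotlib (log-log, isoclines dashed)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    pts = landscape.points
    groups = pts["group"] if "group" in pts else pd.Series(["all"] * len(pts))
    for g in sorted(groups.unique()):
        sel = groups == g
        ax.scatter(pts.loc[sel, "female"], pts.loc[sel, "male"], label=str(g), s=25)
    for level in landscape.isocline_levels:
        iso = landscape.isocline(level)
        ax.plot(iso["female"], iso["male"], "k--", lw=0.6, alpha=0.6)
    ax.set_xlabel("female efficacy (grains deposited per visit)")
    ax.set_ylabel("male efficacy (grains removed per visit)")
    ax.legend(fontsize=8)
    return ax
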
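"""Domain types, CSV readers/writers and validation.

The pipeline works with four raw tables (visitation records, single-visit
pollen counts, unvisited reference/control flowers and the bee functional
group map) plus weighted plant x bee interaction matrices tagged with the
"currency" used to weight the links:

``VN``  visitation frequency,
``DN``  mean per-visit pollen deposition,
``RN``  mean per-visit pollen removal (release),
``FPN`` female performance (visits x deposition),
``MPN`` male performance (visits x removal).

Plants are rows, bees (the higher trophic level) are columns throughout.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CURRENCIES = ("VN", "DN", "RN", "FPN", "MPN")
FUNCTIONAL_GROUPS = ("thief", "robber", "anther_buzzing", "flower_buzzing")
BEHAVIOURS = ("buzzing", "no_buzzing")
REFERENCE_KINDS = ("unvisited_anther_reference", "unvisited_stigma_control")


class SchemaError(ValueError):
    """A table is missing a mandatory column or uses an unknown schema."""


class ValidationError(ValueError):
    """A table row violates an invariant (negative count, bad label...)."""


@dataclass(frozen=True)
class VisitRecord:
    """One observed flower visit."""

    plant_species: str
    bee_species: str
    behaviour: str = "buzzing"
    touched_reproductive: bool = True
    observation_block: str = ""
    date: _dt.date | None = None
    row_number: int | None = None
    extra: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.plant_species or not self.bee_species:
            raise ValidationError(
                f"row {self.row_number}: empty plant or bee label"
            )
        if self.behaviour not in BEHAVIOURS:
            raise ValidationError(
                f"row {self.row_number}: behaviour {self.behaviour!r} not in "
                f"{BEHAVIOURS}"
            )


@dataclass(frozen=True)
class SingleVisitRecord:
    """Pollen counts from a flower exposed to exactly one bee visit.

    ``anther_count_remaining`` is the pollen count in the counting-chamber
    aliquot of the macerated-anther suspension (scaled to whole-flower grain
    numbers by the accounting stage); ``stigma_count`` is the exhaustive count
    of conspecific grains on the stigma.
    """

    plant_species: str
    bee_species: str
    anther_count_remaining: float
    stigma_count: int
    row_number: int | None = None
    extra: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.plant_species or not self.bee_species:
            raise ValidationError(
                f"row {self.row_number}: empty plant or bee label"
            )
        if self.anther_count_remaining < 0:
            raise ValidationError(
                f"row {self.row_number}: anther_count_remaining "
                f"{self.anther_count_remaining} < 0"
            )
        if self.stigma_count < 0:
            raise ValidationError(
                f"row {self.row_number}: stigma_count {self.stigma_count} < 0"
            )


@dataclass(frozen=True)
class ReferenceFlower:
    """An unvisited bagged flower used as reference (anthers) or control (stigma)."""

    plant_species: str
    kind: str
    replicate_counts: tuple[float, ...]
    row_number: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in REFERENCE_KINDS:
            raise ValidationError(
                f"row {self.row_number}: kind {self.kind!r} not in {REFERENCE_KINDS}"
            )
        if len(self.replicate_counts) == 0:
            raise ValidationError(
                f"row {self.row_number}: no replicate counts"
            )
        if any(c < 0 for c in self.replicate_counts):
            raise ValidationError(
                f"row {self.row_number}: negative replicate count"
            )


class FunctionalGroupMap(dict):
    """Total mapping bee species -> functional group.

    Groups are the four behavioural classes of visitors to poricidal-anther
    flowers: ``thief`` (mouthpart collection, no damage), ``robber``
    (destructive anther/petal cutting), ``anther_buzzing`` (vibrates single
    anthers) and ``flower_buzzing`` (vibrates the whole flower).
    """

    def __setitem__(self, key: str, value: str) -> None:
        if value not in FUNCTIONAL_GROUPS:
            raise ValidationError(
                f"functional group {value!r} for {key!r} not in {FUNCTIONAL_GROUPS}"
            )
        super().__setitem__(key, value)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "FunctionalGroupMap":
        out = cls()
        for bee, group in pairs:
            out[bee] = group
        return out

    def group_members(self, group: str) -> list[str]:
        return sorted(b for b, g in self.items() if g == group)

    def require(self, bee_species: Iterable[str]) -> None:
        missing = sorted(set(bee_species) - set(self))
        if missing:
            raise ValidationError(
                f"bee species not in functional group map: {missing}"
            )


@dataclass
class InteractionMatrix:
    """Weighted bipartite plant x bee matrix with a currency tag.

    ``provenance`` optionally flags each cell of an efficacy or performance
    matrix as ``"observed"``, ``"imputed"`` or ``"zero"``.
    """

    weights: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    currency: str
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.row_labels = [str(r) for r in self.row_labels]
        self.col_labels = [str(c) for c in self.col_labels]
        if self.currency not in CURRENCIES:
            raise ValidationError(f"unknown currency {self.currency!r}")
        if self.weights.ndim != 2:
            raise ValidationError("weights must be 2-D")
        if self.weights.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError(
                f"weights shape {self.weights.shape} does not match labels "
                f"({len(self.row_labels)} x {len(self.col_labels)})"
            )
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValidationError("duplicate plant labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValidationError("duplicate bee labels")
        if np.any(self.weights < 0):
            raise ValidationError("negative interaction weights")
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("non-finite interaction weights")

    # -- basic quantities -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    @property
    def row_totals(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=self.row_labels, columns=self.col_labels
        )

    # -- bookkeeping ------------------------------------------------------
    def drop_empty(self) -> tuple["InteractionMatrix", dict[str, list[str]]]:
        """Return a copy without all-zero rows/columns, plus what was dropped.

        Metrics are undefined for empty marginals, so species retained as
        zero rows/columns in the bookkeeping frame are removed before metric
        computation; the dropped labels are returned for logging.
        """
        keep_r = self.row_totals > 0
        keep_c = self.col_totals > 0
        dropped = {
            "plants": [l for l, k in zip(self.row_labels, keep_r) if not k],
            "bees": [l for l, k in zip(self.col_labels, keep_c) if not k],
        }
        sub = InteractionMatrix(
            self.weights[np.ix_(keep_r, keep_c)],
            [l for l, k in zip(self.row_labels, keep_r) if k],
            [l for l, k in zip(self.col_labels, keep_c) if k],
            self.currency,
            provenance=None
            if self.provenance is None
            else self.provenance[np.ix_(keep_r, keep_c)],
        )
        return sub, dropped

    def require_nonempty(self) -> None:
        if self.total <= 0:
            raise ValidationError(
                f"{self.currency} matrix is all-zero; metrics are undefined"
            )

    # -- CSV dialect: first row bee labels, first column plant labels ------
    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        frame = self.to_frame()
        frame.index.name = "plant_species"
        frame.to_csv(path, float_format="%.12g")

    @classmethod
    def read_csv(cls, path: str | Path, currency: str) -> "InteractionMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            frame.to_numpy(dtype=float),
            list(frame.index.astype(str)),
            list(frame.columns.astype(str)),
            currency,
        )


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

_SCHEMAS: dict[str, tuple[str, ...]] = {
    "visits": ("plant_species", "bee_species"),
    "single_visits": (
        "plant_species",
        "bee_species",
        "anther_count_remaining",
        "stigma_count",
    ),
    "references": ("plant_species", "kind"),
    "groups": ("bee_species", "functional_group"),
}


def _load_frame(path: str | Path, schema: str) -> pd.DataFrame:
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown table kind {schema!r}")
    frame = pd.read_csv(path)
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    missing = [c for c in _SCHEMAS[schema] if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) {missing} for {schema} table"
        )
    return frame


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "y"):
        return True
    if text in ("false", "0", "no", "n"):
        return False
    raise ValidationError(f"cannot interpret {value!r} as boolean")


def read_visits(path: str | Path) -> list[VisitRecord]:
    frame = _load_frame(path, "visits")
    known = {
        "plant_species",
        "bee_species",
        "behaviour",
        "touched_reproductive",
        "observation_block",
        "date",
    }
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        data = dict(zip(frame.columns, row))
        date = None
        if "date" in data and not pd.isna(data["date"]):
            date = pd.Timestamp(data["date"]).date()
        records.append(
            VisitRecord(
                plant_species=str(data["plant_species"]),
                bee_species=str(data["bee_species"]),
                behaviour=str(data.get("behaviour", "buzzing")),
                touched_reproductive=_parse_bool(
                    data.get("touched_reproductive", True)
                ),
                observation_block=str(data.get("observation_block", "")),
                date=date,
                row_number=i,
                extra={k: v for k, v in data.items() if k not in known},
            )
        )
    return records


def read_single_visits(path: str | Path) -> list[SingleVisitRecord]:
    frame = _load_frame(path, "single_visits")
    known = set(_SCHEMAS["single_visits"])
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        data = dict(zip(frame.columns, row))
        records.append(
            SingleVisitRecord(
                plant_species=str(data["plant_species"]),
                bee_species=str(data["bee_species"]),
                anther_count_remaining=float(data["anther_count_remaining"]),
                stigma_count=int(data["stigma_count"]),
                row_number=i,
                extra={k: v for k, v in data.items() if k not in known},
            )
        )
    return records


def read_references(path: str | Path) -> list[ReferenceFlower]:
    """Read reference flowers; replicate aliquot counts live in columns
    ``replicate_1 .. replicate_k`` (missing values allowed past the first)."""
    frame = _load_frame(path, "references")
    rep_cols = sorted(
        (c for c in frame.columns if c.startswith("replicate_")),
        key=lambda c: int(c.split("_")[-1]),
    )
    if not rep_cols:
        raise SchemaError(f"{path}: no replicate_* columns in references table")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        data = dict(zip(frame.columns, row))
        reps = tuple(
            float(data[c]) for c in rep_cols if not pd.isna(data[c])
        )
        records.append(
            ReferenceFlower(
                plant_species=str(data["plant_species"]),
                kind=str(data["kind"]),
                replicate_counts=reps,
                row_number=i,
            )
        )
    return records


def read_group_map(path: str | Path) -> FunctionalGroupMap:
    frame = _load_frame(path, "groups")
    return FunctionalGroupMap.from_pairs(
        (str(r.bee_species), str(r.functional_group))
        for r in frame.itertuples(index=False)
    )


def read_tables(path: str | Path, schema: str):
    """Dispatch reader for one of the four table kinds."""
    readers = {
        "visits": read_visits,
        "single_visits": read_single_visits,
        "references": read_references,
        "groups": read_group_map,
    }
    if schema not in readers:
        raise SchemaError(f"unknown table kind {schema!r}")
    return readers[schema](path)


# ---------------------------------------------------------------------------
# Table writers (used by the synthetic generator and the pipeline)
# ---------------------------------------------------------------------------

def write_visits(records: Sequence[VisitRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "plant_species": [r.plant_species for r in records],
            "bee_species": [r.bee_species for r in records],
            "behaviour": [r.behaviour for r in records],
            "touched_reproductive": [r.touched_reproductive for r in records],
            "observation_block": [r.observation_block for r in records],
            "date": [r.date.isoformat() if r.date else "" for r in records],
        }
    ).to_csv(path, index=False)


def write_single_visits(
    records: Sequence[SingleVisitRecord], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "plant_species": [r.plant_species for r in records],
            "bee_species": [r.bee_species for r in records],
            "anther_count_remaining": [r.anther_count_remaining for r in records],
            "stigma_count": [r.stigma_count for r in records],
        }
    ).to_csv(path, index=False)


def write_references(records: Sequence[ReferenceFlower], path: str | Path) -> None:
    width = max(len(r.replicate_counts) for r in records)
    data: dict[str, list] = {
        "plant_species": [r.plant_species for r in records],
        "kind": [r.kind for r in records],
    }
    for k in range(width):
        data[f"replicate_{k + 1}"] = [
            r.replicate_counts[k] if k < len(r.replicate_counts) else ""
            for r in records
        ]
    pd.DataFrame(data).to_csv(path, index=False)


def write_group_map(group_map: FunctionalGroupMap, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bee_species": sorted(group_map),
            "functional_group": [group_map[b] for b in sorted(group_map)],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_counts(
    records: Sequence[VisitRecord],
    plant_labels: Sequence[str] | None = None,
    bee_labels: Sequence[str] | None = None,
    require_touch: bool = False,
) -> InteractionMatrix:
    """Tally visit records into a visitation matrix (currency ``VN``).

    ``plant_labels`` / ``bee_labels`` fix the matrix frame so that species
    with zero observed visits are kept as zero rows/columns. With
    ``require_touch`` visits that did not contact the reproductive
    structures are excluded (default keeps all recorded visits).
    """
    if not records:
        raise ValidationError("no visit records to aggregate")
    used = [r for r in records if r.touched_reproductive or not require_touch]
    plants = (
        [str(p) for p in plant_labels]
        if plant_labels is not None
        else sorted({r.plant_species for r in records})
    )
    bees = (
        [str(b) for b in bee_labels]
        if bee_labels is not None
        else sorted({r.bee_species for r in records})
    )
    p_index = {p: i for i, p in enumerate(plants)}
    b_index = {b: j for j, b in enumerate(bees)}
    weights = np.zeros((len(plants), len(bees)))
    for r in used:
        try:
            weights[p_index[r.plant_species], b_index[r.bee_species]] += 1
        except KeyError as exc:
            raise ValidationError(
                f"row {r.row_number}: species {exc.args[0]!r} not in matrix frame"
            ) from None
    return InteractionMatrix(weights, plants, bees, "VN")
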
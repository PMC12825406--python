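"""Synthetic buzz-pollination community generator.

Emulates the structure of a field study of bees visiting poricidal-anther
(*Chamaecrista*-like) pollen flowers: 10 plant species, 33 bee species in
four behavioural functional groups (6 flower-buzzing, 17 anther-buzzing,
2 robber, 4 thief), about 1838 visits in total with the two buzzing groups
contributing about 79% of them, plus single-visit pollen removal/deposition
experiments and unvisited reference/control flowers.

Visit counts per (bee, plant) pair follow a zero-inflated negative binomial;
per-visit pollen quantities follow zero-inflated lognormal bodies moment-
matched to configured (mean, sd); removal is truncated at the plant's
realized reference pollen total. Everything is reproducible under the
config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    FUNCTIONAL_GROUPS,
    FunctionalGroupMap,
    ReferenceFlower,
    SingleVisitRecord,
    VisitRecord,
)

GROUPS = ("flower_buzzing", "anther_buzzing", "robber", "thief")


class ConfigError(ValueError):
    """Synthetic configuration violates an invariant or is infeasible."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic community.

    ``visit_rate[(group, plant)]`` is the expected number of recorded visits
    (zero inflation included) by the whole group to that plant; within a
    group it is split across species by a geometric abundance series so one
    dominant species emerges, as in real visitation data. Per-visit
    ``deposition_params`` / ``removal_params`` are overall (mean, sd) in
    pollen grains, zero mass included.
    """

    n_plants: int = 10
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "flower_buzzing": 6,
            "anther_buzzing": 17,
            "robber": 2,
            "thief": 4,
        }
    )
    visit_rate: dict[tuple[str, str], float] = field(default_factory=dict)
    zero_inflation: dict[str, float] = field(
        default_factory=lambda: {
            "flower_buzzing": 0.20,
            "anther_buzzing": 0.30,
            "robber": 0.50,
            "thief": 0.40,
        }
    )
    dispersion: dict[str, float] = field(
        default_factory=lambda: {
            "flower_buzzing": 1.0,
            "anther_buzzing": 0.7,
            "robber": 0.5,
            "thief": 0.6,
        }
    )
    deposition_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "flower_buzzing": (24.4, 14.8),
            "anther_buzzing": (18.0, 12.0),
            "robber": (3.6, 3.3),
            "thief": (3.6, 3.3),
        }
    )
    removal_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "flower_buzzing": (12000.0, 8000.0),
            "anther_buzzing": (4000.0, 3500.0),
            "robber": (25671.2, 2418.3),
            "thief": (141.22, 320.4),
        }
    )
    deposition_zero: dict[str, float] = field(
        default_factory=lambda: {
            "flower_buzzing": 0.05,
            "anther_buzzing": 0.05,
            "robber": 0.25,
            "thief": 0.25,
        }
    )
    removal_zero: dict[str, float] = field(
        default_factory=lambda: {
            "flower_buzzing": 0.02,
            "anther_buzzing": 0.05,
            "robber": 0.0,
            "thief": 0.30,
        }
    )
    reference_total: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0
    # secondary knobs
    aliquot_factor: float = 24.0  # 240 ul suspension / 10 ul counted
    n_single_visits_per_plant: int = 91
    n_reference_flowers: int = 10
    stigma_selfing_mean: float = 2.0
    # pair-level morphological matching: per-visit removal for a (bee, plant)
    # pair scales with (that bee's visitation share on the plant)^exponent,
    # renormalized so the bee's visit-weighted mean stays at the group anchor.
    # Vibration-mediated pollen removal tracks the same flower-bee fit that
    # drives visitation; deposition is comparatively uniform across the
    # buzzing bees, so its default exponent is 0.
    removal_matching: float = 1.5
    deposition_matching: float = 0.0
    species_abundance_decay: dict[str, float] = field(
        default_factory=lambda: {
            "flower_buzzing": 0.50,
            "anther_buzzing": 0.85,
            "robber": 0.60,
            "thief": 0.70,
        }
    )

    def validate(self) -> None:
        if set(self.group_sizes) != set(GROUPS):
            raise ConfigError(
                f"group_sizes keys must be exactly {sorted(GROUPS)}"
            )
        for name, probs in (
            ("zero_inflation", self.zero_inflation),
            ("deposition_zero", self.deposition_zero),
            ("removal_zero", self.removal_zero),
        ):
            for g, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}[{g}] = {p} not a probability")
        for g, k in self.dispersion.items():
            if k <= 0:
                raise ConfigError(f"dispersion[{g}] = {k} must be positive")
        for params, zeros, what in (
            (self.deposition_params, self.deposition_zero, "deposition"),
            (self.removal_params, self.removal_zero, "removal"),
        ):
            for g, (mean, sd) in params.items():
                if sd < 0:
                    raise ConfigError(f"{what} sd for {g} is negative")
                p0 = zeros.get(g, 0.0)
                if p0 > 0 and sd == 0:
                    raise ConfigError(
                        f"{what} for {g}: sd=0 with zero-inflation>0 is an "
                        "infeasible moment match"
                    )
        for rate in self.visit_rate.values():
            if rate < 0:
                raise ConfigError("negative visit rate")

    @property
    def plant_labels(self) -> list[str]:
        return [f"plant_{i + 1:02d}" for i in range(self.n_plants)]

    @property
    def bee_labels(self) -> dict[str, list[str]]:
        prefix = {
            "flower_buzzing": "fb",
            "anther_buzzing": "ab",
            "robber": "ro",
            "thief": "th",
        }
        return {
            g: [f"{prefix[g]}{i + 1:02d}" for i in range(self.group_sizes[g])]
            for g in GROUPS
        }

    def group_map(self) -> FunctionalGroupMap:
        pairs = []
        for g, bees in self.bee_labels.items():
            pairs.extend((b, g) for b in bees)
        return FunctionalGroupMap.from_pairs(pairs)


# Group shares of total visitation: the two buzzing groups carry 79% of the
# rate mass, with flower-buzzing the most frequent manipulation behaviour.
_GROUP_SHARE = {
    "flower_buzzing": 0.45,
    "anther_buzzing": 0.34,
    "robber": 0.13,
    "thief": 0.08,
}
# How evenly each group spreads its visits over plants (higher = more even)
# and which end of the plant axis it prefers. Robbers are concentrated on a
# couple of abundant hosts; buzzing groups range widely.
_PREF_SCALE = {
    "flower_buzzing": 6.0,
    "anther_buzzing": 4.0,
    "robber": 1.2,
    "thief": 2.0,
}
_PREF_CENTER = {
    "flower_buzzing": 0,
    "anther_buzzing": 3,
    "robber": 7,
    "thief": 5,
}


def default_config(total_visits: float = 1838.0, seed: int = 0) -> SyntheticConfig:
    """Default study-scale configuration.

    10 plants x 33 bees, expected visit total ``total_visits``, buzzing
    groups holding 79% of the rate mass, per-visit pollen moments anchored
    to the group-level means/SDs of the emulated system.
    """
    cfg = SyntheticConfig(seed=seed)
    plants = cfg.plant_labels
    n = cfg.n_plants
    for g in GROUPS:
        center, scale = _PREF_CENTER[g], _PREF_SCALE[g]
        pref = np.exp(-np.minimum(
            np.abs(np.arange(n) - center), n - np.abs(np.arange(n) - center)
        ) / scale)
        pref = pref / pref.sum()
        for p, w in zip(plants, pref):
            cfg.visit_rate[(g, p)] = float(total_visits * _GROUP_SHARE[g] * w)
    for i, p in enumerate(plants):
        cfg.reference_total[p] = (28000.0 + 600.0 * i, 2500.0)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _zi_lognormal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    zero_prob: float,
    size: int,
) -> np.ndarray:
    """Zero-inflated lognormal with overall moments (mean, sd).

    The lognormal body is moment-matched so that the mixture (zeros
    included) has exactly the configured mean and sd.
    """
    if size == 0:
        return np.zeros(0)
    if mean == 0:
        return np.zeros(size)
    q = 1.0 - zero_prob
    if q <= 0:
        return np.zeros(size)
    body_mean = mean / q
    body_sq = (sd**2 + mean**2) / q
    body_var = body_sq - body_mean**2
    if body_var < 0:
        raise ConfigError(
            f"infeasible moment match: mean={mean}, sd={sd}, "
            f"zero_prob={zero_prob}"
        )
    if body_var == 0:
        draws = np.full(size, body_mean)
    else:
        sigma2 = np.log1p(body_var / body_mean**2)
        mu = np.log(body_mean) - sigma2 / 2.0
        draws = rng.lognormal(mu, np.sqrt(sigma2), size)
    zeros = rng.random(size) < zero_prob
    draws[zeros] = 0.0
    return draws


def _zinb(
    rng: np.random.Generator,
    mean: np.ndarray,
    dispersion: float,
    zero_prob: float,
) -> np.ndarray:
    """Zero-inflated negative binomial with overall expectation ``mean``."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    q = 1.0 - zero_prob
    pos = mean > 0
    if q <= 0 or not np.any(pos):
        return out
    body_mean = mean[pos] / q
    p = dispersion / (dispersion + body_mean)
    counts = rng.negative_binomial(dispersion, p)
    counts[rng.random(counts.shape) < zero_prob] = 0
    out[pos] = counts
    return out


@dataclass
class SyntheticTables:
    """Bundle of the four generated tables."""

    visits: list[VisitRecord]
    single_visits: list[SingleVisitRecord]
    references: list[ReferenceFlower]
    group_map: FunctionalGroupMap
    plant_labels: list[str]
    bee_labels: list[str]


_TOUCH_PROB = {
    "flower_buzzing": 0.95,
    "anther_buzzing": 0.85,
    "robber": 0.30,
    "thief": 0.20,
}


def _species_rates(cfg: SyntheticConfig) -> tuple[list[str], list[str], np.ndarray]:
    """Expand (group, plant) rates to a per-(plant, bee) rate matrix."""
    plants = cfg.plant_labels
    bees: list[str] = []
    cols: list[np.ndarray] = []
    n = cfg.n_plants
    for g in GROUPS:
        members = cfg.bee_labels[g]
        decay = cfg.species_abundance_decay[g]
        w = decay ** np.arange(len(members))
        w = w / w.sum()
        g_rates = np.array(
            [cfg.visit_rate.get((g, p), 0.0) for p in plants]
        )
        for s, (b, ws) in enumerate(zip(members, w)):
            # small deterministic per-species shift of the plant profile so
            # species in a group are similar but not proportional columns
            shifted = np.roll(g_rates, s % 3 - 1)
            shifted = shifted * (g_rates.sum() / shifted.sum()) if shifted.sum() else shifted
            bees.append(b)
            cols.append(ws * shifted)
    rates = np.column_stack(cols) if cols else np.zeros((n, 0))
    return plants, bees, rates


def generate(config: SyntheticConfig) -> SyntheticTables:
    """Draw one synthetic field season from the configured community."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    plants, bees, rates = _species_rates(config)
    group_map = config.group_map()
    bee_group = {b: group_map[b] for b in bees}

    # --- reference and control flowers (drawn first: removal truncates at
    # the realized reference totals) ---
    references: list[ReferenceFlower] = []
    ref_mean_realized: dict[str, float] = {}
    for p in plants:
        mean, sd = config.reference_total.get(p, (30000.0, 2500.0))
        totals = np.maximum(rng.normal(mean, sd, config.n_reference_flowers), 0.0)
        flower_means = []
        for total in totals:
            reps = rng.poisson(total / config.aliquot_factor, 6).astype(float)
            references.append(
                ReferenceFlower(p, "unvisited_anther_reference", tuple(reps))
            )
            flower_means.append(reps.mean() * config.aliquot_factor)
        ref_mean_realized[p] = float(np.mean(flower_means))
        for _ in range(config.n_reference_flowers):
            count = float(rng.poisson(config.stigma_selfing_mean))
            references.append(
                ReferenceFlower(p, "unvisited_stigma_control", (count,))
            )

    # --- visitation records ---
    visits: list[VisitRecord] = []
    if rates.size:
        group_of_col = np.array([bee_group[b] for b in bees])
        counts = np.zeros(rates.shape, dtype=int)
        for g in GROUPS:
            cols = group_of_col == g
            if not cols.any():
                continue
            counts[:, cols] = _zinb(
                rng,
                rates[:, cols],
                config.dispersion[g],
                config.zero_inflation[g],
            )
        block = 0
        for i, p in enumerate(plants):
            for j, b in enumerate(bees):
                g = bee_group[b]
                for _ in range(counts[i, j]):
                    block += 1
                    visits.append(
                        VisitRecord(
                            plant_species=p,
                            bee_species=b,
                            behaviour="buzzing"
                            if g in ("flower_buzzing", "anther_buzzing")
                            else "no_buzzing",
                            touched_reproductive=bool(
                                rng.random() < _TOUCH_PROB[g]
                            ),
                            observation_block=f"block_{block:05d}",
                        )
                    )

    # --- single-visit experiments ---
    # pair-level efficacy multipliers from morphological matching: for bee b
    # with plant shares s_p, mult_p = s_p^gamma / sum_p(s_p * s_p^gamma),
    # which keeps the bee's visit-weighted mean efficacy at the group anchor
    def _matching(gamma: float) -> np.ndarray:
        mult = np.ones_like(rates)
        if gamma <= 0 or rates.size == 0:
            return mult
        totals = rates.sum(axis=0, keepdims=True)
        shares = np.divide(rates, totals, out=np.zeros_like(rates), where=totals > 0)
        raw = shares**gamma
        norm = (shares * raw).sum(axis=0, keepdims=True)
        return np.divide(raw, norm, out=np.ones_like(raw), where=norm > 0)

    removal_mult = _matching(config.removal_matching)
    deposition_mult = _matching(config.deposition_matching)

    single_visits: list[SingleVisitRecord] = []
    for i, p in enumerate(plants):
        col_rates = rates[i]
        if col_rates.sum() <= 0:
            continue
        probs = col_rates / col_rates.sum()
        chosen = rng.choice(len(bees), size=config.n_single_visits_per_plant, p=probs)
        ref_total = ref_mean_realized[p]
        for j in chosen:
            b = bees[j]
            g = bee_group[b]
            dep_mean, dep_sd = config.deposition_params[g]
            rem_mean, rem_sd = config.removal_params[g]
            dep_k = deposition_mult[i, j]
            rem_k = removal_mult[i, j]
            deposited = float(
                _zi_lognormal(
                    rng, dep_mean * dep_k, dep_sd * dep_k,
                    config.deposition_zero[g], 1,
                )[0]
            )
            removed = float(
                _zi_lognormal(
                    rng, rem_mean * rem_k, rem_sd * rem_k,
                    config.removal_zero[g], 1,
                )[0]
            )
            removed = min(removed, ref_total)
            remaining_chamber = max(ref_total - removed, 0.0) / config.aliquot_factor
            stigma = int(round(deposited)) + int(
                rng.poisson(config.stigma_selfing_mean)
            )
            single_visits.append(
                SingleVisitRecord(
                    plant_species=p,
                    bee_species=b,
                    anther_count_remaining=remaining_chamber,
                    stigma_count=stigma,
                )
            )

    return SyntheticTables(
        visits=visits,
        single_visits=single_visits,
        references=references,
        group_map=group_map,
        plant_labels=plants,
        bee_labels=bees,
    )
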
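"""Seeded synthetic generators for site datasets and Delphi expert panels.

Both generators are deterministic functions of ``(config, seed)``.  Each
generated artifact (each site; the panel's items, each round's noise,
each round's dropouts) draws from its own pseudo-random stream spawned
from the master seed with :class:`numpy.random.SeedSequence`, so adding
a site or a round never perturbs earlier artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .delphi import LikertItem, ResponseMatrix, RoundPlan
from .errors import ConfigurationError
from .site_model import (
    M2_PER_HA,
    ClimateRecord,
    LimitingVariable,
    ManagementCapacity,
    RecreationZone,
    SiteProfile,
)

__all__ = [
    "ZoneClassSpec",
    "SiteGenConfig",
    "PanelGenConfig",
    "generate_site_dataset",
    "generate_panel",
    "expected_discretized_score",
    "DEFAULT_CUTPOINTS",
]

#: Cut-points mapping a latent continuous score onto the 1..5 scale:
#: scores below 1.5 -> 1, [1.5, 2.5) -> 2, ... , >= 4.5 -> 5.
DEFAULT_CUTPOINTS: tuple[float, ...] = (1.5, 2.5, 3.5, 4.5)


@dataclass(frozen=True)
class ZoneClassSpec:
    """One recreation class to generate per site."""

    use_type: str
    class_label: int
    area_fraction_range: tuple[float, float]  # fraction of site area, in [0, 1]
    space_per_visitor_m2: float

    def __post_init__(self) -> None:
        lo, hi = self.area_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(
                f"area_fraction_range must be ordered within [0, 1], got {self.area_fraction_range}"
            )
        if self.space_per_visitor_m2 <= 0:
            raise ConfigurationError("space_per_visitor_m2 must be > 0")


_DEFAULT_ZONE_CLASSES = (
    ZoneClassSpec("extensive", 1, (0.005, 0.02), 2500.0),
    ZoneClassSpec("extensive", 2, (0.005, 0.02), 2500.0),
    ZoneClassSpec("intensive", 1, (0.0005, 0.002), 1500.0),
    ZoneClassSpec("intensive", 2, (0.0005, 0.002), 1500.0),
)

_DEFAULT_CLIMATE_DAY_MEANS = {
    "Cf1": 15.0, "Cf2": 7.0, "Cf3": 6.0, "Cf4": 16.0,
    "Cf5": 100.0, "Cf6": 3.0, "Cf8": 40.0,
}


@dataclass(frozen=True)
class SiteGenConfig:
    """Configuration for :func:`generate_site_dataset`."""

    seed: int = 0
    n_sites: int = 3
    area_range_ha: tuple[float, float] = (2_000.0, 80_000.0)
    zone_classes: tuple[ZoneClassSpec, ...] = _DEFAULT_ZONE_CLASSES
    climate_day_means: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLIMATE_DAY_MEANS))
    operating_days_choices: tuple[int, ...] = (109, 155, 365)
    guardians_per_1000ha_range: tuple[float, float] = (0.2, 1.0)
    emc_fraction_range: tuple[float, float] = (0.2, 0.9)
    availability_hours: float = 8.0
    average_visit_hours: float = 8.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        lo, hi = self.area_range_ha
        if not (0 < lo <= hi):
            raise ConfigurationError(f"area_range_ha must be ordered positive, got {self.area_range_ha}")
        elo, ehi = self.emc_fraction_range
        if not (0.0 <= elo <= ehi <= 1.0):
            raise ConfigurationError("emc_fraction_range must be ordered within [0, 1]")
        max_fraction = sum(spec.area_fraction_range[1] for spec in self.zone_classes)
        if max_fraction > 1.0:
            raise ConfigurationError(
                f"zone area fractions can sum to {max_fraction:.3f} > 1; infeasible config")
        for mean in self.climate_day_means.values():
            if mean < 0:
                raise ConfigurationError("climate_day_means must be >= 0")


def generate_site_dataset(
    config: SiteGenConfig,
) -> tuple[list[SiteProfile], list[RecreationZone], list[ClimateRecord], list[ManagementCapacity]]:
    """Generate a consistent four-table site dataset.

    Climate day counts are Poisson draws truncated at 365 so they always
    satisfy the limiting-variable bound; Emc is a rounded fraction of the
    Imc implied by the one-guardian-per-1000-ha rule, clipped to
    ``[0, Imc]``.
    """
    master = np.random.SeedSequence(config.seed)
    site_seeds = master.spawn(config.n_sites)

    sites: list[SiteProfile] = []
    zones: list[RecreationZone] = []
    climate: list[ClimateRecord] = []
    management: list[ManagementCapacity] = []

    for i in range(config.n_sites):
        rng = np.random.default_rng(site_seeds[i])
        name = f"site_{i + 1:03d}"
        area_ha = float(rng.uniform(*config.area_range_ha))
        operating_days = int(rng.choice(np.asarray(config.operating_days_choices)))
        guardians_rate = float(rng.uniform(*config.guardians_per_1000ha_range))
        guardians = int(round(guardians_rate * area_ha / 1000.0))
        stations = int(rng.integers(1, 8))

        sites.append(SiteProfile(
            name=name,
            total_area_ha=round(area_ha, 1),
            guardians_count=guardians,
            guard_stations=stations,
            operating_days=operating_days,
            availability_hours=config.availability_hours,
            average_visit_hours=config.average_visit_hours,
            established_year=int(rng.integers(1960, 2021)),
            reported_annual_visitors=int(rng.integers(5_000, 400_000)),
        ))

        for spec in config.zone_classes:
            fraction = float(rng.uniform(*spec.area_fraction_range))
            zones.append(RecreationZone(
                site_name=name,
                use_type=spec.use_type,
                class_label=spec.class_label,
                area_m2=round(fraction * area_ha * M2_PER_HA, 0),
                space_per_visitor_m2=spec.space_per_visitor_m2,
            ))

        variables = []
        for code, mean in config.climate_day_means.items():
            count = int(min(rng.poisson(mean), 365))
            variables.append(LimitingVariable(
                code=code, magnitude=count, unit="days", total=365.0))
        climate.append(ClimateRecord(
            site_name=name,
            station_name=f"station_{i + 1:03d}",
            elevation_m=float(round(rng.uniform(500, 3500), 0)),
            latitude=f"{rng.uniform(25, 40):.4f}",
            longitude=f"{rng.uniform(44, 63):.4f}",
            variables=tuple(variables),
        ))

        imc = max(int(np.floor(area_ha / 1000.0 + 0.5)), 1)
        emc_fraction = float(rng.uniform(*config.emc_fraction_range))
        emc = int(np.clip(round(emc_fraction * imc), 0, imc))
        management.append(ManagementCapacity(site_name=name, imc=imc, emc=emc))

    return sites, zones, climate, management


# ---------------------------------------------------------------------------
# expert panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelGenConfig:
    """Configuration for :func:`generate_panel`.

    ``latent_item_means`` fixes the per-item latent means explicitly; if
    omitted they are drawn uniformly from ``latent_mean_range``.  Each
    response is the latent mean plus Gaussian noise of scale
    ``dispersion``, discretized onto 1..5 by ``cutpoints`` (values
    beyond the outer cut-points clamp to 1 or 5).
    """

    seed: int = 0
    n_experts: int = 38
    dimensions: tuple[tuple[str, int], ...] = (
        ("environmental-physical", 22),
        ("socio-cultural", 10),
        ("economic-institutional", 8),
    )
    latent_item_means: Optional[tuple[float, ...]] = None
    latent_mean_range: tuple[float, float] = (2.0, 4.5)
    dispersion: float = 1.0
    rounds: int = 3
    dropout_per_round: tuple[int, ...] = (0, 3, 2)
    removed_per_round: tuple[int, ...] = (2, 1, 1)
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS

    @property
    def n_items(self) -> int:
        return sum(count for _, count in self.dimensions)

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ConfigurationError("n_experts must be >= 1")
        if self.rounds < 1:
            raise ConfigurationError("rounds must be >= 1")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if len(self.dropout_per_round) < self.rounds:
            raise ConfigurationError("dropout_per_round must cover every round")
        if len(self.removed_per_round) < self.rounds:
            raise ConfigurationError("removed_per_round must cover every round")
        if sum(self.dropout_per_round[: self.rounds]) >= self.n_experts:
            raise ConfigurationError("total dropout must leave at least one respondent")
        if sum(self.removed_per_round[: self.rounds]) >= self.n_items:
            raise ConfigurationError("total removals must leave at least one item")
        if self.latent_item_means is not None:
            if len(self.latent_item_means) != self.n_items:
                raise ConfigurationError(
                    f"latent_item_means has {len(self.latent_item_means)} entries "
                    f"for {self.n_items} items")
            for m in self.latent_item_means:
                if not 1.0 <= m <= 5.0:
                    raise ConfigurationError("latent means must be in [1, 5]")
        if list(self.cutpoints) != sorted(self.cutpoints) or len(self.cutpoints) != 4:
            raise ConfigurationError("cutpoints must be four increasing thresholds")


def _discretize(latent: np.ndarray, cutpoints: Sequence[float]) -> np.ndarray:
    return 1 + np.searchsorted(np.asarray(cutpoints), latent, side="left")


def expected_discretized_score(
    latent_mean: float,
    dispersion: float,
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
) -> float:
    """Exact expectation of a discretized latent-plus-Gaussian response.

    This is the generator's probability table contracted with the score
    values — the independent oracle for mean-recovery tests.
    """
    cuts = np.asarray(cutpoints, dtype=float)
    if dispersion == 0:
        return float(_discretize(np.asarray([latent_mean]), cuts)[0])
    upper = stats.norm.cdf(cuts, loc=latent_mean, scale=dispersion)
    probs = np.diff(np.concatenate([[0.0], upper, [1.0]]))
    return float(np.dot(np.arange(1, 6), probs))


def generate_panel(
    config: PanelGenConfig,
) -> tuple[list[LikertItem], list[ResponseMatrix], list[RoundPlan]]:
    """Generate items, one full response matrix per round, and round plans.

    Matrices always contain every panel expert; attrition is expressed
    through the plans' nonrespondent lists, which are nested across
    rounds (an expert who drops out stays out).  Item removals are drawn
    without replacement from the items still retained.
    """
    master = np.random.SeedSequence(config.seed)
    seq_items, seq_latent, seq_rounds, seq_attrition = master.spawn(4)

    items: list[LikertItem] = []
    for dim, count in config.dimensions:
        start = len(items)
        for j in range(count):
            items.append(LikertItem(
                item_id=f"I{start + j + 1:03d}", dimension=dim,
                label=f"{dim} impact {j + 1}"))
    item_ids = [it.item_id for it in items]
    expert_ids = [f"E{k + 1:03d}" for k in range(config.n_experts)]

    if config.latent_item_means is not None:
        latent = np.asarray(config.latent_item_means, dtype=float)
    else:
        latent_rng = np.random.default_rng(seq_latent)
        latent = latent_rng.uniform(*config.latent_mean_range, size=config.n_items)

    round_seeds = seq_rounds.spawn(config.rounds)
    attrition_rng = np.random.default_rng(seq_attrition)

    matrices: list[ResponseMatrix] = []
    plans: list[RoundPlan] = []
    dropped: list[str] = []
    active_pool = list(expert_ids)
    retained = list(item_ids)

    for r in range(config.rounds):
        rng = np.random.default_rng(round_seeds[r])
        noise = rng.normal(0.0, config.dispersion, size=(config.n_experts, config.n_items))
        scores = _discretize(latent[None, :] + noise, config.cutpoints)
        scores = np.clip(scores, 1, 5)
        frame = pd.DataFrame(scores, index=expert_ids, columns=item_ids)
        matrices.append(ResponseMatrix(round_number=r + 1, frame=frame))

        n_drop = config.dropout_per_round[r]
        new_dropouts = sorted(
            attrition_rng.choice(np.asarray(active_pool), size=n_drop, replace=False).tolist()
        ) if n_drop else []
        dropped = dropped + new_dropouts
        active_pool = [e for e in active_pool if e not in set(new_dropouts)]

        n_remove = config.removed_per_round[r]
        removed = sorted(
            attrition_rng.choice(np.asarray(retained), size=n_remove, replace=False).tolist()
        ) if n_remove else []
        retained = [i for i in retained if i not in set(removed)]

        plans.append(RoundPlan(
            round_number=r + 1,
            removed_item_ids=tuple(removed),
            nonrespondent_expert_ids=tuple(dropped),
        ))

    return items, matrices, plans
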
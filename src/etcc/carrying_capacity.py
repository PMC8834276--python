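"""Visitor carrying-capacity engine.

Implements the three-stage capacity cascade used in protected-area
visitor management:

* **PCC** (physical carrying capacity): usable zone area divided by the
  per-visitor space standard, scaled by the daily rotation factor.
* **RCC** (real carrying capacity): PCC reduced by a set of limiting
  (correction) factors, each expressed as a percentage reduction
  ``Cf = m / Mt * 100``.  The default composition is multiplicative,
  ``RCC = PCC * prod((100 - Cf_i) / 100)``; a subtractive variant
  (``RCC = PCC - sum(Cf_i)``) is available behind a mode flag.
* **ECC** (effective carrying capacity): RCC reduced by the
  facility-management deficit ``FM = (Imc - Emc) / Imc * 100``, i.e.
  ``ECC = RCC * (100 - FM) / 100``.

Daily head-counts are integers under a configurable
:class:`RoundingPolicy`; annual counts are daily counts times the site's
operating days.  Full-precision (pre-rounding) values are carried
alongside the rounded integers so that reporting can choose its own
display precision.

The cascade is ordered: ``PCC >= RCC >= ECC`` for every computed result
(equality is legitimate when no limiting factors or no management
deficit apply).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from ._rounding import INT_ROUNDING_MODES, round_half_up, round_to_int
from .errors import ConfigurationError, DomainError, RecordValidationError, UsageError
from .site_model import (
    ClimateRecord,
    LimitingVariable,
    ManagementCapacity,
    RecreationZone,
    SiteProfile,
)

__all__ = [
    "DAYS_PER_YEAR",
    "CorrectionFactor",
    "RoundingPolicy",
    "CapacityResult",
    "rotation_factor",
    "physical_carrying_capacity",
    "annualize",
    "correction_factor",
    "correction_set_from_climate",
    "real_carrying_capacity",
    "ideal_management_capacity",
    "facility_management",
    "effective_carrying_capacity",
    "compute_site",
]

#: Default denominator for day-count limiting variables.
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class CorrectionFactor:
    """A limiting variable expressed as a percentage reduction."""

    code: str
    percent: float
    source_m: Optional[float] = None
    source_mt: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent <= 100.0:
            raise RecordValidationError(
                f"correction factor {self.code!r} percent must be in [0, 100], "
                f"got {self.percent}"
            )


@dataclass(frozen=True)
class RoundingPolicy:
    """Rounding conventions for the daily integer head-counts.

    The defaults (floor for PCC and RCC, ceiling for ECC, integer
    percentages) reproduce the published worked tables this engine was
    calibrated against.
    """

    pcc_daily: str = "floor"
    rcc_daily: str = "floor"
    ecc_daily: str = "ceiling"
    percent_decimals: int = 0

    def __post_init__(self) -> None:
        for name in ("pcc_daily", "rcc_daily", "ecc_daily"):
            mode = getattr(self, name)
            if mode not in INT_ROUNDING_MODES:
                raise UsageError(
                    f"{name} must be one of {INT_ROUNDING_MODES}, got {mode!r}"
                )
        if self.percent_decimals < 0:
            raise UsageError("percent_decimals must be >= 0")


@dataclass(frozen=True)
class CapacityResult:
    """The PCC/RCC/ECC bundle for one recreation-zone class."""

    site_name: str
    use_type: str
    class_label: int
    operating_days: int
    rf: float
    # physical stage
    pcc_exact: float
    pcc_daily: int
    pcc_annual: int
    # real stage
    cf_set: tuple[CorrectionFactor, ...] = ()
    rcc_exact: Optional[float] = None
    rcc_daily: Optional[int] = None
    rcc_annual: Optional[int] = None
    rcc_injected: bool = False
    # effective stage
    fm_percent: Optional[float] = None
    ecc_exact: Optional[float] = None
    ecc_daily: Optional[int] = None
    ecc_annual: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rcc_daily is not None and self.pcc_daily < self.rcc_daily:
            raise RecordValidationError(
                f"{self.site_name} {self.use_type}/{self.class_label}: "
                f"RCC daily {self.rcc_daily} exceeds PCC daily {self.pcc_daily}"
            )
        if (
            self.ecc_daily is not None
            and self.rcc_daily is not None
            and self.rcc_daily < self.ecc_daily
        ):
            raise RecordValidationError(
                f"{self.site_name} {self.use_type}/{self.class_label}: "
                f"ECC daily {self.ecc_daily} exceeds RCC daily {self.rcc_daily}"
            )

    @property
    def zone_key(self) -> tuple[str, str, int]:
        return (self.site_name, self.use_type, self.class_label)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def rotation_factor(availability_hours: float, average_visit_hours: float) -> float:
    """Daily visit turnover: availability hours over average visit length.

    >>> rotation_factor(12, 3)
    4.0
    """
    if availability_hours <= 0:
        raise DomainError(f"availability_hours must be > 0, got {availability_hours}")
    if average_visit_hours <= 0:
        raise DomainError(f"average_visit_hours must be > 0, got {average_visit_hours}")
    return availability_hours / average_visit_hours


def physical_carrying_capacity(
    area_m2: float,
    space_per_visitor_m2: float,
    rf: float,
    policy: RoundingPolicy = RoundingPolicy(),
) -> int:
    """Daily physical carrying capacity: ``area / space * rf`` rounded per policy.

    The area term is interpreted as one visitor (``V = 1``) per
    ``space_per_visitor_m2`` of usable area.
    """
    if area_m2 < 0:
        raise DomainError(f"area_m2 must be >= 0, got {area_m2}")
    if space_per_visitor_m2 <= 0:
        raise DomainError(f"space_per_visitor_m2 must be > 0, got {space_per_visitor_m2}")
    if rf <= 0:
        raise DomainError(f"rf must be > 0, got {rf}")
    return round_to_int(area_m2 / space_per_visitor_m2 * rf, policy.pcc_daily)


def annualize(daily: int, operating_days: int) -> int:
    """Annual visitor capacity: exact integer product of daily count and season length."""
    if daily < 0:
        raise DomainError(f"daily must be >= 0, got {daily}")
    if not 0 <= operating_days <= 366:
        raise DomainError(f"operating_days must be in [0, 366], got {operating_days}")
    return int(daily) * int(operating_days)


def correction_factor(
    limiting: LimitingVariable,
    percent_decimals: int = 0,
    *,
    total: Optional[float] = None,
) -> CorrectionFactor:
    """Percentage reduction for one limiting variable: ``m / Mt * 100`` half-up.

    ``total`` overrides the variable's own denominator when given.
    """
    mt = total if total is not None else limiting.total
    if mt is None or mt <= 0:
        raise DomainError(
            f"limiting variable {limiting.code!r} has no positive denominator (Mt)"
        )
    percent = round_half_up(limiting.magnitude / mt * 100.0, percent_decimals)
    percent = min(percent, 100.0)
    return CorrectionFactor(
        code=limiting.code, percent=percent, source_m=limiting.magnitude, source_mt=mt
    )


def correction_set_from_climate(
    record: ClimateRecord,
    mt_defaults: Optional[Mapping[str, float]] = None,
    *,
    percent_overrides: Optional[Mapping[str, float]] = None,
    percent_decimals: int = 0,
) -> list[CorrectionFactor]:
    """Build the ordered correction-factor list for one site's climate record.

    Day-unit variables fall back to a denominator of ``Mt = 365`` days.
    Hour-unit variables have no natural default denominator: each must
    either receive an explicit ``Mt`` (via the record or ``mt_defaults``)
    or an explicit ``percent_overrides`` entry, otherwise a
    :class:`~etcc.errors.ConfigurationError` naming the code is raised.
    """
    mt_defaults = dict(mt_defaults or {})
    percent_overrides = dict(percent_overrides or {})
    out: list[CorrectionFactor] = []
    for var in record.variables:
        if var.code in percent_overrides:
            pct = float(percent_overrides[var.code])
            out.append(CorrectionFactor(code=var.code, percent=pct,
                                        source_m=var.magnitude, source_mt=None))
            continue
        mt = var.total
        if mt is None:
            mt = mt_defaults.get(var.code)
        if mt is None and var.unit == "days":
            mt = DAYS_PER_YEAR
        if mt is None:
            raise ConfigurationError(
                f"hour-unit variable {var.code!r} for site {record.site_name!r} "
                "needs an explicit Mt or a percent override"
            )
        out.append(correction_factor(var, percent_decimals, total=mt))
    return out


def real_carrying_capacity(
    pcc_daily: float,
    cf_percents: Sequence[float],
    mode: str = "multiplicative",
    policy: RoundingPolicy = RoundingPolicy(),
    *,
    exact: bool = False,
) -> float | int:
    """Daily real carrying capacity from PCC and correction percentages.

    ``multiplicative`` (default) composes the reductions as a product of
    survival fractions; ``subtractive`` subtracts the raw terms from the
    PCC.  Results are floored at zero.  With ``exact=True`` the
    pre-rounding float is returned.
    """
    if pcc_daily < 0:
        raise DomainError(f"pcc_daily must be >= 0, got {pcc_daily}")
    if mode == "multiplicative":
        value = float(pcc_daily)
        for pct in cf_percents:
            if not 0.0 <= pct <= 100.0:
                raise DomainError(f"correction percent must be in [0, 100], got {pct}")
            value *= (100.0 - pct) / 100.0
    elif mode == "subtractive":
        for term in cf_percents:
            if term < 0:
                raise DomainError(f"subtractive term must be >= 0, got {term}")
        value = float(pcc_daily) - math.fsum(cf_percents)
    else:
        raise UsageError(f"unknown RCC mode {mode!r}; expected 'multiplicative' or 'subtractive'")
    value = max(value, 0.0)
    if exact:
        return value
    return max(round_to_int(value, policy.rcc_daily), 0)


def ideal_management_capacity(total_area_ha: float, hectares_per_guardian: float = 1000.0) -> int:
    """Guardian head-count needed at one guardian per ``hectares_per_guardian``.

    Half-up rounded, minimum one guardian.
    """
    if total_area_ha <= 0:
        raise DomainError(f"total_area_ha must be > 0, got {total_area_ha}")
    if hectares_per_guardian <= 0:
        raise DomainError(f"hectares_per_guardian must be > 0, got {hectares_per_guardian}")
    return max(int(round_half_up(total_area_ha / hectares_per_guardian)), 1)


def facility_management(imc: int, emc: int, percent_decimals: int = 0) -> float:
    """Facility-management deficit ``(Imc - Emc) / Imc * 100`` in percent.

    >>> facility_management(36, 14)
    61.0
    """
    if imc <= 0:
        raise DomainError(f"imc must be > 0, got {imc}")
    if not 0 <= emc <= imc:
        raise DomainError(f"emc must satisfy 0 <= emc <= imc, got emc={emc}, imc={imc}")
    return round_half_up((imc - emc) / imc * 100.0, percent_decimals)


def effective_carrying_capacity(
    rcc_daily: float,
    fm_percent: float,
    policy: RoundingPolicy = RoundingPolicy(),
    *,
    exact: bool = False,
) -> float | int:
    """Daily effective carrying capacity: ``RCC * (100 - FM) / 100``.

    Rounded per ``policy.ecc_daily`` (default ceiling) and floored at zero.
    """
    if rcc_daily < 0:
        raise DomainError(f"rcc_daily must be >= 0, got {rcc_daily}")
    if not 0.0 <= fm_percent <= 100.0:
        raise DomainError(f"fm_percent must be in [0, 100], got {fm_percent}")
    value = float(rcc_daily) * ((100.0 - fm_percent) / 100.0)
    if exact:
        return value
    return max(round_to_int(value, policy.ecc_daily), 0)


# ---------------------------------------------------------------------------
# site-level orchestration
# ---------------------------------------------------------------------------

def compute_site(
    profile: SiteProfile,
    zones: Iterable[RecreationZone],
    climate: Optional[ClimateRecord] = None,
    management: Optional[ManagementCapacity] = None,
    policy: RoundingPolicy = RoundingPolicy(),
    *,
    mt_defaults: Optional[Mapping[str, float]] = None,
    cf_percent_overrides: Optional[Mapping[str, float]] = None,
    rcc_injection: Optional[Mapping[tuple[str, str, int], int]] = None,
    rcc_mode: str = "multiplicative",
    strict: bool = True,
) -> list[CapacityResult]:
    """Run the full PCC -> RCC -> ECC cascade for every zone of one site.

    Parameters
    ----------
    rcc_injection
        Optional mapping ``(site, use_type, class_label) -> daily RCC``
        replacing the computed real-capacity stage for matching zones.
        This supports driving the effective stage from externally
        observed/published RCC figures when the computed ones are not the
        desired input.
    strict
        When true (default), a missing climate or management record
        raises :class:`~etcc.errors.ConfigurationError`.  When false the
        corresponding stages are left unset in the results.

    Returns
    -------
    list of :class:`CapacityResult`, one per zone, in input order.
    """
    zones = [z for z in zones if z.site_name == profile.name]
    if strict and climate is None:
        raise ConfigurationError(f"site {profile.name!r} has no climate record")
    if strict and management is None:
        raise ConfigurationError(f"site {profile.name!r} has no management record")
    if climate is not None and climate.site_name != profile.name:
        raise ConfigurationError(
            f"climate record is for {climate.site_name!r}, not {profile.name!r}"
        )
    if management is not None and management.site_name != profile.name:
        raise ConfigurationError(
            f"management record is for {management.site_name!r}, not {profile.name!r}"
        )

    rf = rotation_factor(profile.availability_hours, profile.average_visit_hours)
    cf_set: tuple[CorrectionFactor, ...] = ()
    if climate is not None:
        cf_set = tuple(correction_set_from_climate(
            climate, mt_defaults,
            percent_overrides=cf_percent_overrides,
            percent_decimals=policy.percent_decimals,
        ))
    fm: Optional[float] = None
    if management is not None:
        fm = facility_management(management.imc, management.emc, policy.percent_decimals)

    injection = dict(rcc_injection or {})
    results: list[CapacityResult] = []
    for zone in zones:
        pcc_exact = zone.area_m2 / zone.space_per_visitor_m2 * rf
        pcc_daily = physical_carrying_capacity(
            zone.area_m2, zone.space_per_visitor_m2, rf, policy)

        rcc_exact: Optional[float] = None
        rcc_daily: Optional[int] = None
        injected = False
        if zone.key in injection:
            rcc_daily = int(injection[zone.key])
            rcc_exact = float(rcc_daily)
            injected = True
        elif climate is not None:
            percents = [cf.percent for cf in cf_set]
            rcc_exact = real_carrying_capacity(
                pcc_exact, percents, rcc_mode, policy, exact=True)
            rcc_daily = real_carrying_capacity(pcc_daily, percents, rcc_mode, policy)

        ecc_exact: Optional[float] = None
        ecc_daily: Optional[int] = None
        if fm is not None and rcc_daily is not None:
            ecc_exact = effective_carrying_capacity(rcc_exact, fm, policy, exact=True)
            ecc_daily = effective_carrying_capacity(rcc_daily, fm, policy)

        results.append(CapacityResult(
            site_name=profile.name,
            use_type=zone.use_type,
            class_label=zone.class_label,
            operating_days=profile.operating_days,
            rf=rf,
            pcc_exact=pcc_exact,
            pcc_daily=pcc_daily,
            pcc_annual=annualize(pcc_daily, profile.operating_days),
            cf_set=cf_set,
            rcc_exact=rcc_exact,
            rcc_daily=rcc_daily,
            rcc_annual=None if rcc_daily is None else annualize(rcc_daily, profile.operating_days),
            rcc_injected=injected,
            fm_percent=fm,
            ecc_exact=ecc_exact,
            ecc_daily=ecc_daily,
            ecc_annual=None if ecc_daily is None else annualize(ecc_daily, profile.operating_days),
        ))
    return results
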
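"""Typed data model for sites, recreation zones, climate and management inputs.

The module defines the record types consumed by the capacity engine,
delimited-text readers/writers for the four input schemas (``sites``,
``zones``, ``climate``, ``management``), a cross-table consistency
validator, and two small descriptive statistics used in site profiling
(guardian density and zone area share).

Conventions
-----------
* Zone areas are stored in square metres; site totals in hectares.
  The conversion factor is fixed at 10,000 m2/ha (:data:`M2_PER_HA`).
* Files are UTF-8 delimited text (comma by default) with a mandatory
  header row; one file per schema.
* Display rounding is half-up and applied only at reporting boundaries;
  loaded values keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from ._rounding import round_half_up
from .errors import DomainError, RecordValidationError, SchemaError

__all__ = [
    "M2_PER_HA",
    "DEFAULT_VARIABLE_UNITS",
    "SiteProfile",
    "RecreationZone",
    "LimitingVariable",
    "ClimateRecord",
    "ManagementCapacity",
    "ValidationIssue",
    "ValidationReport",
    "load_site_dataset",
    "write_site_dataset",
    "validate_dataset",
    "guardian_density",
    "zone_share",
]

M2_PER_HA = 10_000.0

#: Default limiting-variable code set: eight climatic variables, all of
#: them day counts except the seventh, which is measured in hours and
#: therefore needs an explicitly configured denominator downstream.
DEFAULT_VARIABLE_UNITS: dict[str, str] = {
    "Cf1": "days",
    "Cf2": "days",
    "Cf3": "days",
    "Cf4": "days",
    "Cf5": "days",
    "Cf6": "days",
    "Cf7": "hours",
    "Cf8": "days",
}

UseType = Literal["extensive", "intensive"]


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteProfile:
    """One protected area's profile: extent, season, staffing."""

    name: str
    total_area_ha: float
    guardians_count: int
    guard_stations: int
    operating_days: int
    availability_hours: float
    average_visit_hours: float
    established_year: Optional[int] = None
    reported_annual_visitors: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise RecordValidationError("site name must be non-empty")
        if not self.total_area_ha > 0:
            raise RecordValidationError(f"total_area_ha must be > 0, got {self.total_area_ha}")
        if self.guardians_count < 0:
            raise RecordValidationError("guardians_count must be >= 0")
        if self.guard_stations < 0:
            raise RecordValidationError("guard_stations must be >= 0")
        if not 1 <= self.operating_days <= 366:
            raise RecordValidationError(
                f"operating_days must be in [1, 366], got {self.operating_days}"
            )
        if not 0 < self.availability_hours <= 24:
            raise RecordValidationError(
                f"availability_hours must be in (0, 24], got {self.availability_hours}"
            )
        if not self.average_visit_hours > 0:
            raise RecordValidationError("average_visit_hours must be > 0")
        if self.reported_annual_visitors is not None and self.reported_annual_visitors < 0:
            raise RecordValidationError("reported_annual_visitors must be >= 0")


@dataclass(frozen=True)
class RecreationZone:
    """One recreation-class polygon of a site, as a scalar area.

    ``area_ha_reported`` optionally carries an independently published
    hectare figure for the same zone; it is informational only and never
    used by the capacity engine (``area_m2`` is authoritative).
    """

    site_name: str
    use_type: UseType
    class_label: int
    area_m2: float
    space_per_visitor_m2: float
    area_ha_reported: Optional[float] = None

    def __post_init__(self) -> None:
        if self.use_type not in ("extensive", "intensive"):
            raise RecordValidationError(
                f"use_type must be 'extensive' or 'intensive', got {self.use_type!r}"
            )
        if self.class_label not in (1, 2):
            raise RecordValidationError(f"class_label must be 1 or 2, got {self.class_label!r}")
        if self.area_m2 < 0:
            raise RecordValidationError(f"area_m2 must be >= 0, got {self.area_m2}")
        if not self.space_per_visitor_m2 > 0:
            raise RecordValidationError(
                f"space_per_visitor_m2 must be > 0, got {self.space_per_visitor_m2}"
            )

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.site_name, self.use_type, self.class_label)


@dataclass(frozen=True)
class LimitingVariable:
    """A single limiting variable: a magnitude ``m`` out of a total ``Mt``."""

    code: str
    magnitude: float
    unit: Literal["days", "hours"]
    total: Optional[float] = None  # same unit as magnitude; None = not yet configured

    def __post_init__(self) -> None:
        if not self.code:
            raise RecordValidationError("limiting-variable code must be non-empty")
        if self.unit not in ("days", "hours"):
            raise RecordValidationError(f"unit must be 'days' or 'hours', got {self.unit!r}")
        if self.magnitude < 0:
            raise RecordValidationError(f"magnitude must be >= 0, got {self.magnitude}")
        if self.total is not None:
            if not self.total > 0:
                raise RecordValidationError(f"total must be > 0, got {self.total}")
            if self.magnitude > self.total:
                raise RecordValidationError(
                    f"magnitude {self.magnitude} exceeds total {self.total} for {self.code}"
                )


@dataclass(frozen=True)
class ClimateRecord:
    """The ordered limiting-variable set observed at a site's reference station."""

    site_name: str
    station_name: str
    elevation_m: float
    latitude: str
    longitude: str
    variables: tuple[LimitingVariable, ...]

    def __post_init__(self) -> None:
        codes = [v.code for v in self.variables]
        if len(set(codes)) != len(codes):
            raise RecordValidationError(f"duplicate variable codes for site {self.site_name!r}")


@dataclass(frozen=True)
class ManagementCapacity:
    """Ideal vs existing management capacity (guardian head-counts)."""

    site_name: str
    imc: int
    emc: int

    def __post_init__(self) -> None:
        if self.imc <= 0:
            raise RecordValidationError(f"imc must be > 0, got {self.imc}")
        if not 0 <= self.emc <= self.imc:
            raise RecordValidationError(
                f"emc must satisfy 0 <= emc <= imc, got emc={self.emc}, imc={self.imc}"
            )


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

_SITES_REQUIRED = [
    "name", "total_area_ha", "guardians_count", "guard_stations",
    "operating_days", "availability_hours", "average_visit_hours",
]
_SITES_OPTIONAL = ["established_year", "reported_annual_visitors"]
_ZONES_REQUIRED = ["site_name", "use_type", "class_label", "area_m2", "space_per_visitor_m2"]
_ZONES_OPTIONAL = ["area_ha_reported"]
_CLIMATE_REQUIRED = [
    "site_name", "station_name", "elevation_m", "latitude", "longitude",
    "code", "magnitude", "unit",
]
_CLIMATE_OPTIONAL = ["total"]
_MANAGEMENT_REQUIRED = ["site_name", "imc", "emc"]

_SCHEMAS = {
    "sites": (_SITES_REQUIRED, _SITES_OPTIONAL),
    "zones": (_ZONES_REQUIRED, _ZONES_OPTIONAL),
    "climate": (_CLIMATE_REQUIRED, _CLIMATE_OPTIONAL),
    "management": (_MANAGEMENT_REQUIRED, []),
}


def _check_header(df: pd.DataFrame, schema: str) -> None:
    required, optional = _SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    extra = [c for c in df.columns if c not in required + optional]
    if missing:
        raise SchemaError(f"{schema} file is missing column(s): {', '.join(missing)}")
    if extra:
        raise SchemaError(f"{schema} file has unexpected column(s): {', '.join(extra)}")


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
        return None
    return int(value)


def _opt_float(value) -> Optional[float]:
    if value is None or pd.isna(value):
        return None
    return float(value)


def load_site_dataset(path: str | Path, schema: str, *, sep: str = ","):
    """Load one delimited table into a list of typed, validated records.

    Parameters
    ----------
    path
        Delimited text file with a header matching ``schema``.
    schema
        One of ``sites``, ``zones``, ``climate``, ``management``.

    Returns
    -------
    list
        Records in input-row order.  The ``climate`` schema returns one
        :class:`ClimateRecord` per site (variables in row order).
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    _check_header(df, schema)

    try:
        if schema == "sites":
            return _sites_from_frame(df)
        if schema == "zones":
            return _zones_from_frame(df)
        if schema == "climate":
            return _climate_from_frame(df)
        return _management_from_frame(df)
    except RecordValidationError:
        raise
    except (ValueError, TypeError) as exc:  # bad cell contents
        raise RecordValidationError(f"{schema} file {path}: {exc}") from exc


def _row_guard(schema: str, index: int):
    def wrap(exc: Exception) -> RecordValidationError:
        return RecordValidationError(f"{schema} row {index}: {exc}")
    return wrap


def _sites_from_frame(df: pd.DataFrame) -> list[SiteProfile]:
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(SiteProfile(
                name=str(row.name),
                total_area_ha=float(row.total_area_ha),
                guardians_count=int(row.guardians_count),
                guard_stations=int(row.guard_stations),
                operating_days=int(row.operating_days),
                availability_hours=float(row.availability_hours),
                average_visit_hours=float(row.average_visit_hours),
                established_year=_opt_int(getattr(row, "established_year", None)),
                reported_annual_visitors=_opt_int(getattr(row, "reported_annual_visitors", None)),
            ))
        except RecordValidationError as exc:
            raise _row_guard("sites", i)(exc) from exc
    return out


def _zones_from_frame(df: pd.DataFrame) -> list[RecreationZone]:
    out: list[RecreationZone] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            zone = RecreationZone(
                site_name=str(row.site_name),
                use_type=str(row.use_type),
                class_label=int(row.class_label),
                area_m2=float(row.area_m2),
                space_per_visitor_m2=float(row.space_per_visitor_m2),
                area_ha_reported=_opt_float(getattr(row, "area_ha_reported", None)),
            )
        except RecordValidationError as exc:
            raise _row_guard("zones", i)(exc) from exc
        if zone.key in seen:
            raise RecordValidationError(f"zones row {i}: duplicate zone key {zone.key}")
        seen.add(zone.key)
        out.append(zone)
    return out


def _climate_from_frame(df: pd.DataFrame) -> list[ClimateRecord]:
    records: list[ClimateRecord] = []
    for i, (site, group) in enumerate(df.groupby("site_name", sort=False)):
        first = group.iloc[0]
        variables = []
        for j, row in enumerate(group.itertuples(index=False)):
            try:
                variables.append(LimitingVariable(
                    code=str(row.code),
                    magnitude=float(row.magnitude),
                    unit=str(row.unit),
                    total=_opt_float(getattr(row, "total", None)),
                ))
            except RecordValidationError as exc:
                raise _row_guard("climate", j)(exc) from exc
        records.append(ClimateRecord(
            site_name=str(site),
            station_name=str(first["station_name"]),
            elevation_m=float(first["elevation_m"]),
            latitude=str(first["latitude"]),
            longitude=str(first["longitude"]),
            variables=tuple(variables),
        ))
    return records


def _management_from_frame(df: pd.DataFrame) -> list[ManagementCapacity]:
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(ManagementCapacity(
                site_name=str(row.site_name), imc=int(row.imc), emc=int(row.emc),
            ))
        except RecordValidationError as exc:
            raise _row_guard("management", i)(exc) from exc
    return out


def write_site_dataset(records: Sequence, path: str | Path, schema: str, *, sep: str = ",") -> None:
    """Write records back to delimited text; inverse of :func:`load_site_dataset`."""
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    path = Path(path)
    if schema == "climate":
        rows = []
        for rec in records:
            for var in rec.variables:
                rows.append({
                    "site_name": rec.site_name,
                    "station_name": rec.station_name,
                    "elevation_m": rec.elevation_m,
                    "latitude": rec.latitude,
                    "longitude": rec.longitude,
                    "code": var.code,
                    "magnitude": var.magnitude,
                    "unit": var.unit,
                    "total": var.total,
                })
        df = pd.DataFrame(rows, columns=_CLIMATE_REQUIRED + _CLIMATE_OPTIONAL)
    else:
        required, optional = _SCHEMAS[schema]
        cols = required + optional
        rows = []
        for rec in records:
            row = {f.name: getattr(rec, f.name) for f in dc_fields(rec)}
            rows.append({c: row.get(c) for c in cols})
        df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep=sep, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# cross-table validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    category: str  # dangling_zone | missing_climate | missing_management | zone_area_excess
    site_name: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __len__(self) -> int:
        return len(self.issues)

    def __iter__(self):
        return iter(self.issues)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i.category, i.site_name, i.message) for i in self.issues],
            columns=["category", "site_name", "message"],
        )


def validate_dataset(
    sites: Iterable[SiteProfile],
    zones: Iterable[RecreationZone],
    climate: Iterable[ClimateRecord] = (),
    management: Iterable[ManagementCapacity] = (),
) -> ValidationReport:
    """Cross-check the four collections; an empty report means consistent.

    Flags zones referencing unknown sites, sites lacking climate or
    management records, and per-site zone-area sums exceeding the site's
    total area.
    """
    report = ValidationReport()
    site_names = {s.name for s in sites}
    climate_names = {c.site_name for c in climate}
    management_names = {m.site_name for m in management}

    zone_area_by_site: dict[str, float] = {}
    for z in zones:
        if z.site_name not in site_names:
            report.issues.append(ValidationIssue(
                "dangling_zone", z.site_name,
                f"zone {z.use_type}/{z.class_label} references unknown site {z.site_name!r}",
            ))
        zone_area_by_site[z.site_name] = zone_area_by_site.get(z.site_name, 0.0) + z.area_m2

    for s in sites:
        if s.name not in climate_names:
            report.issues.append(ValidationIssue(
                "missing_climate", s.name, f"site {s.name!r} has no climate record"))
        if s.name not in management_names:
            report.issues.append(ValidationIssue(
                "missing_management", s.name, f"site {s.name!r} has no management record"))
        total_m2 = s.total_area_ha * M2_PER_HA
        zsum = zone_area_by_site.get(s.name, 0.0)
        if zsum > total_m2:
            report.issues.append(ValidationIssue(
                "zone_area_excess", s.name,
                f"zone areas sum to {zsum:,.0f} m2, exceeding site total "
                f"{total_m2:,.0f} m2",
            ))
    return report


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def guardian_density(guardians_count: int, total_area_ha: float) -> float:
    """Guardians per hectare expressed as a percentage, half-up at 2 dp.

    >>> guardian_density(14, 35765)
    0.04
    """
    if total_area_ha <= 0:
        raise DomainError(f"total_area_ha must be > 0, got {total_area_ha}")
    if guardians_count < 0:
        raise DomainError(f"guardians_count must be >= 0, got {guardians_count}")
    return round_half_up(guardians_count / total_area_ha * 100.0, 2)


def zone_share(part_area: float, whole_area: float) -> float:
    """Share of ``whole_area`` taken by ``part_area`` in percent, half-up at 1 dp.

    Both arguments must be in the same unit.

    >>> zone_share(557.1, 1000.0)
    55.7
    """
    if whole_area <= 0:
        raise DomainError(f"whole_area must be > 0, got {whole_area}")
    if not 0 <= part_area <= whole_area:
        raise DomainError(
            f"part_area must satisfy 0 <= part <= whole, got part={part_area}, whole={whole_area}"
        )
    return round_half_up(part_area / whole_area * 100.0, 1)
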
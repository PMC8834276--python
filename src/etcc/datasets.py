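"""Bundled example dataset: three protected areas of Tehran province.

The tables transcribe the published study inputs for Lar national park,
the Jajrud protected area and the Tangeh Vashi natural monument: site
profiles, recreation-zone areas, climatic limiting variables, and
management capacities.  Two pieces of study configuration that are not
derivable from the tables ship alongside:

* the published percentages for the hour-based sunny-hours variable
  (``Cf7``), whose denominator is not stated anywhere and therefore
  cannot be recomputed; and
* the published daily real-capacity figures, which do not follow from
  either composition rule applied to the published correction
  percentages and are therefore treated as observed inputs to the
  effective-capacity stage.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .delphi import ItemSummary
from .site_model import (
    ClimateRecord,
    ManagementCapacity,
    RecreationZone,
    SiteProfile,
    load_site_dataset,
)

__all__ = [
    "LAR",
    "JAJRUD",
    "TANGEH_VASHI",
    "TEHRAN_CF7_PERCENT",
    "TEHRAN_RCC_DAILY",
    "load_tehran_dataset",
    "load_tehran_delphi_round3",
    "tehran_data_dir",
]

LAR = "Lar national park"
JAJRUD = "Jajrud protected area"
TANGEH_VASHI = "Tangeh Vashi natural monument"

#: Published Cf7 (intense sunny hours) percentages per site.  The
#: hour-count magnitudes (2717 / 2833 / 3010 h) do not yield these
#: percentages under any natural hours-per-year denominator, so the
#: printed values are carried as configuration.
TEHRAN_CF7_PERCENT: dict[str, dict[str, float]] = {
    LAR: {"Cf7": 21.0},
    JAJRUD: {"Cf7": 19.0},
    TANGEH_VASHI: {"Cf7": 18.0},
}

#: Published daily real carrying capacity per zone class (observed
#: figures injected into the effective-capacity stage).
TEHRAN_RCC_DAILY: dict[tuple[str, str, int], int] = {
    (LAR, "extensive", 1): 1,
    (LAR, "extensive", 2): 2,
    (JAJRUD, "extensive", 1): 4,
    (JAJRUD, "extensive", 2): 6,
    (JAJRUD, "intensive", 1): 1,
    (JAJRUD, "intensive", 2): 2,
    (TANGEH_VASHI, "extensive", 1): 1,
    (TANGEH_VASHI, "extensive", 2): 3,
}


def tehran_data_dir() -> Path:
    return Path(resources.files("etcc").joinpath("data", "tehran"))  # type: ignore[arg-type]


def load_tehran_dataset() -> tuple[
    list[SiteProfile], list[RecreationZone], list[ClimateRecord], list[ManagementCapacity]
]:
    """Load the bundled three-site dataset (sites, zones, climate, management)."""
    root = tehran_data_dir()
    return (
        load_site_dataset(root / "sites.csv", "sites"),
        load_site_dataset(root / "zones.csv", "zones"),
        load_site_dataset(root / "climate.csv", "climate"),
        load_site_dataset(root / "management.csv", "management"),
    )


def load_tehran_delphi_round3() -> list[ItemSummary]:
    """Published round-3 item summaries (36 items across three dimensions)."""
    df = pd.read_csv(tehran_data_dir() / "delphi_round3.csv")
    return [
        ItemSummary(
            item_id=str(r.item_id),
            n=int(r.n),
            mean=float(r.mean),
            sd=float(r.sd),
            variance=float(r.variance),
            dimension=str(r.dimension),
            label=str(r.label),
            rank=int(r.rank),
        )
        for r in df.itertuples(index=False)
    ]
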
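# etcc

Visitor carrying-capacity and expert-panel aggregation toolkit for
protected-area ecotourism planning.

The package implements the classic three-stage capacity cascade used in
visitor management:

* **PCC** — physical carrying capacity: usable zone area over the
  per-visitor space standard, scaled by the daily rotation factor
  (availability hours / average visit length);
* **RCC** — real carrying capacity: PCC reduced by limiting (correction)
  factors, each a percentage `Cf = m / Mt × 100` derived from climatic
  day counts (multiplicative composition by default, subtractive behind a
  mode flag);
* **ECC** — effective carrying capacity: RCC reduced by the
  facility-management deficit `FM = (Imc − Emc) / Imc × 100`, where the
  ideal management capacity follows a one-guardian-per-1000-ha staffing
  standard.

Daily head-counts are rounded under a configurable policy (floor for
PCC/RCC, ceiling for ECC by default) and annualized over each site's
operating season. A companion `delphi` module aggregates multi-round
Likert questionnaires (per-item n/mean/SD/variance, within-dimension
competition ranking, equally weighted dimension means, item removal and
expert attrition across rounds), and a `synthetic` module provides
seeded generators for both site datasets and expert panels so the whole
pipeline runs with no external data.

A transcription of a published three-site case study (Lar national park,
Jajrud protected area and the Tangeh Vashi natural monument, Tehran
province) ships as a bundled dataset (`etcc.datasets`) together with the
two pieces of study configuration that are not derivable from the tables
(the hour-based `Cf7` percentages and the observed daily RCC figures
injected into the ECC stage).

## CLI

```sh
# full cascade over a four-table dataset
etcc compute --sites sites.csv --zones zones.csv --climate climate.csv \
     --management management.csv [--policy policy.yaml] \
     [--cf-override overrides.yaml] [--rcc-override rcc.csv] --out report/

# cross-table consistency check (exit 1 on inconsistencies)
etcc validate --sites sites.csv --zones zones.csv \
     --climate climate.csv --management management.csv

# multi-round Delphi aggregation
etcc delphi --items items.csv --responses r1.csv --responses r2.csv \
     --responses r3.csv --plan plans.csv --out report/

# seeded synthetic data
etcc synth sites --seed 42 --out data/
etcc synth panel --seed 42 --out panel/
```

`compute` writes one wide table per stage (`capacity_pcc.csv`,
`capacity_rcc.csv`, `capacity_ecc.csv`) plus a full-precision JSON
mirror (`capacity.json`) that parses back into `CapacityResult` records,
and echoes the effective configuration to `run_config.json`.

## Library quick start

```python
from etcc import RoundingPolicy, compute_site
from etcc.datasets import (
    TEHRAN_CF7_PERCENT, TEHRAN_RCC_DAILY, load_tehran_dataset)

sites, zones, climate, management = load_tehran_dataset()
profile = sites[0]
results = compute_site(
    profile, zones,
    next(c for c in climate if c.site_name == profile.name),
    next(m for m in management if m.site_name == profile.name),
    cf_percent_overrides=TEHRAN_CF7_PERCENT[profile.name],
    rcc_injection=TEHRAN_RCC_DAILY,
)
```

## Known dataset caveats

The bundled transcription reproduces its source tables including their
quirks; these are handled explicitly rather than patched silently:

* one printed daily PCC (`22,226`) is a typo for 2226 (consistent with
  the printed annual value);
* the printed daily RCC values do not follow from either composition
  rule applied to the printed correction percentages, so they are
  treated as observed inputs (`TEHRAN_RCC_DAILY`);
* the hour-based `Cf7` percentages have no recoverable denominator and
  ship as configuration (`TEHRAN_CF7_PERCENT`);
* one published ECC row (Tangeh Vashi ET2) breaks the ceiling rounding
  convention the other five rows follow.
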
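"""Report rendering: wide per-stage capacity tables plus a machine mirror.

One delimited table is written per capacity stage (PCC / RCC / ECC) with
daily and annual columns formatted with thousands separators, mirroring
the layout of the published worked table.  A JSON mirror with full
precision is emitted alongside and parses back into
:class:`~etcc.carrying_capacity.CapacityResult` records.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .carrying_capacity import CapacityResult, CorrectionFactor
from .errors import UsageError

__all__ = ["render_capacity_report", "parse_capacity_report", "render_delphi_report"]

log = logging.getLogger(__name__)

_USE_ABBREV = {"extensive": "ET", "intensive": "IT"}


def _fmt(value: Optional[int]) -> str:
    return "" if value is None else f"{value:,}"


def _class_code(result: CapacityResult) -> str:
    return f"{_USE_ABBREV.get(result.use_type, result.use_type)}{result.class_label}"


def _pcc_frame(results: Sequence[CapacityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "site": r.site_name,
            "recreation_class": _class_code(r),
            "rf": r.rf,
            "daily": _fmt(r.pcc_daily),
            "annual": _fmt(r.pcc_annual),
        })
    return pd.DataFrame(rows)


def _rcc_frame(results: Sequence[CapacityResult]) -> pd.DataFrame:
    codes: list[str] = []
    for r in results:
        for cf in r.cf_set:
            if cf.code not in codes:
                codes.append(cf.code)
    rows = []
    for r in results:
        row = {"site": r.site_name, "recreation_class": _class_code(r)}
        percents = {cf.code: cf.percent for cf in r.cf_set}
        for code in codes:
            row[code] = percents.get(code, "")
        row["daily"] = _fmt(r.rcc_daily)
        row["annual"] = _fmt(r.rcc_annual)
        rows.append(row)
    return pd.DataFrame(rows)


def _ecc_frame(results: Sequence[CapacityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "site": r.site_name,
            "recreation_class": _class_code(r),
            "fm_percent": "" if r.fm_percent is None else r.fm_percent,
            "daily": _fmt(r.ecc_daily),
            "annual": _fmt(r.ecc_annual),
        })
    return pd.DataFrame(rows)


def _result_to_dict(r: CapacityResult) -> dict:
    return {
        "site_name": r.site_name,
        "use_type": r.use_type,
        "class_label": r.class_label,
        "operating_days": r.operating_days,
        "rf": r.rf,
        "pcc_exact": r.pcc_exact,
        "pcc_daily": r.pcc_daily,
        "pcc_annual": r.pcc_annual,
        "cf_set": [
            {"code": cf.code, "percent": cf.percent,
             "source_m": cf.source_m, "source_mt": cf.source_mt}
            for cf in r.cf_set
        ],
        "rcc_exact": r.rcc_exact,
        "rcc_daily": r.rcc_daily,
        "rcc_annual": r.rcc_annual,
        "rcc_injected": r.rcc_injected,
        "fm_percent": r.fm_percent,
        "ecc_exact": r.ecc_exact,
        "ecc_daily": r.ecc_daily,
        "ecc_annual": r.ecc_annual,
    }


def render_capacity_report(results: Sequence[CapacityResult], out_dir: str | Path) -> list[Path]:
    """Write the per-stage tables and the JSON mirror; returns written paths."""
    results = list(results)
    if not results:
        raise UsageError("render_capacity_report requires at least one result")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = out_dir / "capacity_pcc.csv"
    _pcc_frame(results).to_csv(path, index=False, encoding="utf-8")
    written.append(path)

    if any(r.rcc_daily is not None for r in results):
        path = out_dir / "capacity_rcc.csv"
        _rcc_frame(results).to_csv(path, index=False, encoding="utf-8")
        written.append(path)
    else:
        log.info("RCC stage empty; capacity_rcc.csv omitted")

    if any(r.ecc_daily is not None for r in results):
        path = out_dir / "capacity_ecc.csv"
        _ecc_frame(results).to_csv(path, index=False, encoding="utf-8")
        written.append(path)
    else:
        log.info("ECC stage empty; capacity_ecc.csv omitted")

    path = out_dir / "capacity.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([_result_to_dict(r) for r in results], fh, indent=2)
        fh.write("\n")
    written.append(path)
    return written


def parse_capacity_report(json_path: str | Path) -> list[CapacityResult]:
    """Read the JSON mirror back into equal :class:`CapacityResult` records."""
    with open(json_path, encoding="utf-8") as fh:
        raw = json.load(fh)
    out = []
    for d in raw:
        cf_set = tuple(
            CorrectionFactor(code=c["code"], percent=c["percent"],
                             source_m=c["source_m"], source_mt=c["source_mt"])
            for c in d["cf_set"]
        )
        out.append(CapacityResult(**{**d, "cf_set": cf_set}))
    return out


def render_delphi_report(final_table: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write the final prioritized Delphi table (delimited + JSON mirror)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "delphi_final.csv"
    final_table.to_csv(csv_path, index=False, encoding="utf-8")
    json_path = out_dir / "delphi_final.json"
    final_table.to_json(json_path, orient="records", indent=2)
    return [csv_path, json_path]
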
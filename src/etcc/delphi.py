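"""Multi-round Delphi aggregation of Likert questionnaires.

A Delphi study here is a sequence of rounds.  Each round has a response
matrix (experts x items, scores on a 1-5 Likert scale), and a round plan
listing experts who did not respond and items dropped after the round.
Per item we compute respondent count, mean, sample standard deviation
and sample variance; items are ranked within their dimension by
descending mean (competition ranking), and each dimension gets an
equally weighted total mean of its item means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._rounding import round_half_up
from .errors import DomainError, RecordValidationError, UsageError

__all__ = [
    "LIKERT_MIN",
    "LIKERT_MAX",
    "LikertItem",
    "ResponseMatrix",
    "ItemSummary",
    "DimensionSummary",
    "RoundPlan",
    "RoundResult",
    "DelphiResult",
    "item_statistics",
    "dimension_summary",
    "rank_items",
    "run_round",
    "run_delphi",
    "load_items",
    "load_responses",
    "load_plans",
    "write_items",
    "write_responses",
    "write_plans",
]

LIKERT_MIN, LIKERT_MAX = 1, 5


@dataclass(frozen=True)
class LikertItem:
    item_id: str
    dimension: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.item_id:
            raise RecordValidationError("item_id must be non-empty")
        if not self.dimension:
            raise RecordValidationError("dimension must be non-empty")


@dataclass
class ResponseMatrix:
    """One round's responses: an experts-by-items grid of 1..5 scores.

    ``frame`` is indexed by expert id with one column per item id;
    missing responses are NaN.
    """

    round_number: int
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.round_number < 1:
            raise RecordValidationError(f"round_number must be >= 1, got {self.round_number}")
        if self.frame.index.has_duplicates:
            raise RecordValidationError("expert ids must be unique")
        if self.frame.columns.has_duplicates:
            raise RecordValidationError("item ids must be unique")
        values = self.frame.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size and (
            (finite < LIKERT_MIN).any() or (finite > LIKERT_MAX).any()
            or (finite != np.round(finite)).any()
        ):
            raise RecordValidationError(
                f"all responses must be integers in {LIKERT_MIN}..{LIKERT_MAX}"
            )

    @property
    def expert_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.frame.columns)


@dataclass(frozen=True)
class ItemSummary:
    """Aggregated statistics for one item in one round."""

    item_id: str
    n: int
    mean: float
    sd: float
    variance: float
    dimension: str = ""
    label: str = ""
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise RecordValidationError("n must be >= 1")
        if not LIKERT_MIN <= self.mean <= LIKERT_MAX:
            raise RecordValidationError(
                f"mean must be in [{LIKERT_MIN}, {LIKERT_MAX}], got {self.mean}")
        if self.sd < 0 or self.variance < 0:
            raise RecordValidationError("sd and variance must be >= 0")
        if self.rank is not None and self.rank < 1:
            raise RecordValidationError("rank must be >= 1")


@dataclass(frozen=True)
class DimensionSummary:
    dimension: str
    items: tuple[ItemSummary, ...]
    total_mean: float


@dataclass(frozen=True)
class RoundPlan:
    """Post-round bookkeeping: items dropped and experts who did not respond."""

    round_number: int
    removed_item_ids: tuple[str, ...] = ()
    nonrespondent_expert_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "removed_item_ids", tuple(self.removed_item_ids))
        object.__setattr__(
            self, "nonrespondent_expert_ids", tuple(self.nonrespondent_expert_ids))


@dataclass(frozen=True)
class RoundResult:
    round_number: int
    item_summaries: tuple[ItemSummary, ...]
    dimension_summaries: tuple[DimensionSummary, ...]
    retained_items: tuple[LikertItem, ...]
    respondent_count: int


@dataclass(frozen=True)
class DelphiResult:
    rounds: tuple[RoundResult, ...]

    @property
    def final_round(self) -> RoundResult:
        return self.rounds[-1]

    def final_table(self, decimals: int = 2) -> pd.DataFrame:
        """Final prioritized table: last round's statistics restricted to
        the items retained after that round, grouped by dimension with
        ranks and dimension total means."""
        last = self.final_round
        retained_ids = {it.item_id for it in last.retained_items}
        rows = []
        for dim in last.dimension_summaries:
            kept = [s for s in dim.items if s.item_id in retained_ids]
            ranked = rank_items(kept)
            total = dimension_summary([s.mean for s in ranked], decimals) if ranked else np.nan
            for s in ranked:
                rows.append({
                    "dimension": s.dimension,
                    "item_id": s.item_id,
                    "label": s.label,
                    "n": s.n,
                    "mean": round_half_up(s.mean, decimals),
                    "sd": round_half_up(s.sd, 3),
                    "variance": round_half_up(s.variance, 3),
                    "rank": s.rank,
                    "dimension_total_mean": total,
                })
        return pd.DataFrame(rows, columns=[
            "dimension", "item_id", "label", "n", "mean", "sd",
            "variance", "rank", "dimension_total_mean",
        ])


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def item_statistics(values: Sequence[float], *, item_id: str = "",
                    dimension: str = "", label: str = "") -> ItemSummary:
    """Respondent count, mean, sample SD and sample variance of one item.

    The variance uses the n-1 denominator; a single response yields
    sd = variance = 0 by convention.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("item_statistics requires at least one response")
    if np.isnan(arr).any():
        raise RecordValidationError("responses must not contain missing values")
    if ((arr < LIKERT_MIN) | (arr > LIKERT_MAX)).any() or (arr != np.round(arr)).any():
        raise RecordValidationError(
            f"all responses must be integers in {LIKERT_MIN}..{LIKERT_MAX}")
    n = int(arr.size)
    mean = float(arr.mean())
    variance = float(arr.var(ddof=1)) if n > 1 else 0.0
    return ItemSummary(
        item_id=item_id, n=n, mean=mean, sd=float(np.sqrt(variance)),
        variance=variance, dimension=dimension, label=label,
    )


def dimension_summary(item_means: Sequence[float], decimals: int = 2) -> float:
    """Equally weighted arithmetic mean of item means, half-up rounded.

    Items count equally regardless of how many experts answered each.
    """
    means = list(item_means)
    if not means:
        raise DomainError("dimension_summary requires at least one item mean")
    return round_half_up(float(np.mean(means)), decimals)


def rank_items(item_summaries: Sequence[ItemSummary]) -> list[ItemSummary]:
    """Assign within-dimension competition ranks by descending mean.

    Ties share the smallest applicable rank and the following rank is
    skipped; equal means keep their input order in the returned list.
    All summaries must belong to a single dimension.
    """
    summaries = list(item_summaries)
    if not summaries:
        return []
    dims = {s.dimension for s in summaries}
    if len(dims) > 1:
        raise UsageError(f"rank_items requires a single dimension, got {sorted(dims)}")
    order = sorted(range(len(summaries)), key=lambda i: -summaries[i].mean)
    means = [summaries[i].mean for i in order]
    ranked: list[ItemSummary] = []
    for pos, i in enumerate(order):
        # competition rank: 1 + number of strictly greater means
        rank = 1 + sum(1 for m in means if m > summaries[i].mean)
        ranked.append(replace(summaries[i], rank=rank))
    return ranked


# ---------------------------------------------------------------------------
# round execution
# ---------------------------------------------------------------------------

def _group_by_dimension(items: Sequence[LikertItem]) -> dict[str, list[LikertItem]]:
    grouped: dict[str, list[LikertItem]] = {}
    for it in items:
        grouped.setdefault(it.dimension, []).append(it)
    return grouped


def run_round(
    matrix: ResponseMatrix,
    items: Sequence[LikertItem],
    plan: Optional[RoundPlan] = None,
) -> RoundResult:
    """Aggregate one round and apply its plan.

    Non-respondents listed in the plan are excluded from every item's n;
    statistics cover all current items; the plan's removals take effect
    for subsequent rounds (they are excluded from ``retained_items``).
    """
    items = list(items)
    item_ids = [it.item_id for it in items]
    if plan is None:
        plan = RoundPlan(round_number=matrix.round_number)
    known = set(item_ids)
    unknown = [i for i in plan.removed_item_ids if i not in known]
    if unknown:
        raise UsageError(f"plan removes unknown item(s): {', '.join(unknown)}")
    missing_cols = [i for i in item_ids if i not in matrix.frame.columns]
    if missing_cols:
        raise UsageError(
            f"round {matrix.round_number} matrix lacks item column(s): "
            f"{', '.join(missing_cols)}")

    dropouts = set(plan.nonrespondent_expert_ids)
    respondents = [e for e in matrix.expert_ids if e not in dropouts]
    frame = matrix.frame.loc[respondents, item_ids]

    summaries: list[ItemSummary] = []
    for it in items:
        col = frame[it.item_id].dropna()
        if col.empty:
            raise DomainError(
                f"item {it.item_id!r} has no responses in round {matrix.round_number}")
        summaries.append(item_statistics(
            col.tolist(), item_id=it.item_id, dimension=it.dimension, label=it.label))

    dim_summaries: list[DimensionSummary] = []
    for dim, dim_items in _group_by_dimension(items).items():
        dim_ids = [it.item_id for it in dim_items]
        dim_stats = rank_items([s for s in summaries if s.item_id in set(dim_ids)])
        dim_summaries.append(DimensionSummary(
            dimension=dim,
            items=tuple(dim_stats),
            total_mean=dimension_summary([s.mean for s in dim_stats]),
        ))

    removed = set(plan.removed_item_ids)
    retained = tuple(it for it in items if it.item_id not in removed)
    return RoundResult(
        round_number=matrix.round_number,
        item_summaries=tuple(summaries),
        dimension_summaries=tuple(dim_summaries),
        retained_items=retained,
        respondent_count=len(respondents),
    )


def run_delphi(
    matrices: Sequence[ResponseMatrix],
    items: Sequence[LikertItem],
    plans: Sequence[RoundPlan] = (),
) -> DelphiResult:
    """Run an ordered sequence of rounds, carrying item removals forward.

    Round numbers must be contiguous starting from the first matrix's
    round; a gap raises :class:`~etcc.errors.UsageError`.
    """
    if not matrices:
        raise UsageError("run_delphi requires at least one round")
    matrices = sorted(matrices, key=lambda m: m.round_number)
    numbers = [m.round_number for m in matrices]
    expected = list(range(numbers[0], numbers[0] + len(numbers)))
    if numbers != expected:
        raise UsageError(f"round numbers {numbers} are not contiguous")
    plan_by_round: dict[int, RoundPlan] = {}
    for p in plans:
        if p.round_number in plan_by_round:
            raise UsageError(f"duplicate plan for round {p.round_number}")
        plan_by_round[p.round_number] = p

    current = list(items)
    ids = [it.item_id for it in current]
    if len(set(ids)) != len(ids):
        raise RecordValidationError("item ids must be unique")

    rounds: list[RoundResult] = []
    for matrix in matrices:
        result = run_round(matrix, current, plan_by_round.get(matrix.round_number))
        rounds.append(result)
        current = list(result.retained_items)
    return DelphiResult(rounds=tuple(rounds))


# ---------------------------------------------------------------------------
# delimited-text IO
# ---------------------------------------------------------------------------

def load_items(path: str | Path) -> list[LikertItem]:
    df = pd.read_csv(path)
    required = {"item_id", "dimension", "label"}
    if not required.issubset(df.columns):
        raise UsageError(f"items file must have columns {sorted(required)}")
    return [
        LikertItem(item_id=str(r.item_id), dimension=str(r.dimension),
                   label="" if pd.isna(r.label) else str(r.label))
        for r in df.itertuples(index=False)
    ]


def load_responses(path: str | Path, round_number: int) -> ResponseMatrix:
    """Read a long-format response file (expert_id, item_id, score)."""
    df = pd.read_csv(path)
    required = {"expert_id", "item_id", "score"}
    if not required.issubset(df.columns):
        raise UsageError(f"responses file must have columns {sorted(required)}")
    wide = df.pivot(index="expert_id", columns="item_id", values="score")
    wide.index = wide.index.astype(str)
    wide.columns = wide.columns.astype(str)
    return ResponseMatrix(round_number=round_number, frame=wide)


def load_plans(path: str | Path) -> list[RoundPlan]:
    """Read a plans file (round, removed_item_ids, nonrespondent_ids).

    Id lists are semicolon-separated; empty cells mean no removals/dropouts.
    """
    df = pd.read_csv(path)
    required = {"round", "removed_item_ids", "nonrespondent_ids"}
    if not required.issubset(df.columns):
        raise UsageError(f"plans file must have columns {sorted(required)}")

    def split(cell) -> tuple[str, ...]:
        if pd.isna(cell) or str(cell).strip() == "":
            return ()
        return tuple(part.strip() for part in str(cell).split(";") if part.strip())

    return [
        RoundPlan(round_number=int(r.round),
                  removed_item_ids=split(r.removed_item_ids),
                  nonrespondent_expert_ids=split(r.nonrespondent_ids))
        for r in df.itertuples(index=False)
    ]


def write_items(items: Iterable[LikertItem], path: str | Path) -> None:
    pd.DataFrame(
        [(it.item_id, it.dimension, it.label) for it in items],
        columns=["item_id", "dimension", "label"],
    ).to_csv(path, index=False, encoding="utf-8")


def write_responses(matrix: ResponseMatrix, path: str | Path) -> None:
    long = (
        matrix.frame.stack().rename("score").reset_index()
        .rename(columns={"level_0": "expert_id", "level_1": "item_id"})
    )
    long.columns = ["expert_id", "item_id", "score"]
    long["score"] = long["score"].astype(int)
    long.to_csv(path, index=False, encoding="utf-8")


def write_plans(plans: Iterable[RoundPlan], path: str | Path) -> None:
    pd.DataFrame(
        [(p.round_number, ";".join(p.removed_item_ids),
          ";".join(p.nonrespondent_expert_ids)) for p in plans],
        columns=["round", "removed_item_ids", "nonrespondent_ids"],
    ).to_csv(path, index=False, encoding="utf-8")
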
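"""Challenge ranking: per-column ranks, overall sum-of-ranks score, and the
standard-deviation tie-break.

Methods are ranked on their overall performance to segment the three tissue
classes. For each of the nine scored columns — measure m ∈ {D, H95, AVD}
crossed with component c ∈ {GM, WM, CSF} — methods are sorted on the mean
over cases (D descending, H95 and AVD ascending) and ranked 1 (best) to n.
The overall score s is the sum of a method's nine ranks; final ranks are
assigned by sorting s ascending. Methods with equal s are ordered by their
σ rank: the identical procedure re-run on the standard deviations instead
of the means. Brain and ICV columns are ranked for display but do not enter
the score.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import MEASURES, Measure, MethodSummary
from .volumes import EVALUATED_COMPONENTS, Component

__all__ = [
    "Direction",
    "SCORED_COLUMNS",
    "DISPLAY_COLUMNS",
    "RankTable",
    "Leaderboard",
    "rank_column",
    "build_rank_table",
    "overall_score",
    "sigma_rank",
    "final_ranking",
]

#: sort direction per measure: best value first.
class Direction(enum.Enum):
    ASCENDING = "ascending"
    DESCENDING = "descending"


MEASURE_DIRECTION = {
    Measure.DICE: Direction.DESCENDING,  # higher overlap is better
    Measure.H95: Direction.ASCENDING,    # smaller boundary distance is better
    Measure.AVD: Direction.ASCENDING,    # smaller volume error is better
}

_SCORED_COMPONENTS = (Component.GM, Component.WM, Component.CSF)
_DISPLAY_COMPONENTS = (Component.BRAIN, Component.ICV)

#: The nine (measure, component) cells that enter the overall score.
SCORED_COLUMNS = tuple((m, c) for m in MEASURES for c in _SCORED_COMPONENTS)
#: Brain/ICV cells: ranked and reported, never scored.
DISPLAY_COLUMNS = tuple((m, c) for m in MEASURES for c in _DISPLAY_COMPONENTS)
ALL_COLUMNS = SCORED_COLUMNS + DISPLAY_COLUMNS


@dataclass
class RankTable:
    """Integer rank per (method, measure, component); 1 is best.

    Within each column the ranks are a permutation of 1..n.
    """

    methods: list[str]
    ranks: dict[tuple[str, Measure, Component], int]

    def rank(self, method: str, measure: Measure, component: Component) -> int:
        return self.ranks[(method, measure, component)]


@dataclass
class Leaderboard:
    """Final ordering of methods with scores and tie-break bookkeeping."""

    methods: list[str]                      # sorted best-first
    rank_table: RankTable                   # all 15 per-column ranks
    overall: dict[str, int]                 # sum of the 9 scored ranks
    sigma_score: dict[str, int]             # sum of the 9 σ ranks
    sigma_ranks: dict[str, int]             # rank of the σ scores
    final_rank: dict[str, int]              # 1..n
    residual_ties: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self, summaries: list[MethodSummary] | None = None) -> pd.DataFrame:
        """Leaderboard table: final rank, method, per-column rank and, when
        summaries are given, the μ(σ) cells; score s and σ rank last."""
        by_name = {s.method: s for s in summaries} if summaries else {}
        rows = []
        for method in self.methods:
            row: dict[str, object] = {"r": self.final_rank[method], "method": method}
            for m, c in ALL_COLUMNS:
                stem = f"{m.value}_{c.value}"
                row[f"rank_{stem}"] = self.rank_table.rank(method, m, c)
                if method in by_name:
                    row[f"mu_{stem}"] = by_name[method].mean[(m, c)]
                    row[f"sigma_{stem}"] = by_name[method].std[(m, c)]
            row["s"] = self.overall[method]
            row["sigma_rank"] = self.sigma_ranks[method]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, summaries: list[MethodSummary] | None = None) -> str:
        frame = self.to_frame(summaries)
        doc = {
            "leaderboard": frame.to_dict(orient="records"),
            "residual_ties": [list(t) for t in self.residual_ties],
        }
        return json.dumps(doc, indent=2)


def _worst_sentinel(direction: Direction) -> float:
    # a value no finite measurement can beat, used for undefined cells
    return -math.inf if direction is Direction.DESCENDING else math.inf


def rank_column(
    values: list[tuple[str, float]],
    direction: Direction,
    sigmas: dict[str, float] | None = None,
) -> list[tuple[str, int]]:
    """Rank methods on one column of values; best value gets rank 1.

    Mean ties are broken by the method's σ in the same column (ascending —
    the steadier method wins) and then by method name, so every method
    receives a distinct integer rank and the result is deterministic.
    NaN values (undefined metrics) are replaced by a worst-possible
    sentinel before sorting so a failing method is ranked last, not dropped.
    """
    names = [name for name, _ in values]
    if len(set(names)) != len(names):
        raise ValueError("duplicate method names in rank column")
    if not names:
        raise ValueError("cannot rank an empty column")
    sigmas = sigmas or {}
    sign = -1.0 if direction is Direction.DESCENDING else 1.0

    def key(item: tuple[str, float]):
        name, value = item
        if math.isnan(value):
            value = _worst_sentinel(direction)
        sig = sigmas.get(name, 0.0)
        if math.isnan(sig):
            sig = math.inf
        return (sign * value, sig, name)

    ordered = sorted(values, key=key)
    return [(name, rank) for rank, (name, _) in enumerate(ordered, start=1)]


def build_rank_table(
    summaries: list[MethodSummary], on_sigma: bool = False
) -> RankTable:
    """Rank every (measure, component) column across methods.

    With ``on_sigma`` the columns are ranked on the standard deviations
    (always ascending — steadier is better) instead of the means; this is
    the first step of the tie-break procedure.
    """
    methods = [s.method for s in summaries]
    if len(set(methods)) != len(methods):
        raise ValueError("duplicate method names")
    ranks: dict[tuple[str, Measure, Component], int] = {}
    for m, c in ALL_COLUMNS:
        if on_sigma:
            col = [(s.method, s.std[(m, c)]) for s in summaries]
            ranked = rank_column(col, Direction.ASCENDING)
        else:
            col = [(s.method, s.mean[(m, c)]) for s in summaries]
            sig = {s.method: s.std[(m, c)] for s in summaries}
            ranked = rank_column(col, MEASURE_DIRECTION[m], sigmas=sig)
        for name, r in ranked:
            ranks[(name, m, c)] = r
    return RankTable(methods=methods, ranks=ranks)


def overall_score(table: RankTable, method: str) -> int:
    """Sum of a method's nine scored (GM/WM/CSF) ranks; lower is better."""
    try:
        return sum(table.rank(method, m, c) for m, c in SCORED_COLUMNS)
    except KeyError as exc:
        raise KeyError(f"missing rank cell for method {method!r}: {exc}") from exc


def sigma_rank(summaries: list[MethodSummary]) -> list[tuple[str, int]]:
    """Tie-break ranks: re-run the ranking procedure on the σ values.

    Per scored column, methods are ranked on σ ascending; the nine σ ranks
    are summed into a σ score, and the σ scores are themselves ranked
    ascending 1..n.
    """
    table = build_rank_table(summaries, on_sigma=True)
    scores = [(s.method, float(overall_score(table, s.method))) for s in summaries]
    return rank_column(scores, Direction.ASCENDING)


def final_ranking(summaries: list[MethodSummary]) -> Leaderboard:
    """Build the leaderboard: ranks from means, overall score s, final rank.

    Equal overall scores are resolved by the σ rank; any residual tie is
    broken lexicographically by method name and flagged in the result.
    """
    if not summaries:
        raise ValueError("no method summaries to rank")
    table = build_rank_table(summaries)
    overall = {s.method: overall_score(table, s.method) for s in summaries}
    sig_table = build_rank_table(summaries, on_sigma=True)
    sigma_score = {
        s.method: overall_score(sig_table, s.method) for s in summaries
    }
    sig_ranks = dict(sigma_rank(summaries))
    order = sorted(
        (s.method for s in summaries),
        key=lambda name: (overall[name], sig_ranks[name], name),
    )
    final = {name: i for i, name in enumerate(order, start=1)}
    # the σ-rank column itself is always a strict permutation (its internal
    # ties fall back to method name), so a residual tie is a pair with equal
    # overall score AND equal σ score: their relative order came only from
    # the lexicographic rule and deserves a flag in the report
    residual = [
        (a, b)
        for a, b in zip(order, order[1:])
        if overall[a] == overall[b] and sigma_score[a] == sigma_score[b]
    ]
    return Leaderboard(
        methods=order,
        rank_table=table,
        overall=overall,
        sigma_score=sigma_score,
        sigma_ranks=sig_ranks,
        final_rank=final,
        residual_ties=residual,
    )
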
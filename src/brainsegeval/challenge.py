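"""Embedded leaderboard of a published 18-method brain-tissue segmentation
challenge, used as reference data for the ranking machinery.

Two tables ship with the package:

* ``challenge_cells.csv`` — per (method, measure, component): the published
  rank, mean μ over the 15 test cases, and standard deviation σ;
* ``challenge_overall.csv`` — per method: the published overall score s
  (sum of the nine GM/WM/CSF ranks), final rank r, and, where the tie-break
  was invoked, the σ rank.

Means and standard deviations are as printed (rounded to one decimal, some
to two significant figures); the published ranks were computed on full
precision, so re-ranking the rounded means does not reproduce every rank
cell — only the rank cells and their sums are exact reference values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import MEASURES, Measure, MethodSummary
from .volumes import EVALUATED_COMPONENTS, Component

__all__ = ["load_cells", "load_overall", "challenge_summaries", "published_rank"]

_MEASURE = {m.value: m for m in MEASURES}
_COMPONENT = {c.value: c for c in EVALUATED_COMPONENTS}


def _read(name: str) -> pd.DataFrame:
    with resources.files("brainsegeval.data").joinpath(name).open() as f:
        return pd.read_csv(f)


def load_cells() -> pd.DataFrame:
    """Per-cell table: method, measure, component, rank, mean, sd."""
    return _read("challenge_cells.csv")


def load_overall() -> pd.DataFrame:
    """Per-method table: method, overall score s, final rank r, σ rank."""
    return _read("challenge_overall.csv")


def challenge_summaries() -> list[MethodSummary]:
    """The published μ/σ cells as :class:`MethodSummary` objects (15 cases)."""
    cells = load_cells()
    out = []
    for method, grp in cells.groupby("method", sort=False):
        mean: dict[tuple[Measure, Component], float] = {}
        std: dict[tuple[Measure, Component], float] = {}
        for _, row in grp.iterrows():
            key = (_MEASURE[row["measure"]], _COMPONENT[row["component"]])
            mean[key] = float(row["mean"])
            std[key] = float(row["sd"])
        out.append(MethodSummary(method=str(method), mean=mean, std=std, n_cases=15))
    return out


def published_rank(method: str, measure: Measure, component: Component) -> int:
    """The published rank cell for one method in one column."""
    cells = load_cells()
    sel = cells[
        (cells["method"] == method)
        & (cells["measure"] == measure.value)
        & (cells["component"] == component.value)
    ]
    if sel.empty:
        raise KeyError(f"no published cell for {method}/{measure.value}/{component.value}")
    return int(sel["rank"].iloc[0])
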
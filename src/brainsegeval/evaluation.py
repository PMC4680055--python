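"""Per-case evaluation over the five anatomical components and mean/σ
aggregation of a method's results over a test set.

Each case compares one candidate segmentation against the 8-structure
reference: the reference is merged to the tissue scheme, cerebellum and
brainstem voxels are excluded from both volumes, and Dice, H95 and AVD are
computed for GM, WM, CSF, brain (GM+WM) and intracranial volume (GM+WM+CSF).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import MetricTriple, mask_metrics
from .volumes import (
    EVALUATED_COMPONENTS,
    Component,
    LabelVolume,
    Scheme,
    as_tissue,
    component_mask,
    merge_to_tissue,
)

__all__ = [
    "Measure",
    "MEASURES",
    "CaseResult",
    "MethodSummary",
    "evaluate_case",
    "summarize",
    "cases_to_frame",
    "summary_to_frame",
    "summary_from_frame",
]

log = logging.getLogger(__name__)


class Measure(enum.Enum):
    """The three evaluation measures."""

    DICE = "D"
    H95 = "H95"
    AVD = "AVD"


MEASURES = (Measure.DICE, Measure.H95, Measure.AVD)

#: column names used in CSV exports, per measure.
_CSV_COLUMN = {Measure.DICE: "dice_pct", Measure.H95: "h95_mm", Measure.AVD: "avd_pct"}


@dataclass
class CaseResult:
    """Dice/H95/AVD triples for the five components of one test case."""

    case_id: str
    components: dict[Component, MetricTriple]

    def __post_init__(self) -> None:
        missing = [c for c in EVALUATED_COMPONENTS if c not in self.components]
        if missing:
            raise ValueError(f"case {self.case_id} missing components: {missing}")

    def value(self, measure: Measure, component: Component) -> float:
        t = self.components[component]
        return {Measure.DICE: t.dice, Measure.H95: t.h95, Measure.AVD: t.avd}[measure]


@dataclass
class MethodSummary:
    """Mean μ and standard deviation σ per (measure, component) for one method.

    σ is the sample standard deviation (n−1 denominator); with a single
    case σ is 0. ``counts`` records how many cases contributed to each
    cell — cases with an undefined H95 are excluded from that cell with a
    logged warning rather than silently propagating NaN into the ranking.
    """

    method: str
    mean: dict[tuple[Measure, Component], float]
    std: dict[tuple[Measure, Component], float]
    n_cases: int
    counts: dict[tuple[Measure, Component], int] = field(default_factory=dict)


def evaluate_case(
    candidate: LabelVolume, reference: LabelVolume, case_id: str = "case"
) -> CaseResult:
    """Evaluate one candidate segmentation against the raw-scheme reference.

    The candidate may be tissue-scheme (the submission convention: 0
    background, 1 GM, 2 WM, 3 CSF) or raw-scheme, in which case it is
    merged automatically. Exclusion (cerebellum/brainstem) is defined by
    the reference and applied to both volumes.
    """
    if reference.scheme is not Scheme.RAW:
        raise ValueError("reference must be a raw-scheme volume")
    if candidate.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: candidate {candidate.shape} vs reference {reference.shape}"
        )
    if not np.allclose(candidate.spacing, reference.spacing, atol=1e-4):
        raise ValueError(
            f"spacing mismatch: candidate {candidate.spacing} vs reference {reference.spacing}"
        )
    ref_tissue, excluded = merge_to_tissue(reference)
    cand_tissue = as_tissue(candidate)
    results: dict[Component, MetricTriple] = {}
    for comp in EVALUATED_COMPONENTS:
        a = component_mask(cand_tissue, comp, excluded)
        g = component_mask(ref_tissue, comp, excluded)
        results[comp] = mask_metrics(a, g)
        if not results[comp].h95_defined:
            log.warning("case %s component %s: H95 undefined (empty boundary)", case_id, comp.value)
    return CaseResult(case_id=case_id, components=results)


def summarize(results: list[CaseResult], method: str) -> MethodSummary:
    """Mean and sample standard deviation per (measure, component) over cases."""
    if not results:
        raise ValueError("cannot summarize an empty result list")
    mean: dict[tuple[Measure, Component], float] = {}
    std: dict[tuple[Measure, Component], float] = {}
    counts: dict[tuple[Measure, Component], int] = {}
    for m in MEASURES:
        for c in EVALUATED_COMPONENTS:
            vals = np.array([r.value(m, c) for r in results], dtype=float)
            ok = ~np.isnan(vals)
            if ok.sum() < len(vals):
                log.warning(
                    "method %s: excluding %d case(s) with undefined %s/%s from the summary",
                    method, int((~ok).sum()), m.value, c.value,
                )
            vals = vals[ok]
            counts[(m, c)] = int(vals.size)
            if vals.size == 0:
                mean[(m, c)] = float("nan")
                std[(m, c)] = float("nan")
            else:
                mean[(m, c)] = float(vals.mean())
                std[(m, c)] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return MethodSummary(method=method, mean=mean, std=std, n_cases=len(results), counts=counts)


def cases_to_frame(results: list[CaseResult], method: str) -> pd.DataFrame:
    """One row per (method, case, component) with dice_pct, h95_mm, avd_pct."""
    rows = []
    for r in results:
        for c in EVALUATED_COMPONENTS:
            t = r.components[c]
            rows.append(
                {
                    "method": method,
                    "case_id": r.case_id,
                    "component": c.value,
                    "dice_pct": t.dice,
                    "h95_mm": t.h95,
                    "avd_pct": t.avd,
                }
            )
    return pd.DataFrame(rows)


def summary_to_frame(summary: MethodSummary) -> pd.DataFrame:
    """Single-row frame with mu_/sigma_ column pairs per measure-component."""
    row: dict[str, object] = {"method": summary.method, "n_cases": summary.n_cases}
    for m in MEASURES:
        for c in EVALUATED_COMPONENTS:
            stem = f"{_CSV_COLUMN[m]}_{c.value}"
            row[f"mu_{stem}"] = summary.mean[(m, c)]
            row[f"sigma_{stem}"] = summary.std[(m, c)]
            row[f"n_{stem}"] = summary.counts.get((m, c), summary.n_cases)
    return pd.DataFrame([row])


def summary_from_frame(frame: pd.DataFrame) -> list[MethodSummary]:
    """Rebuild method summaries from a summary CSV frame (inverse of
    :func:`summary_to_frame`, rows may come from several files)."""
    out = []
    for _, row in frame.iterrows():
        mean, std, counts = {}, {}, {}
        for m in MEASURES:
            for c in EVALUATED_COMPONENTS:
                stem = f"{_CSV_COLUMN[m]}_{c.value}"
                mean[(m, c)] = float(row[f"mu_{stem}"])
                std[(m, c)] = float(row[f"sigma_{stem}"])
                counts[(m, c)] = int(row.get(f"n_{stem}", row["n_cases"]))
        out.append(
            MethodSummary(
                method=str(row["method"]),
                mean=mean,
                std=std,
                n_cases=int(row["n_cases"]),
                counts=counts,
            )
        )
    return out
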
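"""Cohort-referenced plan-quality scoring and dose-constraint checking.

Competing plan groups are ranked by a relative-deviation score.  For each
scored item j (a structure/metric pair) the cohort-best value across the
groups is the reference C_j — the minimum for lower-is-better metrics
(OAR doses, HI, near-max target dose), the maximum for higher-is-better
ones (TC, CI).  A group's item score is

    S_j = | (M_j - C_j) / C_j * P_j |

with M_j the group's value and P_j a weight (1 by default), and its
overall score is the plain sum S_D = sum_j S_j, split into a target (PTV)
and an organ-at-risk (OAR) subtotal.  The group holding the best value of
an item scores exactly 0 on it; a group scoring 0 overall is best on every
item; lower S_D means a better plan.

The reference is selected per item, not as one global best plan: with real
cohorts different groups hold different per-item optima, so even the
winning group accrues a nonzero subtotal from the items it does not lead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ScoringError, ScoringUndefinedError, ValidationError

__all__ = [
    "MetricSpec",
    "ScoreItem",
    "ScoreBreakdown",
    "ConstraintTable",
    "ConstraintReport",
    "select_reference",
    "item_score",
    "aggregate_score",
    "score_cohort",
    "evaluate_constraints",
    "breakdowns_to_frame",
]

LOWER_BETTER = "lower_better"
HIGHER_BETTER = "higher_better"


@dataclass(frozen=True)
class MetricSpec:
    """One scored item: which metric of which structure, its direction of
    merit, its category (ptv | oar) and its weight P_j."""

    structure: str
    metric: str
    category: str
    direction: str
    weight: float = 1.0

    def __post_init__(self):
        if self.category not in ("ptv", "oar"):
            raise ValidationError(f"category must be 'ptv' or 'oar', got {self.category!r}")
        if self.direction not in (LOWER_BETTER, HIGHER_BETTER):
            raise ValidationError(
                f"direction must be '{LOWER_BETTER}' or '{HIGHER_BETTER}', "
                f"got {self.direction!r}"
            )
        if self.weight <= 0:
            raise ValidationError("weight must be positive")


@dataclass(frozen=True)
class ScoreItem:
    spec: MetricSpec
    group: str
    m: float  # measured value M_j
    c: float  # reference value C_j
    s: float  # item score S_j
    reference_groups: tuple[str, ...]


@dataclass(frozen=True)
class ScoreBreakdown:
    """All item scores of one group plus its subtotals and overall score."""

    group: str
    items: tuple[ScoreItem, ...]

    @property
    def ptv_subtotal(self) -> float:
        return aggregate_score([i.s for i in self.items if i.spec.category == "ptv"])

    @property
    def oar_subtotal(self) -> float:
        return aggregate_score([i.s for i in self.items if i.spec.category == "oar"])

    @property
    def overall(self) -> float:
        return aggregate_score([i.s for i in self.items])


def select_reference(
    values: Mapping[str, float], direction: str
) -> tuple[float, tuple[str, ...]]:
    """Cohort-best value across groups and every group attaining it.

    Best = minimum for lower-is-better, maximum for higher-is-better.
    """
    if len(values) < 2:
        raise ScoringError("reference selection needs at least two groups")
    vals = np.asarray(list(values.values()), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("all group values must be finite")
    if direction == LOWER_BETTER:
        c = float(vals.min())
    elif direction == HIGHER_BETTER:
        c = float(vals.max())
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    refs = tuple(g for g, v in values.items() if v == c)
    return c, refs


def item_score(m: float, c: float, weight: float = 1.0) -> float:
    """S_j = |(M_j - C_j)/C_j * P_j|; 0 exactly when the group holds the
    reference value.  Undefined for C_j = 0 (relative deviation has no
    scale there)."""
    if c == 0:
        raise ScoringUndefinedError("reference value C_j = 0: relative score undefined")
    if weight <= 0:
        raise ValidationError("weight must be positive")
    if m == c:
        return 0.0
    return abs((m - c) / c * weight)


def aggregate_score(items: Iterable[float]) -> float:
    """S_D = sum of item scores; the empty sum is 0."""
    total = 0.0
    for s in items:
        if not np.isfinite(s) or s < 0:
            raise ValidationError(f"item scores must be finite and >= 0, got {s}")
        total += s
    return total


def score_cohort(
    table: pd.DataFrame, specs: Sequence[MetricSpec]
) -> list[ScoreBreakdown]:
    """Score every group of a long-format metric table against the
    per-item cohort-best references.

    ``table`` needs columns group, structure, metric, value (plan_id
    optional); when several plans per group are present (one per patient)
    the *group mean* of each cell is scored.  Full precision is retained —
    rounding is a reporting concern.
    """
    required = {"group", "structure", "metric", "value"}
    if not required.issubset(table.columns):
        raise ScoringError(f"metric table must have columns {sorted(required)}")
    means = table.groupby(["group", "structure", "metric"], sort=False)["value"].mean()
    groups = list(dict.fromkeys(table["group"]))
    items_by_group: dict[str, list[ScoreItem]] = {g: [] for g in groups}
    for spec in specs:
        values: dict[str, float] = {}
        for g in groups:
            try:
                values[g] = float(means[(g, spec.structure, spec.metric)])
            except KeyError:
                raise ScoringError(
                    f"missing cell: group {g!r}, structure {spec.structure!r}, "
                    f"metric {spec.metric!r}"
                ) from None
        c, refs = select_reference(values, spec.direction)
        for g in groups:
            s = item_score(values[g], c, spec.weight)
            items_by_group[g].append(
                ScoreItem(spec=spec, group=g, m=values[g], c=c, s=s, reference_groups=refs)
            )
    return [ScoreBreakdown(group=g, items=tuple(items_by_group[g])) for g in groups]


def breakdowns_to_frame(breakdowns: Sequence[ScoreBreakdown]) -> pd.DataFrame:
    """Flatten breakdowns to a tidy table (group, structure, metric,
    category, measured, reference, score)."""
    rows = [
        {
            "group": b.group,
            "structure": i.spec.structure,
            "metric": i.spec.metric,
            "category": i.spec.category,
            "measured": i.m,
            "reference": i.c,
            "score": i.s,
        }
        for b in breakdowns
        for i in b.items
    ]
    return pd.DataFrame(
        rows,
        columns=["group", "structure", "metric", "category", "measured", "reference", "score"],
    )


@dataclass(frozen=True)
class ConstraintTable:
    """Upper-bound dose constraints: rows of (structure, metric, bound, units)."""

    rows: pd.DataFrame

    def __post_init__(self):
        required = {"structure", "metric", "bound"}
        if not required.issubset(self.rows.columns):
            raise ValidationError(f"constraint table must have columns {sorted(required)}")
        if (self.rows["bound"] <= 0).any():
            raise ValidationError("constraint bounds must be positive")
        if self.rows.duplicated(["structure", "metric"]).any():
            raise ValidationError("one constraint row per (structure, metric) allowed")


@dataclass(frozen=True)
class ConstraintReport:
    """Row-level statuses plus one pass/fail verdict per plan."""

    rows: pd.DataFrame  # plan_id, structure, metric, value, bound, status
    plan_summary: pd.DataFrame  # plan_id, n_pass, n_fail, n_unevaluated, plan_pass


def evaluate_constraints(
    table: pd.DataFrame, constraints: ConstraintTable, plan_col: str = "plan_id"
) -> ConstraintReport:
    """Check each plan against every upper-bound constraint.

    A row passes iff value <= bound (inclusive at the bound).  A constraint
    whose metric is absent from the plan is marked ``unevaluated`` and
    blocks the plan-level pass.
    """
    if plan_col not in table.columns:
        raise ScoringError(f"metric table must have a {plan_col!r} column")
    values = table.set_index([plan_col, "structure", "metric"])["value"]
    if values.index.duplicated().any():
        raise ScoringError("duplicate (plan, structure, metric) rows in metric table")
    rows = []
    for pid in dict.fromkeys(table[plan_col]):
        for _, cons in constraints.rows.iterrows():
            key = (pid, cons["structure"], cons["metric"])
            if key in values.index:
                value = float(values[key])
                status = "pass" if value <= cons["bound"] else "fail"
            else:
                value = np.nan
                status = "unevaluated"
            rows.append(
                {
                    "plan_id": pid,
                    "structure": cons["structure"],
                    "metric": cons["metric"],
                    "value": value,
                    "bound": float(cons["bound"]),
                    "status": status,
                }
            )
    rows_df = pd.DataFrame(
        rows, columns=["plan_id", "structure", "metric", "value", "bound", "status"]
    )
    summary = (
        rows_df.groupby("plan_id", sort=False)["status"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["pass", "fail", "unevaluated"], fill_value=0)
        .rename(columns={"pass": "n_pass", "fail": "n_fail", "unevaluated": "n_unevaluated"})
        .reset_index()
    )
    summary["plan_pass"] = (summary["n_fail"] == 0) & (summary["n_unevaluated"] == 0)
    return ConstraintReport(rows=rows_df, plan_summary=summary)
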
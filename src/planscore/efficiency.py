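"""Delivery-efficiency metrics and group-comparison statistics.

Efficiency side: total monitor units (MU) per plan and the fraction of
segments below a small-MU threshold (default 5 MU, strict ``<``) — many
tiny segments lengthen delivery and are harder to deliver accurately.

Statistics side: a normality-gated two-sample comparison.  Each sample
(or, for paired data, the within-patient differences) is tested with
Shapiro–Wilk at alpha = 0.05; if normality is accepted a t-test is used
(paired or two-sample), otherwise a rank-sum test (Wilcoxon signed-rank
when paired, Mann–Whitney U otherwise).  Families of comparisons against a
reference group are Bonferroni-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ValidationError
from .synthetic import SegmentRecord

__all__ = [
    "ComparisonResult",
    "total_mu",
    "small_segment_fraction",
    "efficiency_table",
    "compare_groups",
    "bonferroni",
    "compare_cohort",
    "split_plan_id",
]

ALPHA = 0.05
SMALL_MU_THRESHOLD = 5.0


def _mu_array(segments) -> np.ndarray:
    if isinstance(segments, pd.DataFrame):
        mu = segments["mu"].to_numpy(dtype=float)
    else:
        segments = list(segments)
        if segments and isinstance(segments[0], SegmentRecord):
            mu = np.array([s.mu for s in segments], dtype=float)
        else:
            mu = np.asarray(segments, dtype=float)
    if mu.size == 0:
        raise ValidationError("segment list is empty")
    if np.any(mu < 0):
        raise ValidationError("segment MU must be >= 0")
    return mu


def total_mu(segments) -> float:
    """Sum of segment monitor units of one plan."""
    return float(_mu_array(segments).sum())


def small_segment_fraction(segments, threshold: float = SMALL_MU_THRESHOLD) -> float:
    """Percentage of segments with MU strictly below ``threshold``."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    mu = _mu_array(segments)
    return float(100.0 * (mu < threshold).mean())


def split_plan_id(plan_id: str) -> tuple[str, str]:
    """Split the canonical "P{nn}-{group}" plan id into (patient, group)."""
    patient, _, group = plan_id.partition("-")
    if not group:
        raise ValidationError(f"plan_id {plan_id!r} is not of the form 'patient-group'")
    return patient, group


def efficiency_table(
    segments: pd.DataFrame, threshold: float = SMALL_MU_THRESHOLD
) -> pd.DataFrame:
    """Per-plan total MU and small-segment share from a segments table
    (columns plan_id, beam, segment, mu); group parsed from the plan id."""
    rows = []
    for pid, sub in segments.groupby("plan_id", sort=False):
        patient, group = split_plan_id(pid)
        rows.append(
            {
                "plan_id": pid,
                "patient": patient,
                "group": group,
                "n_segments": len(sub),
                "total_mu": total_mu(sub),
                "small_segment_pct": small_segment_fraction(sub, threshold),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["plan_id", "patient", "group", "n_segments", "total_mu", "small_segment_pct"],
    )


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    group_a: str
    group_b: str
    test_used: str  # "t" | "rank_sum"
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool

    def __post_init__(self):
        if not (0.0 <= self.p_raw <= self.p_adjusted <= 1.0):
            raise ValidationError(
                f"require 0 <= p_raw <= p_adjusted <= 1, got "
                f"({self.p_raw}, {self.p_adjusted})"
            )


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    try:
        return float(sps.shapiro(x).pvalue) > alpha
    except ValueError:  # zero-range input; treat as non-normal
        return False


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = True,
    alpha: float = ALPHA,
    metric: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> ComparisonResult:
    """Normality-gated two-sided comparison of two samples.

    Paired samples are compared through their elementwise differences;
    identical paired samples are reported as statistic 0, p = 1 without
    invoking a test (every rank-sum statistic is degenerate there).
    ``p_adjusted`` is initialised to ``p_raw``; apply :func:`bonferroni`
    afterwards for a family of comparisons.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each sample needs at least 3 observations")
    if paired and a.size != b.size:
        raise ValidationError("paired comparison requires equal-length samples")
    if paired:
        d = a - b
        if np.allclose(d, 0.0):
            test_used, stat, p = "t", 0.0, 1.0
        elif _is_normal(d, alpha):
            res = sps.ttest_rel(a, b)
            test_used, stat, p = "t", float(res.statistic), float(res.pvalue)
        else:
            res = sps.wilcoxon(a, b)
            test_used, stat, p = "rank_sum", float(res.statistic), float(res.pvalue)
    else:
        if _is_normal(a, alpha) and _is_normal(b, alpha):
            res = sps.ttest_ind(a, b)
            test_used, stat, p = "t", float(res.statistic), float(res.pvalue)
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            test_used, stat, p = "rank_sum", float(res.statistic), float(res.pvalue)
    p = min(max(p, 0.0), 1.0)
    return ComparisonResult(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        test_used=test_used,
        statistic=stat,
        p_raw=p,
        p_adjusted=p,
        significant=p < alpha,
    )


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value min(1, m * p_raw) for a family of ``m``
    comparisons."""
    if m < 1:
        raise ValidationError("family size m must be >= 1")
    if not (0.0 <= p_raw <= 1.0):
        raise ValidationError("p_raw must be in [0, 1]")
    return min(1.0, m * p_raw)


def adjust_family(
    results: Sequence[ComparisonResult], m: int | None = None, alpha: float = ALPHA
) -> list[ComparisonResult]:
    """Apply the Bonferroni correction across a family of comparisons."""
    m = len(results) if m is None else m
    return [
        replace(r, p_adjusted=bonferroni(r.p_raw, m), significant=bonferroni(r.p_raw, m) < alpha)
        for r in results
    ]


def compare_cohort(
    table: pd.DataFrame,
    reference_group: str,
    value_col: str = "value",
    paired: bool = True,
    m: int | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Compare every group against ``reference_group`` for every
    (structure, metric) cell of a long-format table.

    Pairing joins plans of the same patient (parsed from plan_id) across
    groups.  The Bonferroni family is, per cell, the set of comparisons
    against the reference (``m`` defaults to the number of other groups).
    Returns a tidy results table.
    """
    if "plan_id" not in table.columns:
        raise ValidationError("table must carry plan_id for cohort comparisons")
    table = table.assign(patient=[split_plan_id(p)[0] for p in table["plan_id"]])
    groups = [g for g in dict.fromkeys(table["group"]) if g != reference_group]
    if reference_group not in set(table["group"]):
        raise ValidationError(f"reference group {reference_group!r} not in table")
    family = m if m is not None else len(groups)
    out = []
    for (structure, metric), cell in table.groupby(["structure", "metric"], sort=False):
        wide = cell.pivot(index="patient", columns="group", values=value_col)
        results = []
        for g in groups:
            sub = wide[[reference_group, g]].dropna()
            results.append(
                compare_groups(
                    sub[g],
                    sub[reference_group],
                    paired=paired,
                    alpha=alpha,
                    metric=f"{structure}:{metric}",
                    group_a=g,
                    group_b=reference_group,
                )
            )
        for r in adjust_family(results, m=family, alpha=alpha):
            out.append(
                {
                    "structure": structure,
                    "metric": metric,
                    "group": r.group_a,
                    "reference": r.group_b,
                    "test_used": r.test_used,
                    "statistic": r.statistic,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "significant": r.significant,
                }
            )
    return pd.DataFrame(
        out,
        columns=[
            "structure",
            "metric",
            "group",
            "reference",
            "test_used",
            "statistic",
            "p_raw",
            "p_adjusted",
            "significant",
        ],
    )
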
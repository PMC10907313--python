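"""Replicate-level statistics of the GUV recruitment assay.

The statistical unit is the replicate (one imaging chamber): per replicate the
proportion of recognised vesicles carrying at least one punctum is an exact
rational, conditions are summarised as mean +/- sample SD across replicates,
and conditions are compared by Student's t tests or one-way ANOVA.  Also
provides the live-cell above-threshold-area metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from skimage.measure import label, regionprops

from .puncta import GUVQuantRecord

__all__ = [
    "ReplicateResult",
    "ConditionSummary",
    "ComparisonResult",
    "proportion_guvs_with_puncta",
    "summarize_replicates",
    "compare_conditions",
    "cell_positive_area",
]


class EmptyInputError(ValueError):
    pass


@dataclass
class ReplicateResult:
    """Condition-level statistics of one replicate (imaging chamber)."""

    condition: str
    replicate_id: str
    n_guvs: int
    n_guvs_with_puncta: dict[str, int]
    proportion_with_puncta: dict[str, Fraction]
    coloc_proportion: Optional[float] = None


@dataclass
class ConditionSummary:
    condition: str
    values: list[float]
    mean: float
    sd: Optional[float]  # None for a single replicate


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    group_means: list[float]
    group_sds: list[Optional[float]]
    n_per_group: list[int]


def proportion_guvs_with_puncta(records: Sequence[GUVQuantRecord], channel: str
                                ) -> Fraction:
    """Exact proportion of vesicles with at least one punctum in ``channel``."""
    if not records:
        raise EmptyInputError("no GUV records: proportion is undefined, not 0")
    n_with = sum(1 for r in records if r.has_punctum.get(channel, False))
    return Fraction(n_with, len(records))


def _sd(values: Sequence[float]) -> Optional[float]:
    if len(values) < 2:
        return None
    return float(np.std(values, ddof=1))


def summarize_replicates(proportions_by_condition: dict[str, Sequence[float]]
                         ) -> list[ConditionSummary]:
    """Mean and sample SD (n-1 denominator) of per-replicate proportions.

    A condition with a single replicate reports SD as None, never 0.
    """
    out = []
    for condition, values in proportions_by_condition.items():
        vals = [float(v) for v in values]
        if not vals:
            raise EmptyInputError(f"condition {condition!r} has no replicates")
        out.append(ConditionSummary(condition, vals, float(np.mean(vals)), _sd(vals)))
    return out


def compare_conditions(groups: Sequence[Sequence[float]], test: str = "student_t",
                       group_names: Optional[Sequence[str]] = None) -> ComparisonResult:
    """Compare per-replicate values between conditions.

    ``test`` is one of 'student_t' (pooled-variance two-tailed), 'welch_t',
    'one_tailed_t' (alternative: second group mean below the first), or
    'anova' (one-way).  t tests require exactly two groups; every group needs
    at least two points.
    """
    names = list(group_names) if group_names is not None else [
        f"group{i}" for i in range(len(groups))]
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups to compare")
    for name, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {name!r} has {arr.size} point(s); "
                             "variance-based tests need at least 2")

    if test in ("student_t", "welch_t", "one_tailed_t"):
        if len(arrays) != 2:
            raise ValueError(f"{test} requires exactly two groups, got {len(arrays)}")
        a, b = arrays
        equal_var = test != "welch_t"
        alternative = "greater" if test == "one_tailed_t" else "two-sided"
        res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
        statistic, p = float(res.statistic), float(res.pvalue)
        if np.isnan(statistic):  # zero variance in both groups, equal means
            statistic = 0.0
            p = 0.5 if alternative == "greater" else 1.0
    elif test == "anova":
        res = stats.f_oneway(*arrays)
        statistic, p = float(res.statistic), float(res.pvalue)
        if np.isnan(statistic):
            statistic, p = 0.0, 1.0
    else:
        raise ValueError(f"unknown test {test!r}")

    return ComparisonResult(
        test=test, statistic=statistic, p_value=p,
        group_means=[float(a.mean()) for a in arrays],
        group_sds=[_sd(list(a)) for a in arrays],
        n_per_group=[int(a.size) for a in arrays],
    )


def cell_positive_area(cell_image: np.ndarray, threshold: float,
                       min_particle_size: int = 0) -> int:
    """Above-threshold particle area of one cell, in pixels.

    Pixels strictly above ``threshold`` count; ``min_particle_size`` optionally
    drops connected particles smaller than that many pixels (8-connectivity).
    The threshold is supplied per cell, mirroring a per-cell manual choice.
    """
    img = np.asarray(cell_image, dtype=float)
    mask = img > threshold
    if min_particle_size <= 1:
        return int(mask.sum())
    labels = label(mask, connectivity=2)
    return int(sum(rp.area for rp in regionprops(labels)
                   if rp.area >= min_particle_size))
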
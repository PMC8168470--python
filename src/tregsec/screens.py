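"""Panel screens and the shared group-statistics engine.

Panels (immunometabolism enzymes, trained-immunity enzymes, ROS regulatome)
are screened against each contrast's up/down DEG sets by plain intersection.
Group-level comparisons (means +/- SEM, two-group tests) are shared by every
stage that summarizes per-dataset counts across condition groups.

The dispersion attached to group means is the standard error of the mean
(sample sd / sqrt(n)).  The default two-group test is Welch's t; for very
small groups (min n < 4) an exact Mann-Whitney U is used instead.  Both are
reported with the method name so downstream tables are self-describing.  No
multiple-testing correction is applied across the handful of group
comparisons; a BH q-value is attached for information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .catalogs import GeneCatalog
from .de import ContrastResult


@dataclass(frozen=True)
class PanelScreenRecord:
    """Counts of panel genes among one contrast's up/down DEGs."""

    dataset_id: str
    panel: str
    n_up: int
    n_down: int

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down


def screen_panel(contrast: ContrastResult, panel: GeneCatalog) -> PanelScreenRecord:
    """Plain intersections of the panel with the up/down DEG sets."""
    return PanelScreenRecord(
        dataset_id=contrast.dataset_id,
        panel=panel.name,
        n_up=len(contrast.up_genes & panel.genes),
        n_down=len(contrast.down_genes & panel.genes),
    )


def mean_sem(values: Sequence[float]) -> tuple[float, float | None]:
    """Arithmetic mean and SEM (sample sd with n-1 / sqrt(n)).

    SEM is ``None`` for a single value; an empty list raises.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sem of empty list")
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, None
    return mean, float(arr.std(ddof=1) / math.sqrt(arr.size))


def two_group_test(
    a: Sequence[float], b: Sequence[float], method: str = "welch_t"
) -> tuple[float, float]:
    """Two-sided two-group test: ``welch_t`` or ``mann_whitney``.

    Welch's t uses the Welch-Satterthwaite df and needs >= 2 values per
    group; Mann-Whitney is exact for min(n) <= 8 without ties, otherwise a
    normal approximation with tie correction.  Two groups with zero variance
    and equal means return (0, 1).
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if method == "welch_t":
        if x.size < 2 or y.size < 2:
            raise ValueError("welch_t needs >= 2 values per group")
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            if x.mean() == y.mean():
                return 0.0, 1.0
            return math.inf if x.mean() > y.mean() else -math.inf, 0.0
        res = stats.ttest_ind(x, y, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if method == "mann_whitney":
        if x.size < 1 or y.size < 1:
            raise ValueError("mann_whitney needs >= 1 value per group")
        ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
        mode = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=mode)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test method {method!r}")


@dataclass
class GroupComparison:
    """Per-group summaries plus one two-group test on a chosen metric.

    ``values`` keeps the raw per-dataset numbers so the comparison is fully
    reproducible from the object alone.
    """

    metric: str
    values: dict[str, list[float]]
    means: dict[str, float]
    sems: dict[str, float | None]
    test: str
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "values": self.values,
            "means": self.means,
            "sems": self.sems,
            "test": self.test,
            "comparison": [self.group_a, self.group_b],
            "statistic": self.statistic,
            "p_value": self.p_value,
            "excluded_groups": self.excluded,
        }


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    metric: str = "value",
    focal_group: str | None = None,
    method: str | None = None,
) -> GroupComparison:
    """Summarize groups and test ``focal_group`` against the pooled rest.

    Groups with fewer than two datasets are excluded from testing (but still
    summarized).  With exactly two testable groups the test is between them;
    with more, ``focal_group`` (required then) is tested against the pooled
    remaining values.  ``method=None`` picks Welch's t, falling back to
    exact Mann-Whitney when either side has fewer than 4 values.
    """
    groups = {g: list(map(float, v)) for g, v in values_by_group.items()}
    if any(len(v) == 0 for v in groups.values()):
        empty = [g for g, v in groups.items() if not v]
        raise ValueError(f"empty group(s): {empty}")
    summaries = {g: mean_sem(v) for g, v in groups.items()}
    testable = [g for g, v in groups.items() if len(v) >= 2]
    excluded = sorted(set(groups) - set(testable))
    if len(testable) < 2:
        raise ValueError("need >= 2 groups with >= 2 datasets each for testing")

    if focal_group is not None and focal_group not in testable and len(testable) == 2:
        focal_group = None  # fall back to the two testable groups
    if len(testable) == 2 and focal_group is None:
        name_a, name_b = testable
        a, b = groups[name_a], groups[name_b]
    else:
        if focal_group is None:
            raise ValueError("focal_group required with more than two groups")
        if focal_group not in testable:
            raise ValueError(f"focal group {focal_group!r} not testable")
        name_a = focal_group
        name_b = "rest"
        a = groups[focal_group]
        b = [x for g in testable if g != focal_group for x in groups[g]]

    if method is None:
        method = "welch_t" if min(len(a), len(b)) >= 4 else "mann_whitney"
    statistic, p = two_group_test(a, b, method=method)
    return GroupComparison(
        metric=metric,
        values=groups,
        means={g: m for g, (m, _) in summaries.items()},
        sems={g: s for g, (_, s) in summaries.items()},
        test=method,
        group_a=name_a,
        group_b=name_b,
        statistic=statistic,
        p_value=p,
        excluded=excluded,
    )
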
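"""Secretome decomposition: DEG x catalog count/percentage tables.

Each contrast's up- and down-regulated gene lists are intersected with each
secretome catalog (or panel) and reported as counts plus percentages of the
contrast's **total** DEG count (up + down over all genes, not just catalog
members).  Percentages are rounded half away from zero to two decimals, the
convention that reproduces published count/percentage tables of this kind
exactly (e.g. 356 exosome up-DEGs of 1584 total DEGs -> 22.47).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogs import CatalogSuite, GeneCatalog
from .de import ConditionGroup, ContrastResult


def percent(numerator: int, denominator: int) -> float | None:
    """``100 * numerator / denominator`` rounded half away from zero to two
    decimals.  Returns ``None`` (missing) when the denominator is zero."""
    if denominator < 0 or numerator < 0:
        raise ValueError("counts must be non-negative")
    if denominator == 0:
        return None
    exact = Decimal(100 * numerator) / Decimal(denominator)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DecompositionRow:
    """One contrast x one catalog: catalog-member DEG counts and /DEG%."""

    dataset_id: str
    catalog: str
    total_deg: int
    n_up: int
    pct_up: float | None
    n_down: int
    pct_down: float | None


def decompose(contrast: ContrastResult, catalog: GeneCatalog) -> DecompositionRow:
    """Intersect the contrast's up/down DEG sets with one catalog.

    ``total_deg`` is the contrast's full DEG count; catalog genes absent
    from the platform simply never intersect (no coverage correction).
    """
    up = contrast.up_genes
    down = contrast.down_genes
    total = len(up) + len(down)
    n_up = len(up & catalog.genes)
    n_down = len(down & catalog.genes)
    return DecompositionRow(
        dataset_id=contrast.dataset_id,
        catalog=catalog.name,
        total_deg=total,
        n_up=n_up,
        pct_up=percent(n_up, total),
        n_down=n_down,
        pct_down=percent(n_down, total),
    )


DECOMPOSITION_COLUMNS = [
    "dataset_id",
    "catalog",
    "TotalDEG",
    "up",
    "up_pct",
    "down",
    "down_pct",
]


def decompose_suite(
    contrasts: Sequence[ContrastResult], suite: CatalogSuite
) -> pd.DataFrame:
    """Full contrast x catalog cross product as a tidy table.

    Row order is deterministic: contrasts in input order, catalogs in suite
    insertion order.
    """
    rows = []
    for contrast in contrasts:
        for catalog in suite.catalogs.values():
            r = decompose(contrast, catalog)
            rows.append(
                {
                    "dataset_id": r.dataset_id,
                    "catalog": r.catalog,
                    "TotalDEG": r.total_deg,
                    "up": r.n_up,
                    "up_pct": r.pct_up,
                    "down": r.n_down,
                    "down_pct": r.pct_down,
                }
            )
    return pd.DataFrame(rows, columns=DECOMPOSITION_COLUMNS)


def aggregate_by_group(
    rows: pd.DataFrame,
    groups: Mapping[str, ConditionGroup | str],
    column: str,
    catalog: str | None = None,
) -> pd.DataFrame:
    """Per-condition-group mean and SEM of one decomposition column.

    ``groups`` maps dataset_id -> condition group.  Single-dataset groups
    report SEM as missing (NaN).  Raises on datasets without a group or on
    an empty selection.
    """
    from .screens import mean_sem  # shared group-statistics primitives

    sel = rows if catalog is None else rows[rows["catalog"] == catalog]
    if sel.empty:
        raise ValueError("no rows to aggregate")
    missing = set(sel["dataset_id"]) - set(groups)
    if missing:
        raise ValueError(f"datasets without a condition group: {sorted(missing)}")
    out = []
    labels = {d: ConditionGroup(g).value for d, g in groups.items()}
    sel = sel.assign(condition_group=[labels[d] for d in sel["dataset_id"]])
    for group, sub in sel.groupby("condition_group", sort=True):
        values = sub[column].dropna().to_numpy(dtype=float)
        if values.size == 0:
            raise ValueError(f"group {group!r} has no usable values")
        mean, sem = mean_sem(values)
        out.append(
            {
                "condition_group": group,
                "n_datasets": int(values.size),
                "mean": mean,
                "sem": np.nan if sem is None else sem,
            }
        )
    return pd.DataFrame(out, columns=["condition_group", "n_datasets", "mean", "sem"])
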
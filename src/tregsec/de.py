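"""Per-gene case-vs-control contrasts and threshold-based DEG calling.

The differential-expression layer is deliberately simple and transparent:

* array data (log2 intensities) — per-gene Welch two-sample t-test, with
  ``log2fc = mean(case) - mean(control)``;
* RNA-seq counts — library-size normalization to counts-per-million, a
  ``log2(CPM + 0.5)`` transform, then the same Welch test.

A gene is called **up** when ``log2fc > fc_threshold`` and
``p < p_threshold``, **down** when ``log2fc < -fc_threshold`` and
``p < p_threshold``, and **ns** otherwise.  Thresholds default to 1 log2
unit (two-fold) and p < 0.05, strict at the boundary; an inclusive-fold-
change switch is provided.  Raw p is thresholded; Benjamini-Hochberg q is
reported alongside for information only.

A per-contrast housekeeping QC checks that reference genes (ACTB ... TBP)
stay within a fold-change band, flagging contrasts with suspect
normalization.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalogs import GeneCatalog, normalize_symbol

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"


class Platform(str, enum.Enum):
    ARRAY = "array"
    RNASEQ = "rnaseq"


class TissueClass(str, enum.Enum):
    LYMPHOID = "lymphoid"
    NON_LYMPHOID = "non_lymphoid"


class ConditionGroup(str, enum.Enum):
    """Study-arm grouping of datasets: healthy, benign disease, and the two
    tumor compartments (spleen of tumor-bearing animals vs tumor tissue)."""

    NORMAL = "normal"
    BENIGN = "benign"
    TUMOR_SPLEEN = "tumor_spleen"
    TUMOR_TISSUE = "tumor_tissue"


@dataclass(frozen=True)
class DatasetMeta:
    tissue: str
    tissue_class: TissueClass
    condition_group: ConditionGroup

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissue_class", TissueClass(self.tissue_class))
        object.__setattr__(self, "condition_group", ConditionGroup(self.condition_group))

    def to_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "tissue_class": self.tissue_class.value,
            "condition_group": self.condition_group.value,
        }


@dataclass(frozen=True)
class Thresholds:
    """DEG calling cutoffs.

    ``fc_threshold`` is in log2 units (1 = two-fold); ``p_threshold`` applies
    to the raw p-value.  With ``inclusive_fc`` the fold-change comparison is
    ``|log2fc| >= fc_threshold`` instead of strict ``>``; p stays strict.
    """

    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    inclusive_fc: bool = False

    def __post_init__(self) -> None:
        if not self.fc_threshold > 0:
            raise ValueError("fc_threshold must be > 0")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")


def classify_deg(log2fc: float, p: float, thresholds: Thresholds = Thresholds()) -> str:
    """Pure status rule: 'up', 'down' or 'ns'.

    Boundary values (|log2fc| exactly at the threshold with the default
    strict convention, or p exactly at the threshold) are 'ns'.
    """
    if not (0 <= p <= 1) or math.isnan(p):
        raise ValueError(f"p-value out of [0, 1]: {p}")
    if p >= thresholds.p_threshold:
        return STATUS_NS
    if thresholds.inclusive_fc:
        if log2fc >= thresholds.fc_threshold:
            return STATUS_UP
        if log2fc <= -thresholds.fc_threshold:
            return STATUS_DOWN
    else:
        if log2fc > thresholds.fc_threshold:
            return STATUS_UP
        if log2fc < -thresholds.fc_threshold:
            return STATUS_DOWN
    return STATUS_NS


@dataclass
class ExpressionDataset:
    """A genes x samples matrix with case/control labels and metadata.

    ``values`` holds log2 intensities (array) or non-negative integer counts
    (rnaseq), indexed by normalized gene symbol.  ``sample_group`` labels
    each column 'case' or 'control'; at least two replicates per arm are
    required.
    """

    dataset_id: str
    platform: Platform
    values: pd.DataFrame
    sample_group: Sequence[str]
    metadata: DatasetMeta

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        groups = list(self.sample_group)
        if len(groups) != self.values.shape[1]:
            raise ValueError("sample_group length must match number of columns")
        bad = set(groups) - {"case", "control"}
        if bad:
            raise ValueError(f"sample_group labels must be case/control, got {bad}")
        if groups.count("case") < 2 or groups.count("control") < 2:
            raise ValueError("need >= 2 case and >= 2 control samples")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        if self.platform is Platform.RNASEQ:
            vals = self.values.to_numpy()
            if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                raise ValueError("rnaseq values must be non-negative integers")
        self.sample_group = groups

    @property
    def case(self) -> pd.DataFrame:
        mask = [g == "case" for g in self.sample_group]
        return self.values.loc[:, mask]

    @property
    def control(self) -> pd.DataFrame:
        mask = [g == "control" for g in self.sample_group]
        return self.values.loc[:, mask]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ContrastResult:
    """Per-gene log2 fold change, p, BH q and up/down/ns status for one
    case-vs-control comparison.  ``table`` is indexed by gene symbol."""

    dataset_id: str
    table: pd.DataFrame
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        required = {"log2fc", "p_value", "status"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"contrast table missing columns {missing}")
        bad = set(self.table["status"]) - {STATUS_UP, STATUS_DOWN, STATUS_NS}
        if bad:
            raise ValueError(f"unknown status values {bad}")

    @property
    def genes(self) -> set[str]:
        return set(self.table.index)

    @property
    def up_genes(self) -> set[str]:
        return set(self.table.index[self.table["status"] == STATUS_UP])

    @property
    def down_genes(self) -> set[str]:
        return set(self.table.index[self.table["status"] == STATUS_DOWN])

    @property
    def deg_genes(self) -> set[str]:
        return self.up_genes | self.down_genes

    @property
    def n_deg(self) -> int:
        return int((self.table["status"] != STATUS_NS).sum())


def cpm_log2(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Counts-per-million per sample, then log2(CPM + pseudocount)."""
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("sample with zero total counts")
    cpm = counts.divide(libsize, axis=1) * 1e6
    return np.log2(cpm + pseudocount)


def _welch(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t-test along axis 1.

    Returns (t, p, zero_variance_flag).  Genes with zero variance in *both*
    arms get p = 1 and are flagged; the t statistic is reported as 0 there.
    """
    n1, n2 = case.shape[1], control.shape[1]
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    zero = (v1 == 0) & (v2 == 0)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(zero, 0.0, t)
    p = np.where(zero, 1.0, p)
    return t, p, zero


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (reported for information)."""
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")


def compute_contrast(
    dataset: ExpressionDataset, thresholds: Thresholds = Thresholds()
) -> ContrastResult:
    """Welch-test every gene and assign DEG status per ``thresholds``."""
    if dataset.platform is Platform.RNASEQ:
        values = cpm_log2(dataset.values.astype(float))
    else:
        values = dataset.values.astype(float)
    case = values.loc[:, [g == "case" for g in dataset.sample_group]].to_numpy()
    control = values.loc[:, [g == "control" for g in dataset.sample_group]].to_numpy()
    t, p, zero = _welch(case, control)
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    status = [classify_deg(fc, pv, thresholds) for fc, pv in zip(log2fc, p)]
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "q_value": bh_adjust(p),
            "t_statistic": t,
            "zero_variance": zero,
            "status": status,
        },
        index=pd.Index(dataset.genes, name="gene"),
    )
    return ContrastResult(dataset.dataset_id, table, thresholds)


@dataclass
class HousekeepingQC:
    """Housekeeping fold changes against an acceptance band.

    ``passed`` is True iff every housekeeping gene measured in the contrast
    has log2fc within ``band``; genes absent from the dataset are listed in
    ``missing`` and do not fail the check.
    """

    dataset_id: str
    log2fc: dict[str, float]
    band: tuple[float, float]
    passed: bool
    missing: list[str]
    failing: list[str]


#: Default acceptance band in log2 units; wide enough to admit fold changes
#: housekeeping genes show across heterogeneous public Treg datasets.
DEFAULT_HK_BAND = (-1.3, 1.3)


def housekeeping_qc(
    contrast: ContrastResult,
    hk: GeneCatalog,
    band: tuple[float, float] = DEFAULT_HK_BAND,
) -> HousekeepingQC:
    """Check housekeeping-gene fold changes against ``band``."""
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")
    present = sorted(hk.genes & contrast.genes)
    missing = sorted(hk.genes - contrast.genes)
    if not present:
        raise ValueError(
            f"no housekeeping genes present in contrast {contrast.dataset_id!r}"
        )
    fcs = {g: float(contrast.table.at[g, "log2fc"]) for g in present}
    failing = [g for g, fc in fcs.items() if not (lo <= fc <= hi)]
    return HousekeepingQC(
        dataset_id=contrast.dataset_id,
        log2fc=fcs,
        band=(lo, hi),
        passed=not failing,
        missing=missing,
        failing=failing,
    )


@dataclass
class DegSummary:
    dataset_id: str
    n_deg: int
    n_up: int
    n_down: int
    pct_up: float | None  # percent of DEGs that are up; None when no DEGs


def deg_summary(contrast: ContrastResult) -> DegSummary:
    """Total/up/down DEG counts and the percent-up-of-DEGs headline number."""
    from .decompose import percent  # shared rounding rule

    n_up = len(contrast.up_genes)
    n_down = len(contrast.down_genes)
    total = n_up + n_down
    return DegSummary(
        dataset_id=contrast.dataset_id,
        n_deg=total,
        n_up=n_up,
        n_down=n_down,
        pct_up=percent(n_up, total),
    )


# ---------------------------------------------------------------------------
# I/O


def write_contrast(contrast: ContrastResult, path: str | Path) -> None:
    contrast.table.to_csv(path, sep="\t", float_format="%.10g")


def read_contrast(
    path: str | Path,
    dataset_id: str | None = None,
    thresholds: Thresholds = Thresholds(),
) -> ContrastResult:
    table = pd.read_csv(path, sep="\t", index_col="gene")
    table.index = [normalize_symbol(g) for g in table.index]
    table.index.name = "gene"
    return ContrastResult(dataset_id or Path(path).stem, table, thresholds)


def load_deg_table(
    path: str | Path,
    dataset_id: str | None = None,
    thresholds: Thresholds = Thresholds(),
) -> ContrastResult:
    """Import adapter for pre-computed DEG tables (``gene, log2fc, p``).

    Accepts exports from external differential-expression tools; statuses
    are (re-)derived from the supplied thresholds.  A ``p_value`` or ``p``
    column is accepted.
    """
    table = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in table.columns}
    gene_col = cols.get("gene") or table.columns[0]
    p_col = cols.get("p_value") or cols.get("p")
    fc_col = cols.get("log2fc") or cols.get("logfc")
    if p_col is None or fc_col is None:
        raise ValueError(f"{path}: DEG table needs gene, log2fc and p columns")
    out = pd.DataFrame(
        {
            "log2fc": table[fc_col].astype(float).to_numpy(),
            "p_value": table[p_col].astype(float).to_numpy(),
        },
        index=pd.Index([normalize_symbol(g) for g in table[gene_col]], name="gene"),
    )
    if out.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene symbols after normalization")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["status"] = [
        classify_deg(fc, p, thresholds)
        for fc, p in zip(out["log2fc"], out["p_value"])
    ]
    return ContrastResult(dataset_id or Path(path).stem, out, thresholds)


def write_expression(dataset: ExpressionDataset, matrix_path: str | Path) -> None:
    """Write the matrix as TSV plus a sidecar ``<stem>.meta.json``."""
    matrix_path = Path(matrix_path)
    dataset.values.to_csv(matrix_path, sep="\t", float_format="%.10g")
    meta = {
        "dataset_id": dataset.dataset_id,
        "platform": dataset.platform.value,
        "sample_group": list(dataset.sample_group),
        **dataset.metadata.to_dict(),
    }
    sidecar = matrix_path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_expression(matrix_path: str | Path) -> ExpressionDataset:
    matrix_path = Path(matrix_path)
    sidecar = matrix_path.with_suffix(".meta.json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = [normalize_symbol(g) for g in values.index]
    values.index.name = "gene"
    if meta["platform"] == Platform.RNASEQ.value:
        values = values.round().astype(np.int64)
    return ExpressionDataset(
        dataset_id=meta["dataset_id"],
        platform=meta["platform"],
        values=values,
        sample_group=meta["sample_group"],
        metadata=DatasetMeta(
            tissue=meta["tissue"],
            tissue_class=meta["tissue_class"],
            condition_group=meta["condition_group"],
        ),
    )
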
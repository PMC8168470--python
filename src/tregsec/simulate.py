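"""Synthetic expression datasets, regulator contrasts and catalogs with
planted ground truth.

Every downstream stage of the workbench is exercised on simulated data in
which the "truth" — which genes are differentially expressed, which belong
to which catalog, which genes a regulator induces or suppresses, which are
ROS-promoted — is planted by construction and recorded in a
:class:`TruthTable`.  Planting is by exact count (``round(frac * n)``), not
by Bernoulli thinning, so truth sizes are deterministic and recovery can be
asserted exactly.

Randomness discipline: each generator stage draws from its own stream
derived from ``config.seed`` via ``numpy.random.SeedSequence`` spawn keys
(see :data:`STREAM_KEYS`), so adding or reordering a stage never perturbs
the draws of another.  Identical configs give bit-identical outputs.

What is emulated: array-style log2-intensity matrices with Gaussian noise,
RNA-seq negative-binomial count matrices with log-normal library sizes,
small replicate numbers per arm, planted DEG fractions with effect sizes
spread around a mean |log2FC|, planted catalog membership, and planted
overlap fractions between Treg DEGs and regulator-perturbation DEGs.
Batch effects, probe-level structure and single-cell sparsity are not
modeled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalogs import (
    CatalogCategory,
    CatalogSuite,
    GeneCatalog,
    HOUSEKEEPING_GENES,
    PathwaySignature,
)
from .collaboration import PerturbationKind, Regulator, RegulatorContrast
from .de import (
    STATUS_DOWN,
    STATUS_NS,
    STATUS_UP,
    ConditionGroup,
    ContrastResult,
    DatasetMeta,
    ExpressionDataset,
    Platform,
    Thresholds,
    TissueClass,
)

#: Spawn keys for the per-stage random streams.
STREAM_KEYS = {
    "plant": 0,       # DEG selection and effect sizes
    "expression": 1,  # noise / counts
    "regulator": 2,   # regulator overlap selection (offset by regulator index)
    "dualko": 3,      # dual-KO class assignment
    "catalogs": 4,    # synthetic catalog membership
}

#: Catalog sizes used for the full-scale synthetic suite: the four
#: secretion-route catalogs, the three screening panels and the
#: housekeeping list.
DEFAULT_CATALOG_SIZES: dict[str, int] = {
    CatalogCategory.SECRETOME_CANONICAL.value: 2641,
    CatalogCategory.SECRETOME_CASP1.value: 961,
    CatalogCategory.SECRETOME_CASP4.value: 1223,
    CatalogCategory.SECRETOME_EXOSOME.value: 6560,
    CatalogCategory.PANEL_IMMUNOMETABOLISM.value: 191,
    CatalogCategory.PANEL_TRAINED_IMMUNITY.value: 102,
    CatalogCategory.PANEL_ROS_REGULATOME.value: 165,
    CatalogCategory.HOUSEKEEPING.value: 9,
}

CATALOG_NAMES = {
    CatalogCategory.SECRETOME_CANONICAL.value: "canonical_secretome",
    CatalogCategory.SECRETOME_CASP1.value: "caspase1_secretome",
    CatalogCategory.SECRETOME_CASP4.value: "caspase4_secretome",
    CatalogCategory.SECRETOME_EXOSOME.value: "exosome_secretome",
    CatalogCategory.PANEL_IMMUNOMETABOLISM.value: "immunometabolism_panel",
    CatalogCategory.PANEL_TRAINED_IMMUNITY.value: "trained_immunity_panel",
    CatalogCategory.PANEL_ROS_REGULATOME.value: "ros_regulatome_panel",
    CatalogCategory.HOUSEKEEPING.value: "housekeeping",
}

#: Default planted regulator-overlap fractions (frac_induced,
#: frac_suppressed): the master Treg transcription factor dominates, the
#: PD-1 axis contributes substantially, CTLA-4 blockade touches little.
DEFAULT_REGULATOR_OVERLAP: dict[str, tuple[float, float]] = {
    "FOXP3": (0.85, 0.85),
    "PD1": (0.60, 0.50),
    "CTLA4": (0.15, 0.10),
}

REGULATOR_KINDS = {
    "FOXP3": PerturbationKind.KNOCKOUT,
    "CTLA4": PerturbationKind.BLOCKADE,
    "PD1": PerturbationKind.BLOCKADE,
    "NOX2": PerturbationKind.KNOCKOUT,
    "NRF2": PerturbationKind.KNOCKOUT,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of one simulated case/control dataset.

    ``effect_size_log2`` is the mean planted absolute log2 fold change;
    individual effects are drawn uniformly on ``[0.6, 1.4] x`` that mean
    (so the default 2.0 spreads effects over [1.2, 2.8]).  ``noise_sd``
    applies to array platforms, ``dispersion`` to RNA-seq negative
    binomials.  Replicate counts default to 4 vs 4, a desk-scale convention
    for public Treg profiling experiments.
    """

    seed: int = 0
    n_genes: int = 10000
    platform: Platform = Platform.ARRAY
    n_case: int = 4
    n_control: int = 4
    frac_up: float = 0.05
    frac_down: float = 0.05
    effect_size_log2: float = 2.0
    noise_sd: float = 0.4
    dispersion: float = 0.1
    catalog_sizes: Mapping[str, int] | None = None
    planted_catalog_deg_rate: float = 0.06
    regulator_overlap: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGULATOR_OVERLAP)
    )
    dataset_id: str = "sim"
    tissue: str = "spleen"
    tissue_class: TissueClass = TissueClass.LYMPHOID
    condition_group: ConditionGroup = ConditionGroup.NORMAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "platform", Platform(self.platform))
        object.__setattr__(self, "tissue_class", TissueClass(self.tissue_class))
        object.__setattr__(self, "condition_group", ConditionGroup(self.condition_group))
        for name in ("frac_up", "frac_down", "planted_catalog_deg_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.frac_up + self.frac_down < 1:
            raise ValueError("frac_up + frac_down must be < 1")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >= 2 replicates per arm")
        if self.n_genes <= len(HOUSEKEEPING_GENES):
            raise ValueError("n_genes too small")
        if self.effect_size_log2 <= 0 or self.noise_sd <= 0 or self.dispersion <= 0:
            raise ValueError("effect_size_log2, noise_sd and dispersion must be > 0")
        for reg, (fi, fs) in self.regulator_overlap.items():
            if not (0 <= fi <= 1 and 0 <= fs <= 1):
                raise ValueError(f"overlap fractions for {reg} must be in [0, 1]")


def stream(config: SimulationConfig, name: str, offset: int = 0) -> np.random.Generator:
    """Per-stage random stream derived from the config seed."""
    key = STREAM_KEYS[name] * 1000 + offset
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(key,)))


TRUTH_NULL = "null"


@dataclass
class TruthTable:
    """Planted per-gene truth: DEG status/effect, catalog membership,
    regulator relations (``<REG>_relation`` columns) and ROS class."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        up = t["status"] == STATUS_UP
        down = t["status"] == STATUS_DOWN
        null = t["status"] == TRUTH_NULL
        if not (up | down | null).all():
            raise ValueError("truth status must be up/down/null")
        if not (t.loc[up, "log2fc"] > 0).all() or not (t.loc[down, "log2fc"] < 0).all():
            raise ValueError("planted status inconsistent with log2fc sign")
        if not (t.loc[null, "log2fc"] == 0).all():
            raise ValueError("null genes must have log2fc == 0")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def planted_up(self) -> list[str]:
        return list(self.table.index[self.table["status"] == STATUS_UP])

    @property
    def planted_down(self) -> list[str]:
        return list(self.table.index[self.table["status"] == STATUS_DOWN])

    def catalog_members(self, catalog: str) -> set[str]:
        col = f"in_{catalog}"
        if col not in self.table.columns:
            raise KeyError(f"no planted membership for catalog {catalog!r}")
        return set(self.table.index[self.table[col]])

    def regulator_relation(self, regulator: str) -> pd.Series:
        col = f"{regulator}_relation"
        if col not in self.table.columns:
            raise KeyError(f"no planted relation for regulator {regulator!r}")
        return self.table[col]


def truth_contrast(
    truth: TruthTable,
    dataset_id: str = "truth",
    thresholds: Thresholds = Thresholds(),
) -> ContrastResult:
    """Noiseless contrast read directly off the truth table.

    Planted DEGs get their planted log2fc with p = 1e-9; null genes get
    (0, 1).  Used for exact-recovery checks of the set-algebra stages.
    """
    t = truth.table
    is_deg = t["status"] != TRUTH_NULL
    table = pd.DataFrame(
        {
            "log2fc": t["log2fc"].astype(float),
            "p_value": np.where(is_deg, 1e-9, 1.0),
            "q_value": np.where(is_deg, 1e-9, 1.0),
            "status": np.where(is_deg, t["status"], STATUS_NS),
        },
        index=t.index.copy(),
    )
    return ContrastResult(dataset_id, table, thresholds)


def make_symbol_universe(n: int, prefix: str = "G") -> list[str]:
    """Deterministic synthetic symbol universe ``G00000, G00001, ...``."""
    return [f"{prefix}{i:05d}" for i in range(n)]


def make_catalog_suite(
    sizes: Mapping[str, int] | None = None,
    universe: Sequence[str] | None = None,
    seed: int = 0,
) -> CatalogSuite:
    """Synthetic catalog suite with planted membership.

    The four secretome catalogs are carved as disjoint blocks of a
    permutation of the universe; panels are sampled from the whole universe
    and may overlap secretomes.  The housekeeping catalog always holds the
    nine reference genes.  ``sizes`` defaults to the full-scale sizes in
    :data:`DEFAULT_CATALOG_SIZES`.
    """
    sizes = dict(DEFAULT_CATALOG_SIZES if sizes is None else sizes)
    secretome_cats = [c.value for c in CatalogCategory if c.value.startswith("secretome")]
    panel_cats = [c.value for c in CatalogCategory if c.value.startswith("panel")]
    need = sum(sizes.get(c, 0) for c in secretome_cats)
    if universe is None:
        universe = make_symbol_universe(max(need + 1000, 1))
    universe = list(universe)
    if need > len(universe):
        raise ValueError(
            f"universe of {len(universe)} genes cannot hold {need} disjoint secretome genes"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(STREAM_KEYS["catalogs"],))
    )
    perm = rng.permutation(universe)
    catalogs: list[GeneCatalog] = []
    at = 0
    for cat in secretome_cats:
        size = sizes.get(cat, 0)
        if size:
            catalogs.append(
                GeneCatalog.from_symbols(CATALOG_NAMES[cat], perm[at : at + size], cat)
            )
            at += size
    for cat in panel_cats:
        size = sizes.get(cat, 0)
        if size:
            members = rng.choice(universe, size=size, replace=False)
            catalogs.append(GeneCatalog.from_symbols(CATALOG_NAMES[cat], members, cat))
    hk = sizes.get(CatalogCategory.HOUSEKEEPING.value, 0)
    if hk:
        catalogs.append(
            GeneCatalog.from_symbols(
                CATALOG_NAMES[CatalogCategory.HOUSEKEEPING.value],
                HOUSEKEEPING_GENES[:hk],
                CatalogCategory.HOUSEKEEPING,
            )
        )
    return CatalogSuite.from_catalogs(catalogs)


def _plant_degs(
    config: SimulationConfig,
    measured: list[str],
    suite: CatalogSuite | None,
    forced_up: Sequence[str],
    forced_down: Sequence[str],
) -> tuple[list[str], list[str]]:
    """Choose exactly round(frac*n) up and down genes.

    Housekeeping genes are never planted.  Order of claims: forced genes,
    then per-catalog quotas (round(rate x measured catalog size), counting
    already-claimed members), then a random fill.  The DEG fractions are
    always honored exactly; the per-catalog rate is exact whenever the
    fractions leave room for it, and undersatisfied otherwise.
    """
    rng = stream(config, "plant")
    n_up = round(config.frac_up * config.n_genes)
    n_down = round(config.frac_down * config.n_genes)
    hk = set(HOUSEKEEPING_GENES)
    pool = [g for g in measured if g not in hk]
    pool_set = set(pool)

    up: list[str] = []
    down: list[str] = []
    for g in forced_up:
        if g not in pool_set:
            raise ValueError(f"forced up gene {g!r} not in measured pool")
    for g in forced_down:
        if g not in pool_set:
            raise ValueError(f"forced down gene {g!r} not in measured pool")
    up.extend(dict.fromkeys(forced_up))
    down.extend(dict.fromkeys(forced_down))
    if len(up) > n_up or len(down) > n_down:
        raise ValueError("forced genes exceed planted DEG quotas")
    claimed = set(up) | set(down)
    if len(claimed) != len(up) + len(down):
        raise ValueError("forced up and down gene lists overlap")

    if suite is not None and config.planted_catalog_deg_rate > 0:
        flip = 0
        for catalog in suite.catalogs.values():
            if catalog.category == CatalogCategory.HOUSEKEEPING:
                continue
            members = sorted(catalog.genes & pool_set)
            want = round(config.planted_catalog_deg_rate * len(members))
            have = len(claimed & set(members))
            extra = want - have
            if extra <= 0:
                continue
            candidates = [g for g in members if g not in claimed]
            picks = rng.choice(candidates, size=min(extra, len(candidates)), replace=False)
            for g in picks:
                # alternate directions, respecting remaining quotas; when both
                # quotas are exhausted the catalog rate is undersatisfied
                # rather than the DEG fractions being violated
                if (flip % 2 == 0 and len(up) < n_up) or len(down) >= n_down:
                    if len(up) >= n_up:
                        break
                    up.append(g)
                else:
                    down.append(g)
                claimed.add(g)
                flip += 1

    # fill prefers genes outside every catalog so per-catalog DEG counts
    # stay exactly at their planted rate whenever possible
    catalog_genes: set[str] = set()
    if suite is not None:
        for catalog in suite.catalogs.values():
            if catalog.category != CatalogCategory.HOUSEKEEPING:
                catalog_genes |= catalog.genes
    remaining_free = [g for g in pool if g not in claimed and g not in catalog_genes]
    remaining_cat = [g for g in pool if g not in claimed and g in catalog_genes]
    need = (n_up - len(up)) + (n_down - len(down))
    if need > len(remaining_free) + len(remaining_cat):
        raise ValueError("not enough genes to satisfy planted DEG fractions")
    fill = []
    if need:
        take_free = min(need, len(remaining_free))
        fill.extend(rng.choice(remaining_free, size=take_free, replace=False))
        if need - take_free:
            fill.extend(rng.choice(remaining_cat, size=need - take_free, replace=False))
    up.extend(fill[: n_up - len(up)])
    down.extend(fill[len(fill) - (n_down - len(down)) :] if n_down - len(down) else [])
    assert len(up) == n_up and len(down) == n_down
    return up, down


def simulate_dataset(
    config: SimulationConfig,
    universe: Sequence[str] | None = None,
    suite: CatalogSuite | None = None,
    forced_up: Sequence[str] = (),
    forced_down: Sequence[str] = (),
) -> tuple[ExpressionDataset, TruthTable]:
    """Simulate one case/control expression dataset with planted truth.

    ``universe`` optionally fixes the measured gene list (length must be
    ``config.n_genes``); by default the nine housekeeping symbols plus
    synthetic ``G#####`` symbols are used.  ``suite`` enables planted
    catalog membership at ``planted_catalog_deg_rate``; ``forced_up`` /
    ``forced_down`` pin specific genes as DEGs (used to plant DEG sets
    shared between datasets).
    """
    if universe is None:
        measured = list(HOUSEKEEPING_GENES) + make_symbol_universe(
            config.n_genes - len(HOUSEKEEPING_GENES)
        )
    else:
        measured = list(universe)
        if len(measured) != config.n_genes:
            raise ValueError("universe length must equal config.n_genes")
    if len(set(measured)) != len(measured):
        raise ValueError("duplicate genes in universe")

    up, down = _plant_degs(config, measured, suite, forced_up, forced_down)
    rng_plant = stream(config, "plant", offset=1)
    lo, hi = 0.6 * config.effect_size_log2, 1.4 * config.effect_size_log2
    fc = pd.Series(0.0, index=pd.Index(measured, name="gene"))
    fc.loc[up] = rng_plant.uniform(lo, hi, size=len(up))
    fc.loc[down] = -rng_plant.uniform(lo, hi, size=len(down))
    status = pd.Series(TRUTH_NULL, index=fc.index)
    status.loc[up] = STATUS_UP
    status.loc[down] = STATUS_DOWN

    n, n1, n2 = config.n_genes, config.n_case, config.n_control
    rng_expr = stream(config, "expression")
    shift = fc.to_numpy()[:, None]
    if config.platform is Platform.ARRAY:
        baseline = rng_expr.uniform(6.0, 12.0, size=n)[:, None]
        case = baseline + shift + rng_expr.normal(0.0, config.noise_sd, size=(n, n1))
        control = baseline + rng_expr.normal(0.0, config.noise_sd, size=(n, n2))
        values = np.hstack([case, control])
    else:
        abundance = 2.0 ** rng_expr.uniform(3.0, 9.0, size=n)
        p_gene = abundance / abundance.sum()
        libsize = rng_expr.lognormal(mean=np.log(1e6), sigma=0.2, size=n1 + n2)
        mu = p_gene[:, None] * libsize[None, :]
        mu[:, :n1] *= 2.0**shift
        r = 1.0 / config.dispersion
        values = rng_expr.negative_binomial(r, r / (r + mu)).astype(np.int64)

    columns = [f"case_{i + 1}" for i in range(n1)] + [f"ctrl_{i + 1}" for i in range(n2)]
    frame = pd.DataFrame(values, index=fc.index.copy(), columns=columns)
    dataset = ExpressionDataset(
        dataset_id=config.dataset_id,
        platform=config.platform,
        values=frame,
        sample_group=["case"] * n1 + ["control"] * n2,
        metadata=DatasetMeta(
            tissue=config.tissue,
            tissue_class=config.tissue_class,
            condition_group=config.condition_group,
        ),
    )
    truth_frame = pd.DataFrame({"status": status, "log2fc": fc})
    if suite is not None:
        for name, catalog in suite.catalogs.items():
            truth_frame[f"in_{name}"] = truth_frame.index.isin(catalog.genes)
    return dataset, TruthTable(truth_frame)


def simulate_regulator_contrast(
    config: SimulationConfig,
    truth: TruthTable,
    regulator: str,
) -> tuple[RegulatorContrast, TruthTable]:
    """Plant a perturbation-vs-control DEG table against ``truth``.

    Exactly ``round(frac_induced x planted-up)`` Treg-up genes are DOWN in
    the perturbation (regulator-induced) and ``round(frac_suppressed x
    planted-down)`` Treg-down genes are UP (regulator-suppressed).  A small
    same-direction overlap (5% of each planted list) and a block of
    perturbation-only DEGs are added so downstream classification has to
    reject them; both land in non-collaboration by construction.  Returns
    the contrast and a truth table extended with a ``<REG>_relation``
    column.
    """
    regulator = str(Regulator(regulator).value)
    if regulator not in config.regulator_overlap:
        raise ValueError(f"regulator {regulator!r} not in config.regulator_overlap")
    frac_induced, frac_suppressed = config.regulator_overlap[regulator]
    reg_index = sorted(config.regulator_overlap).index(regulator)
    rng = stream(config, "regulator", offset=reg_index)

    genes = truth.genes
    planted_up = truth.planted_up
    planted_down = truth.planted_down
    n_ind = round(frac_induced * len(planted_up))
    n_sup = round(frac_suppressed * len(planted_down))
    induced = list(rng.choice(planted_up, size=n_ind, replace=False)) if n_ind else []
    suppressed = (
        list(rng.choice(planted_down, size=n_sup, replace=False)) if n_sup else []
    )

    pert_up = set(suppressed)
    pert_down = set(induced)
    # same-direction decoys among the remaining Treg DEGs
    rest_up = [g for g in planted_up if g not in pert_down]
    rest_down = [g for g in planted_down if g not in pert_up]
    n_decoy_up = min(round(0.05 * len(planted_up)), len(rest_up))
    n_decoy_down = min(round(0.05 * len(planted_down)), len(rest_down))
    pert_up |= set(rng.choice(rest_up, size=n_decoy_up, replace=False)) if n_decoy_up else set()
    pert_down |= (
        set(rng.choice(rest_down, size=n_decoy_down, replace=False)) if n_decoy_down else set()
    )
    # perturbation-only DEGs among planted-null genes
    nulls = [g for g in genes if truth.table.at[g, "status"] == TRUTH_NULL]
    n_only = min(round(0.02 * len(genes)), len(nulls))
    if n_only:
        only = rng.choice(nulls, size=n_only, replace=False)
        half = n_only // 2
        pert_up |= set(only[:half])
        pert_down |= set(only[half:])

    log2fc = np.zeros(len(genes))
    p = np.ones(len(genes))
    status = np.full(len(genes), STATUS_NS, dtype=object)
    index = pd.Index(genes, name="gene")
    pos = {g: i for i, g in enumerate(genes)}
    for g in pert_up:
        log2fc[pos[g]], p[pos[g]], status[pos[g]] = 2.0, 1e-4, STATUS_UP
    for g in pert_down:
        log2fc[pos[g]], p[pos[g]], status[pos[g]] = -2.0, 1e-4, STATUS_DOWN
    table = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "q_value": p, "status": status}, index=index
    )
    contrast = ContrastResult(f"{regulator}_perturbation", table)

    relation = pd.Series("none", index=truth.table.index, name=f"{regulator}_relation")
    relation.loc[induced] = "induced"
    relation.loc[suppressed] = "suppressed"
    new_table = truth.table.copy()
    new_table[f"{regulator}_relation"] = relation
    kind = REGULATOR_KINDS.get(regulator, PerturbationKind.KNOCKOUT)
    return RegulatorContrast(regulator, kind, contrast), TruthTable(new_table)


def simulate_dual_ko(
    config: SimulationConfig,
    class_sizes: tuple[int, int, int],
    universe: Sequence[str] | None = None,
) -> tuple[ContrastResult, ContrastResult, pd.Series]:
    """Plant two KO contrasts realizing exact ROS class sizes.

    ``class_sizes = (n_promoted, n_suppressed, n_uncertain)``: promoted
    genes are up in the NOX2 KO and down in the NRF2 KO; suppressed the
    reverse; uncertain genes are DEG in both with the same sign (split
    evenly up/up and down/down).  Every other gene is non-DEG in at least
    one contrast; a block of single-contrast DEGs is included so the
    classifier's exclusion rule is exercised.  Returns the two contrasts
    and the planted class as a gene-indexed Series
    (promoted/suppressed/uncertain/none).
    """
    n_promoted, n_suppressed, n_uncertain = class_sizes
    if min(class_sizes) < 0:
        raise ValueError("class sizes must be non-negative")
    if universe is None:
        universe = list(HOUSEKEEPING_GENES) + make_symbol_universe(
            max(config.n_genes, sum(class_sizes) + 300) - len(HOUSEKEEPING_GENES)
        )
    genes = list(universe)
    total = n_promoted + n_suppressed + n_uncertain
    if total > len(genes):
        raise ValueError(f"class sizes sum to {total} > {len(genes)} genes")

    rng = stream(config, "dualko")
    perm = list(rng.permutation(genes))
    promoted = perm[:n_promoted]
    suppressed = perm[n_promoted : n_promoted + n_suppressed]
    uncertain = perm[n_promoted + n_suppressed : total]
    rest = perm[total:]
    n_single = min(100, len(rest) // 2)
    nox2_only = rest[:n_single]
    nrf2_only = rest[n_single : 2 * n_single]

    half = n_uncertain // 2
    unc_upup, unc_downdown = uncertain[:half], uncertain[half:]

    def build(dataset_id: str, ups: Iterable[str], downs: Iterable[str]) -> ContrastResult:
        index = pd.Index(genes, name="gene")
        table = pd.DataFrame(
            {
                "log2fc": 0.0,
                "p_value": 1.0,
                "q_value": 1.0,
                "status": STATUS_NS,
            },
            index=index,
        )
        ups, downs = list(ups), list(downs)
        table.loc[ups, ["log2fc", "p_value", "q_value"]] = [2.0, 1e-4, 1e-4]
        table.loc[ups, "status"] = STATUS_UP
        table.loc[downs, ["log2fc", "p_value", "q_value"]] = [-2.0, 1e-4, 1e-4]
        table.loc[downs, "status"] = STATUS_DOWN
        return ContrastResult(dataset_id, table)

    nox2 = build(
        "NOX2_ko", ups=promoted + unc_upup + nox2_only[: n_single // 2],
        downs=suppressed + unc_downdown + nox2_only[n_single // 2 :],
    )
    nrf2 = build(
        "NRF2_ko", ups=suppressed + unc_upup + nrf2_only[: n_single // 2],
        downs=promoted + unc_downdown + nrf2_only[n_single // 2 :],
    )
    classes = pd.Series("none", index=pd.Index(genes, name="gene"), name="ros_class")
    classes.loc[promoted] = "promoted"
    classes.loc[suppressed] = "suppressed"
    classes.loc[uncertain] = "uncertain"
    return nox2, nrf2, classes


def make_signatures(
    truth: TruthTable,
    n_members: int = 30,
    prefix: str = "",
) -> list[PathwaySignature]:
    """Signed signatures derived from a truth table.

    Builds one signature expected to be called activated (members planted
    up, expected direction +1), one inhibited (members planted down,
    expected +1, so observed opposes expected), one mixed (z near 0) and
    one null (non-DEG members) — enough to exercise every call status.
    """
    up = truth.planted_up
    down = truth.planted_down
    nulls = [g for g in truth.genes if truth.table.at[g, "status"] == TRUTH_NULL]
    if len(up) < n_members or len(down) < n_members or len(nulls) < n_members:
        raise ValueError("truth table too small for signature construction")
    half = n_members // 2
    return [
        PathwaySignature(f"{prefix}activated_program", {g: 1 for g in up[:n_members]}),
        PathwaySignature(f"{prefix}inhibited_program", {g: 1 for g in down[:n_members]}),
        PathwaySignature(
            f"{prefix}mixed_program",
            {**{g: 1 for g in up[n_members : n_members + half]},
             **{g: 1 for g in down[n_members : n_members + half]}},
        ),
        PathwaySignature(f"{prefix}null_program", {g: 1 for g in nulls[:n_members]}),
    ]


# ---------------------------------------------------------------------------
# config / truth I/O


def save_config(config: SimulationConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    for key in ("platform", "tissue_class", "condition_group"):
        data[key] = getattr(config, key).value
    data["regulator_overlap"] = {k: list(v) for k, v in config.regulator_overlap.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_config(path: str | Path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text())
    if "regulator_overlap" in data:
        data["regulator_overlap"] = {
            k: tuple(v) for k, v in data["regulator_overlap"].items()
        }
    if data.get("catalog_sizes") is not None:
        data["catalog_sizes"] = dict(data["catalog_sizes"])
    return SimulationConfig(**data)


def write_truth(truth: TruthTable, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t", float_format="%.10g")


def read_truth(path: str | Path) -> TruthTable:
    table = pd.read_csv(path, sep="\t", index_col="gene")
    for col in table.columns:
        if col.startswith("in_"):
            table[col] = table[col].astype(bool)
    return TruthTable(table)
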
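"""End-to-end orchestration: demo fixtures, the staged pipeline run, and the
markdown report.

``make_fixtures`` writes a complete synthetic workspace — expression
datasets for every condition group, the catalog suite, signed signatures,
regulator and dual-KO contrasts, and count-engineered contrasts that
reproduce selected published count/percentage table rows — plus a run
config.  ``run_pipeline`` then executes the eight stages (load, DEG
calling, secretome decomposition, pathway enrichment, regulator
collaboration, ROS regulatome, panel screens, group statistics), writing
every stage's table under the output directory and a manifest with the
config hash, seed and per-stage row counts.  Re-running with an identical
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import collaboration as collab
from . import enrichment as enr
from . import ros as rosmod
from . import screens as scr
from .decompose import decompose_suite
from .catalogs import (
    CatalogCategory,
    CatalogSuite,
    GeneCatalog,
    HOUSEKEEPING_GENES,
    load_gmt,
    load_signatures_gmt,
    write_gmt,
    write_signatures_gmt,
)
from .de import (
    ConditionGroup,
    ContrastResult,
    Thresholds,
    compute_contrast,
    deg_summary,
    housekeeping_qc,
    read_contrast,
    read_expression,
    write_contrast,
    write_expression,
)
from .simulate import (
    CATALOG_NAMES,
    DEFAULT_CATALOG_SIZES,
    SimulationConfig,
    make_catalog_suite,
    make_signatures,
    make_symbol_universe,
    simulate_dataset,
    simulate_dual_ko,
    simulate_regulator_contrast,
    stream,
    truth_contrast,
    write_truth,
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and cutoffs for one pipeline run (serializable to YAML)."""

    datasets: list[str]
    catalogs_gmt: str
    signatures_gmt: str
    regulator_contrasts: dict[str, str]
    nox2_contrast: str
    nrf2_contrast: str
    out_dir: str
    seed: int = 0
    catalog_categories: dict[str, str] = field(default_factory=dict)
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    inclusive_fc: bool = False
    p_cut: float = 0.05
    z_cut: float = 2.0
    housekeeping_band: tuple[float, float] = (-1.3, 1.3)
    focal_group: str = ConditionGroup.TUMOR_TISSUE.value

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(self.fc_threshold, self.p_threshold, self.inclusive_fc)

    @property
    def cutoffs(self) -> enr.EnrichmentCutoffs:
        return enr.EnrichmentCutoffs(self.p_cut, self.z_cut)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["housekeeping_band"] = list(self.housekeeping_band)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["housekeeping_band"] = tuple(data.get("housekeeping_band", (-1.3, 1.3)))
        return cls(**data)

    def validate_paths(self) -> None:
        paths = [self.catalogs_gmt, self.signatures_gmt, self.nox2_contrast,
                 self.nrf2_contrast, *self.datasets, *self.regulator_contrasts.values()]
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")


def _sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the manifest (also written to disk)."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds
    stages: list[dict] = []

    def stage_done(name: str, rows: int) -> None:
        stages.append({"name": name, "rows": int(rows)})

    # -- load ---------------------------------------------------------------
    try:
        categories = {k: CatalogCategory(v) for k, v in config.catalog_categories.items()}
        catalogs = load_gmt(config.catalogs_gmt, categories)
        suite = CatalogSuite.from_catalogs(catalogs, load_signatures_gmt(config.signatures_gmt))
        datasets = [read_expression(p) for p in config.datasets]
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    stage_done("load", len(datasets) + len(suite.catalogs) + len(suite.signatures))
    groups = {d.dataset_id: d.metadata.condition_group.value for d in datasets}

    # -- deg ----------------------------------------------------------------
    try:
        contrasts = [compute_contrast(d, thresholds) for d in datasets]
        for c in contrasts:
            write_contrast(c, out / f"contrast_{c.dataset_id}.tsv")
        summaries = [deg_summary(c) for c in contrasts]
        pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
            out / "deg_summary.tsv", sep="\t", index=False, float_format="%.10g"
        )
        hk_list = suite.by_category(CatalogCategory.HOUSEKEEPING)
        qc_report = {}
        if hk_list:
            for c in contrasts:
                qc = housekeeping_qc(c, hk_list[0], config.housekeeping_band)
                qc_report[c.dataset_id] = {
                    "passed": qc.passed,
                    "log2fc": {g: round(v, 6) for g, v in qc.log2fc.items()},
                    "failing": qc.failing,
                    "missing": qc.missing,
                }
        _json_dump(qc_report, out / "housekeeping_qc.json")
    except Exception as exc:
        raise PipelineError("deg", str(exc)) from exc
    stage_done("deg", len(contrasts))

    # -- decompose ----------------------------------------------------------
    try:
        secretome_suite = CatalogSuite.from_catalogs(suite.secretomes)
        table = decompose_suite(contrasts, secretome_suite)
        table.to_csv(out / "decomposition.tsv", sep="\t", index=False, float_format="%.10g")
    except Exception as exc:
        raise PipelineError("decompose", str(exc)) from exc
    stage_done("decompose", len(table))

    # -- enrich -------------------------------------------------------------
    try:
        all_records = []
        for c in contrasts:
            all_records.extend(
                enr.enrich_contrast(c, suite.signatures.values(), cutoffs=config.cutoffs)
            )
        enr.records_to_frame(all_records).to_csv(
            out / "enrichment.tsv", sep="\t", index=False, float_format="%.10g"
        )
        by_group: dict[str, list] = {}
        for r in all_records:
            by_group.setdefault(groups[r.dataset_id], []).append(r)
        summaries_by_group = {
            g: enr.venn_summary(g, rs) for g, rs in sorted(by_group.items())
        }
        _json_dump(
            {g: s.to_dict() for g, s in summaries_by_group.items()},
            out / "pathway_groups.json",
        )
        if len(summaries_by_group) >= 2:
            _json_dump(
                enr.cross_group_overlap(summaries_by_group),
                out / "pathway_cross_group.json",
            )
    except Exception as exc:
        raise PipelineError("enrich", str(exc)) from exc
    stage_done("enrich", len(all_records))

    # -- collaborate --------------------------------------------------------
    try:
        partitions: dict[str, dict[str, collab.CollaborationPartition]] = {}
        rows = []
        for reg_name, path in sorted(config.regulator_contrasts.items()):
            reg = collab.RegulatorContrast(
                reg_name,
                "blockade" if reg_name in ("CTLA4", "PD1") else "knockout",
                read_contrast(path, thresholds=thresholds),
            )
            partitions[reg_name] = {}
            for c in contrasts:
                part = collab.partition_collaboration(c, reg)
                partitions[reg_name][c.dataset_id] = part
                rows.append(part.to_dict())
        pd.DataFrame(rows).to_csv(
            out / "collaboration.tsv", sep="\t", index=False, float_format="%.10g"
        )
    except Exception as exc:
        raise PipelineError("collaborate", str(exc)) from exc
    stage_done("collaborate", len(rows))

    # -- ros ----------------------------------------------------------------
    try:
        nox2 = read_contrast(config.nox2_contrast, thresholds=thresholds)
        nrf2 = read_contrast(config.nrf2_contrast, thresholds=thresholds)
        partition = rosmod.classify_ros(nox2, nrf2)
        part_rows = [
            {"gene": g, "ros_class": cls}
            for cls in ("promoted", "suppressed", "uncertain")
            for g in sorted(getattr(partition, cls))
        ]
        pd.DataFrame(part_rows, columns=["gene", "ros_class"]).to_csv(
            out / "ros_partition.tsv", sep="\t", index=False
        )
        ros_records = {c.dataset_id: rosmod.screen_contrast(c, partition) for c in contrasts}
        pd.DataFrame([r.to_dict() for r in ros_records.values()]).to_csv(
            out / "ros_screens.tsv", sep="\t", index=False
        )
    except Exception as exc:
        raise PipelineError("ros", str(exc)) from exc
    stage_done("ros", partition.total_classified)

    # -- screens ------------------------------------------------------------
    try:
        panels = [
            c for c in suite.catalogs.values() if c.category.value.startswith("panel")
        ]
        screen_rows = []
        panel_records: dict[str, dict[str, scr.PanelScreenRecord]] = {}
        for panel in panels:
            panel_records[panel.name] = {}
            for c in contrasts:
                rec = scr.screen_panel(c, panel)
                panel_records[panel.name][c.dataset_id] = rec
                screen_rows.append(
                    {
                        "dataset_id": rec.dataset_id,
                        "panel": rec.panel,
                        "n_up": rec.n_up,
                        "n_down": rec.n_down,
                        "n_total": rec.n_total,
                    }
                )
        pd.DataFrame(screen_rows).to_csv(out / "panel_screens.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("screens", str(exc)) from exc
    stage_done("screens", len(screen_rows))

    # -- group_stats --------------------------------------------------------
    try:
        stats_report: dict[str, dict] = {}
        pct_by_group: dict[str, list[float]] = {}
        for s in summaries:
            if s.pct_up is not None:
                pct_by_group.setdefault(groups[s.dataset_id], []).append(s.pct_up)
        stats_report["pct_up_of_degs"] = scr.compare_groups(
            pct_by_group, metric="pct_up_of_degs", focal_group=config.focal_group
        ).to_dict()
        for reg_name, parts in partitions.items():
            stats_report[f"noncollab_{reg_name}"] = collab.compare_noncollab_across_groups(
                parts, groups, focal_group=config.focal_group
            ).to_dict()
        stats_report["ros_down_suppressed"] = rosmod.compare_ros_screens(
            ros_records, groups, focal_group=config.focal_group
        ).to_dict()
        for panel_name, recs in panel_records.items():
            values: dict[str, list[float]] = {}
            for ds, rec in recs.items():
                values.setdefault(groups[ds], []).append(float(rec.n_down))
            stats_report[f"down_{panel_name}"] = scr.compare_groups(
                values, metric=f"down_{panel_name}", focal_group=config.focal_group
            ).to_dict()
        _json_dump(stats_report, out / "group_stats.json")
    except Exception as exc:
        raise PipelineError("group_stats", str(exc)) from exc
    stage_done("group_stats", len(stats_report))

    config_text = yaml.safe_dump(
        {**dataclasses.asdict(config), "housekeeping_band": list(config.housekeeping_band)},
        sort_keys=True,
    )
    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": config.seed,
        "stages": stages,
    }
    _json_dump(manifest, out / "manifest.json")
    write_report(out)
    return manifest


def write_report(out: Path) -> None:
    """One-page markdown summary assembled from the stage outputs."""
    manifest = json.loads((out / "manifest.json").read_text())
    deg = pd.read_csv(out / "deg_summary.tsv", sep="\t")
    lines = [
        "# Treg secretome workbench run summary",
        "",
        f"- seed: {manifest['seed']}",
        f"- config sha256: `{manifest['config_sha256']}`",
        "",
        "## Stages",
        "",
        "| stage | rows |",
        "| --- | --- |",
    ]
    lines += [f"| {s['name']} | {s['rows']} |" for s in manifest["stages"]]
    lines += ["", "## DEG summary", "", "```", deg.to_string(index=False), "```", ""]
    (out / "summary.md").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fixtures


#: Printed count/percentage table rows re-engineered as exact fixtures:
#: per dataset, the total DEG count, the number of planted up/down DEGs,
#: and the catalog-member counts among them.
PRINTED_TABLE_ROWS: dict[str, dict] = {
    "kidney_rnaseq": {
        "n_up": 718,
        "n_down": 866,
        "up": {"exosome_secretome": 356, "caspase1_secretome": 20, "caspase4_secretome": 42},
        "down": {"exosome_secretome": 174, "caspase1_secretome": 4, "caspase4_secretome": 5},
    },
    "regeneration_kidney": {
        "n_up": 1500,
        "n_down": 1108,
        "up": {"canonical_secretome": 265},
        "down": {"canonical_secretome": 86},
    },
    "muscle4d_spleen": {
        "n_up": 200,
        "n_down": 113,
        "up": {"exosome_secretome": 115},
        "down": {},
    },
    "tc1_spleen": {
        "n_up": 900,
        "n_down": 876,
        "up": {"canonical_secretome": 194},
        "down": {},
    },
    "b16_tumor": {
        "n_up": 1200,
        "n_down": 1262,
        "up": {"exosome_secretome": 572},
        "down": {},
    },
    "breast_tumor": {
        "n_up": 743,
        "n_down": 750,
        "up": {},
        "down": {"exosome_secretome": 250},
    },
}


def make_table_fixtures(
    suite: CatalogSuite, universe: Sequence[str]
) -> dict[str, ContrastResult]:
    """Contrasts engineered so :func:`tregsec.decompose.decompose`
    reproduces the printed table cells in :data:`PRINTED_TABLE_ROWS`.

    Catalog-member DEGs are taken from the head of each catalog's sorted
    member list; filler DEGs come from genes outside every secretome
    catalog, so each catalog's intersection counts are exact.
    """
    secretome_genes: set[str] = set()
    for cat in suite.secretomes:
        secretome_genes |= cat.genes
    free = sorted(set(universe) - secretome_genes - set(HOUSEKEEPING_GENES))
    contrasts = {}
    for dataset_id, spec_row in PRINTED_TABLE_ROWS.items():
        up: list[str] = []
        down: list[str] = []
        for cat_name, count in spec_row["up"].items():
            members = sorted(suite.catalogs[cat_name].genes)
            up.extend(members[:count])
        for cat_name, count in spec_row["down"].items():
            members = sorted(suite.catalogs[cat_name].genes)
            offset = spec_row["up"].get(cat_name, 0)  # keep up/down disjoint
            down.extend(members[offset : offset + count])
        fill_up = spec_row["n_up"] - len(up)
        fill_down = spec_row["n_down"] - len(down)
        if fill_up + fill_down > len(free):
            raise ValueError("universe too small for table fixtures")
        up.extend(free[:fill_up])
        down.extend(free[fill_up : fill_up + fill_down])
        index = pd.Index(list(universe), name="gene")
        table = pd.DataFrame(
            {"log2fc": 0.0, "p_value": 1.0, "q_value": 1.0, "status": "ns"}, index=index
        )
        table.loc[up, ["log2fc", "p_value", "q_value"]] = [2.0, 1e-4, 1e-4]
        table.loc[up, "status"] = "up"
        table.loc[down, ["log2fc", "p_value", "q_value"]] = [-2.0, 1e-4, 1e-4]
        table.loc[down, "status"] = "down"
        contrasts[dataset_id] = ContrastResult(dataset_id, table)
    return contrasts


#: The eight demo datasets: two per condition group, mixed platforms, with
#: tumor-tissue datasets skewed toward downregulation.
DEMO_DATASETS: list[dict] = [
    dict(dataset_id="normal_spleen", platform="array", tissue="spleen",
         tissue_class="lymphoid", condition_group="normal",
         frac_up=0.065, frac_down=0.035),
    dict(dataset_id="normal_kidney", platform="rnaseq", tissue="kidney",
         tissue_class="non_lymphoid", condition_group="normal",
         frac_up=0.065, frac_down=0.035),
    dict(dataset_id="benign_muscle", platform="array", tissue="skeletal muscle",
         tissue_class="non_lymphoid", condition_group="benign",
         frac_up=0.06, frac_down=0.04),
    dict(dataset_id="benign_kidney", platform="rnaseq", tissue="kidney",
         tissue_class="non_lymphoid", condition_group="benign",
         frac_up=0.06, frac_down=0.04),
    dict(dataset_id="tumor_spleen_b16", platform="rnaseq", tissue="spleen",
         tissue_class="lymphoid", condition_group="tumor_spleen",
         frac_up=0.065, frac_down=0.035),
    dict(dataset_id="tumor_spleen_mc38", platform="rnaseq", tissue="spleen",
         tissue_class="lymphoid", condition_group="tumor_spleen",
         frac_up=0.065, frac_down=0.035),
    dict(dataset_id="tumor_tissue_b16", platform="rnaseq", tissue="melanoma",
         tissue_class="non_lymphoid", condition_group="tumor_tissue",
         frac_up=0.04, frac_down=0.08),
    dict(dataset_id="tumor_tissue_mc38", platform="rnaseq", tissue="colon tumor",
         tissue_class="non_lymphoid", condition_group="tumor_tissue",
         frac_up=0.04, frac_down=0.08),
]


def make_fixtures(
    out_dir: str | Path,
    seed: int = 0,
    n_genes: int = 10000,
    universe_size: int = 12500,
    catalog_sizes: Mapping[str, int] | None = None,
    ros_class_sizes: tuple[int, int, int] = (1384, 936, 10),
) -> RunConfig:
    """Write a complete demo workspace and return its run config.

    Contents: the synthetic catalog suite (full-scale sizes by default),
    two expression datasets per condition group with partially shared
    planted DEGs, signed pathway signatures (globally shared activated and
    inhibited programs, dataset-specific programs, a dual program planted
    in opposite directions within the tumor-tissue group, and a null
    program), regulator perturbation contrasts (FOXP3 / CTLA4 / PD1), the
    dual-KO ROS contrasts, the printed-table reproduction contrasts, per-
    dataset truth tables and a ready-to-run ``run.yaml``.
    """
    out = Path(out_dir)
    data = out / "data"
    data.mkdir(parents=True, exist_ok=True)
    base = SimulationConfig(seed=seed, n_genes=n_genes)

    full_universe = make_symbol_universe(universe_size)
    suite = make_catalog_suite(catalog_sizes, full_universe, seed=seed)
    write_gmt(suite.catalogs.values(), data / "catalogs.gmt")

    rng = stream(base, "plant", offset=99)
    perm = list(rng.permutation(full_universe))
    measured = list(HOUSEKEEPING_GENES) + perm[: n_genes - len(HOUSEKEEPING_GENES)]
    n_shared = max(20, round(0.03 * n_genes))
    n_dual = max(5, round(0.003 * n_genes))
    shared_up = perm[:n_shared]
    shared_down = perm[n_shared : 2 * n_shared]
    dual_genes = perm[2 * n_shared : 2 * n_shared + n_dual]

    datasets = []
    truths = {}
    for i, spec_row in enumerate(DEMO_DATASETS):
        forced_up = list(shared_up)
        forced_down = list(shared_down)
        if spec_row["dataset_id"] == "tumor_tissue_b16":
            forced_up += dual_genes
        if spec_row["dataset_id"] == "tumor_tissue_mc38":
            forced_down += dual_genes
        cfg = dataclasses.replace(base, seed=seed + 1 + i, **spec_row)
        ds, truth = simulate_dataset(
            cfg, universe=measured, suite=suite,
            forced_up=forced_up, forced_down=forced_down,
        )
        write_expression(ds, data / f"{ds.dataset_id}.tsv")
        write_truth(truth, data / f"{ds.dataset_id}.truth.tsv")
        datasets.append(ds)
        truths[ds.dataset_id] = truth

    # signatures: shared programs from the globally forced genes, specific
    # programs from one dataset's own planting, a dual program, and a null.
    ref_truth = truths["normal_spleen"]
    nulls = [
        g for g in ref_truth.genes
        if all(t.table.at[g, "status"] == "null" for t in truths.values())
    ]
    signatures = [
        enr.PathwaySignature("core_up_program", {g: 1 for g in shared_up[:40]}),
        enr.PathwaySignature("core_down_program", {g: 1 for g in shared_down[:40]}),
        enr.PathwaySignature("dual_program", {g: 1 for g in dual_genes}),
        enr.PathwaySignature("null_program", {g: 1 for g in nulls[:40]}),
    ]
    own_up = [g for g in ref_truth.planted_up if g not in shared_up][:40]
    if len(own_up) >= 2:
        signatures.append(
            enr.PathwaySignature("normal_spleen_program", {g: 1 for g in own_up})
        )
    write_signatures_gmt(signatures, data / "signatures.gmt")

    # regulator contrasts planted against the reference dataset's truth
    regulator_paths = {}
    truth = ref_truth
    for reg in ("FOXP3", "CTLA4", "PD1"):
        reg_contrast, truth = simulate_regulator_contrast(base, truth, reg)
        path = data / f"{reg}_perturbation.tsv"
        write_contrast(reg_contrast.contrast, path)
        regulator_paths[reg] = str(path)
    write_truth(truth, data / "normal_spleen.truth.tsv")  # with relations

    nox2, nrf2, ros_classes = simulate_dual_ko(base, ros_class_sizes, universe=full_universe)
    write_contrast(nox2, data / "NOX2_ko.tsv")
    write_contrast(nrf2, data / "NRF2_ko.tsv")
    ros_classes.to_csv(data / "ros_truth.tsv", sep="\t")

    table_universe = make_symbol_universe(max(universe_size, 16000))
    table_suite = make_catalog_suite(catalog_sizes, table_universe, seed=seed)
    for dataset_id, contrast in make_table_fixtures(table_suite, table_universe).items():
        write_contrast(contrast, data / f"table_{dataset_id}.tsv")

    config = RunConfig(
        datasets=[str(data / f"{d['dataset_id']}.tsv") for d in DEMO_DATASETS],
        catalogs_gmt=str(data / "catalogs.gmt"),
        signatures_gmt=str(data / "signatures.gmt"),
        regulator_contrasts=regulator_paths,
        nox2_contrast=str(data / "NOX2_ko.tsv"),
        nrf2_contrast=str(data / "NRF2_ko.tsv"),
        out_dir=str(out / "out"),
        seed=seed,
        catalog_categories={
            CATALOG_NAMES[cat]: cat for cat in DEFAULT_CATALOG_SIZES
        },
    )
    config.to_yaml(out / "run.yaml")
    return config
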
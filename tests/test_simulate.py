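import dataclasses

import numpy as np
import pandas as pd
import pytest

from tregsec.de import Platform
from tregsec.ros import classify_ros
from tregsec.simulate import (
    SimulationConfig,
    load_config,
    make_catalog_suite,
    save_config,
    simulate_dataset,
    simulate_dual_ko,
    simulate_regulator_contrast,
    truth_contrast,
)


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_up=0.6, frac_down=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(frac_up=-0.1)

    def test_replicate_minimum(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_case=1)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=5, platform="rnaseq", frac_up=0.02)
        save_config(cfg, tmp_path / "cfg.yaml")
        assert load_config(tmp_path / "cfg.yaml") == cfg


class TestSimulateDataset:
    def test_zero_fractions_no_planted_degs(self):
        _, truth = simulate_dataset(SimulationConfig(frac_up=0, frac_down=0, n_genes=300))
        assert not truth.planted_up and not truth.planted_down
        assert (truth.table["log2fc"] == 0).all()

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(seed=7, n_genes=400)
        ds1, t1 = simulate_dataset(cfg)
        ds2, t2 = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(ds1.values, ds2.values)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_seeds_differ(self):
        ds1, _ = simulate_dataset(SimulationConfig(seed=1, n_genes=400))
        ds2, _ = simulate_dataset(SimulationConfig(seed=2, n_genes=400))
        assert not ds1.values.equals(ds2.values)

    def test_planted_counts_exact(self):
        cfg = SimulationConfig(seed=3, n_genes=1000, frac_up=0.07, frac_down=0.03)
        _, truth = simulate_dataset(cfg)
        assert len(truth.planted_up) == 70
        assert len(truth.planted_down) == 30

    def test_truth_sign_consistency(self):
        _, truth = simulate_dataset(SimulationConfig(seed=8, n_genes=500))
        t = truth.table
        assert (t.loc[t["status"] == "up", "log2fc"] > 0).all()
        assert (t.loc[t["status"] == "down", "log2fc"] < 0).all()

    def test_rnaseq_counts_are_nonnegative_integers(self):
        ds, _ = simulate_dataset(SimulationConfig(seed=2, n_genes=300, platform="rnaseq"))
        assert ds.platform is Platform.RNASEQ
        vals = ds.values.to_numpy()
        assert vals.dtype.kind == "i" and (vals >= 0).all()

    def test_housekeeping_genes_never_planted(self):
        _, truth = simulate_dataset(SimulationConfig(seed=5, n_genes=300, frac_up=0.2))
        assert truth.table.loc["ACTB", "status"] == "null"
        assert truth.table.loc["TBP", "status"] == "null"

    def test_catalog_planting_rate_exact(self):
        suite = make_catalog_suite(
            sizes={"secretome_canonical": 1000, "secretome_exosome": 500},
            universe=[f"G{i:05d}" for i in range(2000 - 9)],
            seed=6,
        )
        cfg = SimulationConfig(
            seed=6, n_genes=2000, frac_up=0.1, frac_down=0.1,
            planted_catalog_deg_rate=0.1,
        )
        _, truth = simulate_dataset(cfg, suite=suite)
        members = truth.catalog_members("canonical_secretome")
        planted = set(truth.planted_up) | set(truth.planted_down)
        assert len(members & planted) == 100  # round(0.1 * 1000)

    def test_forced_genes_planted(self):
        cfg = SimulationConfig(seed=4, n_genes=500)
        _, truth = simulate_dataset(cfg, forced_up=["G00001"], forced_down=["G00002"])
        assert truth.table.loc["G00001", "status"] == "up"
        assert truth.table.loc["G00002", "status"] == "down"


class TestSimulateRegulatorContrast:
    def make_truth(self, **kw):
        cfg = SimulationConfig(seed=10, n_genes=2000, **kw)
        _, truth = simulate_dataset(cfg)
        return cfg, truth

    def test_full_overlap_boundary(self):
        cfg, truth = self.make_truth()
        cfg = dataclasses.replace(cfg, regulator_overlap={"FOXP3": (1.0, 1.0)})
        reg, truth2 = simulate_regulator_contrast(cfg, truth, "FOXP3")
        # every planted Treg-up gene is regulator-induced
        assert set(truth.planted_up) <= reg.contrast.down_genes
        relation = truth2.regulator_relation("FOXP3")
        assert (relation.loc[truth.planted_up] == "induced").all()

    def test_zero_overlap_boundary(self):
        from tregsec.collaboration import noncollab_fraction, partition_collaboration

        cfg, truth = self.make_truth()
        cfg = dataclasses.replace(cfg, regulator_overlap={"FOXP3": (0.0, 0.0)})
        reg, truth2 = simulate_regulator_contrast(cfg, truth, "FOXP3")
        part = partition_collaboration(truth_contrast(truth2), reg)
        assert noncollab_fraction(part, among="up") == 100.00

    def test_exact_count_planting(self):
        cfg = SimulationConfig(
            seed=11, n_genes=2000, frac_up=0.05, frac_down=0.05,
            regulator_overlap={"PD1": (0.8, 0.5)},
        )
        _, truth = simulate_dataset(cfg)
        assert len(truth.planted_up) == 100
        _, truth2 = simulate_regulator_contrast(cfg, truth, "PD1")
        relation = truth2.regulator_relation("PD1")
        assert (relation == "induced").sum() == 80  # round(0.8 * 100)
        assert (relation == "suppressed").sum() == 50

    def test_unknown_regulator_rejected(self):
        cfg, truth = self.make_truth()
        with pytest.raises(ValueError):
            simulate_regulator_contrast(cfg, truth, "NOX2")


class TestSimulateDualKO:
    def test_empty_partition(self):
        cfg = SimulationConfig(seed=1, n_genes=500)
        nox2, nrf2, classes = simulate_dual_ko(cfg, (0, 0, 0))
        part = classify_ros(nox2, nrf2)
        assert part.total_classified == 0

    def test_toy_instance_gene_by_gene(self):
        # brute-force check of all six planted genes against the classifier
        cfg = SimulationConfig(seed=2, n_genes=500)
        nox2, nrf2, classes = simulate_dual_ko(cfg, (3, 2, 1))
        part = classify_ros(nox2, nrf2)
        for gene in classes.index:
            planted = classes.at[gene]
            expected = None if planted == "none" else planted
            assert part.class_of(gene) == expected, gene
        assert (len(part.promoted), len(part.suppressed), len(part.uncertain)) == (3, 2, 1)

    def test_oversized_classes_rejected(self):
        cfg = SimulationConfig(seed=3, n_genes=100)
        with pytest.raises(ValueError):
            simulate_dual_ko(cfg, (90, 90, 90), universe=[f"G{i}" for i in range(100)])

    def test_determinism(self):
        cfg = SimulationConfig(seed=9, n_genes=500)
        a = simulate_dual_ko(cfg, (20, 10, 4))
        b = simulate_dual_ko(cfg, (20, 10, 4))
        pd.testing.assert_frame_equal(a[0].table, b[0].table)
        pd.testing.assert_series_equal(a[2], b[2])
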
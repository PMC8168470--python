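import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tregsec.catalogs import GeneCatalog, HOUSEKEEPING_GENES
from tregsec.de import (
    ContrastResult,
    DatasetMeta,
    ExpressionDataset,
    Thresholds,
    classify_deg,
    compute_contrast,
    cpm_log2,
    deg_summary,
    housekeeping_qc,
    load_deg_table,
)
from tregsec.simulate import SimulationConfig, simulate_dataset


def welch_textbook(x, y):
    """Independent closed-form Welch oracle (statistic, df, two-sided p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    return t, df, 2 * stats.t.sf(abs(t), df)


def array_dataset(values, groups, dataset_id="ds"):
    frame = pd.DataFrame(
        values, index=pd.Index([f"G{i}" for i in range(len(values))], name="gene")
    )
    return ExpressionDataset(
        dataset_id=dataset_id,
        platform="array",
        values=frame,
        sample_group=groups,
        metadata=DatasetMeta("spleen", "lymphoid", "normal"),
    )


class TestClassifyDeg:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (1.2, 0.01, "up"),
            (-1.5, 0.2, "ns"),
            (1.0, 0.01, "ns"),  # strict boundary on |log2fc|
            (-1.0, 0.01, "ns"),
            (1.2, 0.05, "ns"),  # strict boundary on p
            (-1.2, 0.049, "down"),
            (0.0, 0.0, "ns"),
        ],
    )
    def test_rule(self, fc, p, expected):
        assert classify_deg(fc, p) == expected

    def test_inclusive_fc_switch(self):
        inclusive = Thresholds(inclusive_fc=True)
        assert classify_deg(1.0, 0.01, inclusive) == "up"
        assert classify_deg(-1.0, 0.01, inclusive) == "down"
        assert classify_deg(1.0, 0.05, inclusive) == "ns"  # p stays strict

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            classify_deg(1.0, 1.5)


class TestComputeContrast:
    def test_identical_columns_all_ns(self):
        col = np.array([5.0, 8.0, 10.0])
        ds = array_dataset(
            np.column_stack([col, col, col, col]),
            ["case", "case", "control", "control"],
        )
        result = compute_contrast(ds)
        assert (result.table["log2fc"] == 0).all()
        assert (result.table["status"] == "ns").all()
        assert result.table["zero_variance"].all()
        assert (result.table["p_value"] == 1).all()

    def test_toy_welch_example(self):
        # single gene: case {5,6,7} vs control {1,2,3} on the log2 scale
        ds = array_dataset(
            [[5.0, 6.0, 7.0, 1.0, 2.0, 3.0]],
            ["case", "case", "case", "control", "control", "control"],
        )
        result = compute_contrast(ds)
        row = result.table.iloc[0]
        assert row["log2fc"] == pytest.approx(4.0)
        assert row["t_statistic"] == pytest.approx(4.898979, abs=1e-5)
        assert row["p_value"] == pytest.approx(0.0080499, abs=1e-6)
        assert row["status"] == "up"

    def test_planted_strong_shift_called_up(self, rng):
        base = rng.uniform(6, 12, size=50)
        noise = lambda n: rng.normal(0, 0.1, size=(50, n))
        case = base[:, None] + noise(4)
        case[0] += 2.0  # planted +2 log2 shift on the first gene
        control = base[:, None] + noise(4)
        ds = array_dataset(np.hstack([case, control]), ["case"] * 4 + ["control"] * 4)
        result = compute_contrast(ds)
        assert result.table.iloc[0]["status"] == "up"

    def test_welch_matches_textbook_oracle(self, rng):
        # implementation route (scipy-based, vectorized) vs closed form
        for _ in range(100):
            n1, n2 = rng.integers(3, 8, size=2)
            x = rng.normal(0, rng.uniform(0.5, 2), size=n1)
            y = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), size=n2)
            ds = array_dataset(
                [np.concatenate([x, y])], ["case"] * n1 + ["control"] * n2
            )
            row = compute_contrast(ds).table.iloc[0]
            t_ref, _, p_ref = welch_textbook(x, y)
            assert row["t_statistic"] == pytest.approx(t_ref, abs=1e-10)
            assert row["p_value"] == pytest.approx(p_ref, abs=1e-10)

    def test_status_partition_invariant(self):
        cfg = SimulationConfig(seed=4, n_genes=500)
        ds, _ = simulate_dataset(cfg)
        result = compute_contrast(ds)
        counts = result.table["status"].value_counts()
        assert counts.sum() == cfg.n_genes

    def test_threshold_monotonicity(self):
        # loosening thresholds never shrinks the DEG set
        cfg = SimulationConfig(seed=9, n_genes=800, noise_sd=0.8)
        ds, _ = simulate_dataset(cfg)
        tight = compute_contrast(ds, Thresholds(1.0, 0.05))
        loose_fc = compute_contrast(ds, Thresholds(0.5, 0.05))
        loose_p = compute_contrast(ds, Thresholds(1.0, 0.2))
        assert tight.deg_genes <= loose_fc.deg_genes
        assert tight.deg_genes <= loose_p.deg_genes

    def test_rnaseq_cpm_route(self):
        cfg = SimulationConfig(seed=12, n_genes=2000, platform="rnaseq")
        ds, truth = simulate_dataset(cfg)
        result = compute_contrast(ds)
        planted_up = set(truth.planted_up)
        recovered = len(planted_up & result.up_genes) / len(planted_up)
        assert recovered > 0.7  # counts are noisier than arrays

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            array_dataset([[1.0, 2.0, 3.0]], ["case", "control", "control"])


class TestCpm:
    def test_library_size_normalization(self):
        counts = pd.DataFrame({"s1": [90, 10], "s2": [900, 100]})
        logcpm = cpm_log2(counts)
        # same composition at different depths -> identical log-CPM
        assert np.allclose(logcpm["s1"], logcpm["s2"])


class TestHousekeepingQC:
    def hk(self):
        return GeneCatalog.from_symbols("hk", HOUSEKEEPING_GENES, "housekeeping")

    def test_all_zero_passes(self, make_contrast):
        contrast = make_contrast(ns=list(HOUSEKEEPING_GENES) + ["G1"])
        qc = housekeeping_qc(contrast, self.hk())
        assert qc.passed and not qc.failing

    def test_extreme_gene_named(self, make_contrast):
        contrast = make_contrast(up=["ACTB"], ns=[g for g in HOUSEKEEPING_GENES if g != "ACTB"])
        qc = housekeeping_qc(contrast, self.hk())
        assert not qc.passed and qc.failing == ["ACTB"]

    def test_default_band_accepts_observed_extremes(self, make_contrast):
        # a housekeeping panel ranging from -1.27 to 1.28 must pass the default band
        genes = list(HOUSEKEEPING_GENES)
        table = pd.DataFrame(
            {
                "log2fc": [-1.27, 1.28] + [0.0] * 7,
                "p_value": [1.0] * 9,
                "status": ["ns"] * 9,
            },
            index=pd.Index(genes, name="gene"),
        )
        qc = housekeeping_qc(ContrastResult("x", table), self.hk())
        assert qc.passed

    def test_missing_genes_listed_not_failing(self, make_contrast):
        contrast = make_contrast(ns=["ACTB", "GAPDH", "OTHER"])
        qc = housekeeping_qc(contrast, self.hk())
        assert qc.passed
        assert "TBP" in qc.missing

    def test_no_housekeeping_present_errors(self, make_contrast):
        contrast = make_contrast(ns=["G1", "G2"])
        with pytest.raises(ValueError):
            housekeeping_qc(contrast, self.hk())


class TestDegSummary:
    def test_counts_and_pct(self, make_contrast):
        contrast = make_contrast(up=[f"U{i}" for i in range(60)],
                                 down=[f"D{i}" for i in range(40)])
        s = deg_summary(contrast)
        assert (s.n_deg, s.n_up, s.n_down, s.pct_up) == (100, 60, 40, 60.00)

    def test_degenerate_no_degs(self, make_contrast):
        s = deg_summary(make_contrast(ns=["G1", "G2"]))
        assert s.n_deg == 0 and s.pct_up is None


class TestDegTableAdapter:
    def test_import_and_reclassification(self, tmp_path):
        path = tmp_path / "degs.tsv"
        path.write_text(
            "gene\tlog2FC\tP\nIl6\t2.5\t0.001\nFoxp3\t-1.4\t0.01\nActb\t0.1\t0.9\n"
        )
        contrast = load_deg_table(path, "imported")
        assert contrast.up_genes == {"IL6"}
        assert contrast.down_genes == {"FOXP3"}
        assert contrast.table.loc["ACTB", "status"] == "ns"
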
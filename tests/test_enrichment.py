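import math
from fractions import Fraction
from math import comb

import pytest

from tregsec.catalogs import PathwaySignature
from tregsec.enrichment import (
    ACTIVATED,
    INHIBITED,
    NOT_CALLED,
    EnrichmentCutoffs,
    activation_z,
    classify_pathway,
    cross_group_overlap,
    enrich_contrast,
    fisher_enrichment,
    venn_summary,
)


def hypergeom_tail_bruteforce(k, N, K, n):
    """Exact upper-tail P(X >= k) by combinatorial enumeration."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


def sig(genes, direction=1, name="sig"):
    return PathwaySignature(name, {g: direction for g in genes})


class TestFisherEnrichment:
    def test_exact_small_case(self):
        # N=4, K=2, n=2, k=2 -> 1/6 by enumerating all C(4,2)=6 draws
        universe = {"A", "B", "C", "D"}
        k, K, n, N, p = fisher_enrichment({"A", "B"}, sig(["A", "B"]), universe)
        assert (k, K, n, N) == (2, 2, 2, 4)
        assert p == pytest.approx(1 / 6, abs=1e-12)

    def test_zero_overlap_p_is_one(self):
        universe = {f"G{i}" for i in range(20)}
        *_, p = fisher_enrichment({"G0", "G1"}, sig(["G10", "G11"]), universe)
        assert p == pytest.approx(1.0)

    def test_matches_bruteforce_over_small_grid(self, rng):
        # exhaustive-style check across the N <= 30 regime
        for _ in range(300):
            N = int(rng.integers(2, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = {f"G{i}" for i in range(N)}
            members = set(list(universe)[:K])
            deg = set(rng.choice(sorted(universe), size=n, replace=False))
            signature = sig(sorted(members)) if K >= 2 else sig(sorted(members) + ["PAD"])
            k, K_, n_, N_, p = fisher_enrichment(deg, signature, universe)
            assert p == pytest.approx(hypergeom_tail_bruteforce(k, N_, K_, n_), abs=1e-10)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(set(), sig(["A", "B"]), {"A", "B"})
        with pytest.raises(ValueError):
            fisher_enrichment({"A"}, sig(["A", "B"]), set())


class TestActivationZ:
    @pytest.mark.parametrize(
        "n_consistent,n_inconsistent,expected",
        [(9, 0, 3.0), (2, 2, 0.0), (8, 1, 7 / 3)],
    )
    def test_examples(self, make_contrast, n_consistent, n_inconsistent, expected):
        up = [f"U{i}" for i in range(n_consistent)]
        down = [f"D{i}" for i in range(n_inconsistent)]
        contrast = make_contrast(up=up, down=down, ns=["N"])
        signature = sig(up + down, direction=1)
        assert activation_z(contrast, signature) == pytest.approx(expected)

    def test_missing_when_no_directional_overlap(self, make_contrast):
        contrast = make_contrast(up=["A"], ns=["B"])
        signature = PathwaySignature("s", {"A": 0, "B": 0})
        assert activation_z(contrast, signature) is None

    def test_antisymmetric_under_direction_flip(self, make_contrast, rng):
        genes = [f"G{i}" for i in range(40)]
        contrast = make_contrast(up=genes[:15], down=genes[15:25], ns=genes[25:])
        directions = {g: int(d) for g, d in zip(genes, rng.choice([-1, 0, 1], size=40))}
        signature = PathwaySignature("s", directions)
        z = activation_z(contrast, signature)
        z_flipped = activation_z(contrast, signature.flipped())
        if z is None:
            assert z_flipped is None
        else:
            assert z_flipped == pytest.approx(-z)


class TestClassifyPathway:
    @pytest.mark.parametrize(
        "p,z,expected",
        [
            (0.01, 2.5, ACTIVATED),
            (0.01, -3.0, INHIBITED),
            (0.2, 3.0, NOT_CALLED),
            (0.05, 3.0, NOT_CALLED),  # p boundary strict
            (0.01, 2.0, ACTIVATED),  # z boundary inclusive
            (0.01, -2.0, INHIBITED),
            (0.01, 1.99, NOT_CALLED),
            (0.01, None, NOT_CALLED),
        ],
    )
    def test_rule(self, p, z, expected):
        assert classify_pathway(p, z) == expected


class TestEnrichContrast:
    def test_planted_signature_activated(self, make_contrast):
        # signature fully contained in up-DEGs with all directions +1
        universe = [f"G{i}" for i in range(200)]
        contrast = make_contrast(up=universe[:10], ns=universe[10:])
        records = enrich_contrast(contrast, [sig(universe[:10], name="planted")])
        (rec,) = records
        assert rec.status == ACTIVATED and rec.p_value < 0.05 and rec.z >= 2

    def test_universe_defaults_to_measured_genes(self, make_contrast):
        contrast = make_contrast(up=["A"], ns=["B", "C", "D"])
        (rec,) = enrich_contrast(contrast, [sig(["A", "B"])])
        assert rec.N == 4


class TestVennSummary:
    def rec(self, dataset, pathway, status):
        from tregsec.enrichment import EnrichmentRecord

        return EnrichmentRecord(dataset, pathway, 5, 10, 20, 100, 0.01,
                                2.5 if status == ACTIVATED else -2.5, status)

    def test_shared_and_specific(self):
        records = [
            self.rec("A", "P1", ACTIVATED),
            self.rec("A", "P2", ACTIVATED),
            self.rec("B", "P1", ACTIVATED),
        ]
        s = venn_summary("g", records)
        assert s.sharing == {"P1": "shared", "P2": "specific"}
        assert s.n_dual == 0

    def test_dual(self):
        records = [self.rec("A", "P1", ACTIVATED), self.rec("B", "P1", INHIBITED)]
        s = venn_summary("g", records)
        assert s.direction["P1"] == "dual" and s.sharing["P1"] == "dual"

    def test_single_dataset_all_specific(self):
        records = [self.rec("A", f"P{i}", ACTIVATED) for i in range(3)]
        s = venn_summary("g", records)
        assert s.n_specific == 3 and s.n_shared == 0

    def test_counts_partition(self, rng):
        # direction labels partition all called pathways
        statuses = [ACTIVATED, INHIBITED]
        records = [
            self.rec(f"D{d}", f"P{p}", statuses[int(rng.integers(2))])
            for d in range(4)
            for p in range(10)
        ]
        s = venn_summary("g", records)
        assert s.n_activated + s.n_inhibited + s.n_dual == len(s.direction)
        assert s.n_shared + s.n_specific + s.n_dual == len(s.sharing)


class TestCrossGroupOverlap:
    def summary(self, group, pathways):
        records = [
            TestVennSummary().rec(f"{group}_ds", p, ACTIVATED) for p in pathways
        ]
        return venn_summary(group, records)

    def test_shared_and_specific_sets(self):
        summaries = {
            "g1": self.summary("g1", ["P1", "P2"]),
            "g2": self.summary("g2", ["P2", "P3"]),
        }
        report = cross_group_overlap(summaries)
        assert report[ACTIVATED]["all_shared"] == ["P2"]
        assert report[ACTIVATED]["specific"]["g1"] == ["P1"]
        assert report[ACTIVATED]["specific"]["g2"] == ["P3"]

    def test_identical_groups_all_shared(self):
        summaries = {
            "g1": self.summary("g1", ["P1", "P2"]),
            "g2": self.summary("g2", ["P1", "P2"]),
        }
        report = cross_group_overlap(summaries)
        assert report[ACTIVATED]["all_shared"] == ["P1", "P2"]
        assert report[ACTIVATED]["specific"] == {"g1": [], "g2": []}

    def test_disjoint_groups_zero_shared(self):
        summaries = {
            "g1": self.summary("g1", ["P1"]),
            "g2": self.summary("g2", ["P2"]),
        }
        assert cross_group_overlap(summaries)[ACTIVATED]["all_shared"] == []

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            cross_group_overlap({"g1": self.summary("g1", ["P1"])})
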
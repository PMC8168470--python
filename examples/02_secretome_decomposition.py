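"""Decompose a contrast's DEGs against the four secretome catalogs.

The four catalogs (canonical, caspase-1, caspase-4, exosome routes) are
pairwise disjoint; each row reports how many of the contrast's up/down
DEGs fall in the catalog and what percent of the total DEG count that is.
"""

from tregsec import (
    SimulationConfig,
    compute_contrast,
    decompose_suite,
    make_catalog_suite,
    simulate_dataset,
    union_size,
    validate_disjoint,
)

# full-scale catalog sizes: 2641 / 961 / 1223 / 6560, union 11,385
suite = make_catalog_suite(seed=0)
report = validate_disjoint(suite.secretomes)
print(f"secretome catalogs disjoint: {report.passed}; "
      f"union of distinct genes: {union_size(suite.secretomes)}")

# simulate a dataset measuring a subset of the catalog universe
universe = sorted(set().union(*(c.genes for c in suite.secretomes)))
config = SimulationConfig(seed=7, n_genes=8000, planted_catalog_deg_rate=0.04)
dataset, truth = simulate_dataset(config, universe=universe[:8000], suite=suite)
contrast = compute_contrast(dataset)

from tregsec.catalogs import CatalogSuite

table = decompose_suite([contrast], CatalogSuite.from_catalogs(suite.secretomes))
print(table.to_string(index=False))
# 'up'/'down' count catalog genes among the DEGs; 'up_pct'/'down_pct' are
# percentages of the contrast's TOTAL DEG count, two decimals.
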
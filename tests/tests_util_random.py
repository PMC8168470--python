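"""Shared random-instance builders for property tests."""

import numpy as np
import pandas as pd

from tregsec.collaboration import RegulatorContrast
from tregsec.de import ContrastResult


def random_contrast(rng, genes, dataset_id="rand"):
    status = rng.choice(["up", "down", "ns"], size=len(genes), p=[0.2, 0.2, 0.6])
    log2fc = np.where(status == "up", 2.0, np.where(status == "down", -2.0, 0.0))
    p = np.where(status == "ns", 1.0, 1e-4)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "q_value": p, "status": status},
        index=pd.Index(genes, name="gene"),
    )
    return ContrastResult(dataset_id, table)


def random_contrast_pair(rng):
    """A random Treg contrast and regulator contrast over partly overlapping
    gene universes (the perturbation misses some Treg genes)."""
    n = int(rng.integers(20, 120))
    genes = [f"G{i}" for i in range(n)]
    treg = random_contrast(rng, genes, "treg")
    keep = max(5, int(0.8 * n))
    pert_genes = list(rng.choice(genes, size=keep, replace=False))
    pert = random_contrast(rng, pert_genes, "pert")
    return treg, RegulatorContrast("custom", "knockout", pert)


def random_ko_pair(rng):
    """Two random KO contrasts over partly overlapping universes."""
    n = int(rng.integers(20, 150))
    genes = [f"G{i}" for i in range(n)]
    keep = max(5, int(0.9 * n))
    a = random_contrast(rng, genes, "nox2")
    b_genes = list(rng.choice(genes, size=keep, replace=False))
    b = random_contrast(rng, b_genes, "nrf2")
    return a, b
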
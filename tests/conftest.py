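import numpy as np
import pandas as pd
import pytest

from tregsec.de import ContrastResult, Thresholds


@pytest.fixture
def make_contrast():
    """Factory building a ContrastResult from explicit up/down/ns gene lists."""

    def build(up=(), down=(), ns=(), dataset_id="toy", thresholds=Thresholds()):
        up, down, ns = list(up), list(down), list(ns)
        genes = up + down + ns
        assert len(set(genes)) == len(genes), "gene lists overlap"
        table = pd.DataFrame(
            {
                "log2fc": [2.0] * len(up) + [-2.0] * len(down) + [0.0] * len(ns),
                "p_value": [1e-4] * (len(up) + len(down)) + [1.0] * len(ns),
                "q_value": [1e-4] * (len(up) + len(down)) + [1.0] * len(ns),
                "status": ["up"] * len(up) + ["down"] * len(down) + ["ns"] * len(ns),
            },
            index=pd.Index(genes, name="gene"),
        )
        return ContrastResult(dataset_id, table, thresholds)

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
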
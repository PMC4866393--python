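import numpy as np
import pandas as pd
import pytest

from coexshift.io import ExpressionMatrix


def make_metadata(n_regions=2, n_per_stratum=4, regions=None):
    regions = regions or [f"R{i}" for i in range(1, n_regions + 1)]
    rows = []
    for window in ("prenatal", "postnatal"):
        for region in regions:
            for t in range(n_per_stratum):
                rows.append(
                    {
                        "sample_id": f"{region}_{window[:4]}_{t}",
                        "region": region,
                        "age": f"t{t}",
                        "window": window,
                    }
                )
    return pd.DataFrame(rows)


def make_expression(n_genes=10, n_regions=2, n_per_stratum=4, seed=0):
    meta = make_metadata(n_regions, n_per_stratum)
    rng = np.random.default_rng(seed)
    values = rng.normal(5.0, 1.0, size=(n_genes, len(meta)))
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    return ExpressionMatrix(gene_ids, values, meta)


@pytest.fixture
def toy_expression():
    return make_expression()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
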
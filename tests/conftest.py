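import numpy as np
import pandas as pd
import pytest

from myomics.design import GroupDesign
from myomics.simulate import make_manifest


@pytest.fixture
def tissue_design() -> GroupDesign:
    """Three samples each of NM, LM and LMS (no cell lines)."""
    return GroupDesign.default(with_cell=False)


@pytest.fixture
def full_design() -> GroupDesign:
    """Three samples each of NM, LM, LMS and cell lines."""
    return GroupDesign.default(with_cell=True)


@pytest.fixture
def small_manifest() -> pd.DataFrame:
    return make_manifest(n_genes=50, seed=7)


def make_track(lrr, baf=None, chrom="1", spacing=10_000) -> pd.DataFrame:
    """Single-chromosome probe track from explicit LRR (and optional BAF)."""
    lrr = np.asarray(lrr, dtype=float)
    n = lrr.size
    if baf is None:
        baf = np.full(n, 0.5)
    return pd.DataFrame(
        {
            "probe_id": [f"rs{i}" for i in range(n)],
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * spacing,
            "lrr": lrr,
            "baf": np.asarray(baf, dtype=float),
            "genotype": "AB",
        }
    )
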
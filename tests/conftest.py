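import numpy as np
import pandas as pd
import pytest

from dpprs.plinkio import PanelGenotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_meta(snps):
    """meta frame from (snp_id, chrom, pos, a1, a2) tuples."""
    return pd.DataFrame(snps, columns=["snp_id", "chrom", "pos", "a1", "a2"])


@pytest.fixture
def small_panel(rng):
    """5 individuals x 4 SNPs dosage panel with one missing genotype."""
    meta = make_meta(
        [
            ("rs1", 1, 100, "A", "G"),
            ("rs2", 1, 200, "C", "T"),
            ("rs3", 2, 50, "G", "A"),
            ("rs4", 2, 150, "T", "C"),
        ]
    )
    vals = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 1],
            [2, 0, 1, np.nan],
            [0, 2, 1, 2],
            [1, 0, 0, 1],
        ],
        dtype=float,
    )
    return PanelGenotypes(vals, meta)
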
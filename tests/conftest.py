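import numpy as np
import pandas as pd
import pytest

from ferroscreen.crispr_screen import ScreenCountTable, rpm_normalize


@pytest.fixture
def small_screen_table():
    """3 genes x 2 sgRNAs, control + one treated sample."""
    sgrnas = [f"g{i}_sg{j}" for i in range(3) for j in range(2)]
    genes = [f"g{i}" for i in range(3) for _ in range(2)]
    counts = pd.DataFrame(
        {
            "DMSO": [100, 120, 90, 110, 100, 100],
            "d4": [800, 900, 95, 105, 100, 100],
        },
        index=sgrnas,
    )
    table = ScreenCountTable(
        counts=counts,
        gene_map=pd.Series(genes, index=sgrnas),
        sample_conditions={"DMSO": "DMSO", "d4": "d4"},
    )
    return rpm_normalize(table)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
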
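import numpy as np
import pandas as pd
import pytest

from gutglyc import generate_cohort
from gutglyc.preprocess import derive_glycaemic_panel
from gutglyc.tables import GenusAbundanceTable


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    table, cohort, truth = generate_cohort(
        n_participants=800, n_genera=24, n_provinces=8, seed=101
    )
    cohort = derive_glycaemic_panel(cohort)
    return table, cohort, truth


def make_table(values, ids=None, genera=None) -> GenusAbundanceTable:
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    genera = genera or [f"g{j}" for j in range(values.shape[1])]
    return GenusAbundanceTable(pd.DataFrame(values, index=ids, columns=genera))
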
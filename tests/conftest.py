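import numpy as np
import pandas as pd
import pytest

from micronet.io_tables import AsvTable
from micronet import synthetic_data as sd


@pytest.fixture
def small_table() -> AsvTable:
    """6 samples x 5 taxa with two stages; hand-set counts."""
    counts = np.array([
        [10, 0, 5, 1, 0],
        [12, 1, 4, 0, 0],
        [8, 0, 6, 2, 1],
        [0, 20, 1, 1, 0],
        [1, 18, 0, 3, 0],
        [2, 25, 2, 0, 1],
    ])
    samples = [f"s{i}" for i in range(1, 7)]
    taxa = [f"t{i}" for i in range(1, 6)]
    meta = pd.DataFrame({"stage": ["early"] * 3 + ["late"] * 3}, index=samples)
    taxonomy = {t: f"k__Bacteria;p__P{i};c__;o__;f__;g__G{i}"
                for i, t in enumerate(taxa)}
    return AsvTable(counts, samples, taxa, taxonomy, meta)


@pytest.fixture(scope="session")
def planted_run():
    """One full-scale synthetic community with planted modules (seed 11)."""
    spec = sd.SyntheticSpec(seed=11,
                            planted_modules=sd.default_module_layout())
    table, truth = sd.generate_community(spec)
    return spec, table, truth
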
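import numpy as np
import pandas as pd
import pytest

import tknet
from tknet.preprocess import AsvCountTable


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset (2 experiments x 2 groups x 8)."""
    return tknet.generate_dataset(tknet.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    counts, host, meta, truth = default_dataset
    return tknet.analyze(counts, host, meta, run_null=False)


@pytest.fixture()
def toy_counts():
    """Tiny hand-checkable count table: 4 samples x 5 ASVs, two experiments."""
    counts = pd.DataFrame(
        [[900, 95, 5, 1, 0],
         [900, 95, 5, 0, 0],
         [850, 120, 10, 0, 0],
         [880, 100, 8, 0, 0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["A1", "A2", "A3", "A4", "A5"],
    )
    tax = pd.Series(
        ["k__Bacteria;p__Firmicutes;c__;o__;f__;g__",
         "k__Bacteria;p__Bacteroidetes;c__;o__;f__;g__",
         "k__Bacteria;p__Firmicutes;c__;o__;f__;g__",
         "k__Bacteria;p__Proteobacteria;c__;o__;f__;g__",
         ""],
        index=counts.columns,
    )
    return AsvCountTable(counts, tax)


@pytest.fixture()
def toy_metadata():
    return pd.DataFrame(
        {
            "experiment": ["Exp1", "Exp1", "Exp2", "Exp2"],
            "group": ["Control", "Treatment", "Control", "Treatment"],
            "cohort": ["c1", "c1", "c2", "c2"],
            "timepoint": ["12wk"] * 4,
        },
        index=["s1", "s2", "s3", "s4"],
    )
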
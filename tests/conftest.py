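import numpy as np
import pandas as pd
import pytest

from gxephos import CohortConfig, PhosphoTable, SampleMeta, generate_cohort, preprocess
from gxephos.regulation import analyse_regulation


@pytest.fixture(scope="session")
def small_cohort():
    """One medium synthetic cohort shared by read-only tests."""
    cfg = CohortConfig(n_phosphopeptides=1000, seed=3)
    table, meta, truth = generate_cohort(cfg)
    return cfg, table, meta, truth


@pytest.fixture(scope="session")
def processed(small_cohort):
    cfg, table, meta, truth = small_cohort
    tab = preprocess(table)
    reg = analyse_regulation(tab, meta)
    return cfg, tab, meta, truth, reg


@pytest.fixture
def tiny_table():
    """Hand-sized intensity table: 3 peptides x 4 samples."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 10.0, 20.0],
            "s2": [2.0, 11.0, np.nan],
            "s3": [3.0, 12.0, 22.0],
            "s4": [4.0, 13.0, 23.0],
        },
        index=pd.Index(["a", "b", "c"], name="peptide_id"),
    )
    loc = pd.Series([0.9, 0.8, 0.76], index=values.index)
    return PhosphoTable(values, loc)


@pytest.fixture
def two_by_two_meta():
    """Minimal 2-strain x 2-diet x 2-treatment design, 3 replicates/cell."""
    rows = []
    for strain in ("A", "B"):
        for diet in ("CHOW", "HFD"):
            for treat in ("unstimulated", "insulin"):
                for rep in range(1, 4):
                    rows.append(
                        {
                            "sample_id": f"{strain}_{diet}_{treat}_{rep}",
                            "strain": strain,
                            "diet": diet,
                            "treatment": treat,
                            "replicate": rep,
                        }
                    )
    return SampleMeta(pd.DataFrame(rows))
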
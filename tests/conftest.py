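import numpy as np
import pandas as pd
import pytest

from psacorrect.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def sim_cohort():
    """A moderate synthetic screened cohort under default study conditions."""
    return simulate_cohort(SimulationConfig(n_population=6000, seed=42))


@pytest.fixture
def make_cohort_file(tmp_path):
    """Write a list of row dicts as a TSV cohort file and return its path."""

    def _make(rows, filename="cohort.tsv", columns=None):
        df = pd.DataFrame(rows, columns=columns)
        path = tmp_path / filename
        df.to_csv(path, sep="\t", index=False)
        return path

    return _make


@pytest.fixture
def basic_rows():
    """Two fully valid subjects with the 4-SNP PSA panel."""
    return [
        {"subject_id": "A1", "psa": 4.2, "age": 61.0, "centre": "Bristol",
         "gleason": 6, "stage": "T1", "rs2736098": 1, "rs10788160": 0,
         "rs11067228": 2, "rs17632542": 2},
        {"subject_id": "A2", "psa": 6.8, "age": 64.5, "centre": "Leeds",
         "gleason": 7, "stage": "T2a", "rs2736098": 0, "rs10788160": 1,
         "rs11067228": 1, "rs17632542": 1},
    ]
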
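import numpy as np
import pandas as pd
import pytest

from yhap.calling import call_cohort
from yhap.fixtures import TOTAL_COHORT_N, table1_cohort, table1_counts, table1_tree
from yhap.frequency import build_frequency_table
from yhap.genotype_io import GenotypeMatrix, region_series


def matrix_from_rows(rows: dict[str, dict[str, str]]) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {sample: {marker: call}} (missing -> N)."""
    df = pd.DataFrame.from_dict(rows, orient="index").fillna("N")
    df.index.name = "sample_id"
    return GenotypeMatrix(df)


def random_call_matrix(seed: int, n_samples: int = 12, n_markers: int = 8,
                       p=(0.5, 0.3, 0.2)) -> GenotypeMatrix:
    rng = np.random.default_rng(seed)
    values = rng.choice(["A", "D", "N"], size=(n_samples, n_markers), p=list(p))
    return GenotypeMatrix(pd.DataFrame(
        values, index=[f"S{i}" for i in range(n_samples)],
        columns=[f"M{j}" for j in range(n_markers)]))


@pytest.fixture(scope="session")
def fig1_tree():
    return table1_tree()


@pytest.fixture(scope="session")
def table1_reference():
    return table1_counts()


@pytest.fixture(scope="session")
def fixture_cohort():
    """(matrix, truth, metadata) regenerated from the published counts."""
    return table1_cohort()


@pytest.fixture(scope="session")
def fixture_assignments(fig1_tree, fixture_cohort):
    matrix, _truth, _meta = fixture_cohort
    return call_cohort(fig1_tree, matrix)


@pytest.fixture(scope="session")
def fixture_table(fig1_tree, fixture_cohort, fixture_assignments):
    _matrix, _truth, meta = fixture_cohort
    return build_frequency_table(fixture_assignments, region_series(meta),
                                 TOTAL_COHORT_N, fig1_tree)
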
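import numpy as np
import pandas as pd
import pytest

from responderomics.synthetic import SimulationParams, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated cohort shared by read-only tests."""
    return simulate_all(SimulationParams(n_genes=800, seed=1))


@pytest.fixture(scope="session")
def small_sheet(small_sim):
    return small_sim["sheet"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def baseline_design(small_sim):
    """Subjects x genes baseline design over the planted baseline genes."""
    sim = small_sim
    sheet, expr, truth = sim["sheet"], sim["expression"], sim["truth"]
    w0 = sheet.table[sheet.table["timepoint"] == "w0"]
    X = (
        expr.subset_features(truth.baseline_diff_genes)
        .subset_samples(w0["sample_id"].tolist())
        .to_frame()
        .T
    )
    X.index = w0["subject_id"].tolist()
    y = pd.Series(sheet.subject_outcome()).loc[X.index]
    return X, y
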
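import numpy as np
import pandas as pd
import pytest


def make_ct_rows(sample_id, mirna_id, values, plate_id="p1"):
    return [
        {"sample_id": sample_id, "mirna_id": mirna_id, "replicate": i,
         "plate_id": plate_id, "ct": v}
        for i, v in enumerate(values, start=1)
    ]


@pytest.fixture
def triplicate_qc_fixture():
    """12-well plate exercising every QC flag, with hand-computed outcomes."""
    rows = []
    rows += make_ct_rows("A", "m1", [25.0, 25.1, 25.2])        # pass, mean 25.1
    rows += make_ct_rows("A", "m2", [25.0, 25.0, 25.0])        # pass, SD 0
    rows += make_ct_rows("B", "m1", [25.0, 25.1, 27.0])        # rescued_pair, 25.05
    rows += make_ct_rows("B", "m2", [24.0, 25.0, 26.0])        # fail_sd (no pair works)
    return pd.DataFrame(rows)


@pytest.fixture
def delta_ct_fixture():
    """Worked 2-sample example: target C_T {24, 26}, reference {20, 20}."""
    rows = []
    rows += make_ct_rows("A", "target", [24.0] * 3)
    rows += make_ct_rows("B", "target", [26.0] * 3)
    rows += make_ct_rows("A", "miR-16", [20.0] * 3)
    rows += make_ct_rows("B", "miR-16", [20.0] * 3)
    return pd.DataFrame(rows)


@pytest.fixture
def logistic_8sample_fixture():
    """Tiny printed dataset for oracle comparison: one predictor, n=8."""
    x = np.array([-1.2, -0.7, -0.3, 0.1, -0.2, 0.4, 0.9, 1.5])
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    return x.reshape(-1, 1), y


@pytest.fixture
def separable_labels():
    rng = np.random.default_rng(42)
    x = np.concatenate([rng.normal(0.9, 0.01, 10), rng.normal(0.1, 0.01, 10)])
    y = np.array([1] * 10 + [0] * 10)
    return x, y
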